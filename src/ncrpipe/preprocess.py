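"""Scan/schedule modelling, stimulus-wise concatenation, and the systemic regressor.

An fNIRS recording is modelled as a channels x samples matrix of [HbO]
concentration changes sampled at a fixed rate (1.77 Hz for the 16-channel
forehead probe this pipeline was designed around).  A Stroop session is a
block design: blocks of five stimuli of one type (neutral N, congruent C,
incongruent I) separated by rests.  Connectivity is computed per stimulus
type on the task blocks of that type, concatenated in temporal order.

The systemic regressor is the channel average of the high-pass-filtered
[HbO] signals: background physiology (blood pressure waves, respiration
aliased into the recording) is common to all channels, so its channel
average is used downstream to partial it out of every channel pair.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "STIM_TYPES",
    "REST",
    "ProbeLayout",
    "HbOScan",
    "StimulusEvent",
    "BlockDesign",
    "StimulusSchedule",
    "FilterSpec",
    "ConcatenatedSeries",
    "Regressor",
    "make_schedule",
    "extract_concatenated",
    "segment_bounds",
    "apply_filter",
    "build_regressor",
    "read_scan_csv",
    "write_scan_csv",
    "read_snirf",
    "read_schedule",
    "write_schedule",
    "read_behavior_csv",
    "write_behavior_csv",
]

STIM_TYPES = ("N", "C", "I")
REST = "REST"

DEFAULT_FS = 1.77  # Hz


def _round_half_up(x: float) -> int:
    """Deterministic half-up rounding (3.5 -> 4), unlike numpy's banker's rounding."""
    return int(math.floor(x + 0.5))


@dataclass(frozen=True)
class ProbeLayout:
    """Optode geometry metadata for a rectangular forehead probe.

    Four LEDs (L1..L4) and ten shared detectors (D1..D10) at 2.5 cm
    separation yield 16 channels.  Only ``n_channels`` and the labels are
    used computationally; sources/detectors are carried as metadata.
    """

    n_channels: int = 16
    labels: tuple[str, ...] = ()
    sources: tuple[str, ...] = tuple(f"L{i}" for i in range(1, 5))
    detectors: tuple[str, ...] = tuple(f"D{i}" for i in range(1, 11))
    sd_distance_cm: float = 2.5

    def __post_init__(self):
        if self.n_channels < 2:
            raise ValueError("a probe needs at least 2 channels")
        if not self.labels:
            object.__setattr__(
                self, "labels", tuple(f"C{i}" for i in range(1, self.n_channels + 1))
            )
        if len(self.labels) != self.n_channels:
            raise ValueError("number of labels must match n_channels")
        if len(set(self.labels)) != self.n_channels:
            raise ValueError("channel labels must be unique")


@dataclass
class HbOScan:
    """One subject's [HbO] recording: channels x samples, plus metadata."""

    data: np.ndarray
    fs: float = DEFAULT_FS
    subject_id: str = ""
    group: str = ""
    layout: ProbeLayout | None = None

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("scan data must be a 2-D channels x samples matrix")
        if self.data.shape[1] == 0:
            raise ValueError("scan contains no samples")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if np.isnan(self.data).any():
            raise ValueError("scan contains missing (NaN) samples; gaps are an input error")
        if self.layout is None:
            self.layout = ProbeLayout(n_channels=self.data.shape[0])
        elif self.layout.n_channels != self.data.shape[0]:
            raise ValueError("scan row count does not match probe layout")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass(frozen=True, order=True)
class StimulusEvent:
    onset: float
    duration: float
    type: str

    def __post_init__(self):
        if self.duration <= 0:
            raise ValueError("event duration must be positive")
        if self.onset < 0:
            raise ValueError("event onset must be non-negative")

    @property
    def offset(self) -> float:
        return self.onset + self.duration


@dataclass(frozen=True)
class BlockDesign:
    """Block-design parameters of the Stroop session.

    Defaults reproduce the session used throughout: 15 stimuli per type in
    blocks of five, 4 s inter-stimulus interval (so 20 s task blocks), 20 s
    rests between blocks and 30 s leading/trailing rest — 400 s in total.
    """

    stimuli_per_type: int = 15
    block_size: int = 5
    isi: float = 4.0
    inter_block_rest: float = 20.0
    lead_rest: float = 30.0
    trail_rest: float = 30.0
    stim_types: tuple[str, ...] = STIM_TYPES

    @property
    def block_duration(self) -> float:
        return self.block_size * self.isi

    @property
    def blocks_per_type(self) -> int:
        if self.stimuli_per_type % self.block_size:
            raise ValueError(
                f"stimuli_per_type={self.stimuli_per_type} not divisible by "
                f"block_size={self.block_size}"
            )
        return self.stimuli_per_type // self.block_size

    @property
    def total_duration(self) -> float:
        n_blocks = self.blocks_per_type * len(self.stim_types)
        return (
            self.lead_rest
            + n_blocks * self.block_duration
            + (n_blocks - 1) * self.inter_block_rest
            + self.trail_rest
        )


@dataclass
class StimulusSchedule:
    """Time-ordered, non-overlapping task/rest events of one session."""

    events: tuple[StimulusEvent, ...]
    design: BlockDesign | None = None

    def __post_init__(self):
        self.events = tuple(self.events)
        prev_end = -np.inf
        for ev in self.events:
            if ev.onset < prev_end - 1e-9:
                raise ValueError("schedule events overlap or are out of order")
            prev_end = ev.offset

    @property
    def duration(self) -> float:
        return self.events[-1].offset if self.events else 0.0

    def events_of(self, stim_type: str) -> tuple[StimulusEvent, ...]:
        return tuple(ev for ev in self.events if ev.type == stim_type)

    @property
    def stim_types(self) -> tuple[str, ...]:
        seen = []
        for ev in self.events:
            if ev.type != REST and ev.type not in seen:
                seen.append(ev.type)
        return tuple(sorted(seen))


def make_schedule(design: BlockDesign = BlockDesign(), seed: int = 0) -> StimulusSchedule:
    """Build a randomized block schedule: seeded permutation of the task blocks.

    Raises if the per-type stimulus count is not divisible by the block size
    (blocks must be homogeneous).
    """
    for st in design.stim_types:
        if design.stimuli_per_type % design.block_size:
            raise ValueError(
                f"stimulus type {st!r}: {design.stimuli_per_type} stimuli cannot be "
                f"split into blocks of {design.block_size}"
            )
    blocks = [st for st in design.stim_types for _ in range(design.blocks_per_type)]
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(blocks))
    events: list[StimulusEvent] = [StimulusEvent(0.0, design.lead_rest, REST)]
    t = design.lead_rest
    for i, k in enumerate(order):
        events.append(StimulusEvent(t, design.block_duration, blocks[k]))
        t += design.block_duration
        if i < len(blocks) - 1:
            events.append(StimulusEvent(t, design.inter_block_rest, REST))
            t += design.inter_block_rest
    events.append(StimulusEvent(t, design.trail_rest, REST))
    return StimulusSchedule(tuple(events), design=design)


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter specification for the systemic regressor.

    The default is an 8th-order high-pass whose pass-band edge sits at the
    upper corner (0.1 Hz) with the transition reaching down to 0.09 Hz; the
    sense is configurable to low-pass, in which case the lower corner is the
    edge.  Zero-phase (forward-backward) application is the default so the
    regressor carries no group delay into the correlation analysis.
    """

    order: int = 8
    mode: str = "highpass"
    corner_hz: float = 0.09
    stop_hz: float = 0.1
    application: str = "zero-phase"

    def __post_init__(self):
        if self.order < 1:
            raise ValueError("filter order must be >= 1")
        if self.mode not in ("highpass", "lowpass"):
            raise ValueError("mode must be 'highpass' or 'lowpass'")
        if self.application not in ("zero-phase", "causal"):
            raise ValueError("application must be 'zero-phase' or 'causal'")
        if not (0 < self.corner_hz and 0 < self.stop_hz):
            raise ValueError("corner frequencies must be positive")

    @property
    def edge_hz(self) -> float:
        return max(self.corner_hz, self.stop_hz) if self.mode == "highpass" else min(
            self.corner_hz, self.stop_hz
        )

    def sos(self, fs: float) -> np.ndarray:
        nyq = fs / 2.0
        if not self.edge_hz < nyq:
            raise ValueError("filter edge must lie below the Nyquist frequency")
        return sps.butter(self.order, self.edge_hz / nyq, btype=self.mode, output="sos")

    def gain(self, freq_hz: float, fs: float) -> float:
        """Magnitude response of the designed digital filter at ``freq_hz``.

        For zero-phase application the forward-backward pass squares the
        magnitude response.
        """
        w = 2 * np.pi * freq_hz / fs
        _, h = sps.sosfreqz(self.sos(fs), worN=[w])
        g = float(np.abs(h[0]))
        return g * g if self.application == "zero-phase" else g


def apply_filter(series: np.ndarray, fs: float, spec: FilterSpec = FilterSpec()) -> np.ndarray:
    """Filter a 1-D series (or each row of a 2-D array) with the given spec."""
    x = np.asarray(series, dtype=float)
    n = x.shape[-1]
    if n <= 3 * spec.order:
        raise ValueError(
            f"series of length {n} too short for order-{spec.order} zero-phase filtering"
        )
    sos = spec.sos(fs)
    if spec.application == "zero-phase":
        return sps.sosfiltfilt(sos, x, axis=-1)
    return sps.sosfilt(sos, x, axis=-1)


@dataclass
class ConcatenatedSeries:
    """Stimulus-wise concatenation of one or more series, with segment bounds.

    ``boundaries`` are the cumulative sample offsets of the segment edges in
    the concatenated array (``0, n1, n1+n2, ...``); ``source_bounds`` are the
    half-open sample windows in the source recording.
    """

    values: np.ndarray
    stim_type: str
    boundaries: tuple[int, ...]
    source_bounds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        b = tuple(self.boundaries)
        if list(b) != sorted(set(b)):
            raise ValueError("segment boundaries must be strictly increasing")
        if b and b[-1] != self.values.shape[-1]:
            raise ValueError("segment lengths do not sum to the concatenated length")
        self.boundaries = b

    @property
    def n_segments(self) -> int:
        return max(len(self.boundaries) - 1, 0)


@dataclass
class Regressor:
    """Channel-averaged filtered [HbO] series spanning the whole scan."""

    values: np.ndarray
    fs: float
    spec: FilterSpec

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("regressor must be a single series")


def segment_bounds(
    schedule: StimulusSchedule, stim_type: str, fs: float, n_samples: int
) -> tuple[tuple[int, int], ...]:
    """Half-open sample windows of the blocks of ``stim_type``, onset order.

    Onsets map to samples by half-up rounding of ``onset*fs``; each window
    holds ``round(duration*fs)`` samples.
    """
    events = schedule.events_of(stim_type)
    if not events:
        raise ValueError(f"stimulus type {stim_type!r} does not occur in the schedule")
    bounds = []
    for ev in sorted(events, key=lambda e: e.onset):
        start = _round_half_up(ev.onset * fs)
        stop = start + _round_half_up(ev.duration * fs)
        if stop > n_samples:
            raise ValueError(
                f"event {ev.type} at {ev.onset:g}s extends past the end of the scan"
            )
        bounds.append((start, stop))
    return tuple(bounds)


def extract_concatenated(
    series: HbOScan | Regressor | np.ndarray,
    schedule: StimulusSchedule,
    stim_type: str,
    fs: float | None = None,
) -> ConcatenatedSeries:
    """Concatenate the blocks of one stimulus type, in onset order.

    Sample values are copied bit-exactly; no resampling or detrending.
    Accepts a scan (channels x samples), a regressor, or a raw array (which
    then needs ``fs``).
    """
    if isinstance(series, HbOScan):
        data, fs = series.data, series.fs
    elif isinstance(series, Regressor):
        data, fs = series.values, series.fs
    else:
        if fs is None:
            raise ValueError("fs is required when passing a raw array")
        data = np.asarray(series, dtype=float)
    bounds = segment_bounds(schedule, stim_type, fs, data.shape[-1])
    pieces = [data[..., a:b] for a, b in bounds]
    lengths = [b - a for a, b in bounds]
    boundaries = tuple(np.cumsum([0] + lengths).tolist())
    return ConcatenatedSeries(
        np.concatenate(pieces, axis=-1), stim_type, boundaries, source_bounds=bounds
    )


def build_regressor(scan: HbOScan, spec: FilterSpec = FilterSpec()) -> Regressor:
    """Channel average of the filtered [HbO] signals over the full scan.

    The average (rather than the sum) is used; correlation-based statistics
    are invariant to the scale, and the mean keeps concentration units.
    """
    if scan.n_channels == 0 or scan.n_samples == 0:
        raise ValueError("cannot build a regressor from an empty scan")
    filtered = apply_filter(scan.data, scan.fs, spec)
    return Regressor(filtered.mean(axis=0), scan.fs, spec)


# ---------------------------------------------------------------------------
# I/O: delimited-text scans, JSON/TSV schedules, CSV behavioral records
# ---------------------------------------------------------------------------

def write_scan_csv(scan: HbOScan, path, sidecar: bool = True) -> None:
    """One column per channel, header row with channel labels; fs in a JSON sidecar."""
    df = pd.DataFrame(scan.data.T, columns=list(scan.layout.labels))
    df.to_csv(path, index=False)
    if sidecar:
        meta = {"fs": scan.fs, "subject_id": scan.subject_id, "group": scan.group}
        with open(str(path) + ".json", "w") as fh:
            json.dump(meta, fh)


def read_scan_csv(path, fs: float | None = None, subject_id: str = "", group: str = "") -> HbOScan:
    meta = {}
    try:
        with open(str(path) + ".json") as fh:
            meta = json.load(fh)
    except FileNotFoundError:
        pass
    if fs is None:
        fs = meta.get("fs")
    if fs is None:
        raise ValueError("sampling rate not given and no sidecar JSON found")
    df = pd.read_csv(path)
    layout = ProbeLayout(n_channels=df.shape[1], labels=tuple(df.columns))
    return HbOScan(
        df.to_numpy().T,
        fs=float(fs),
        subject_id=subject_id or meta.get("subject_id", ""),
        group=group or meta.get("group", ""),
        layout=layout,
    )


def read_snirf(path, subject_id: str = "", group: str = "") -> HbOScan:
    """Minimal SNIRF (HDF5) reader: maps /nirs/data1 to a scan.

    Reads ``dataTimeSeries`` (time x channels) and derives the sampling rate
    from the ``time`` vector.  Intended for pre-converted [HbO] series only.
    """
    import h5py

    with h5py.File(path, "r") as fh:
        data = np.asarray(fh["/nirs/data1/dataTimeSeries"]).T
        t = np.asarray(fh["/nirs/data1/time"]).ravel()
    if t.size >= 2:
        fs = 1.0 / float(np.median(np.diff(t)))
    elif t.size == 1:  # SNIRF allows [start, dt]
        fs = 1.0 / float(t[0])
    else:
        raise ValueError("SNIRF file carries no time information")
    return HbOScan(data, fs=fs, subject_id=subject_id, group=group)


def write_schedule(schedule: StimulusSchedule, path) -> None:
    path = str(path)
    rows = [(ev.type, ev.onset, ev.duration) for ev in schedule.events]
    if path.endswith(".json"):
        with open(path, "w") as fh:
            json.dump([{"type": t, "onset_s": o, "duration_s": d} for t, o, d in rows], fh)
    else:
        pd.DataFrame(rows, columns=["type", "onset_s", "duration_s"]).to_csv(
            path, sep="\t", index=False
        )


def read_schedule(path) -> StimulusSchedule:
    path = str(path)
    if path.endswith(".json"):
        with open(path) as fh:
            rows = json.load(fh)
        events = [StimulusEvent(r["onset_s"], r["duration_s"], r["type"]) for r in rows]
    else:
        df = pd.read_csv(path, sep="\t")
        events = [
            StimulusEvent(o, d, t) for t, o, d in df[["type", "onset_s", "duration_s"]].itertuples(index=False)
        ]
    return StimulusSchedule(tuple(sorted(events, key=lambda e: e.onset)))


def write_behavior_csv(records, path) -> None:
    """Rows: subject_id, group, stim_type, acc_percent, rt_ms."""
    rows = []
    for rec in records:
        for st in STIM_TYPES:
            rows.append(
                {
                    "subject_id": rec.subject_id,
                    "group": rec.group,
                    "stim_type": st,
                    "acc_percent": rec.acc[st],
                    "rt_ms": rec.rt[st] * 1000.0,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_behavior_csv(path):
    """Read behavioral records; RT is accepted in ms and stored in seconds."""
    from .biomarker_stats import BehavioralRecord

    df = pd.read_csv(path)
    records = []
    for (sid, grp), sub in df.groupby(["subject_id", "group"], sort=False):
        acc = dict(zip(sub["stim_type"], sub["acc_percent"]))
        rt = {st: v / 1000.0 for st, v in zip(sub["stim_type"], sub["rt_ms"])}
        records.append(BehavioralRecord(subject_id=str(sid), group=str(grp), acc=acc, rt=rt))
    return records
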