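import numpy as np
import pytest

from ncrpipe import (
    BlockDesign,
    FilterSpec,
    HbOScan,
    ProbeLayout,
    Regressor,
    StimulusEvent,
    StimulusSchedule,
    apply_filter,
    build_regressor,
    extract_concatenated,
    make_schedule,
    read_behavior_csv,
    read_scan_csv,
    read_schedule,
    write_behavior_csv,
    write_scan_csv,
    write_schedule,
)
from ncrpipe.biomarker_stats import BehavioralRecord
from ncrpipe.preprocess import REST, segment_bounds


class TestSchedule:
    def test_default_design_block_structure(self):
        sched = make_schedule(BlockDesign(), seed=0)
        task = [ev for ev in sched.events if ev.type != REST]
        assert len(task) == 9
        assert all(ev.duration == 20.0 for ev in task)
        assert sorted(ev.type for ev in task) == sorted("NNN" "CCC" "III")

    def test_default_total_duration_400s(self):
        # 30 lead + 9 blocks x 20 + 8 rests x 20 + 30 trail
        sched = make_schedule(BlockDesign(), seed=3)
        assert sched.duration == pytest.approx(400.0)
        assert sched.events[0].type == REST and sched.events[0].duration == 30.0
        assert sched.events[-1].type == REST and sched.events[-1].duration == 30.0

    def test_seeded_determinism_and_randomization(self):
        a = make_schedule(seed=5)
        b = make_schedule(seed=5)
        assert [ev.type for ev in a.events] == [ev.type for ev in b.events]
        orders = {tuple(ev.type for ev in make_schedule(seed=s).events) for s in range(8)}
        assert len(orders) > 1  # block order is actually randomized

    def test_non_divisible_counts_name_the_offender(self):
        with pytest.raises(ValueError, match="N"):
            make_schedule(BlockDesign(stimuli_per_type=14), seed=0)

    def test_overlapping_events_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            StimulusSchedule(
                (StimulusEvent(0.0, 30.0, "N"), StimulusEvent(10.0, 30.0, "C"))
            )


class TestExtractConcatenated:
    def test_three_blocks_at_fnirs_rate(self, default_schedule):
        # round(20 * 1.77) = 35 samples per block
        n = int(default_schedule.duration * 1.77 + 0.5)
        scan = HbOScan(np.arange(16 * n, dtype=float).reshape(16, n), fs=1.77)
        cat = extract_concatenated(scan, default_schedule, "N")
        assert cat.n_segments == 3
        assert cat.values.shape == (16, 105)
        assert cat.boundaries == (0, 35, 70, 105)

    def test_values_copied_bit_exactly(self, default_schedule):
        n = int(default_schedule.duration * 1.77 + 0.5)
        g = np.random.default_rng(0)
        scan = HbOScan(g.standard_normal((16, n)), fs=1.77)
        cat = extract_concatenated(scan, default_schedule, "I")
        for (a, b), lo, hi in zip(
            cat.source_bounds, cat.boundaries[:-1], cat.boundaries[1:]
        ):
            assert np.array_equal(cat.values[:, lo:hi], scan.data[:, a:b])

    def test_single_segment_is_identity_slice(self):
        sched = StimulusSchedule(
            (StimulusEvent(0.0, 10.0, REST), StimulusEvent(10.0, 20.0, "N"))
        )
        scan = HbOScan(np.random.default_rng(1).standard_normal((4, 60)), fs=2.0)
        cat = extract_concatenated(scan, sched, "N")
        assert np.array_equal(cat.values, scan.data[:, 20:60])

    def test_absent_type_errors(self, default_schedule, small_scan):
        with pytest.raises(ValueError, match="does not occur"):
            extract_concatenated(small_scan, default_schedule, "X")

    def test_event_past_scan_end_errors(self, default_schedule):
        short = HbOScan(np.zeros((16, 100)), fs=1.77)
        with pytest.raises(ValueError, match="past the end"):
            extract_concatenated(short, default_schedule, "N")

    def test_half_up_onset_rounding(self):
        # onset 1.25 s at fs=2 -> sample 2.5 -> half-up 3
        sched = StimulusSchedule((StimulusEvent(1.25, 2.0, "N"),))
        bounds = segment_bounds(sched, "N", fs=2.0, n_samples=100)
        assert bounds == ((3, 7),)


class TestFilter:
    def test_highpass_kills_dc(self):
        out = apply_filter(np.full(400, 5.0), fs=1.77)
        assert np.max(np.abs(out)) < 1e-6 * 5.0

    @pytest.mark.parametrize(
        "freq,check",
        [(0.3, lambda gain: gain > 0.99), (0.01, lambda gain: gain < 0.05)],
    )
    def test_gain_matches_designed_transfer_function(self, freq, check):
        fs, spec = 1.77, FilterSpec()
        t = np.arange(4000) / fs
        x = np.sin(2 * np.pi * freq * t)
        y = apply_filter(x, fs, spec)
        measured = np.std(y[500:-500]) / np.std(x[500:-500])
        designed = spec.gain(freq, fs)
        assert check(measured)
        assert measured == pytest.approx(designed, abs=0.02)

    def test_linearity(self, rng):
        x = rng.standard_normal(300)
        y = rng.standard_normal(300)
        lhs = apply_filter(2.0 * x + 3.0 * y, 1.77)
        rhs = 2.0 * apply_filter(x, 1.77) + 3.0 * apply_filter(y, 1.77)
        assert np.allclose(lhs, rhs, atol=1e-10)

    def test_zero_phase_no_group_delay(self):
        fs = 1.77
        t = np.arange(2000) / fs
        x = np.sin(2 * np.pi * 0.25 * t)
        y = apply_filter(x, fs)
        xc = np.correlate(y[200:-200], x[200:-200], mode="full")
        lag = int(np.argmax(xc)) - (len(x) - 401)
        assert lag == 0

    def test_too_short_series_errors(self):
        with pytest.raises(ValueError, match="too short"):
            apply_filter(np.ones(10), 1.77)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            FilterSpec(mode="bandpass")
        with pytest.raises(ValueError):
            FilterSpec(order=0)
        with pytest.raises(ValueError, match="Nyquist"):
            FilterSpec(corner_hz=0.9, stop_hz=1.0).sos(1.77)


class TestRegressor:
    def test_identical_channels_equal_filtered_channel(self):
        row = np.random.default_rng(2).standard_normal(300)
        scan = HbOScan(np.tile(row, (16, 1)), fs=1.77)
        reg = build_regressor(scan)
        assert np.allclose(reg.values, apply_filter(row, 1.77), atol=1e-12)

    def test_channel_permutation_invariance(self, control_scan):
        reg = build_regressor(control_scan)
        perm = np.random.default_rng(3).permutation(16)
        shuffled = HbOScan(control_scan.data[perm], fs=control_scan.fs)
        assert np.allclose(build_regressor(shuffled).values, reg.values)

    def test_full_scan_length(self, control_scan):
        reg = build_regressor(control_scan)
        assert reg.values.shape == (control_scan.n_samples,)

    def test_concatenation_shares_channel_boundaries(self, control_scan, default_schedule):
        reg = build_regressor(control_scan)
        cat_ch = extract_concatenated(control_scan, default_schedule, "C")
        cat_reg = extract_concatenated(reg, default_schedule, "C")
        assert cat_ch.boundaries == cat_reg.boundaries


class TestScanValidation:
    def test_nan_samples_rejected(self):
        data = np.zeros((4, 100))
        data[2, 50] = np.nan
        with pytest.raises(ValueError, match="missing"):
            HbOScan(data)

    def test_bad_rate_and_layout(self):
        with pytest.raises(ValueError):
            HbOScan(np.zeros((4, 100)), fs=0.0)
        with pytest.raises(ValueError, match="layout"):
            HbOScan(np.zeros((4, 100)), layout=ProbeLayout(n_channels=16))

    def test_probe_labels_unique(self):
        with pytest.raises(ValueError, match="unique"):
            ProbeLayout(n_channels=2, labels=("C1", "C1"))


class TestIO:
    def test_scan_csv_roundtrip(self, tmp_path, control_scan):
        path = tmp_path / "scan.csv"
        write_scan_csv(control_scan, path)
        back = read_scan_csv(path)
        assert back.fs == control_scan.fs
        assert np.allclose(back.data, control_scan.data)
        assert back.layout.labels == control_scan.layout.labels

    @pytest.mark.parametrize("name", ["sched.json", "sched.tsv"])
    def test_schedule_roundtrip(self, tmp_path, default_schedule, name):
        path = tmp_path / name
        write_schedule(default_schedule, path)
        back = read_schedule(path)
        assert [(e.type, e.onset, e.duration) for e in back.events] == [
            (e.type, e.onset, e.duration) for e in default_schedule.events
        ]

    def test_snirf_reader_maps_time_series(self, tmp_path):
        import h5py
        from ncrpipe import read_snirf

        g = np.random.default_rng(5)
        data = g.standard_normal((120, 16))  # SNIRF stores time x channels
        path = tmp_path / "scan.snirf"
        with h5py.File(path, "w") as fh:
            fh.create_dataset("/nirs/data1/dataTimeSeries", data=data)
            fh.create_dataset("/nirs/data1/time", data=np.arange(120) / 1.77)
        scan = read_snirf(path, subject_id="s9")
        assert scan.data.shape == (16, 120)
        assert scan.fs == pytest.approx(1.77, rel=1e-6)
        assert np.allclose(scan.data, data.T)

    def test_behavior_roundtrip_ms_to_seconds(self, tmp_path):
        rec = BehavioralRecord(
            subject_id="s1",
            group="control",
            acc={"N": 98.2, "C": 97.2, "I": 92.8},
            rt={"N": 0.9757, "C": 1.0418, "I": 1.1706},
        )
        path = tmp_path / "behavior.csv"
        write_behavior_csv([rec], path)
        back = read_behavior_csv(path)
        assert back[0].rt["N"] == pytest.approx(0.9757)
        assert back[0].acc["I"] == pytest.approx(92.8)
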