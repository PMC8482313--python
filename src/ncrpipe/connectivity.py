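"""Stimulus-wise partial-correlation functional connectivity.

For each stimulus type the FC matrix holds, for every channel pair (i, j),
the first-order partial correlation r_{ij|k}: the Pearson correlation
between the two concatenated, *unprocessed* [HbO] series after removing the
linear effect of the common systemic regressor k,

    r_{ij|k} = (r_ij - r_ik r_jk) / sqrt((1 - r_ik^2)(1 - r_jk^2)).

Only the regressor is filtered; channel series enter raw.  Means are
removed over the concatenated series as a whole (concatenate first,
correlate second), not per segment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import (
    HbOScan,
    Regressor,
    StimulusSchedule,
    extract_concatenated,
)

__all__ = ["FCMatrix", "partial_correlation", "build_fc", "read_fc_csv", "write_fc_csv"]


@dataclass
class FCMatrix:
    """Symmetric partial-correlation connectivity matrix for one stimulus type.

    The diagonal is fixed to 1 by convention and is excluded from all
    downstream thresholding.
    """

    values: np.ndarray
    stim_type: str = ""
    subject_id: str = ""
    labels: tuple[str, ...] = ()
    n_samples: int | None = None  # concatenated series length behind the estimate

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("FC matrix must be square")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("FC matrix must be symmetric")
        off = v[~np.eye(v.shape[0], dtype=bool)]
        if off.size and (np.abs(off) > 1 + 1e-9).any():
            raise ValueError("off-diagonal FC entries must lie in [-1, 1]")
        self.values = v
        if not self.labels:
            self.labels = tuple(f"C{i}" for i in range(1, v.shape[0] + 1))

    @property
    def n_channels(self) -> int:
        return self.values.shape[0]


def partial_correlation(x: np.ndarray, y: np.ndarray, z: np.ndarray) -> float:
    """First-order partial correlation of ``x`` and ``y`` given ``z``.

    Equivalent to the Pearson correlation of the residuals of x and y after
    least-squares regression on z.  Degenerate inputs (zero variance, or a
    control series perfectly correlated with x or y) raise rather than
    returning NaN.
    """
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    z = np.asarray(z, float).ravel()
    n = x.size
    if y.size != n or z.size != n:
        raise ValueError("series must have equal lengths")
    if n < 3:
        raise ValueError("need at least 3 samples")
    xs = np.vstack([x, y, z])
    sd = xs.std(axis=1)
    if (sd == 0).any():
        which = ["x", "y", "z"][int(np.argmax(sd == 0))]
        raise ValueError(f"series {which} has zero variance")
    r = np.corrcoef(xs)
    r_xy, r_xz, r_yz = r[0, 1], r[0, 2], r[1, 2]
    if min(1 - r_xz**2, 1 - r_yz**2) <= 1e-15:
        raise ValueError("control series is perfectly correlated with an input")
    val = (r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    return float(np.clip(val, -1.0, 1.0))


def build_fc(
    scan: HbOScan,
    regressor: Regressor,
    schedule: StimulusSchedule,
    stim_type: str,
) -> FCMatrix:
    """Partial-correlation FC matrix of one stimulus type.

    Channels and the regressor are concatenated over identical segment
    boundaries; every unordered channel pair gets r_{ij|k} with k the
    concatenated regressor.
    """
    if regressor.values.shape[0] != scan.n_samples:
        raise ValueError("regressor length does not match the scan")
    cat = extract_concatenated(scan, schedule, stim_type)
    cat_reg = extract_concatenated(regressor, schedule, stim_type)
    if cat.boundaries != cat_reg.boundaries:
        raise AssertionError("channel and regressor segment boundaries diverge")

    ch = cat.values  # (n_channels, n_samples)
    sd = ch.std(axis=1)
    if (sd == 0).any():
        bad = scan.layout.labels[int(np.argmax(sd == 0))]
        raise ValueError(f"channel {bad} has zero variance over the {stim_type} window")
    stacked = np.vstack([ch, cat_reg.values])
    r = np.corrcoef(stacked)
    n = scan.n_channels
    r_ij = r[:n, :n]
    r_ik = r[:n, n]
    denom_sq = 1.0 - r_ik**2
    if (denom_sq <= 1e-15).any():
        bad = scan.layout.labels[int(np.argmax(denom_sq <= 1e-15))]
        raise ValueError(f"channel {bad} is perfectly correlated with the regressor")
    pc = (r_ij - np.outer(r_ik, r_ik)) / np.sqrt(np.outer(denom_sq, denom_sq))
    pc = np.clip((pc + pc.T) / 2.0, -1.0, 1.0)  # symmetrize against rounding noise
    np.fill_diagonal(pc, 1.0)
    return FCMatrix(
        pc,
        stim_type=stim_type,
        subject_id=scan.subject_id,
        labels=scan.layout.labels,
        n_samples=ch.shape[1],
    )


def write_fc_csv(fc: FCMatrix, path) -> None:
    """Square CSV with channel labels on both axes."""
    pd.DataFrame(fc.values, index=list(fc.labels), columns=list(fc.labels)).to_csv(path)


def read_fc_csv(path, stim_type: str = "", subject_id: str = "") -> FCMatrix:
    df = pd.read_csv(path, index_col=0)
    return FCMatrix(
        df.to_numpy(), stim_type=stim_type, subject_id=subject_id, labels=tuple(df.columns)
    )
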