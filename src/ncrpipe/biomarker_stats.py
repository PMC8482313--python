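"""Cognitive quotient, neurocognitive ratio, ANOVA and ROC evaluation.

Per stimulus type i the behavioral cognitive quotient is CQ_i = ACC_i/RT_i
(accuracy in percent, reaction time in seconds), the network ratio is
R_i = GE_CM,i / GE_DM,i, and the neurocognitive ratio — the biomarker this
pipeline exists for — is NCR_i = CQ_i x R_i.  Subject-level summaries are
arithmetic means over the three stimulus types (NCR-bar, CQ-bar, GE-bar).

The convention throughout is mean-of-ratios: CQ is computed per subject
and then averaged within a group, which differs from dividing group-mean
accuracy by group-mean RT whenever subjects are heterogeneous.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as ss

from .preprocess import STIM_TYPES

__all__ = [
    "BehavioralRecord",
    "SubjectResult",
    "RocReport",
    "cognitive_quotient",
    "neurocognitive_ratio",
    "stimulus_mean",
    "anova_one_way",
    "anova_two_way",
    "roc_analysis",
    "pairwise_roc",
    "group_summary",
]


@dataclass
class BehavioralRecord:
    """Accuracy (%) and reaction time (s) per stimulus type for one subject."""

    subject_id: str
    group: str
    acc: dict
    rt: dict

    def __post_init__(self):
        for st in STIM_TYPES:
            if st not in self.acc or st not in self.rt:
                raise ValueError(f"behavioral record is missing stimulus type {st!r}")
        for st, v in self.rt.items():
            if v <= 0:
                raise ValueError(f"reaction time for {st!r} must be positive")
        for st, v in self.acc.items():
            if not 0 <= v <= 100:
                raise ValueError(f"accuracy for {st!r} must lie in [0, 100]")


@dataclass
class SubjectResult:
    """Per-subject, per-stimulus pipeline outcomes plus across-stimulus means."""

    subject_id: str
    group: str
    ge_cm: dict
    ge_dm: dict
    cq: dict
    r: dict = field(default_factory=dict)
    ncr: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.r or not self.ncr:
            self.r, self.ncr = {}, {}
            for st in STIM_TYPES:
                r, ncr = neurocognitive_ratio(self.cq[st], self.ge_cm[st], self.ge_dm[st])
                self.r[st] = r
                self.ncr[st] = ncr

    @property
    def ncr_bar(self) -> float:
        return stimulus_mean(self.ncr)

    @property
    def cq_bar(self) -> float:
        return stimulus_mean(self.cq)

    @property
    def ge_cm_bar(self) -> float:
        return stimulus_mean(self.ge_cm)


def cognitive_quotient(acc: float, rt: float) -> float:
    """CQ = accuracy (%) / reaction time (s)."""
    if rt <= 0:
        raise ValueError("reaction time must be positive")
    if not 0 <= acc <= 100:
        raise ValueError("accuracy must lie in [0, 100]")
    return acc / rt


def neurocognitive_ratio(cq: float, ge_cm: float, ge_dm: float) -> tuple[float, float]:
    """R = GE_CM/GE_DM and NCR = CQ x R."""
    if ge_dm <= 0:
        raise ValueError("GE_DM must be positive for the ratio to be defined")
    r = ge_cm / ge_dm
    return r, cq * r


def stimulus_mean(values) -> float:
    """Arithmetic mean over the three stimulus types N, C, I."""
    if isinstance(values, dict):
        missing = [st for st in STIM_TYPES if st not in values]
        if missing:
            raise ValueError(f"missing stimulus type(s): {missing}")
        vals = [values[st] for st in STIM_TYPES]
    else:
        vals = list(values)
        if len(vals) != 3:
            raise ValueError("exactly three stimulus values are required")
    return float(np.mean(vals))


def anova_one_way(*groups) -> tuple[float, float]:
    """Classical one-way ANOVA F and p over two or more groups.

    Computed from sums of squares directly so degenerate inputs are handled
    explicitly: no variance anywhere gives (F=0, p=1) with a warning;
    perfect separation with zero within-group variance gives (inf, 0).
    """
    if len(groups) == 1:
        groups = tuple(groups[0])
    groups = [np.asarray(g, dtype=float).ravel() for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    m = sum(g.size for g in groups)
    if m - len(groups) < 1:
        raise ValueError("not enough total degrees of freedom")
    grand = np.concatenate(groups).mean()
    ssb = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df_b, df_w = len(groups) - 1, m - len(groups)
    if ssw <= 1e-30:
        if ssb <= 1e-30:
            warnings.warn("ANOVA is degenerate: no variance in the data", stacklevel=2)
            return 0.0, 1.0
        warnings.warn("ANOVA within-group variance is zero", stacklevel=2)
        return float("inf"), 0.0
    f = (ssb / df_b) / (ssw / df_w)
    return float(f), float(ss.f.sf(f, df_b, df_w))


def anova_two_way(values, factor_group, factor_stimulus) -> dict:
    """Unbalanced two-way ANOVA with interaction, Type II sums of squares.

    Returns ``{"group": (F, p), "stimulus": (F, p), "interaction": (F, p)}``.
    Every group x stimulus cell must be non-empty.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "value": np.asarray(values, dtype=float),
            "grp": pd.Categorical(factor_group),
            "stim": pd.Categorical(factor_stimulus),
        }
    )
    counts = df.groupby(["grp", "stim"], observed=False).size()
    if (counts == 0).any():
        empty = counts[counts == 0].index.tolist()
        raise ValueError(f"empty design cell(s): {empty}")
    model = smf.ols("value ~ C(grp) * C(stim)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    return {
        "group": (float(table.loc["C(grp)", "F"]), float(table.loc["C(grp)", "PR(>F)"])),
        "stimulus": (float(table.loc["C(stim)", "F"]), float(table.loc["C(stim)", "PR(>F)"])),
        "interaction": (
            float(table.loc["C(grp):C(stim)", "F"]),
            float(table.loc["C(grp):C(stim)", "PR(>F)"]),
        ),
    }


@dataclass
class RocReport:
    """Operating-point metrics (percent) for one two-class comparison."""

    sensitivity: float
    specificity: float
    accuracy: float
    auc: float
    threshold: float
    positive_class: str

    def to_dict(self) -> dict:
        return {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "auc": self.auc,
            "threshold": self.threshold,
            "positive_class": self.positive_class,
        }


def roc_analysis(scores, labels, positive_class) -> RocReport:
    """Two-class ROC with a Youden-optimal operating point.

    AUC is the tie-aware rank (concordance) statistic; a subject is called
    positive when its score is >= the threshold, the threshold maximizing
    Youden's J = sensitivity + specificity - 1 (ties resolved toward higher
    sensitivity).  All metrics are reported in percent.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == positive_class
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    # tie-aware concordance via midranks (equivalent to Mann-Whitney U)
    ranks = ss.rankdata(scores)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    thresholds = np.unique(scores)
    best = None  # (J, sens, threshold)
    for t in thresholds:
        called = scores >= t
        sens = (called & pos).sum() / n_pos
        spec = (~called & ~pos).sum() / n_neg
        j = sens + spec - 1.0
        cand = (j, sens, -t)
        if best is None or cand > best:
            best = cand
            best_metrics = (sens, spec, t)
    sens, spec, thr = best_metrics
    acc = (sens * n_pos + spec * n_neg) / (n_pos + n_neg)
    return RocReport(
        sensitivity=100.0 * sens,
        specificity=100.0 * spec,
        accuracy=100.0 * acc,
        auc=100.0 * auc,
        threshold=float(thr),
        positive_class=str(positive_class),
    )


def pairwise_roc(scores, groups) -> dict:
    """One ROC per unordered group pair; positive class = higher-mean group."""
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    names = list(dict.fromkeys(groups.tolist()))
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    out = {}
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            mask = (groups == ga) | (groups == gb)
            mean_a = scores[groups == ga].mean()
            mean_b = scores[groups == gb].mean()
            positive = ga if mean_a >= mean_b else gb
            out[(ga, gb)] = roc_analysis(scores[mask], groups[mask], positive)
    return out


def group_summary(results, field_name: str) -> pd.DataFrame:
    """Mean +/- SD table (rows: groups, columns: stimulus types) for one metric.

    ``results`` is an iterable of :class:`SubjectResult`; SDs use the n-1
    denominator over the subjects of a group.
    """
    rows = {}
    for res in results:
        rows.setdefault(res.group, []).append(getattr(res, field_name))
    table = {}
    for grp, dicts in rows.items():
        entry = {}
        for st in STIM_TYPES:
            vals = np.array([d[st] for d in dicts])
            entry[f"{st}_mean"] = vals.mean()
            entry[f"{st}_sd"] = vals.std(ddof=1) if vals.size > 1 else 0.0
        table[grp] = entry
    return pd.DataFrame(table).T
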