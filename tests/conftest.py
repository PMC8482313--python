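import numpy as np
import pytest

from ncrpipe import (
    BlockDesign,
    GroupProfile,
    HbOScan,
    make_schedule,
    simulate_scan,
)
from ncrpipe.reference import REFERENCE_ACC, REFERENCE_RT


@pytest.fixture(scope="session")
def default_schedule():
    return make_schedule(BlockDesign(), seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def profile(name="control", n=13, cm=0.7, dm=0.25, **overrides):
    """Group profile with published behavioral tables for a known group."""
    base = dict(
        name=name,
        n_subjects=n,
        rt={st: REFERENCE_RT[name][st] for st in "NCI"},
        acc={st: REFERENCE_ACC[name][st] for st in "NCI"},
        cm_coupling=cm,
        dm_coupling=dm,
    )
    base.update(overrides)
    return GroupProfile(**base)


@pytest.fixture(scope="session")
def control_scan(default_schedule):
    return simulate_scan(
        profile(), default_schedule, seed=42, subject_id="control_001"
    )


@pytest.fixture(scope="session")
def small_scan():
    """Tiny deterministic 4-channel scan for cheap unit tests."""
    g = np.random.default_rng(0)
    return HbOScan(g.standard_normal((4, 250)), fs=1.77, subject_id="tiny")


def planted_toy_fcs(n_subjects=10, seed=0):
    """Six-channel FC sets where only eigencomponents {1, 2} carry a
    stimulus effect.

    Component 1 loads uniformly on channels 0-3, component 2 carries the
    alternating contrast (+,-,+,-) on the same channels; their
    interference makes pair strengths (lam1 +/- lam2)/4.  Singles are
    stimulus-flat (a rank-1 reconstruction's ranking is scale-invariant),
    but the pair's binarized topology switches deterministically between
    three disjoint edges and a connected four-channel path, so the
    across-stimulus GE ANOVA is minimized by exactly {1, 2}.
    """
    v1 = np.array([1, 1, 1, 1, 0, 0]) / 2.0
    v2 = np.array([1, -1, 1, -1, 0, 0]) / 2.0
    v3 = np.array([0, 0, 0, 0, 1, 1]) / np.sqrt(2)
    v4 = np.array([0, 0, 0, 0, 1, -1]) / np.sqrt(2)
    v5 = np.array([1, 0, -1, 0, 0, 0]) / np.sqrt(2)
    v6 = np.array([0, 1, 0, -1, 0, 0]) / np.sqrt(2)
    basis = np.column_stack([v1, v2, v3, v4, v5, v6])
    lam_by_stim = {
        "N": (2.09, 1.71),
        "C": (1.95, 1.52),
        "I": (2.09, 0.855),
    }
    tail = np.array([0.52, 0.10, 0.20, 0.14])
    g = np.random.default_rng(seed)
    subjects = []
    for _ in range(n_subjects):
        eps = g.normal(0, 0.01, size=6)
        fcs = {}
        for st, (l1, l2) in lam_by_stim.items():
            lam = np.concatenate([[l1, l2], tail]) + eps
            m = (basis * lam) @ basis.T
            fcs[st] = (m + m.T) / 2
        subjects.append(fcs)
    return subjects
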