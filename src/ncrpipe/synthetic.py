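"""Seeded synthetic fNIRS cohorts with known ground truth.

No recordings ship with this package, so every stage is exercised on a
generative model that reproduces the statistical structure the pipeline
assumes:

* a shared low-frequency systemic background (sum of sinusoids in the
  0.01-0.1 Hz band plus a broadband AR(1) process), common to all channels
  with per-channel gains — exactly the confound the partial-correlation
  regressor targets;
* task-evoked responses: stimulus boxcars convolved with a double-gamma
  hemodynamic response function, added to every channel with modest gain;
* a cognitive-mode (CM) network: correlated innovations in a single
  hub-organized task community, active during task blocks, whose
  recruited extent grows with stimulus demand (about 10 of 16 channels
  under neutral stimuli, 13 under congruent, all 16 under incongruent
  interference) and whose coherence is set by the group's CM coupling
  strength — the parameter a patient group is deficient in;
* a default-mode (DM) network: stimulus-indifferent correlated
  innovations in a second community;
* white measurement noise.

Because the binarized-graph global efficiency used downstream sees only
the rank order of connectivity, a coupling deficit expresses itself
through recoverability: the control network's hub-and-spoke structure
stands above the eigenvalue sampling-noise bulk and reconstructs into a
spread, demand-scaled graph (high, stimulus-sensitive GE_CM), while a
weakly coupled network generates too little coherent variance to clear
the noise floor, leaving reconstructions dominated by sampling noise —
concentrated, nested graphs with low GE_CM.

Behavioral records are drawn from group-level reaction-time and accuracy
distributions matching the published cohort tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .biomarker_stats import BehavioralRecord
from .preprocess import (
    BlockDesign,
    HbOScan,
    ProbeLayout,
    StimulusSchedule,
    make_schedule,
)
from .reference import GROUP_SIZES, GROUPS, REFERENCE_ACC, REFERENCE_RT

__all__ = [
    "GroupProfile",
    "GroundTruth",
    "Cohort",
    "NetworkTemplate",
    "default_networks",
    "default_cohort_profiles",
    "simulate_behavior",
    "simulate_scan",
    "simulate_cohort",
    "deficit_cohort_profiles",
    "null_cohort_profiles",
]

# CM coupling defaults grade from healthy down to the most impaired group.
DEFAULT_COUPLING = {"control": 0.70, "migraine": 0.55, "ocd": 0.45, "schizo": 0.30}
DEFAULT_DM_COUPLING = {"control": 0.25, "migraine": 0.35, "ocd": 0.35, "schizo": 0.35}

RT_FLOOR_S = 0.150  # physiological lower bound on reaction time
N_TRIALS = 15  # stimuli per type, hence the accuracy grid 100*k/15


@dataclass(frozen=True)
class GroupProfile:
    """Generative parameters of one subject group.

    ``rt``/``acc`` map stimulus type -> (mean, SD) in ms / %.  Coupling
    strengths are pairwise correlation levels in [0, 1) on the network
    graphs; amplitudes are in units of the white-noise SD.
    """

    name: str
    n_subjects: int
    rt: dict
    acc: dict
    cm_coupling: float = 0.70
    dm_coupling: float = 0.40
    task_amplitude: float = 0.3
    systemic_amplitude: float = 0.3
    fast_systemic_amplitude: float = 0.3
    network_amplitude: float = 1.6
    noise_sd: float = 0.3

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("a group needs at least one subject")
        for cname, c in (("cm_coupling", self.cm_coupling), ("dm_coupling", self.dm_coupling)):
            if not 0 <= c < 1:
                raise ValueError(f"{cname} must lie in [0, 1)")
        for st, (mean, sd) in self.rt.items():
            if mean <= 0 or sd < 0:
                raise ValueError(f"invalid RT parameters for {st!r}")
        for st, (mean, sd) in self.acc.items():
            if not 0 <= mean <= 100 or sd < 0:
                raise ValueError(f"invalid ACC parameters for {st!r}")


@dataclass(frozen=True)
class NetworkTemplate:
    """Fixed coupling communities: channel supports per condition.

    ``factors`` maps a condition (stimulus type or REST) to a tuple of
    channel-index tuples; channels sharing a community factor receive a
    pairwise correlation of coupling x ``corr_scale`` (times the loading
    grades).  Dense communities concentrate spectral weight — with ~100
    usable samples per stimulus, only eigenvalues well above the
    sampling-noise bulk are estimable, so a detectable network must be
    low-rank.
    """

    factors: dict
    corr_scale: float = 0.72
    # graded loadings within each community: the leading (hub) channel
    # couples more strongly, so hub-member correlations exceed
    # member-member ones and the binarized network is hub-and-spoke —
    # integrated and efficient — rather than a flat clique
    loading_grades: tuple[float, ...] = (1.0,) + (0.4,) * 15

    def supports(self, condition: str) -> tuple[tuple[int, ...], ...]:
        return tuple(self.factors.get(condition, ()))


def default_networks(n_channels: int = 16) -> tuple[NetworkTemplate, NetworkTemplate]:
    """Deterministic CM and DM network layouts for an n-channel probe.

    The CM network is a single task-positive community organized around a
    hub channel: the hub couples strongly to every recruited member, the
    members more weakly to each other, so the binarized network is
    hub-and-spoke.  Stimulus demand scales the recruited *extent* —
    roughly 10 of 16 channels under neutral stimuli, 13 under congruent
    and the whole probe under incongruent interference, expressing the
    premise that resolving interference recruits a wider, more integrated
    circuit (and thereby raising the network's global efficiency with
    demand).  The DM network is one stimulus-indifferent community over
    every third channel.
    """
    full = n_channels
    n_extent = max(full * 10 // 16, 2)
    c_extent = max(full * 13 // 16, 2)
    cm = NetworkTemplate(
        factors={
            "N": (tuple(range(n_extent)),),
            "C": (tuple(range(c_extent)),),
            "I": (tuple(range(full)),),
        },
        corr_scale=0.72,
        loading_grades=(1.0,) + (0.4,) * (full - 1),
    )
    every_third = tuple(range(0, n_channels, 3))
    dm = NetworkTemplate(
        factors={cond: (every_third,) for cond in ("N", "C", "I", "REST")},
        corr_scale=0.72,
    )
    return cm, dm


def default_cohort_profiles(
    sizes: dict | None = None,
    coupling: dict | None = None,
) -> list[GroupProfile]:
    """The four standard groups with published behavioral distributions."""
    sizes = dict(GROUP_SIZES if sizes is None else sizes)
    coupling = dict(DEFAULT_COUPLING if coupling is None else coupling)
    profiles = []
    for g in GROUPS:
        profiles.append(
            GroupProfile(
                name=g,
                n_subjects=sizes[g],
                rt={st: REFERENCE_RT[g][st] for st in ("N", "C", "I")},
                acc={st: REFERENCE_ACC[g][st] for st in ("N", "C", "I")},
                cm_coupling=coupling[g],
                dm_coupling=DEFAULT_DM_COUPLING[g],
            )
        )
    return profiles


def deficit_cohort_profiles(
    n_control: int = 13,
    n_patient: int = 67,
    control_coupling: float = 0.70,
    patient_coupling: float = 0.30,
) -> list[GroupProfile]:
    """Two-group parameter-recovery cohort: healthy controls versus a pooled
    patient group with a planted CM-coupling deficit (behavior from the
    published control and schizophrenia tables, task amplitudes equal)."""
    return [
        GroupProfile(
            name="control",
            n_subjects=n_control,
            rt={st: REFERENCE_RT["control"][st] for st in ("N", "C", "I")},
            acc={st: REFERENCE_ACC["control"][st] for st in ("N", "C", "I")},
            cm_coupling=control_coupling,
            dm_coupling=0.25,
        ),
        GroupProfile(
            name="patient",
            n_subjects=n_patient,
            rt={st: REFERENCE_RT["schizo"][st] for st in ("N", "C", "I")},
            acc={st: REFERENCE_ACC["schizo"][st] for st in ("N", "C", "I")},
            cm_coupling=patient_coupling,
            dm_coupling=0.35,
        ),
    ]


def null_cohort_profiles(n_control: int = 13, n_patient: int = 67) -> list[GroupProfile]:
    """Calibration cohort with no planted group difference: both groups share
    coupling strengths and behavioral distributions."""
    common = dict(
        rt={st: REFERENCE_RT["control"][st] for st in ("N", "C", "I")},
        acc={st: REFERENCE_ACC["control"][st] for st in ("N", "C", "I")},
        cm_coupling=0.55,
        dm_coupling=0.30,
    )
    return [
        GroupProfile(name="control", n_subjects=n_control, **common),
        GroupProfile(name="patient", n_subjects=n_patient, **common),
    ]


@dataclass
class GroundTruth:
    """What the generator actually planted, for recovery checks."""

    profiles: dict
    cm_network: NetworkTemplate
    dm_network: NetworkTemplate
    master_seed: int

    def to_dict(self) -> dict:
        return {
            "master_seed": self.master_seed,
            "groups": {
                name: {
                    "n_subjects": p.n_subjects,
                    "cm_coupling": p.cm_coupling,
                    "dm_coupling": p.dm_coupling,
                    "task_amplitude": p.task_amplitude,
                }
                for name, p in self.profiles.items()
            },
            "cm_factors": {
                cond: [list(s) for s in sup] for cond, sup in self.cm_network.factors.items()
            },
            "dm_factors": {
                cond: [list(s) for s in sup] for cond, sup in self.dm_network.factors.items()
            },
        }


@dataclass
class Cohort:
    """A complete runnable synthetic dataset."""

    scans: list
    behavior: list
    schedules: list
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# Behavioral simulation
# ---------------------------------------------------------------------------

def simulate_behavior(profile: GroupProfile, seed: int, n_subjects: int | None = None):
    """Draw behavioral records for the group.

    RT per stimulus: truncated normal above 150 ms with the profile's
    mean/SD.  ACC: 100 * correct/15 with correct ~ Binomial(15, mean/100),
    i.e. accuracy lives on the 15-trial grid.
    """
    rng = np.random.default_rng(seed)
    n = profile.n_subjects if n_subjects is None else n_subjects
    records = []
    for s in range(n):
        rt, acc = {}, {}
        for st in ("N", "C", "I"):
            mean_ms, sd_ms = profile.rt[st]
            val = rng.normal(mean_ms, sd_ms)
            while val < RT_FLOOR_S * 1000.0:
                val = rng.normal(mean_ms, sd_ms)
            rt[st] = val / 1000.0
            p = profile.acc[st][0] / 100.0
            if not 0 <= p <= 1:
                raise ValueError("accuracy mean must be a valid probability")
            acc[st] = 100.0 * rng.binomial(N_TRIALS, p) / N_TRIALS
        records.append(
            BehavioralRecord(
                subject_id=f"{profile.name}_{s + 1:03d}", group=profile.name, acc=acc, rt=rt
            )
        )
    return records


# ---------------------------------------------------------------------------
# Hemodynamic scan simulation
# ---------------------------------------------------------------------------

def double_gamma_hrf(fs: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma hemodynamic response (peak 6 s, undershoot 16 s)."""
    t = np.arange(0, duration, 1.0 / fs)
    a1, a2, ratio = 6.0, 16.0, 6.0
    g1 = np.exp((a1 - 1) * np.log(np.maximum(t, 1e-12)) - t - gammaln(a1))
    g2 = np.exp((a2 - 1) * np.log(np.maximum(t, 1e-12)) - t - gammaln(a2))
    h = g1 - g2 / ratio
    h[t == 0] = 0.0
    # unit-sum normalization: a sustained block response plateaus at the
    # nominal task amplitude rather than at amplitude x integral
    total = h.sum()
    return h / total if total > 0 else h


def _condition_codes(schedule: StimulusSchedule, fs: float, n_samples: int) -> np.ndarray:
    """Stimulus type per sample ('REST' outside task blocks)."""
    from .preprocess import segment_bounds

    codes = np.full(n_samples, "REST", dtype=object)
    for st in schedule.stim_types:
        for a, b in segment_bounds(schedule, st, fs, n_samples):
            codes[a:b] = st
    return codes


def _network_mixing(
    n: int,
    network: NetworkTemplate,
    coupling: float,
    condition: str,
) -> np.ndarray:
    """Unit-variance mixing matrix of one network for one condition.

    Factor-loading construction: each community contributes a shared
    standard-normal factor with loading sqrt(rho), rho = coupling x
    corr_scale, and each channel tops up to unit variance with an
    idiosyncratic term.  Channels sharing one community realize pairwise
    correlation rho exactly (2*rho for a two-community overlap); the
    construction is positive-definite for rho x memberships < 1, enforced
    by capping the shared-variance budget.
    """
    rho = coupling * network.corr_scale
    supports = network.supports(condition)
    grades = network.loading_grades
    loadings = np.zeros((n, len(supports)))
    for f, support in enumerate(supports):
        for pos, i in enumerate(support):
            share = rho * grades[min(pos, len(grades) - 1)]
            # alternating signs: the factor cancels out of the channel
            # average, so the systemic regressor stays free of network
            # signal (|pairwise correlation| is unchanged, and the
            # downstream thresholding is sign-agnostic)
            loadings[i, f] = np.sqrt(share) * (1.0 if pos % 2 == 0 else -1.0)
    shared = (loadings**2).sum(axis=1)
    over = shared > 0.92
    if over.any():  # keep idiosyncratic variance strictly positive
        loadings[over] *= np.sqrt(0.92 / shared[over, None])
        shared = (loadings**2).sum(axis=1)
    idio = np.sqrt(1.0 - shared)
    return np.hstack([loadings, np.diag(idio)])


SLOW_SYSTEMIC_FREQS = (0.012, 0.021, 0.033, 0.053, 0.080)  # Hz, below the 0.1 Hz cut
FAST_SYSTEMIC_AR1 = 0.3


def simulate_scan(
    profile: GroupProfile,
    schedule: StimulusSchedule,
    layout: ProbeLayout = ProbeLayout(),
    seed: int = 0,
    fs: float = 1.77,
    networks: tuple[NetworkTemplate, NetworkTemplate] | None = None,
    subject_id: str = "",
) -> HbOScan:
    """Generate one subject's channels x samples [HbO] scan."""
    rng = np.random.default_rng(seed)
    n = layout.n_channels
    n_samples = int(np.floor(schedule.duration * fs + 0.5))
    if n_samples < 1:
        raise ValueError("schedule duration too short for the sampling rate")
    cm, dm = default_networks(n) if networks is None else networks
    t = np.arange(n_samples) / fs

    # shared slow systemic background (survives the high-pass regressor)
    slow = np.zeros(n_samples)
    amp = np.sqrt(2.0 / len(SLOW_SYSTEMIC_FREQS))  # unit variance in total
    for f in SLOW_SYSTEMIC_FREQS:
        slow += amp * np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi))
    # shared broadband systemic (captured by the high-pass regressor)
    eps = rng.standard_normal(n_samples)
    fast = np.empty(n_samples)
    fast[0] = eps[0]
    for k in range(1, n_samples):
        fast[k] = FAST_SYSTEMIC_AR1 * fast[k - 1] + eps[k]
    fast *= np.sqrt(1 - FAST_SYSTEMIC_AR1**2)  # unit variance

    gains = rng.uniform(0.7, 1.3, size=n)

    # task-evoked responses: boxcar per stimulus type * double-gamma HRF
    hrf = double_gamma_hrf(fs)
    codes = _condition_codes(schedule, fs, n_samples)
    evoked = np.zeros(n_samples)
    for st in schedule.stim_types:
        box = (codes == st).astype(float)
        evoked += np.convolve(box, hrf)[:n_samples]
    task_gains = rng.uniform(0.5, 1.0, size=n)

    # Correlated network innovations, condition-dependent Cholesky.  Each
    # network's variance scales with its coupling: a weakly coupled network
    # produces little coherent activity, so its contribution to the
    # measured series (and hence its realized inter-channel correlation)
    # falls off faster than linearly — a weak network drowns in the
    # systemic background and measurement noise.
    net_cm = np.empty((n, n_samples))
    net_dm = np.empty((n, n_samples))
    for cond in ("N", "C", "I", "REST"):
        cols = codes == cond
        if not cols.any():
            continue
        mix_cm = _network_mixing(n, cm, profile.cm_coupling, cond)
        mix_dm = _network_mixing(n, dm, profile.dm_coupling, cond)
        net_cm[:, cols] = mix_cm @ rng.standard_normal((mix_cm.shape[1], int(cols.sum())))
        net_dm[:, cols] = mix_dm @ rng.standard_normal((mix_dm.shape[1], int(cols.sum())))

    noise = rng.standard_normal((n, n_samples))

    data = (
        np.outer(gains, profile.systemic_amplitude * slow)
        + np.outer(gains, profile.fast_systemic_amplitude * fast)
        + np.outer(task_gains, profile.task_amplitude * evoked)
        + profile.network_amplitude * np.sqrt(profile.cm_coupling) * net_cm
        + np.sqrt(profile.dm_coupling) * net_dm
        + profile.noise_sd * noise
    )
    return HbOScan(
        data,
        fs=fs,
        subject_id=subject_id or f"{profile.name}_sim",
        group=profile.name,
        layout=layout,
    )


def simulate_cohort(
    profiles,
    design: BlockDesign = BlockDesign(),
    master_seed: int = 0,
    layout: ProbeLayout = ProbeLayout(),
    fs: float = 1.77,
) -> Cohort:
    """Generate scans, schedules, behavior, and ground truth for all groups.

    Per-subject randomness is spawned from the master seed, so the whole
    cohort is reproducible bit-for-bit.
    """
    profiles = list(profiles)
    names = [p.name for p in profiles]
    if len(set(names)) != len(names):
        raise ValueError("duplicate group names in cohort profiles")
    networks = default_networks(layout.n_channels)
    ss = np.random.SeedSequence(master_seed)
    scans, behavior, schedules = [], [], []
    for profile in profiles:
        group_ss, behav_ss = ss.spawn(2)
        behav_seed = int(behav_ss.generate_state(1)[0] % (2**31))
        behavior.extend(simulate_behavior(profile, seed=behav_seed))
        for s, subj_ss in enumerate(group_ss.spawn(profile.n_subjects)):
            sched_seed, scan_seed = (int(v % (2**31)) for v in subj_ss.generate_state(2))
            schedule = make_schedule(design, seed=sched_seed)
            scan = simulate_scan(
                profile,
                schedule,
                layout=layout,
                seed=scan_seed,
                fs=fs,
                networks=networks,
                subject_id=f"{profile.name}_{s + 1:03d}",
            )
            scans.append(scan)
            schedules.append(schedule)
    truth = GroundTruth(
        profiles={p.name: p for p in profiles},
        cm_network=networks[0],
        dm_network=networks[1],
        master_seed=master_seed,
    )
    return Cohort(scans=scans, behavior=behavior, schedules=schedules, ground_truth=truth)
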