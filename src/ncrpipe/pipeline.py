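"""End-to-end orchestration: simulate/load -> FC -> search -> GE -> NCR -> stats.

Each stage is a pure function of its inputs plus the master seed, so a
rerun with the same configuration reproduces every number bit-for-bit.
All artifacts are written with provenance (seed, configuration hash,
package version).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .biomarker_stats import (
    SubjectResult,
    anova_one_way,
    anova_two_way,
    cognitive_quotient,
    group_summary,
    pairwise_roc,
    roc_analysis,
)
from .connectivity import build_fc
from .decomposition import SearchConfig, group_efficiencies, optimize_components
from .preprocess import (
    STIM_TYPES,
    BlockDesign,
    FilterSpec,
    build_regressor,
    read_behavior_csv,
    read_scan_csv,
    read_schedule,
)
from .synthetic import GroupProfile, default_cohort_profiles, simulate_cohort

__all__ = ["RunConfig", "PipelineResult", "run_pipeline", "compute_fcs", "StageError"]

log = logging.getLogger("ncrpipe")


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Configuration of a full run.

    Either ``profiles`` (simulation) or ``data_dir`` (scan/schedule/behavior
    files previously written by the simulate stage or by the user) must be
    set.
    """

    profiles: list | None = None
    data_dir: str | None = None
    design: BlockDesign = field(default_factory=BlockDesign)
    filter_spec: FilterSpec = field(default_factory=FilterSpec)
    search: SearchConfig = field(default_factory=SearchConfig)
    control_group: str = "control"
    # Common count threshold used when computing the subject-level GE that
    # enters R and NCR.  GE rises with the number of retained edges, so
    # group comparisons are only meaningful at a matched edge budget; the
    # default keeps the top 15% of directed entries (36 of 240 for 16
    # channels).  Set to None to use each group's own optimized theta
    # (the original iterative protocol), accepting the confound.
    report_theta_cm: int | None = 36
    report_theta_dm: int | None = 36
    out_dir: str | None = None
    seed: int = 0
    log_level: str = "INFO"

    def __post_init__(self):
        if self.profiles is None and self.data_dir is None:
            self.profiles = default_cohort_profiles()
        if self.data_dir is not None and not Path(self.data_dir).exists():
            raise ValueError(f"data_dir {self.data_dir!r} does not exist")

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Load a configuration from JSON or TOML.

        Recognized sections: top-level ``seed``, ``out_dir``, ``data_dir``,
        ``control_group``, ``report_theta_cm``/``report_theta_dm``;
        ``filter`` (FilterSpec fields); ``search`` (SearchConfig fields,
        with ``theta_cm_range``/``theta_dm_range`` as [lo, hi]); ``design``
        (BlockDesign fields); ``profiles`` as a list of group-profile
        dicts (behavioral tables default to the published group values
        when only a known group ``name`` is given).
        """
        path = str(path)
        if path.endswith(".toml"):
            import tomllib

            with open(path, "rb") as fh:
                raw = tomllib.load(fh)
        else:
            with open(path) as fh:
                raw = json.load(fh)

        kwargs: dict = {}
        for key in ("seed", "out_dir", "data_dir", "control_group",
                    "report_theta_cm", "report_theta_dm", "log_level"):
            if key in raw:
                kwargs[key] = raw[key]
        if "filter" in raw:
            kwargs["filter_spec"] = FilterSpec(**raw["filter"])
        if "design" in raw:
            kwargs["design"] = BlockDesign(**raw["design"])
        if "search" in raw:
            sec = dict(raw["search"])
            for rng in ("theta_cm_range", "theta_dm_range"):
                if rng in sec and len(sec[rng]) == 2:
                    lo, hi = sec[rng]
                    sec[rng] = tuple(range(int(lo), int(hi) + 1))
            kwargs["search"] = SearchConfig(**sec)
        if "profiles" in raw:
            from .reference import REFERENCE_ACC, REFERENCE_RT

            profiles = []
            for entry in raw["profiles"]:
                entry = dict(entry)
                name = entry["name"]
                entry.setdefault("rt", REFERENCE_RT.get(name))
                entry.setdefault("acc", REFERENCE_ACC.get(name))
                if entry["rt"] is None or entry["acc"] is None:
                    raise ValueError(
                        f"profile {name!r} needs explicit rt/acc tables (not a known group)"
                    )
                entry["rt"] = {st: tuple(v) for st, v in entry["rt"].items()}
                entry["acc"] = {st: tuple(v) for st, v in entry["acc"].items()}
                profiles.append(GroupProfile(**entry))
            kwargs["profiles"] = profiles
        return cls(**kwargs)

    def digest(self) -> str:
        def default(o):
            if hasattr(o, "__dict__"):
                return {k: v for k, v in o.__dict__.items()}
            if isinstance(o, (tuple, set, frozenset)):
                return sorted(o) if isinstance(o, (set, frozenset)) else list(o)
            return str(o)

        blob = json.dumps(asdict_safe(self), sort_keys=True, default=default)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def asdict_safe(cfg: RunConfig) -> dict:
    out = {}
    for k, v in cfg.__dict__.items():
        try:
            json.dumps(v)
            out[k] = v
        except TypeError:
            out[k] = repr(v)
    return out


@dataclass
class PipelineResult:
    """Everything a full run produces."""

    subject_results: list
    search_results: dict
    summaries: dict
    anova: dict
    roc: dict
    provenance: dict

    def results_frame(self) -> pd.DataFrame:
        rows = []
        for res in self.subject_results:
            for st in STIM_TYPES:
                rows.append(
                    {
                        "subject_id": res.subject_id,
                        "group": res.group,
                        "stim_type": st,
                        "ge_cm": res.ge_cm[st],
                        "ge_dm": res.ge_dm[st],
                        "cq": res.cq[st],
                        "r": res.r[st],
                        "ncr": res.ncr[st],
                    }
                )
        return pd.DataFrame(rows)


def compute_fcs(scan, schedule, filter_spec: FilterSpec = FilterSpec()):
    """Regressor plus the three stimulus-wise FC matrices for one subject."""
    regressor = build_regressor(scan, filter_spec)
    return {st: build_fc(scan, regressor, schedule, st) for st in schedule.stim_types}


def _load_cohort(data_dir: str):
    """Load scans/schedules/behavior written by the simulate stage."""
    root = Path(data_dir)
    behavior = read_behavior_csv(root / "behavior.csv")
    scans, schedules = [], []
    for rec in behavior:
        scan = read_scan_csv(root / f"{rec.subject_id}_scan.csv")
        schedule = read_schedule(str(root / f"{rec.subject_id}_schedule.tsv"))
        scans.append(scan)
        schedules.append(schedule)
    return scans, schedules, behavior


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage in order and return (and optionally write) the bundle."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))

    # --- stage: inputs -----------------------------------------------------
    try:
        if config.data_dir is not None:
            scans, schedules, behavior = _load_cohort(config.data_dir)
        else:
            cohort = simulate_cohort(config.profiles, config.design, config.seed)
            scans, schedules, behavior = cohort.scans, cohort.schedules, cohort.behavior
    except Exception as exc:  # noqa: BLE001
        raise StageError("inputs", exc) from exc
    log.info("cohort: %d subjects", len(scans))

    behav_by_id = {rec.subject_id: rec for rec in behavior}
    if set(behav_by_id) != {s.subject_id for s in scans}:
        raise StageError("inputs", ValueError("behavioral records do not match scans"))

    # --- stage: preprocess + connectivity ---------------------------------
    try:
        fcs_by_subject = {}
        for scan, schedule in zip(scans, schedules):
            fcs_by_subject[scan.subject_id] = compute_fcs(scan, schedule, config.filter_spec)
    except Exception as exc:  # noqa: BLE001
        raise StageError("connectivity", exc) from exc

    groups: dict[str, list] = {}
    for scan in scans:
        groups.setdefault(scan.group, []).append(scan.subject_id)

    # --- stage: component search ------------------------------------------
    search_results = {}
    try:
        for grp, subject_ids in groups.items():
            group_fcs = [fcs_by_subject[sid] for sid in subject_ids]
            search_results[grp] = optimize_components(group_fcs, config.search, group=grp)
            log.info(
                "group %s: CM subset %s, theta_cm=%d, p_cm=%.4g",
                grp,
                search_results[grp].cm_subset,
                search_results[grp].theta_cm,
                search_results[grp].p_cm,
            )
    except Exception as exc:  # noqa: BLE001
        raise StageError("decomposition", exc) from exc

    # --- stage: efficiency + NCR ------------------------------------------
    try:
        subject_results = []
        for grp, subject_ids in groups.items():
            sr = search_results[grp]
            group_fcs = [fcs_by_subject[sid] for sid in subject_ids]
            theta_cm = config.report_theta_cm if config.report_theta_cm is not None else sr.theta_cm
            theta_dm = config.report_theta_dm if config.report_theta_dm is not None else sr.theta_dm
            ge = group_efficiencies(group_fcs, sr.cm_subset, theta_cm, theta_dm)
            for sid, row in zip(subject_ids, ge):
                rec = behav_by_id[sid]
                cq = {st: cognitive_quotient(rec.acc[st], rec.rt[st]) for st in STIM_TYPES}
                subject_results.append(
                    SubjectResult(
                        subject_id=sid,
                        group=grp,
                        ge_cm={st: row[st][0] for st in STIM_TYPES},
                        ge_dm={st: row[st][1] for st in STIM_TYPES},
                        cq=cq,
                    )
                )
    except Exception as exc:  # noqa: BLE001
        raise StageError("efficiency", exc) from exc

    # --- stage: statistics --------------------------------------------------
    try:
        summaries = {
            name: group_summary(subject_results, name)
            for name in ("cq", "ge_cm", "ge_dm", "r", "ncr")
        }
        frame = None
        anova: dict = {"within_group": {}, "between_group": {}}
        for metric in ("cq", "ge_cm", "ge_dm", "ncr"):
            anova["within_group"][metric] = {}
            for grp, subject_ids in groups.items():
                vals = [
                    [getattr(r, metric)[st] for r in subject_results if r.group == grp]
                    for st in STIM_TYPES
                ]
                f, p = anova_one_way(*vals)
                anova["within_group"][metric][grp] = {"F": f, "p": p}
            anova["between_group"][metric] = {}
            for st in STIM_TYPES:
                vals = [
                    [getattr(r, metric)[st] for r in subject_results if r.group == grp]
                    for grp in groups
                ]
                f, p = anova_one_way(*vals)
                anova["between_group"][metric][st] = {"F": f, "p": p}
        if len(groups) >= 2:
            values, f_grp, f_stim = [], [], []
            for r in subject_results:
                for st in STIM_TYPES:
                    values.append(r.ncr[st])
                    f_grp.append(r.group)
                    f_stim.append(st)
            anova["two_way_ncr"] = {
                k: {"F": v[0], "p": v[1]}
                for k, v in anova_two_way(values, f_grp, f_stim).items()
            }

        roc: dict = {}
        if config.control_group in groups and len(groups) >= 2:
            labels = np.array(
                [
                    config.control_group
                    if r.group == config.control_group
                    else "patient"
                    for r in subject_results
                ]
            )
            for metric, attr in (
                ("CQ_bar", "cq_bar"),
                ("GE_bar", "ge_cm_bar"),
                ("NCR_bar", "ncr_bar"),
            ):
                scores = np.array([getattr(r, attr) for r in subject_results])
                roc[metric] = roc_analysis(scores, labels, config.control_group)
            scores = np.array([r.ncr_bar for r in subject_results])
            grp_labels = np.array([r.group for r in subject_results])
            roc["pairwise_NCR_bar"] = pairwise_roc(scores, grp_labels)
    except Exception as exc:  # noqa: BLE001
        raise StageError("statistics", exc) from exc

    from . import __version__

    provenance = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "version": __version__,
        "n_subjects": len(scans),
        "groups": {g: len(ids) for g, ids in groups.items()},
    }
    result = PipelineResult(
        subject_results=subject_results,
        search_results=search_results,
        summaries=summaries,
        anova=anova,
        roc=roc,
        provenance=provenance,
    )
    if config.out_dir:
        _write_bundle(result, config)
    return result


def _float_fmt(x: float) -> str:
    return f"{x:.10g}"


def _write_bundle(result: PipelineResult, config: RunConfig) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.results_frame().to_csv(out / "subject_results.csv", index=False, float_format="%.10g")
    for name, df in result.summaries.items():
        df.to_csv(out / f"summary_{name}.tsv", sep="\t", float_format="%.10g")
    with open(out / "search_results.json", "w") as fh:
        json.dump({g: sr.to_dict() for g, sr in result.search_results.items()}, fh, indent=2)
    with open(out / "anova.json", "w") as fh:
        json.dump(result.anova, fh, indent=2)
    roc_payload = {}
    for key, val in result.roc.items():
        if key == "pairwise_NCR_bar":
            roc_payload[key] = {f"{a}|{b}": rep.to_dict() for (a, b), rep in val.items()}
        else:
            roc_payload[key] = val.to_dict()
    with open(out / "roc.json", "w") as fh:
        json.dump(roc_payload, fh, indent=2)
    with open(out / "provenance.json", "w") as fh:
        json.dump(result.provenance, fh, indent=2)
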