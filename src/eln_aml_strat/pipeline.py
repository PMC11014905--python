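"""End-to-end validation run: simulate/ingest, classify, compare stratifications.

:func:`run_validation` orchestrates the full analysis a stratification
validation study performs:

* classification of every patient under both editions and the
  reclassification cross-tab (with Sankey-ready flows);
* per-edition, per-endpoint Kaplan–Meier curves and pairwise log-rank tests;
* univariable Cox hazard ratios of each risk group against favorable;
* a multivariable Cox model (2022 group, age per decade, sex, log WBC, bone
  marrow blast %, and transplant as a time-dependent state), entering all
  covariates that pass univariable screening jointly, with no selection
  beyond the screen;
* Harrell's C for both stratifications with a paired comparison;
* the censored category NRI at a series of horizons, for all subjects and
  restricted to reclassified subjects;
* transplant analyses among CR patients: Mantel–Byar tests with
  time-dependent Cox fits per risk group, and a sensitivity analysis
  censoring at transplant.

All outputs are machine-readable JSON/TSV files plus a manifest with the
config hash and seed; identical config and seed produce byte-identical
reports.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .classify import (
    ADVERSE,
    FAVORABLE,
    GROUPS,
    INTERMEDIATE,
    classify,
    derive_profile,
    reclassification_crosstab,
)
from .cohort import DEFAULT_VAF_CUTOFF, Cohort, read_cohort
from .simulate import CohortBlueprint, default_blueprint, generate_cohort
from .survival import (
    ConvergenceError,
    SurvData,
    censor_at_event,
    compare_c,
    cox_fit,
    harrell_c,
    km_fit,
    logrank_test,
    mantel_byar_test,
    nri_censored,
    reverse_km_median_followup,
    survival_at,
)

__all__ = ["RunConfig", "PipelineError", "run_validation", "hct_subgroup_report"]

logger = logging.getLogger(__name__)

ENDPOINTS = ("OS", "EFS", "RFS")


class PipelineError(RuntimeError):
    """A stage failed; the message carries the stage name and context."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one validation run."""

    mode: str = "simulate"  # "simulate" | "files"
    patients_path: Optional[str] = None
    mutations_path: Optional[str] = None
    blueprint: Optional[CohortBlueprint] = None
    vaf_cutoff: float = DEFAULT_VAF_CUTOFF
    endpoints: tuple[str, ...] = ENDPOINTS
    nri_horizons: tuple[float, ...] = (12.0, 24.0, 36.0, 48.0, 60.0)
    censor_at_hct: bool = True
    bootstrap_reps: int = 1000
    seed: int = 0
    out_dir: str = "validation_out"
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("simulate", "files"):
            raise ValueError("mode must be 'simulate' or 'files'")
        if self.mode == "files" and not (self.patients_path and self.mutations_path):
            raise ValueError("files mode requires patients_path and mutations_path")
        if any(h <= 0 for h in self.nri_horizons):
            raise ValueError("NRI horizons must be positive")
        if self.nri_horizons and self.bootstrap_reps < 100:
            raise ValueError("bootstrap_reps must be >= 100 when NRI is requested")
        unknown = set(self.endpoints) - set(ENDPOINTS)
        if unknown:
            raise ValueError(f"unknown endpoints {sorted(unknown)}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if self.blueprint is not None:
            d["blueprint"] = self.blueprint.to_dict()
        return d


def _round_floats(obj, sig: int = 6):
    """Recursively round floats to ``sig`` significant digits for stable output."""
    if isinstance(obj, float):
        if not math.isfinite(obj):
            return None
        if obj == 0.0:
            return 0.0
        return float(f"{obj:.{sig}g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating,)):
        return _round_floats(float(obj), sig)
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(_round_floats(obj), indent=2, sort_keys=True) + "\n")


def _endpoint_data(cohort: Cohort, endpoint: str, groups: Sequence[str]) -> tuple[SurvData, np.ndarray]:
    """Survival data for one endpoint; RFS is restricted to CR patients."""
    times, events, labels, keep = [], [], [], []
    for p, g in zip(cohort, groups):
        o = p.outcome
        if endpoint == "OS":
            t, e = o.os_time, o.os_event
        elif endpoint == "EFS":
            t, e = o.efs_time, o.efs_event
        else:  # RFS
            if not o.cr_achieved:
                continue
            t, e = o.rfs_time, o.rfs_event
        times.append(t)
        events.append(e)
        labels.append(g)
    return SurvData(np.array(times), np.array(events), group=np.array(labels)), np.array(labels)


def _cox_group_dummies(groups: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "intermediate_vs_favorable": (groups == INTERMEDIATE).astype(float),
        "adverse_vs_favorable": (groups == ADVERSE).astype(float),
    }


def _coxfit_dict(fit) -> dict:
    return {
        "covariates": {
            name: {
                "coef": float(fit.coef[i]),
                "hr": float(fit.hr[i]),
                "se": float(fit.se[i]),
                "ci_lower": float(fit.ci_lower[i]),
                "ci_upper": float(fit.ci_upper[i]),
                "p": float(fit.p[i]),
            }
            for i, name in enumerate(fit.names)
        },
        "loglik": fit.loglik,
        "loglik_null": fit.loglik_null,
        "n": fit.n,
        "n_events": fit.n_events,
        "ties": fit.ties,
        "converged": fit.converged,
    }


def hct_subgroup_report(
    cohort: Cohort, edition: int, vaf_cutoff: float = DEFAULT_VAF_CUTOFF
) -> dict:
    """Transplant effect per risk group, restricted to CR patients.

    For each group under the requested edition: the Mantel–Byar test of the
    time-dependent transplant state on overall survival and the companion
    time-dependent Cox hazard ratio.  Groups without CR patients (or without
    any transplanted patient) are flagged and skipped.
    """
    group_of = {
        p.patient_id: classify(derive_profile(p, vaf_cutoff), edition).group for p in cohort
    }
    out: dict = {"edition": edition, "groups": {}}
    for g in GROUPS:
        members = [p for p in cohort if group_of[p.patient_id] == g and p.outcome.cr_achieved]
        if not members:
            out["groups"][g] = {"flag": "no_cr_patients"}
            continue
        time = np.array([p.outcome.os_time for p in members])
        event = np.array([p.outcome.os_event for p in members])
        entry = np.array(
            [p.outcome.hct_time if p.outcome.hct_received else np.nan for p in members]
        )
        n_hct = int(np.sum(~np.isnan(entry)))
        if n_hct == 0:
            out["groups"][g] = {"flag": "no_hct_recipients", "n_cr": len(members)}
            continue
        try:
            mb = mantel_byar_test(SurvData(time, event), entry)
        except (ConvergenceError, ValueError) as exc:
            out["groups"][g] = {"flag": f"unestimable: {exc}", "n_cr": len(members), "n_hct": n_hct}
            continue
        out["groups"][g] = {
            "n_cr": len(members),
            "n_hct": n_hct,
            "mantel_byar_chi2": mb.statistic,
            "mantel_byar_p": mb.p,
            "hct_hr": float(mb.cox.hr[0]),
            "hct_hr_ci": [float(mb.cox.ci_lower[0]), float(mb.cox.ci_upper[0])],
        }
    return out


def _load_cohort(config: RunConfig) -> Cohort:
    if config.mode == "files":
        return read_cohort(config.patients_path, config.mutations_path)
    bp = config.blueprint if config.blueprint is not None else default_blueprint()
    return generate_cohort(bp, seed=config.seed)


def run_validation(config: RunConfig) -> dict:
    """Execute the full validation analysis and write reports under the
    configured output directory.  Returns the in-memory report dict.

    Any stage error aborts the run with the stage name; partially written
    outputs are removed.
    """
    logging.basicConfig(level=config.log_level)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "setup"
    try:
        report = _run_stages(config, out_dir, written)
    except Exception as exc:
        for path in written:
            path.unlink(missing_ok=True)
        if isinstance(exc, PipelineError):
            raise
        raise PipelineError(f"stage failed: {exc}") from exc
    return report


def _run_stages(config: RunConfig, out_dir: Path, written: list[Path]) -> dict:
    rng_seq = np.random.SeedSequence(config.seed)

    def stage(name):
        logger.info("stage: %s", name)
        return name

    stage("ingest")
    cohort = _load_cohort(config)

    stage("classify")
    calls_17, calls_22 = {}, {}
    for p in cohort:
        profile = derive_profile(p, config.vaf_cutoff)
        calls_17[p.patient_id] = classify(profile, 2017)
        calls_22[p.patient_id] = classify(profile, 2022)
    risk_rows = [
        {
            "patient_id": p.patient_id,
            "eln2017": calls_17[p.patient_id].group,
            "eln2022": calls_22[p.patient_id].group,
            "trace2017": ";".join(calls_17[p.patient_id].trace),
            "trace2022": ";".join(calls_22[p.patient_id].trace),
        }
        for p in cohort
    ]
    risk_path = out_dir / "risk_calls.tsv"
    pd.DataFrame(risk_rows).to_csv(risk_path, sep="\t", index=False)
    written.append(risk_path)

    stage("crosstab")
    ct = reclassification_crosstab(cohort, config.vaf_cutoff)
    crosstab = {
        "matrix": [list(r) for r in ct.matrix],
        "groups": list(GROUPS),
        "marginals_2017": list(ct.row_marginals),
        "marginals_2022": list(ct.col_marginals),
        "total": ct.total,
        "reclassified": ct.off_diagonal_total,
        "flows": ct.flows(),
    }
    ct_path = out_dir / "crosstab.json"
    _write_json(ct_path, crosstab)
    written.append(ct_path)

    groups_by_edition = {
        2017: np.array([calls_17[p.patient_id].group for p in cohort]),
        2022: np.array([calls_22[p.patient_id].group for p in cohort]),
    }

    stage("km_and_logrank")
    curve_rows = []
    tests: dict = {}
    for edition, groups in groups_by_edition.items():
        tests[str(edition)] = {}
        for endpoint in config.endpoints:
            data, labels = _endpoint_data(cohort, endpoint, groups)
            for g in GROUPS:
                if not (data.group == g).any():
                    tests[str(edition)].setdefault(endpoint, {})[f"{g}_5y"] = {
                        "flag": "empty_group"
                    }
                    continue
                sub = data.subset(data.group == g)
                curve = km_fit(sub)
                at5y = survival_at(curve, 60.0)
                for i in range(curve.times.size):
                    curve_rows.append(
                        {
                            "edition": edition,
                            "endpoint": endpoint,
                            "group": g,
                            "time": curve.times[i],
                            "survival": curve.survival[i],
                            "ci_lower": curve.ci_lower[i],
                            "ci_upper": curve.ci_upper[i],
                            "n_at_risk": curve.n_at_risk[i],
                            "n_events": curve.n_events[i],
                        }
                    )
                tests[str(edition)].setdefault(endpoint, {})[f"{g}_5y"] = {
                    "estimate": at5y["estimate"],
                    "ci": [at5y["ci_lower"], at5y["ci_upper"]],
                }
            try:
                overall = logrank_test(data)
                pairs = logrank_test(data, pairwise=True)
                tests[str(edition)][endpoint]["logrank"] = {
                    "chi2": overall.statistic,
                    "df": overall.df,
                    "p": overall.p,
                }
                tests[str(edition)][endpoint]["pairwise_logrank"] = [
                    {"groups": list(r.groups), "chi2": r.statistic, "p": r.p} for r in pairs
                ]
            except ValueError as exc:
                tests[str(edition)][endpoint]["logrank"] = {"flag": str(exc)}
    tests["median_follow_up_months"] = reverse_km_median_followup(
        _endpoint_data(cohort, "OS", groups_by_edition[2022])[0]
    )
    curves_path = out_dir / "curves.tsv"
    pd.DataFrame(curve_rows).to_csv(curves_path, sep="\t", index=False, float_format="%.6g")
    written.append(curves_path)
    tests_path = out_dir / "tests.json"
    _write_json(tests_path, tests)
    written.append(tests_path)

    stage("cox_univariable")
    cox_report: dict = {"univariable": {}, "multivariable": {}}
    for edition, groups in groups_by_edition.items():
        cox_report["univariable"][str(edition)] = {}
        for endpoint in config.endpoints:
            data, labels = _endpoint_data(cohort, endpoint, groups)
            data = SurvData(
                data.time, data.event, covariates=_cox_group_dummies(labels)
            )
            try:
                fit = cox_fit(data)
                cox_report["univariable"][str(edition)][endpoint] = _coxfit_dict(fit)
            except (ValueError, ConvergenceError) as exc:
                cox_report["univariable"][str(edition)][endpoint] = {"flag": str(exc)}

    stage("cox_multivariable")
    groups22 = groups_by_edition[2022]
    base_covs = {
        "age_per_decade": np.array([p.age_years / 10.0 for p in cohort]),
        "male": np.array([1.0 if p.sex == "male" else 0.0 for p in cohort]),
        "log_wbc": np.array([math.log(p.wbc) for p in cohort]),
        "bm_blast_pct": np.array([p.bm_blast_pct for p in cohort]),
    }
    for endpoint in config.endpoints:
        mask = (
            np.array([p.outcome.cr_achieved for p in cohort])
            if endpoint == "RFS"
            else np.ones(len(cohort), dtype=bool)
        )
        sub_patients = [p for p, m in zip(cohort, mask) if m]
        data, labels = _endpoint_data(cohort, endpoint, groups22)
        covs = _cox_group_dummies(labels)
        covs.update({k: v[mask] for k, v in base_covs.items()})
        hct_entry = np.array(
            [
                p.outcome.hct_time if p.outcome.hct_received else np.nan
                for p in sub_patients
            ]
        )
        # clip state entry to the endpoint time (transplant after the event
        # cannot influence it)
        hct_entry = np.where(hct_entry <= data.time, hct_entry, np.nan)
        sd_all = SurvData(data.time, data.event, covariates=covs)

        # univariable screen (p < 0.05) on the non-group covariates; the risk
        # group itself is screened via the joint dummy fit
        selected: list[str] = []
        screen: dict = {}
        try:
            group_fit = cox_fit(sd_all, covariates=list(_cox_group_dummies(labels)))
            screen["risk_group"] = {"p": [float(x) for x in group_fit.p]}
            include_group = bool((group_fit.p < 0.05).any())
        except (ValueError, ConvergenceError) as exc:
            screen["risk_group"] = {"flag": str(exc)}
            include_group = False
        for name in base_covs:
            try:
                f1 = cox_fit(sd_all, covariates=[name])
                screen[name] = _coxfit_dict(f1)["covariates"][name]
                if f1.p[0] < 0.05:
                    selected.append(name)
            except (ValueError, ConvergenceError) as exc:
                screen[name] = {"flag": str(exc)}
        if np.isfinite(hct_entry).any():
            mb_screen = mantel_byar_test(SurvData(data.time, data.event), hct_entry)
            screen["hct_td"] = {"p": mb_screen.p}
            include_hct = mb_screen.defined and mb_screen.p < 0.05
        else:
            include_hct = False
            screen["hct_td"] = {"flag": "no_hct_recipients"}

        final_covs = (list(_cox_group_dummies(labels)) if include_group else []) + selected
        try:
            fit = cox_fit(
                sd_all,
                covariates=final_covs,
                td_entry=hct_entry if include_hct else None,
                td_name="hct_td",
            )
            cox_report["multivariable"][endpoint] = {
                "screen": screen,
                "included": final_covs + (["hct_td"] if include_hct else []),
                "fit": _coxfit_dict(fit),
            }
        except (ValueError, ConvergenceError) as exc:
            cox_report["multivariable"][endpoint] = {"screen": screen, "flag": str(exc)}
    cox_path = out_dir / "cox.json"
    _write_json(cox_path, cox_report)
    written.append(cox_path)

    stage("model_comparison")
    os_data, _ = _endpoint_data(cohort, "OS", groups_by_edition[2022])
    score17 = np.array([GROUPS.index(g) for g in groups_by_edition[2017]], dtype=float)
    score22 = np.array([GROUPS.index(g) for g in groups_by_edition[2022]], dtype=float)
    try:
        cc = compare_c(score17, score22, os_data)
        harrell = {
            "eln2017": cc.c_a,
            "eln2022": cc.c_b,
            "delta": cc.delta,
            "se": cc.se,
            "p": cc.p,
        }
    except ValueError as exc:
        harrell = {"flag": str(exc)}
    modelcomp: dict = {"harrell_c": harrell, "nri": {}}
    nri_seed = int(rng_seq.generate_state(1)[0] % (2**31))
    for horizon in config.nri_horizons:
        entry = {}
        for restricted in (False, True):
            r = nri_censored(
                groups_by_edition[2017],
                groups_by_edition[2022],
                os_data,
                horizon=horizon,
                n_boot=config.bootstrap_reps,
                seed=nri_seed,
                restrict_to_reclassified=restricted,
            )
            entry["reclassified_only" if restricted else "all_subjects"] = {
                "total": r.total,
                "event_component": r.event_component,
                "nonevent_component": r.nonevent_component,
                "ci": [r.ci_lower, r.ci_upper],
                "n_up": r.n_up,
                "n_down": r.n_down,
                "flags": list(r.flags),
            }
        modelcomp["nri"][f"{horizon:g}m"] = entry
    mc_path = out_dir / "modelcomp.json"
    _write_json(mc_path, modelcomp)
    written.append(mc_path)

    stage("hct_analyses")
    hct_report: dict = {"subgroups": hct_subgroup_report(cohort, 2022, config.vaf_cutoff)}
    if config.censor_at_hct:
        sens: dict = {}
        intervening = np.array(
            [p.outcome.hct_time if p.outcome.hct_received else np.nan for p in cohort]
        )
        censored = censor_at_event(os_data, intervening)
        for g in GROUPS:
            sub = censored.subset(np.array(groups_by_edition[2022]) == g)
            at5y = survival_at(km_fit(sub), 60.0)
            sens[g] = {"os_5y": at5y["estimate"], "ci": [at5y["ci_lower"], at5y["ci_upper"]]}
        lr = logrank_test(censored)
        sens["logrank"] = {"chi2": lr.statistic, "df": lr.df, "p": lr.p}
        hct_report["censored_at_hct"] = sens
    hct_path = out_dir / "hct.json"
    _write_json(hct_path, hct_report)
    written.append(hct_path)

    stage("manifest")
    config_dict = config.to_dict()
    config_hash = hashlib.sha256(
        json.dumps(config_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "package_version": __version__,
        "config": config_dict,
        "config_sha256": config_hash,
        "seed": config.seed,
        "n_patients": len(cohort),
        "group_sizes_2017": {g: int((groups_by_edition[2017] == g).sum()) for g in GROUPS},
        "group_sizes_2022": {g: int((groups_by_edition[2022] == g).sum()) for g in GROUPS},
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
    }
    manifest_path = out_dir / "manifest.json"
    _write_json(manifest_path, manifest)
    written.append(manifest_path)

    return {
        "crosstab": crosstab,
        "tests": tests,
        "cox": cox_report,
        "modelcomp": modelcomp,
        "hct": hct_report,
        "manifest": manifest,
        "paths": {p.name: str(p) for p in written},
    }
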