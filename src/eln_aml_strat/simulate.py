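"""Synthetic AML cohort generator.

The generator has two halves:

* **Genotypes** come from a blueprint of archetypes — genotype templates
  (karyotype string plus mutation calls) with fixed counts.  The shipped
  default is a 624-patient table whose composition, once pushed through the
  two rule engines, reproduces the published reclassification structure of a
  real validation cohort (2022 group sizes 205/295/124, 134 patients
  reclassified, and the documented flow counts between editions).  No risk
  label is ever stored in generated data: all group structure must be
  recovered by the classifier, which keeps tests non-circular.

* **Outcomes** come from a parametric survival model: exponential death and
  relapse times with a group-specific hazard (groups assigned internally via
  the 2022 engine and then discarded), Bernoulli complete-remission (CR)
  status with group-specific rates, allogeneic transplant (HCT) assigned
  among CR patients with uniform timing, a post-HCT hazard multiplier, and
  uniform administrative censoring calibrated so the reverse-KM median
  follow-up lands near 84 months.

Everything is deterministic given a seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .classify import classify_eln2022, derive_profile, GROUPS
from .cohort import ClinicalOutcome, Cohort, MutationCall, PatientRecord

__all__ = [
    "MutationSpec",
    "Archetype",
    "CohortBlueprint",
    "default_blueprint",
    "generate_genotypes",
    "simulate_outcomes",
    "generate_cohort",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class MutationSpec:
    """Template for one mutation call; the VAF is drawn at generation time."""

    gene: str
    allelic_ratio: Optional[float] = None
    allele_count: Optional[str] = None
    bzip_in_frame: Optional[bool] = None


@dataclass(frozen=True)
class Archetype:
    """Genotype template replicated ``count`` times in the cohort.

    ``karyotype`` may contain the placeholder ``{sex}`` which is filled with
    the drawn sex-chromosome pair (XX/XY).
    """

    name: str
    count: int
    karyotype: str
    mutations: tuple[MutationSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.count < 0:
            raise ValueError("archetype count must be >= 0")


@dataclass(frozen=True)
class CohortBlueprint:
    """Archetype table plus outcome-simulation parameters.

    Hazards are per month.  ``hr_by_group`` multiplies the baseline
    (favorable) hazard for the intermediate and adverse groups;
    ``post_hct_multiplier`` scales both death and relapse hazards after
    transplant, per group.  ``censor_window`` is the uniform administrative
    censoring interval.
    """

    archetypes: tuple[Archetype, ...]
    baseline_hazard: float = -math.log(0.55) / 60.0  # 5-year OS 0.55 in favorable
    relapse_baseline_hazard: float = -math.log(0.65) / 60.0
    hr_by_group: tuple[float, float, float] = (1.0, 2.340, 4.380)
    cr_prob: tuple[float, float, float] = (0.922, 0.854, 0.661)
    hct_prob_cr: float = 0.449
    hct_window: tuple[float, float] = (3.0, 9.0)
    post_hct_multiplier: tuple[float, float, float] = (1.0, 0.5, 0.5)
    censor_window: tuple[float, float] = (24.0, 144.8)
    cr_window: tuple[float, float] = (0.5, 2.0)
    induction_failure_window: tuple[float, float] = (0.5, 2.0)
    vaf_window: tuple[float, float] = (20.0, 45.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.archetypes:
            raise ValueError("blueprint requires at least one archetype")
        if self.baseline_hazard <= 0 or self.relapse_baseline_hazard <= 0:
            raise ValueError("hazards must be > 0")
        for p in (self.hct_prob_cr, *self.cr_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")
        if any(h <= 0 for h in self.hr_by_group) or any(
            m <= 0 for m in self.post_hct_multiplier
        ):
            raise ValueError("hazard multipliers must be > 0")
        if self.cr_window[1] > self.hct_window[0]:
            # the outcome model decides CR before the transplant hazard break
            raise ValueError("CR assessment window must end before the HCT window starts")

    @property
    def total_count(self) -> int:
        return sum(a.count for a in self.archetypes)

    def to_dict(self) -> dict:
        return {
            "archetypes": [
                {
                    "name": a.name,
                    "count": a.count,
                    "karyotype": a.karyotype,
                    "mutations": [
                        {
                            "gene": m.gene,
                            "allelic_ratio": m.allelic_ratio,
                            "allele_count": m.allele_count,
                            "bzip_in_frame": m.bzip_in_frame,
                        }
                        for m in a.mutations
                    ],
                }
                for a in self.archetypes
            ],
            "baseline_hazard": self.baseline_hazard,
            "relapse_baseline_hazard": self.relapse_baseline_hazard,
            "hr_by_group": list(self.hr_by_group),
            "cr_prob": list(self.cr_prob),
            "hct_prob_cr": self.hct_prob_cr,
            "hct_window": list(self.hct_window),
            "post_hct_multiplier": list(self.post_hct_multiplier),
            "censor_window": list(self.censor_window),
            "cr_window": list(self.cr_window),
            "induction_failure_window": list(self.induction_failure_window),
            "vaf_window": list(self.vaf_window),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CohortBlueprint":
        archetypes = tuple(
            Archetype(
                name=a["name"],
                count=int(a["count"]),
                karyotype=a["karyotype"],
                mutations=tuple(
                    MutationSpec(
                        gene=m["gene"],
                        allelic_ratio=m.get("allelic_ratio"),
                        allele_count=m.get("allele_count"),
                        bzip_in_frame=m.get("bzip_in_frame"),
                    )
                    for m in a.get("mutations", [])
                ),
            )
            for a in d["archetypes"]
        )
        kwargs = {k: v for k, v in d.items() if k != "archetypes"}
        for k in (
            "hr_by_group",
            "cr_prob",
            "hct_window",
            "post_hct_multiplier",
            "censor_window",
            "cr_window",
            "induction_failure_window",
            "vaf_window",
        ):
            if k in kwargs:
                kwargs[k] = tuple(kwargs[k])
        return cls(archetypes=archetypes, **kwargs)


_NORMAL = "46,{sex}[20]"
_T8_21 = "46,{sex},t(8;21)(q22;q22.1)[20]"
_INV16 = "46,{sex},inv(16)(p13.1q22)[20]"

_M = MutationSpec


def default_blueprint() -> CohortBlueprint:
    """The shipped 624-patient archetype table with default outcome calibration.

    Genotype templates only — risk labels are never stored and must emerge
    from the classifiers.  Outcome defaults: favorable-group exponential
    hazard set so five-year survival is 0.55; overall-survival hazard
    multipliers 2.340 (intermediate) and 4.380 (adverse); CR probabilities
    0.922/0.854/0.661; HCT probability 0.449 among CR with uniform timing on
    [3, 9] months; post-HCT hazard multiplier 1.0/0.5/0.5; administrative
    censoring uniform on [24.0, 144.8] months (median 84.4).
    """
    a = [
        Archetype("B01", 59, _T8_21),
        Archetype("B02", 3, _T8_21, (_M("ASXL1"),)),
        Archetype("B03", 25, _INV16),
        Archetype("B04", 2, _INV16, (_M("TP53"),)),
        Archetype("B05", 68, _NORMAL, (_M("NPM1"),)),
        Archetype("B06", 13, _NORMAL, (_M("NPM1"), _M("SRSF2"))),
        Archetype("B07", 14, _NORMAL, (_M("CEBPA", allele_count="biallelic", bzip_in_frame=True),)),
        Archetype("B08", 31, _NORMAL, (_M("NPM1"), _M("FLT3-ITD", allelic_ratio=0.3))),
        Archetype("B09", 3, _NORMAL, (_M("NPM1"), _M("FLT3-ITD", allelic_ratio=0.3), _M("U2AF1"))),
        Archetype("B10", 21, _NORMAL, (_M("CEBPA", allele_count="monoallelic", bzip_in_frame=True),)),
        Archetype("B11", 153, _NORMAL),  # passengers added at generation time
        Archetype("B12", 48, _NORMAL, (_M("FLT3-ITD", allelic_ratio=0.3),)),
        Archetype("B13", 30, _NORMAL, (_M("NPM1"), _M("FLT3-ITD", allelic_ratio=0.8))),
        Archetype("B14", 46, _NORMAL, (_M("SRSF2"),)),
        Archetype("B15", 33, _NORMAL, (_M("FLT3-ITD", allelic_ratio=0.8),)),
        Archetype("B16", 16, "44,{sex},-5,-7,del(17)(p11.2)[18]"),
        Archetype("B17", 1, "45,{sex},-7,del(5)(q13q33),add(12)(p13)[20]", (_M("U2AF1"),)),
        Archetype("B18", 7, "46,{sex},del(5)(q13q33)[20]"),
        Archetype("B19", 5, "46,{sex},t(9;22)(q34;q11.2)[20]"),
        Archetype("B20", 1, "46,{sex},t(6;9)(p23;q34.1)[20]"),
        Archetype("B21", 17, _NORMAL, (_M("TP53"),)),
        Archetype("B22", 14, _NORMAL, (_M("RUNX1"),)),
        Archetype("B23", 14, _NORMAL, (_M("ASXL1"),)),
    ]
    return CohortBlueprint(archetypes=tuple(a))


_PASSENGER_GENES = ("DNMT3A", "TET2", "NRAS")


def _draw_clinical(rng: np.random.Generator) -> dict:
    age = int(np.clip(round(rng.normal(51.0, 13.0)), 18, 84))
    sex = "male" if rng.random() < 0.519 else "female"
    u = rng.random()
    disease = "de_novo" if u < 0.925 else ("secondary" if u < 0.979 else "treatment_related")
    wbc = float(np.clip(rng.lognormal(math.log(15000.0), 1.0), 300.0, 400000.0))
    blast = float(rng.uniform(20.0, 95.0))
    return dict(age_years=age, sex=sex, disease_type=disease, wbc=wbc, bm_blast_pct=blast)


def generate_genotypes(blueprint: CohortBlueprint, seed: Optional[int] = None) -> Cohort:
    """Realize the blueprint as a genotype-only cohort.

    Emits exactly ``count`` patients per archetype with concrete VAFs (drawn
    uniformly from the blueprint's VAF window, well above the positivity
    cut-off) and karyotype strings.  Patient order is shuffled by the seed;
    the same seed yields a byte-identical cohort.
    """
    rng = np.random.default_rng(blueprint.seed if seed is None else seed)
    lo, hi = blueprint.vaf_window
    protos: list[tuple[Archetype, dict, tuple[MutationCall, ...], str]] = []
    for arch in blueprint.archetypes:
        for _ in range(arch.count):
            clin = _draw_clinical(rng)
            karyotype = arch.karyotype.format(sex="XY" if clin["sex"] == "male" else "XX")
            calls = tuple(
                MutationCall(
                    gene=m.gene,
                    vaf=float(rng.uniform(lo, hi)),
                    allelic_ratio=m.allelic_ratio,
                    allele_count=m.allele_count,
                    bzip_in_frame=m.bzip_in_frame,
                )
                for m in arch.mutations
            )
            if arch.name == "B11":
                # benign passengers so lesion-free patients still exercise IO
                k = int(rng.integers(1, len(_PASSENGER_GENES) + 1))
                picks = rng.choice(len(_PASSENGER_GENES), size=k, replace=False)
                calls = tuple(
                    MutationCall(gene=_PASSENGER_GENES[i], vaf=float(rng.uniform(lo, hi)))
                    for i in sorted(picks)
                )
            protos.append((arch, clin, calls, karyotype))

    order = rng.permutation(len(protos))
    width = max(4, len(str(len(protos))))
    records = []
    for new_idx, old_idx in enumerate(order):
        arch, clin, calls, karyotype = protos[old_idx]
        records.append(
            PatientRecord(
                patient_id=f"P{new_idx + 1:0{width}d}",
                karyotype=karyotype,
                mutations=calls,
                outcome=None,
                **clin,
            )
        )
    return Cohort(tuple(records))


def _invert_piecewise_hazard(e: float, lam: float, break_t: float, mult: float) -> float:
    """Event time for unit-exponential draw ``e`` under a hazard that is
    ``lam`` before ``break_t`` and ``lam*mult`` after."""
    if e <= lam * break_t:
        return e / lam
    return break_t + (e - lam * break_t) / (lam * mult)


def simulate_outcomes(
    cohort: Cohort, blueprint: CohortBlueprint, seed: Optional[int] = None
) -> Cohort:
    """Fill in outcomes for a genotype cohort.

    The risk group driving the hazards is computed internally with the 2022
    engine and not stored.  Death and relapse times are exponential with the
    group hazard, scaled by the post-HCT multiplier after transplant;
    CR is Bernoulli with the group rate but requires surviving to the
    response-assessment time; HCT happens only among CR patients still alive
    and under follow-up at the drawn transplant time.  All outcome
    invariants (EFS <= OS, HCT <= OS, RFS present iff CR) hold by
    construction for every seed.
    """
    rng = np.random.default_rng(blueprint.seed if seed is None else seed)
    records = []
    for record in cohort:
        gi = GROUPS.index(classify_eln2022(derive_profile(record)).group)
        lam_death = blueprint.baseline_hazard * blueprint.hr_by_group[gi]
        lam_relapse = blueprint.relapse_baseline_hazard * blueprint.hr_by_group[gi]
        mult = blueprint.post_hct_multiplier[gi]

        # fixed draw schedule keeps the stream aligned across code paths
        u_cr = rng.random()
        censor = rng.uniform(*blueprint.censor_window)
        t_cr = rng.uniform(*blueprint.cr_window)
        u_hct = rng.random()
        t_hct = rng.uniform(*blueprint.hct_window)
        fail_t = rng.uniform(*blueprint.induction_failure_window)
        e_death = rng.exponential()
        e_relapse = rng.exponential()

        # CR requires surviving to response assessment; because t_cr always
        # precedes the earliest transplant time, survival past t_cr depends
        # only on the pre-transplant hazard, so CR can be decided first and
        # the post-HCT hazard break applied only where HCT can occur.
        cr = (u_cr < blueprint.cr_prob[gi]) and e_death > lam_death * t_cr
        hct_candidate = cr and u_hct < blueprint.hct_prob_cr
        break_t = t_hct if hct_candidate else math.inf
        death = _invert_piecewise_hazard(e_death, lam_death, break_t, mult)
        relapse_gap = _invert_piecewise_hazard(
            e_relapse, lam_relapse, max(break_t - t_cr, 0.0), mult
        )
        os_time = min(death, censor)
        os_event = death <= censor

        if cr:
            hct_received = hct_candidate and t_hct < min(death, censor)
            relapse_abs = t_cr + relapse_gap
            event_t = min(relapse_abs, death)
            efs_time = min(event_t, censor)
            efs_event = event_t <= censor
            outcome = ClinicalOutcome(
                os_time=os_time,
                os_event=os_event,
                efs_time=efs_time,
                efs_event=efs_event,
                cr_achieved=True,
                rfs_time=efs_time - t_cr,
                rfs_event=efs_event,
                hct_received=hct_received,
                hct_time=t_hct if hct_received else None,
            )
        else:
            event_t = min(fail_t, death)
            efs_time = min(event_t, censor)
            outcome = ClinicalOutcome(
                os_time=os_time,
                os_event=os_event,
                efs_time=efs_time,
                efs_event=event_t <= censor,
                cr_achieved=False,
                hct_received=False,
            )
        records.append(replace(record, outcome=outcome))
    return Cohort(tuple(records))


def generate_cohort(blueprint: Optional[CohortBlueprint] = None, seed: Optional[int] = None) -> Cohort:
    """Convenience: genotypes plus outcomes in one call.

    Genotypes and outcomes use decoupled seeds derived from ``seed`` so the
    genotype composition stays fixed while outcome draws vary with the seed.
    """
    bp = blueprint if blueprint is not None else default_blueprint()
    s = bp.seed if seed is None else seed
    genotypes = generate_genotypes(bp, seed=s)
    return simulate_outcomes(genotypes, bp, seed=s + 1)
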