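"""Deterministic ELN 2017 and ELN 2022 risk-group rule engines.

Both engines map a :class:`GenotypeProfile` (cytogenetic feature flags plus
curated mutation flags) to one of three risk groups — favorable,
intermediate, adverse — and record the ordered list of rules that fired.

The engines differ in five documented mechanisms:

1. the FLT3-ITD allelic ratio (AR) is consulted only by the 2017 engine
   (low < 0.5 vs high >= 0.5); the 2022 engine never reads it;
2. CEBPA: biallelic mutation is favorable-defining in 2017; an in-frame
   basic-leucine-zipper (bZIP) mutation, mono- or biallelic, in 2022;
3. myelodysplasia-related gene mutations beyond RUNX1/ASXL1 are
   adverse-defining only in 2022;
4. adverse-risk cytogenetics override NPM1-mutated favorable risk in 2022
   (in 2017 the NPM1 rule likewise requires non-adverse cytogenetics);
5. the 2022 cytogenetic adverse list adds t(3q26.2;v) and t(8;16) and
   exempts hyperdiploid karyotypes from the complex-karyotype rule.

Rule precedence is an explicit ordered list evaluated top-down: core-binding
factor (CBF) translocations, then adverse cytogenetics, then the remaining
favorable-defining lesions, then molecular adverse markers, then the
intermediate default.  A favorable-defining lesion therefore suppresses
co-occurring molecular adversity (TP53, myelodysplasia-related genes); the
suppression is recorded in the trace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .cohort import (
    DEFAULT_VAF_CUTOFF,
    MDS_GENES,
    Cohort,
    PatientRecord,
    filter_positive_mutations,
)
from .karyotype import KaryotypeFeatures, is_adverse_cytogenetics, parse_karyotype

__all__ = [
    "FAVORABLE",
    "INTERMEDIATE",
    "ADVERSE",
    "GROUPS",
    "ClassificationError",
    "GenotypeProfile",
    "RiskCall",
    "CrossTab",
    "derive_profile",
    "classify",
    "classify_eln2017",
    "classify_eln2022",
    "reclassification_crosstab",
]

logger = logging.getLogger(__name__)

FAVORABLE = "favorable"
INTERMEDIATE = "intermediate"
ADVERSE = "adverse"
#: Risk groups in increasing order of risk; index = ordinal risk score.
GROUPS = (FAVORABLE, INTERMEDIATE, ADVERSE)

#: 2017 allelic-ratio split: AR < 0.5 is "low", >= 0.5 is "high".
AR_HIGH_THRESHOLD = 0.5
#: 2022 convention: TP53 adversity requires VAF >= 10% (absent VAF qualifies).
TP53_VAF_THRESHOLD = 10.0


class ClassificationError(ValueError):
    """Profile cannot be classified under the requested edition."""


@dataclass(frozen=True)
class GenotypeProfile:
    """Classification inputs derived from one patient record."""

    karyo: KaryotypeFeatures
    npm1_mut: bool = False
    flt3_itd: bool = False
    flt3_itd_ar: float | None = None
    cebpa_bzip_in_frame: bool = False
    cebpa_biallelic: bool = False
    tp53_mut: bool = False
    tp53_vaf: float | None = None
    mds_genes_mut: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if self.flt3_itd_ar is not None and not self.flt3_itd:
            raise ClassificationError("flt3_itd_ar present without flt3_itd")
        unknown = set(self.mds_genes_mut) - MDS_GENES
        if unknown:
            raise ClassificationError(f"not myelodysplasia-related genes: {sorted(unknown)}")
        object.__setattr__(self, "mds_genes_mut", frozenset(self.mds_genes_mut))


@dataclass(frozen=True)
class RiskCall:
    """Risk-group label plus the ordered trace of fired rules."""

    group: str
    edition: int
    trace: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ClassificationError(f"unknown risk group {self.group!r}")
        if not self.trace:
            raise ClassificationError("rule trace must be nonempty")


def derive_profile(
    record: PatientRecord, vaf_cutoff: float = DEFAULT_VAF_CUTOFF
) -> GenotypeProfile:
    """Build the classification inputs from one record.

    Mutation flags are computed from the positivity-filtered calls (VAF >=
    ``vaf_cutoff``); cytogenetic flags from the parsed karyotype string.
    """
    muts = filter_positive_mutations(record, vaf_cutoff)
    karyo = parse_karyotype(record.karyotype)
    genes = {m.gene for m in muts}

    ar_values = [m.allelic_ratio for m in muts if m.gene == "FLT3-ITD" and m.allelic_ratio is not None]
    tp53_vafs = [m.vaf for m in muts if m.gene == "TP53"]
    cebpa_calls = [m for m in muts if m.gene == "CEBPA"]

    return GenotypeProfile(
        karyo=karyo,
        npm1_mut="NPM1" in genes,
        flt3_itd="FLT3-ITD" in genes,
        flt3_itd_ar=max(ar_values) if ar_values else None,
        cebpa_bzip_in_frame=any(m.bzip_in_frame for m in cebpa_calls),
        cebpa_biallelic=any(m.allele_count == "biallelic" for m in cebpa_calls),
        tp53_mut="TP53" in genes,
        tp53_vaf=max(tp53_vafs) if tp53_vafs else None,
        mds_genes_mut=frozenset(genes & MDS_GENES),
    )


def _suppressed(trace: list[str], profile: GenotypeProfile, edition: int) -> None:
    """Note molecular adversity suppressed by a favorable-defining lesion."""
    if profile.tp53_mut:
        trace.append("tp53_suppressed_by_favorable_lesion")
    if edition == 2017:
        hit = profile.mds_genes_mut & {"RUNX1", "ASXL1"}
    else:
        hit = profile.mds_genes_mut
    if hit:
        trace.append("mds_genes_suppressed_by_favorable_lesion")


def classify_eln2017(profile: GenotypeProfile) -> RiskCall:
    """Risk group under the 2017 edition.

    Requires the FLT3-ITD allelic ratio whenever an ITD is present — the 2017
    rules cannot be evaluated without it.
    """
    if profile.flt3_itd and profile.flt3_itd_ar is None:
        raise ClassificationError(
            "2017 classification requires the FLT3-ITD allelic ratio when an ITD is present"
        )
    k = profile.karyo
    trace: list[str] = []
    low_ar = (not profile.flt3_itd) or profile.flt3_itd_ar < AR_HIGH_THRESHOLD

    if k.t_8_21 or k.inv16_or_t16_16:
        trace.append("cbf_translocation")
        _suppressed(trace, profile, 2017)
        return RiskCall(FAVORABLE, 2017, tuple(trace))

    adverse_cyto = is_adverse_cytogenetics(k, 2017)
    if adverse_cyto and k.t_9_11:
        # 2017 footnote convention: t(9;11) takes precedence over rare
        # co-occurring adverse markers.
        trace.append("adverse_cytogenetics_suppressed_by_t_9_11")
        adverse_cyto = False
    if adverse_cyto:
        trace.append("adverse_cytogenetics")
        return RiskCall(ADVERSE, 2017, tuple(trace))

    if profile.npm1_mut and low_ar:
        trace.append("npm1_without_flt3_itd" if not profile.flt3_itd else "npm1_with_low_ar_flt3_itd")
        _suppressed(trace, profile, 2017)
        return RiskCall(FAVORABLE, 2017, tuple(trace))
    if profile.cebpa_biallelic:
        trace.append("cebpa_biallelic")
        _suppressed(trace, profile, 2017)
        return RiskCall(FAVORABLE, 2017, tuple(trace))

    if not k.t_9_11:
        if profile.tp53_mut:
            trace.append("tp53_mutation")
            return RiskCall(ADVERSE, 2017, tuple(trace))
        if profile.mds_genes_mut & {"RUNX1", "ASXL1"}:
            trace.append("runx1_or_asxl1_mutation")
            return RiskCall(ADVERSE, 2017, tuple(trace))
        if (not profile.npm1_mut) and profile.flt3_itd and not low_ar:
            trace.append("flt3_itd_high_ar_wildtype_npm1")
            return RiskCall(ADVERSE, 2017, tuple(trace))
    else:
        trace.append("t_9_11")

    if profile.npm1_mut and profile.flt3_itd and not low_ar:
        trace.append("npm1_with_high_ar_flt3_itd")
    elif (not profile.npm1_mut) and profile.flt3_itd and low_ar:
        trace.append("wildtype_npm1_with_low_ar_flt3_itd")
    if not trace:
        trace.append("no_classifying_lesion")
    return RiskCall(INTERMEDIATE, 2017, tuple(trace))


def classify_eln2022(profile: GenotypeProfile) -> RiskCall:
    """Risk group under the 2022 edition.  The allelic ratio is never read."""
    k = profile.karyo
    trace: list[str] = []

    if k.t_8_21 or k.inv16_or_t16_16:
        trace.append("cbf_translocation")
        _suppressed(trace, profile, 2022)
        return RiskCall(FAVORABLE, 2022, tuple(trace))

    adverse_cyto = is_adverse_cytogenetics(k, 2022)
    if adverse_cyto and k.t_9_11:
        trace.append("adverse_cytogenetics_suppressed_by_t_9_11")
        adverse_cyto = False
    if adverse_cyto:
        trace.append("adverse_cytogenetics")
        return RiskCall(ADVERSE, 2022, tuple(trace))

    if profile.cebpa_bzip_in_frame:
        trace.append("cebpa_bzip_in_frame")
        if profile.tp53_mut:
            # Convention-dependent: favorable-lesion suppression extended to
            # TP53 under CEBPA-bZIP; flagged so downstream users can audit.
            trace.append("tp53_suppressed_by_favorable_lesion")
        if profile.mds_genes_mut:
            trace.append("mds_genes_suppressed_by_favorable_lesion")
        return RiskCall(FAVORABLE, 2022, tuple(trace))
    if profile.npm1_mut and not profile.flt3_itd:
        trace.append("npm1_without_flt3_itd")
        _suppressed(trace, profile, 2022)
        return RiskCall(FAVORABLE, 2022, tuple(trace))

    if profile.tp53_mut and (
        profile.tp53_vaf is None or profile.tp53_vaf >= TP53_VAF_THRESHOLD
    ):
        if profile.tp53_vaf is None:
            logger.info("TP53 call without VAF treated as qualifying for adversity")
            trace.append("tp53_mutation_vaf_absent")
        else:
            trace.append("tp53_mutation")
        return RiskCall(ADVERSE, 2022, tuple(trace))
    if profile.mds_genes_mut:
        trace.append("mds_gene_mutation:" + ",".join(sorted(profile.mds_genes_mut)))
        return RiskCall(ADVERSE, 2022, tuple(trace))

    if k.t_9_11 and "adverse_cytogenetics_suppressed_by_t_9_11" not in trace:
        trace.append("t_9_11")
    elif profile.npm1_mut and profile.flt3_itd:
        trace.append("npm1_with_flt3_itd")
    elif profile.flt3_itd:
        trace.append("flt3_itd_wildtype_npm1")
    if not trace:
        trace.append("no_classifying_lesion")
    return RiskCall(INTERMEDIATE, 2022, tuple(trace))


def classify(profile: GenotypeProfile, edition: int) -> RiskCall:
    """Dispatch to the edition-specific engine."""
    if edition == 2017:
        return classify_eln2017(profile)
    if edition == 2022:
        return classify_eln2022(profile)
    raise ClassificationError(f"unknown ELN edition {edition!r}")


@dataclass(frozen=True)
class CrossTab:
    """3x3 reclassification table indexed (2017 group, 2022 group)."""

    matrix: tuple[tuple[int, ...], ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix)
        if m.shape != (3, 3) or (m < 0).any():
            raise ClassificationError("cross-tab must be a 3x3 nonnegative matrix")

    @property
    def row_marginals(self) -> tuple[int, ...]:
        """Group sizes under the 2017 edition."""
        return tuple(int(sum(row)) for row in self.matrix)

    @property
    def col_marginals(self) -> tuple[int, ...]:
        """Group sizes under the 2022 edition."""
        return tuple(int(sum(col)) for col in zip(*self.matrix))

    @property
    def total(self) -> int:
        return sum(self.row_marginals)

    @property
    def off_diagonal_total(self) -> int:
        """Number of patients whose risk group changed between editions."""
        return self.total - sum(self.matrix[i][i] for i in range(3))

    def cell(self, group_2017: str, group_2022: str) -> int:
        return self.matrix[GROUPS.index(group_2017)][GROUPS.index(group_2022)]

    def flows(self) -> list[dict]:
        """Sankey-ready flow list: one entry per nonzero cell."""
        out = []
        for i, g17 in enumerate(GROUPS):
            for j, g22 in enumerate(GROUPS):
                n = self.matrix[i][j]
                if n:
                    out.append({"from_2017": g17, "to_2022": g22, "n": int(n)})
        return out


def reclassification_crosstab(
    cohort: Cohort, vaf_cutoff: float = DEFAULT_VAF_CUTOFF
) -> CrossTab:
    """Classify every patient under both editions and cross-tabulate.

    Classification errors are re-raised with the offending patient id.
    """
    matrix = np.zeros((3, 3), dtype=int)
    for record in cohort:
        try:
            profile = derive_profile(record, vaf_cutoff)
            g17 = classify_eln2017(profile).group
            g22 = classify_eln2022(profile).group
        except (ClassificationError, ValueError) as exc:
            raise ClassificationError(f"patient {record.patient_id!r}: {exc}") from exc
        matrix[GROUPS.index(g17), GROUPS.index(g22)] += 1
    return CrossTab(tuple(tuple(int(x) for x in row) for row in matrix))
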