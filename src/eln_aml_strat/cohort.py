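"""Patient-level domain types and tab-separated interchange IO.

The package works on curated per-patient records: clinical covariates, a
karyotype string, a list of curated mutation calls from a targeted panel,
and censored outcome times for overall, event-free and relapse-free
survival.  Two TSV files (``patients.tsv`` and ``mutations.tsv``, joined on
``patient_id``) are the interchange format consumed and produced here; all
downstream modules operate on the in-memory types.

Times are stored in months.  Variant allele fractions (VAF) are percentages
in [0, 100].  Absent optional values are serialized as the literal token
``NA`` and booleans as ``0``/``1``.
"""

from __future__ import annotations

import csv
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional, Sequence

__all__ = [
    "CohortError",
    "SchemaError",
    "MutationCall",
    "ClinicalOutcome",
    "PatientRecord",
    "Cohort",
    "MDS_GENES",
    "DEFAULT_GENE_PANEL",
    "DEFAULT_VAF_CUTOFF",
    "read_cohort",
    "write_cohort",
    "filter_positive_mutations",
]

logger = logging.getLogger(__name__)

#: Myelodysplasia-related genes; adverse-defining in the 2022 classification
#: (RUNX1 and ASXL1 were already adverse-defining in 2017).
MDS_GENES = frozenset(
    {"ASXL1", "BCOR", "EZH2", "RUNX1", "SF3B1", "SRSF2", "STAG2", "U2AF1", "ZRSR2"}
)

#: Default targeted-panel vocabulary.  The classification-relevant genes plus
#: common co-occurring drivers/passengers.  The full 45-gene panel is not
#: reconstructable from published material, so unknown symbols are accepted
#: with a logged warning rather than rejected.
DEFAULT_GENE_PANEL = frozenset(
    {
        "NPM1",
        "FLT3-ITD",
        "FLT3-TKD",
        "CEBPA",
        "TP53",
        "DNMT3A",
        "TET2",
        "IDH1",
        "IDH2",
        "NRAS",
        "KRAS",
        "KIT",
        "WT1",
        "PTPN11",
        "GATA2",
        "CSF3R",
        "JAK2",
        "SETBP1",
        "PHF6",
        "NF1",
    }
    | MDS_GENES
)

#: Mutation-positivity cut-off: VAF of 2% or more counts as mutated.
DEFAULT_VAF_CUTOFF = 2.0

SEX_VALUES = ("male", "female")
DISEASE_TYPES = ("de_novo", "secondary", "treatment_related")
ALLELE_COUNTS = ("monoallelic", "biallelic")

NA = "NA"


class CohortError(ValueError):
    """Invalid domain object (violated invariant)."""


class SchemaError(CohortError):
    """Malformed interchange file; carries file/line context in the message."""


@dataclass(frozen=True)
class MutationCall:
    """One curated mutation call from the targeted panel.

    ``allelic_ratio`` (the mutant/wild-type allele ratio) is meaningful only
    for FLT3-ITD; ``allele_count`` and ``bzip_in_frame`` (whether the call is
    an in-frame mutation of the basic leucine zipper domain) only for CEBPA.
    """

    gene: str
    vaf: float
    allelic_ratio: Optional[float] = None
    allele_count: Optional[str] = None
    bzip_in_frame: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.gene:
            raise CohortError("mutation call requires a gene symbol")
        if self.gene not in DEFAULT_GENE_PANEL:
            logger.warning("gene %r is not in the shipped panel vocabulary", self.gene)
        if not (0.0 <= self.vaf <= 100.0):
            raise CohortError(f"vaf must be in [0, 100], got {self.vaf!r}")
        object.__setattr__(self, "vaf", float(self.vaf))
        if self.allelic_ratio is not None:
            object.__setattr__(self, "allelic_ratio", float(self.allelic_ratio))
        if self.allelic_ratio is not None:
            if self.gene != "FLT3-ITD":
                raise CohortError("allelic_ratio is only valid for FLT3-ITD calls")
            if not (self.allelic_ratio >= 0.0):
                raise CohortError(f"allelic_ratio must be >= 0, got {self.allelic_ratio!r}")
        if self.allele_count is not None:
            if self.gene != "CEBPA":
                raise CohortError("allele_count is only valid for CEBPA calls")
            if self.allele_count not in ALLELE_COUNTS:
                raise CohortError(f"allele_count must be one of {ALLELE_COUNTS}")
        if self.bzip_in_frame is not None and self.gene != "CEBPA":
            raise CohortError("bzip_in_frame is only valid for CEBPA calls")


@dataclass(frozen=True)
class ClinicalOutcome:
    """Censored outcome times (months) and response/transplant status.

    Overall survival (OS) and event-free survival (EFS) are measured from
    diagnosis; relapse-free survival (RFS) from achievement of complete
    remission (CR) and is therefore present iff ``cr_achieved``.  ``hct_time``
    is the time of allogeneic transplant, present iff ``hct_received``.
    """

    os_time: float
    os_event: bool
    efs_time: float
    efs_event: bool
    cr_achieved: bool
    rfs_time: Optional[float] = None
    rfs_event: Optional[bool] = None
    hct_received: bool = False
    hct_time: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("os_time", "efs_time"):
            v = getattr(self, name)
            if not (isinstance(v, (int, float)) and math.isfinite(v) and v >= 0):
                raise CohortError(f"{name} must be a finite number >= 0, got {v!r}")
            object.__setattr__(self, name, float(v))
        if self.rfs_time is not None:
            object.__setattr__(self, "rfs_time", float(self.rfs_time))
        if self.hct_time is not None:
            object.__setattr__(self, "hct_time", float(self.hct_time))
        if self.efs_time > self.os_time:
            raise CohortError(
                f"efs_time ({self.efs_time}) must not exceed os_time ({self.os_time})"
            )
        if self.cr_achieved:
            if self.rfs_time is None or self.rfs_event is None:
                raise CohortError("rfs_time/rfs_event required when cr_achieved")
            if not (math.isfinite(self.rfs_time) and self.rfs_time >= 0):
                raise CohortError(f"rfs_time must be >= 0, got {self.rfs_time!r}")
        else:
            if self.rfs_time is not None or self.rfs_event is not None:
                raise CohortError("rfs fields must be absent when CR was not achieved")
        if self.hct_received:
            if self.hct_time is None:
                raise CohortError("hct_time required when hct_received")
            if not (math.isfinite(self.hct_time) and self.hct_time >= 0):
                raise CohortError(f"hct_time must be >= 0, got {self.hct_time!r}")
            if self.hct_time > self.os_time:
                raise CohortError(
                    f"hct_time ({self.hct_time}) must not exceed os_time ({self.os_time})"
                )
        elif self.hct_time is not None:
            raise CohortError("hct_time must be absent when hct_received is false")


@dataclass(frozen=True)
class PatientRecord:
    """One subject: clinical covariates, genotype inputs and outcomes.

    ``outcome`` may be ``None`` for genotype-only cohorts (e.g. freshly
    generated synthetic genotypes before outcome simulation); such cohorts
    cannot be written to disk.
    """

    patient_id: str
    age_years: int
    sex: str
    disease_type: str
    wbc: float
    bm_blast_pct: float
    karyotype: str
    mutations: tuple[MutationCall, ...] = ()
    outcome: Optional[ClinicalOutcome] = None

    def __post_init__(self) -> None:
        if not self.patient_id:
            raise CohortError("patient_id must be nonempty")
        if not (isinstance(self.age_years, int) and self.age_years >= 18):
            raise CohortError(f"age_years must be an integer >= 18, got {self.age_years!r}")
        if self.sex not in SEX_VALUES:
            raise CohortError(f"sex must be one of {SEX_VALUES}, got {self.sex!r}")
        if self.disease_type not in DISEASE_TYPES:
            raise CohortError(
                f"disease_type must be one of {DISEASE_TYPES}, got {self.disease_type!r}"
            )
        if not (self.wbc > 0):
            raise CohortError(f"wbc must be > 0 cells/uL, got {self.wbc!r}")
        object.__setattr__(self, "wbc", float(self.wbc))
        if not (0.0 <= self.bm_blast_pct <= 100.0):
            raise CohortError(f"bm_blast_pct must be in [0, 100], got {self.bm_blast_pct!r}")
        object.__setattr__(self, "bm_blast_pct", float(self.bm_blast_pct))
        if not self.karyotype:
            raise CohortError("karyotype string must be nonempty")
        object.__setattr__(self, "mutations", tuple(self.mutations))


@dataclass(frozen=True)
class Cohort:
    """Ordered, nonempty collection of patients with unique ids."""

    patients: tuple[PatientRecord, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "patients", tuple(self.patients))
        if not self.patients:
            raise CohortError("cohort must be nonempty")
        seen: set[str] = set()
        for p in self.patients:
            if p.patient_id in seen:
                raise CohortError(f"duplicate patient_id {p.patient_id!r}")
            seen.add(p.patient_id)

    def __iter__(self) -> Iterator[PatientRecord]:
        return iter(self.patients)

    def __len__(self) -> int:
        return len(self.patients)

    def __getitem__(self, i: int) -> PatientRecord:
        return self.patients[i]


def filter_positive_mutations(
    record: PatientRecord, vaf_cutoff: float = DEFAULT_VAF_CUTOFF
) -> list[MutationCall]:
    """Return the mutation calls meeting the positivity cut-off.

    A call counts as mutation-positive when its VAF is greater than or equal
    to ``vaf_cutoff`` (percent; default 2%).  Order is preserved and the
    record is not modified.
    """
    if not (0.0 < vaf_cutoff <= 100.0):
        raise ValueError(f"vaf_cutoff must be in (0, 100], got {vaf_cutoff!r}")
    return [m for m in record.mutations if m.vaf >= vaf_cutoff]


# ---------------------------------------------------------------------------
# TSV interchange
# ---------------------------------------------------------------------------

PATIENT_COLUMNS = (
    "patient_id",
    "age_years",
    "sex",
    "disease_type",
    "wbc",
    "bm_blast_pct",
    "karyotype",
    "cr_achieved",
    "hct_received",
    "hct_time",
    "os_time",
    "os_event",
    "efs_time",
    "efs_event",
    "rfs_time",
    "rfs_event",
)

MUTATION_COLUMNS = (
    "patient_id",
    "gene",
    "vaf",
    "allelic_ratio",
    "allele_count",
    "bzip_in_frame",
)


def _ctx(path: Path, line: int) -> str:
    return f"{path.name}:{line}"


def _parse_float(raw: str, col: str, where: str) -> float:
    try:
        v = float(raw)
    except ValueError:
        raise SchemaError(f"{where}: column {col!r} is not a number: {raw!r}") from None
    if not math.isfinite(v):
        raise SchemaError(f"{where}: column {col!r} must be finite, got {raw!r}")
    return v


def _parse_opt_float(raw: str, col: str, where: str) -> Optional[float]:
    return None if raw == NA else _parse_float(raw, col, where)


def _parse_bool(raw: str, col: str, where: str) -> bool:
    if raw == "1":
        return True
    if raw == "0":
        return False
    raise SchemaError(f"{where}: column {col!r} must be 0 or 1, got {raw!r}")


def _parse_opt_bool(raw: str, col: str, where: str) -> Optional[bool]:
    return None if raw == NA else _parse_bool(raw, col, where)


def _fmt(v) -> str:
    if v is None:
        return NA
    if isinstance(v, bool):
        return "1" if v else "0"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def _read_rows(path: Path, columns: Sequence[str]) -> Iterator[tuple[int, dict]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            raise SchemaError(f"{path}: empty file, header row required")
        if tuple(reader.fieldnames) != tuple(columns):
            raise SchemaError(
                f"{path}: header mismatch; expected {list(columns)}, got {reader.fieldnames}"
            )
        for row in reader:
            if None in row or None in row.values():
                raise SchemaError(f"{_ctx(path, reader.line_num)}: wrong number of fields")
            yield reader.line_num, row


def read_cohort(patients_path, mutations_path) -> Cohort:
    """Read a cohort from ``patients.tsv`` + ``mutations.tsv``.

    Mutation rows are joined to patients by ``patient_id``; a mutation row
    referencing an unknown patient is an error.  All domain invariants are
    enforced, and violations are reported with file and line context.
    """
    patients_path = Path(patients_path)
    mutations_path = Path(mutations_path)
    for p in (patients_path, mutations_path):
        if not p.is_file():
            raise FileNotFoundError(p)

    mutations: dict[str, list[MutationCall]] = {}
    mutation_order: dict[str, list[int]] = {}
    for line, row in _read_rows(mutations_path, MUTATION_COLUMNS):
        where = _ctx(mutations_path, line)
        ac = row["allele_count"]
        try:
            call = MutationCall(
                gene=row["gene"],
                vaf=_parse_float(row["vaf"], "vaf", where),
                allelic_ratio=_parse_opt_float(row["allelic_ratio"], "allelic_ratio", where),
                allele_count=None if ac == NA else ac,
                bzip_in_frame=_parse_opt_bool(row["bzip_in_frame"], "bzip_in_frame", where),
            )
        except CohortError as exc:
            raise SchemaError(f"{where}: {exc}") from None
        mutations.setdefault(row["patient_id"], []).append(call)
        mutation_order.setdefault(row["patient_id"], []).append(line)

    records: list[PatientRecord] = []
    seen_ids: set[str] = set()
    for line, row in _read_rows(patients_path, PATIENT_COLUMNS):
        where = _ctx(patients_path, line)
        pid = row["patient_id"]
        if pid in seen_ids:
            raise SchemaError(f"{where}: duplicate patient_id {pid!r}")
        seen_ids.add(pid)
        try:
            age = int(row["age_years"])
        except ValueError:
            raise SchemaError(f"{where}: age_years is not an integer: {row['age_years']!r}")
        try:
            outcome = ClinicalOutcome(
                os_time=_parse_float(row["os_time"], "os_time", where),
                os_event=_parse_bool(row["os_event"], "os_event", where),
                efs_time=_parse_float(row["efs_time"], "efs_time", where),
                efs_event=_parse_bool(row["efs_event"], "efs_event", where),
                cr_achieved=_parse_bool(row["cr_achieved"], "cr_achieved", where),
                rfs_time=_parse_opt_float(row["rfs_time"], "rfs_time", where),
                rfs_event=_parse_opt_bool(row["rfs_event"], "rfs_event", where),
                hct_received=_parse_bool(row["hct_received"], "hct_received", where),
                hct_time=_parse_opt_float(row["hct_time"], "hct_time", where),
            )
            record = PatientRecord(
                patient_id=pid,
                age_years=age,
                sex=row["sex"],
                disease_type=row["disease_type"],
                wbc=_parse_float(row["wbc"], "wbc", where),
                bm_blast_pct=_parse_float(row["bm_blast_pct"], "bm_blast_pct", where),
                karyotype=row["karyotype"],
                mutations=tuple(mutations.pop(pid, [])),
                outcome=outcome,
            )
        except CohortError as exc:
            raise SchemaError(f"{where}: {exc}") from None
        records.append(record)

    if mutations:
        pid = next(iter(mutations))
        line = mutation_order[pid][0]
        raise SchemaError(
            f"{_ctx(mutations_path, line)}: mutation row references unknown patient_id {pid!r}"
        )
    return Cohort(tuple(records))


def write_cohort(cohort: Cohort, out_dir) -> tuple[Path, Path]:
    """Write ``patients.tsv`` + ``mutations.tsv`` so that :func:`read_cohort`
    reproduces the cohort field-for-field.  Returns the two paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    patients_path = out_dir / "patients.tsv"
    mutations_path = out_dir / "mutations.tsv"

    with open(patients_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(PATIENT_COLUMNS)
        for p in cohort:
            o = p.outcome
            if o is None:
                raise CohortError(
                    f"patient {p.patient_id!r} has no outcome; genotype-only cohorts "
                    "cannot be serialized"
                )
            w.writerow(
                [
                    p.patient_id,
                    p.age_years,
                    p.sex,
                    p.disease_type,
                    _fmt(p.wbc),
                    _fmt(p.bm_blast_pct),
                    p.karyotype,
                    _fmt(o.cr_achieved),
                    _fmt(o.hct_received),
                    _fmt(o.hct_time),
                    _fmt(o.os_time),
                    _fmt(o.os_event),
                    _fmt(o.efs_time),
                    _fmt(o.efs_event),
                    _fmt(o.rfs_time),
                    _fmt(o.rfs_event),
                ]
            )

    with open(mutations_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(MUTATION_COLUMNS)
        for p in cohort:
            for m in p.mutations:
                w.writerow(
                    [
                        p.patient_id,
                        m.gene,
                        _fmt(m.vaf),
                        _fmt(m.allelic_ratio),
                        _fmt(m.allele_count),
                        _fmt(m.bzip_in_frame),
                    ]
                )
    return patients_path, mutations_path
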