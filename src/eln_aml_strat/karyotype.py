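"""ISCN-like karyotype parsing into the cytogenetic features the risk rules use.

The supported dialect is deliberately small: comma-separated ISCN tokens
with an optional modal chromosome number, a sex-chromosome field, optional
clone sizes in square brackets, and multiple clones separated by ``/`` (the
union of their abnormalities is taken).  The keyword ``normal`` is accepted
as shorthand for a normal karyotype.  This covers every cytogenetic category
the risk engines distinguish; full ISCN grammar (idem/sl/sdl, uncertain
bands) is out of scope.

Conventions applied:

* complex karyotype: >= 3 abnormalities, not counting the favorable-defining
  core-binding-factor translocations (t(8;21), inv(16)/t(16;16)) themselves;
* monosomal karyotype (Breems): >= 2 distinct autosomal monosomies, or one
  autosomal monosomy plus >= 1 structural abnormality;
* hyperdiploid: modal chromosome number >= 49 with >= 3 numerical gains;
* loss of Y and constitutional abnormalities (``c`` suffix) are ignored;
* unrecognized tokens still count toward the abnormality total and are
  logged, never silently dropped.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, fields

__all__ = [
    "KaryotypeError",
    "KaryotypeFeatures",
    "parse_karyotype",
    "is_adverse_cytogenetics",
    "NORMAL_FEATURES",
]

logger = logging.getLogger(__name__)


class KaryotypeError(ValueError):
    """Unparseable karyotype in a place where parsing is required."""


@dataclass(frozen=True)
class KaryotypeFeatures:
    """Boolean lesion flags plus summary counts extracted from a karyotype."""

    t_8_21: bool = False
    inv16_or_t16_16: bool = False
    t_9_11: bool = False
    t_6_9: bool = False
    t_v_11q23: bool = False  # KMT2A rearrangement other than t(9;11)
    t_9_22: bool = False
    t_8_16: bool = False
    inv3_or_t3_3: bool = False
    t_3q26_v: bool = False  # MECOM rearrangement other than inv(3)/t(3;3)
    del5q_or_minus5: bool = False
    minus7: bool = False
    minus17_or_abn17p: bool = False
    complex: bool = False
    monosomal: bool = False
    hyperdiploid: bool = False
    normal: bool = False
    abnormality_count: int = 0
    chromosome_count: int | None = None

    def __post_init__(self) -> None:
        if self.normal and self.abnormality_count != 0:
            raise KaryotypeError("normal karyotype cannot carry abnormalities")
        if self.complex and self.abnormality_count < 3:
            raise KaryotypeError("complex karyotype requires >= 3 abnormalities")
        if self.monosomal and self.normal:
            raise KaryotypeError("monosomal karyotype cannot be normal")

    def lesion_flags(self) -> dict[str, bool]:
        out = {}
        for f in fields(self):
            if f.type == "bool" and f.name != "normal":
                out[f.name] = getattr(self, f.name)
        return out


NORMAL_FEATURES = KaryotypeFeatures(normal=True, abnormality_count=0, chromosome_count=46)

_SEX_RE = re.compile(r"^[XY]+$")
_NUMERIC_RE = re.compile(r"^([+-])(\d{1,2}|[XY])$")
# structural token: type(chromosomes)(bands)  -- bands optional
_STRUCT_RE = re.compile(r"^(t|inv|del|add|dup|ins|der|i|dic|r|idic)\(([^)]*)\)(?:\(([^)]*)\))?$")
_MODAL_RE = re.compile(r"^(\d{2,3})(?:[~-]\d{2,3})?$")

_STRUCTURAL_TYPES = {"t", "inv", "del", "add", "dup", "ins", "der", "i", "dic", "r", "idic"}


def _split_tokens(text: str) -> list[str]:
    return [tok.strip() for tok in text.split(",") if tok.strip()]


def parse_karyotype(iscn: str) -> KaryotypeFeatures:
    """Parse an ISCN-like karyotype string into :class:`KaryotypeFeatures`.

    Deterministic and total on the supported dialect.  Raises
    :class:`KaryotypeError` on an empty string, or when >= 3 numerical gains
    are present but the modal chromosome number cannot be read (needed to
    decide hyperdiploidy).
    """
    if iscn is None or not iscn.strip():
        raise KaryotypeError("empty karyotype string")
    text = iscn.strip()
    if text.lower() == "normal":
        return NORMAL_FEATURES

    modal: int | None = None
    abnormal_tokens: dict[str, tuple[str, ...]] = {}  # normalized token -> parse info

    for clone_idx, clone in enumerate(text.split("/")):
        clone = re.sub(r"\[\d+\]", "", clone).strip()
        if not clone:
            continue
        tokens = _split_tokens(clone)
        start = 0
        if tokens and (m := _MODAL_RE.match(tokens[0])):
            if clone_idx == 0:
                modal = int(m.group(1))
            start = 1
        if start < len(tokens) and _SEX_RE.match(tokens[start]):
            start += 1
        for tok in tokens[start:]:
            if tok.endswith("c"):  # constitutional abnormality: ignored
                continue
            if tok in ("-Y", "+Y"):  # Y-chromosome gain/loss: ignored by convention
                continue
            abnormal_tokens.setdefault(tok, ())

    monosomies: set[int] = set()
    gains = 0
    n_structural = 0
    n_favorable_defining = 0
    flags = dict.fromkeys(
        (
            "t_8_21",
            "inv16_or_t16_16",
            "t_9_11",
            "t_6_9",
            "t_v_11q23",
            "t_9_22",
            "t_8_16",
            "inv3_or_t3_3",
            "t_3q26_v",
            "del5q_or_minus5",
            "minus7",
            "minus17_or_abn17p",
        ),
        False,
    )

    for tok in abnormal_tokens:
        if m := _NUMERIC_RE.match(tok):
            sign, chrom = m.groups()
            if sign == "-" and chrom not in ("X", "Y"):
                c = int(chrom)
                monosomies.add(c)
                if c == 5:
                    flags["del5q_or_minus5"] = True
                elif c == 7:
                    flags["minus7"] = True
                elif c == 17:
                    flags["minus17_or_abn17p"] = True
            elif sign == "+":
                gains += 1
            continue
        if m := _STRUCT_RE.match(tok):
            n_structural += 1
            kind, chrom_part, band_part = m.group(1), m.group(2), m.group(3) or ""
            chroms = [c.strip() for c in chrom_part.split(";")]
            bands = [b.strip() for b in band_part.split(";")] if band_part else []
            _apply_structural(flags, kind, chroms, bands)
            if kind == "t" and set(chroms) == {"8", "21"}:
                n_favorable_defining += 1
            elif kind == "inv" and chroms == ["16"]:
                n_favorable_defining += 1
            elif kind == "t" and chroms == ["16", "16"]:
                n_favorable_defining += 1
            continue
        n_structural += 1
        logger.warning("unrecognized karyotype token %r counted as one abnormality", tok)

    abnormality_count = len(monosomies) + gains + n_structural
    normal = abnormality_count == 0
    hyperdiploid = False
    if gains >= 3:
        if modal is None:
            raise KaryotypeError(
                f"modal chromosome number required to assess hyperdiploidy: {iscn!r}"
            )
        hyperdiploid = modal >= 49
    is_complex = (abnormality_count - n_favorable_defining) >= 3
    monosomal = len(monosomies) >= 2 or (len(monosomies) == 1 and n_structural >= 1)

    return KaryotypeFeatures(
        **flags,
        complex=is_complex,
        monosomal=monosomal,
        hyperdiploid=hyperdiploid,
        normal=normal,
        abnormality_count=abnormality_count,
        chromosome_count=modal,
    )


def _apply_structural(flags: dict, kind: str, chroms: list[str], bands: list[str]) -> None:
    chrom_set = set(chroms)
    if kind == "t":
        if chrom_set == {"8", "21"}:
            flags["t_8_21"] = True
        elif chroms == ["16", "16"] or chrom_set == {"16"}:
            flags["inv16_or_t16_16"] = True
        elif chrom_set == {"9", "11"}:
            flags["t_9_11"] = True
        elif chrom_set == {"6", "9"}:
            flags["t_6_9"] = True
        elif chrom_set == {"9", "22"}:
            flags["t_9_22"] = True
        elif chrom_set == {"8", "16"}:
            flags["t_8_16"] = True
        elif chrom_set == {"3"}:
            flags["inv3_or_t3_3"] = True
        elif _band_on(chroms, bands, "11", "q23"):
            flags["t_v_11q23"] = True
        elif _band_on(chroms, bands, "3", "q26"):
            flags["t_3q26_v"] = True
    elif kind == "inv":
        if chroms == ["16"]:
            flags["inv16_or_t16_16"] = True
        elif chroms == ["3"]:
            flags["inv3_or_t3_3"] = True
    elif kind == "del":
        if chroms == ["5"] and _any_band(bands, "q"):
            flags["del5q_or_minus5"] = True
        elif chroms == ["17"] and _any_band(bands, "p"):
            flags["minus17_or_abn17p"] = True
        elif chroms == ["17p"]:  # shorthand del(17p)
            flags["minus17_or_abn17p"] = True
        elif chroms == ["5q"]:  # shorthand del(5q)
            flags["del5q_or_minus5"] = True
    elif kind == "add":
        if chroms == ["17"] and _any_band(bands, "p"):
            flags["minus17_or_abn17p"] = True
    elif kind == "i":
        # i(17)(q10): isochromosome of 17q implies loss of 17p
        if chroms == ["17"] and _any_band(bands, "q10"):
            flags["minus17_or_abn17p"] = True


def _band_on(chroms: list[str], bands: list[str], chrom: str, band_prefix: str) -> bool:
    """True if the breakpoint on ``chrom`` starts with ``band_prefix``.

    Bands correspond positionally to chromosomes, e.g. t(9;11)(p21.3;q23.3).
    Without band information the rearrangement is not attributed to the band.
    """
    for i, c in enumerate(chroms):
        if c == chrom and i < len(bands) and bands[i].startswith(band_prefix):
            return True
    return False


def _any_band(bands: list[str], prefix: str) -> bool:
    return any(b.startswith(prefix) for b in bands)


#: Lesions that are adverse-defining in both editions.
_ADVERSE_BOTH = (
    "t_6_9",
    "t_v_11q23",
    "t_9_22",
    "inv3_or_t3_3",
    "del5q_or_minus5",
    "minus7",
    "minus17_or_abn17p",
    "monosomal",
)
#: Added to the adverse list by the 2022 revision.
_ADVERSE_2022_ONLY = ("t_3q26_v", "t_8_16")


def is_adverse_cytogenetics(features: KaryotypeFeatures, edition: int) -> bool:
    """Whether the karyotype alone is adverse-defining under the edition.

    The 2022 revision adds t(3q26.2;v) and t(8;16) to the adverse list and
    exempts hyperdiploid karyotypes with multiple trisomies from the
    complex-karyotype rule (they remain adverse-by-complexity under 2017).
    """
    if edition not in (2017, 2022):
        raise ValueError(f"unknown ELN edition {edition!r}")
    if any(getattr(features, name) for name in _ADVERSE_BOTH):
        return True
    if edition == 2022 and any(getattr(features, name) for name in _ADVERSE_2022_ONLY):
        return True
    if features.complex:
        if edition == 2022 and features.hyperdiploid:
            return False
        return True
    return False
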