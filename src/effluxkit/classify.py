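"""Variant nomenclature, conservation-based calibration and 3-class calls.

Thresholds: the pathogenic cutoff is anchored at the highest-activity
pathogenic control; the benevolent cutoff is the rounded mean of the k
lowest-activity calibration variants, where a calibration variant is a
query whose alternate residue appears as the reference in more than
``min_exceed`` of the non-human species of a vertebrate alignment.

Classification (mean-activity based):
    activity <  pathogenic_cutoff  -> loss_of_function
    activity >= benevolent_cutoff  -> benevolent   (">=" adopted; the
                                      alternate ">" boundary is available)
    otherwise                      -> uncertain
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence, Union

from Bio.Align import MultipleSeqAlignment

from .errors import CalibrationError, HgvsParseError, MsaMappingError

__all__ = [
    "AMINO_ACIDS",
    "Variant",
    "ThresholdSet",
    "VariantCall",
    "DomainMap",
    "parse_hgvs_p",
    "species_with_alt_as_reference",
    "calibration_eligible",
    "derive_benevolent_threshold",
    "derive_pathogenic_threshold",
    "classify",
    "annotate_domains",
]

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

_HGVS_P_RE = re.compile(r"^(?:p\.)?([A-Za-z*]+?)(\d+)([A-Za-z*=]+)$")

ROLES = ("query", "wt", "pathogenic_control", "negative_control", "calibration_candidate")


@dataclass(frozen=True)
class Variant:
    """A missense protein change in p.<Ref><Pos><Alt> one-letter notation."""

    ref_aa: str
    position: int
    alt_aa: str
    cdna_change: str | None = None
    role: str = "query"

    def __post_init__(self) -> None:
        if self.ref_aa not in AMINO_ACIDS or self.alt_aa not in AMINO_ACIDS:
            raise HgvsParseError(
                f"residues must be standard one-letter codes: {self.ref_aa}>{self.alt_aa}"
            )
        if self.ref_aa == self.alt_aa:
            raise HgvsParseError("ref and alt residues must differ")
        if self.position < 1:
            raise HgvsParseError("position must be >= 1")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def hgvs_p(self) -> str:
        return f"p.{self.ref_aa}{self.position}{self.alt_aa}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.hgvs_p


@dataclass(frozen=True)
class ThresholdSet:
    """Pathogenic and benevolent cutoffs with derivation provenance."""

    pathogenic_cutoff: float
    benevolent_cutoff: float
    calibration_variants: tuple = ()
    control_anchor: Variant | None = None
    benevolent_boundary: Literal["ge", "gt"] = "ge"

    def __post_init__(self) -> None:
        if not 0 < self.pathogenic_cutoff < self.benevolent_cutoff <= 100:
            raise ValueError(
                "need 0 < pathogenic_cutoff < benevolent_cutoff <= 100, got "
                f"({self.pathogenic_cutoff}, {self.benevolent_cutoff})"
            )


@dataclass(frozen=True)
class VariantCall:
    variant: Variant
    mean_activity: float
    sd: float
    n: int
    call: str  # loss_of_function | uncertain | benevolent
    domains: tuple[str, ...] = ()


@dataclass(frozen=True)
class DomainMap:
    """Named residue intervals/sets on the mature protein.

    The gateway is a closed interval; annuli are explicit residue sets.
    Additional custom domains (e.g. ECD boundaries, which vary between
    structural assignments) can be supplied via ``extra``.
    """

    gateway: tuple[int, int] = (564, 592)
    annulus: frozenset[int] = frozenset({69, *range(71, 81), 363, *range(368, 380)})
    annulus_central: frozenset[int] = frozenset({73, 74, 77, 371, 375})
    extra: Mapping[str, frozenset[int]] = field(default_factory=dict)

    def members(self) -> dict[str, frozenset[int]]:
        lo, hi = self.gateway
        out = {
            "gateway": frozenset(range(lo, hi + 1)),
            "annulus": self.annulus,
            "annulus_central": self.annulus_central,
        }
        out.update({k: frozenset(v) for k, v in self.extra.items()})
        return out


def parse_hgvs_p(text: str, role: str = "query") -> Variant:
    """Parse ``p.<Ref><Pos><Alt>`` one-letter missense notation.

    The ``p.`` prefix is optional. Three-letter codes, nonsense (X/*),
    synonymous (=) and frameshift notation are rejected as unsupported.
    """
    m = _HGVS_P_RE.match(text.strip())
    if not m:
        raise HgvsParseError(f"cannot parse protein change: {text!r}")
    ref, pos, alt = m.groups()
    if len(ref) != 1 or len(alt) != 1:
        raise HgvsParseError(
            f"only one-letter missense codes are supported: {text!r}"
        )
    if ref not in AMINO_ACIDS or alt not in AMINO_ACIDS:
        raise HgvsParseError(f"invalid or unsupported residue codes: {text!r}")
    if ref == alt:
        raise HgvsParseError(f"synonymous change is not a missense variant: {text!r}")
    return Variant(ref_aa=ref, position=int(pos), alt_aa=alt, role=role)


MsaLike = Union[MultipleSeqAlignment, Sequence[tuple[str, str]], Mapping[str, str]]


def _msa_rows(msa: MsaLike) -> list[tuple[str, str]]:
    if isinstance(msa, MultipleSeqAlignment):
        return [(rec.id, str(rec.seq)) for rec in msa]
    if isinstance(msa, Mapping):
        return list(msa.items())
    return [(rid, str(seq)) for rid, seq in msa]


def map_position_to_column(human_seq: str, position: int) -> int:
    """0-based alignment column of the 1-based ungapped residue ``position``."""
    seen = 0
    for col, ch in enumerate(human_seq):
        if ch != "-":
            seen += 1
            if seen == position:
                return col
    raise MsaMappingError(
        f"position {position} beyond ungapped human length {seen}"
    )


def species_with_alt_as_reference(
    msa: MsaLike, variant: Variant, human_id: str = "human"
) -> int:
    """Count non-human species carrying the variant's alternate residue.

    The residue position is mapped through the ungapped human row; gapped
    rows at that column count as non-matching.
    """
    rows = _msa_rows(msa)
    human = [seq for rid, seq in rows if rid == human_id]
    if not human:
        raise MsaMappingError(f"no row with human identifier {human_id!r}")
    col = map_position_to_column(human[0], variant.position)
    return sum(
        1
        for rid, seq in rows
        if rid != human_id and col < len(seq) and seq[col].upper() == variant.alt_aa
    )


def calibration_eligible(count: int, min_exceed: int = 2) -> bool:
    """True iff strictly more than ``min_exceed`` species carry the alt."""
    if count < 0:
        raise ValueError("count must be >= 0")
    return count > min_exceed


def derive_benevolent_threshold(
    calibration_activities: Sequence[float], k: int = 3
) -> int:
    """Mean of the k lowest calibration activities, nearest integer percent.

    Ties at .5 round away from zero.
    """
    vals = sorted(float(v) for v in calibration_activities)
    if len(vals) < k:
        raise CalibrationError(
            f"need at least {k} eligible calibration variants, got {len(vals)}"
        )
    mean = sum(vals[:k]) / k
    return int(math.floor(mean + 0.5))


def derive_pathogenic_threshold(
    control_activities: Sequence[tuple[Variant, float]]
) -> tuple[float, Variant]:
    """Highest mean activity among pathogenic controls, with its anchor."""
    if not control_activities:
        raise CalibrationError("no pathogenic controls supplied")
    anchor, value = max(control_activities, key=lambda item: item[1])
    return float(value), anchor


def classify(mean_activity: float, thresholds: ThresholdSet) -> str:
    """Assign loss_of_function / uncertain / benevolent from mean activity."""
    if mean_activity < thresholds.pathogenic_cutoff:
        return "loss_of_function"
    if thresholds.benevolent_boundary == "ge":
        benevolent = mean_activity >= thresholds.benevolent_cutoff
    else:
        benevolent = mean_activity > thresholds.benevolent_cutoff
    return "benevolent" if benevolent else "uncertain"


def annotate_domains(
    variant: Variant, domain_map: DomainMap | None = None
) -> list[str]:
    """All domain labels whose residue set contains the variant position."""
    dm = domain_map or DomainMap()
    return sorted(
        label for label, members in dm.members().items() if variant.position in members
    )


def derive_thresholds(
    calibration: Iterable[tuple[Variant, float]],
    controls: Iterable[tuple[Variant, float]],
    k: int = 3,
    benevolent_boundary: Literal["ge", "gt"] = "ge",
) -> ThresholdSet:
    """Full threshold derivation from calibration variants and controls."""
    calibration = tuple(calibration)
    pathogenic, anchor = derive_pathogenic_threshold(list(controls))
    benevolent = derive_benevolent_threshold([v for _, v in calibration], k=k)
    return ThresholdSet(
        pathogenic_cutoff=pathogenic,
        benevolent_cutoff=float(benevolent),
        calibration_variants=calibration,
        control_anchor=anchor,
        benevolent_boundary=benevolent_boundary,
    )
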