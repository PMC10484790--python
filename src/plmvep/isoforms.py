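"""Cross-isoform scoring of variants and detection of isoform-sensitive
and high-variance variants."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .backend import ProteinSequence
from .errors import ValidationError
from .scoring import LLRMatrix, MissenseVariant, score_missense, validate_missense

#: Marker for a variant position spliced out of an isoform.
ABSENT = "ABSENT"


@dataclass(frozen=True)
class IsoformGroup:
    gene_id: str
    isoforms: tuple
    primary_isoform_id: str

    def __post_init__(self):
        if len(self.isoforms) < 1:
            raise ValidationError("isoform group needs at least one isoform")
        ids = [iso.id for iso in self.isoforms]
        if len(set(ids)) != len(ids):
            raise ValidationError(f"duplicate isoform ids in gene {self.gene_id!r}")
        if self.primary_isoform_id not in ids:
            raise ValidationError(
                f"primary isoform {self.primary_isoform_id!r} not in group"
            )

    def get(self, isoform_id: str) -> ProteinSequence:
        for iso in self.isoforms:
            if iso.id == isoform_id:
                return iso
        raise ValidationError(f"no isoform {isoform_id!r} in gene {self.gene_id!r}")


@dataclass(frozen=True)
class VariantIsoformMap:
    """Where one variant lands in each isoform; ABSENT entries mark
    positions spliced out of that isoform."""

    variant_id: str
    entries: tuple  # of (isoform_id, position, ref_aa, alt_aa) or (isoform_id, ABSENT)

    def __post_init__(self):
        if not any(e[1] != ABSENT for e in self.entries):
            raise ValidationError(
                f"variant {self.variant_id!r} absent from every isoform"
            )

    def present_entries(self):
        return [e for e in self.entries if e[1] != ABSENT]


@dataclass(frozen=True)
class IsoformScoreProfile:
    variant_id: str
    scores: dict  # isoform_id -> LLR
    min_score: float
    max_score: float
    sd: float

    def __post_init__(self):
        if self.min_score > self.max_score:
            raise ValidationError("min_score > max_score")
        if self.sd < 0:
            raise ValidationError("sd must be >= 0")

    @property
    def n_isoforms(self) -> int:
        return len(self.scores)


@dataclass(frozen=True)
class SensitivityThresholds:
    """LLR-unit thresholds for isoform-sensitivity calls.

    A variant is isoform-sensitive when its maximum cross-isoform score
    exceeds ``benign_floor``, its minimum falls below
    ``pathogenic_ceiling`` and the max-min gap exceeds
    ``min_difference`` (all strict inequalities).
    """

    benign_floor: float = -7.0
    pathogenic_ceiling: float = -8.0
    min_difference: float = 4.0
    high_variance_sd: float = 2.0
    classification_cutoff: float = -7.5

    def __post_init__(self):
        if self.benign_floor <= self.pathogenic_ceiling:
            raise ValidationError("benign_floor must exceed pathogenic_ceiling")
        if self.min_difference <= 0:
            raise ValidationError("min_difference must be positive")


def score_across_isoforms(
    vmap: VariantIsoformMap,
    matrices: dict,
    validate_against: Optional[dict] = None,
) -> IsoformScoreProfile:
    """Score one variant in every isoform where it is present.

    ``matrices`` maps isoform id to that isoform's :class:`LLRMatrix`;
    ``validate_against`` optionally maps isoform id to the
    :class:`ProteinSequence` for reference-residue checking. The summary
    s.d. is the population standard deviation (divisor n).
    """
    scores = {}
    for entry in vmap.present_entries():
        isoform_id, position, ref_aa, alt_aa = entry
        if isoform_id not in matrices:
            raise ValidationError(
                f"no LLR matrix for isoform {isoform_id!r} "
                f"(variant {vmap.variant_id!r})"
            )
        variant = MissenseVariant(
            protein_id=isoform_id, position=position, ref_aa=ref_aa, alt_aa=alt_aa
        )
        if validate_against is not None:
            validate_missense(variant, validate_against[isoform_id])
        scores[isoform_id] = score_missense(matrices[isoform_id], variant)
    vals = np.array(list(scores.values()), dtype=np.float64)
    return IsoformScoreProfile(
        variant_id=vmap.variant_id,
        scores=scores,
        min_score=float(vals.min()),
        max_score=float(vals.max()),
        sd=float(vals.std(ddof=0)),
    )


def classify_isoform_sensitive(
    profile: IsoformScoreProfile,
    thresholds: SensitivityThresholds = SensitivityThresholds(),
) -> bool:
    return (
        profile.max_score > thresholds.benign_floor
        and profile.min_score < thresholds.pathogenic_ceiling
        and (profile.max_score - profile.min_score) > thresholds.min_difference
    )


def flag_high_variance(
    profile: IsoformScoreProfile,
    thresholds: SensitivityThresholds = SensitivityThresholds(),
) -> Optional[bool]:
    """True iff cross-isoform s.d. exceeds the threshold (strict);
    ``None`` (not applicable) for single-isoform profiles."""
    if profile.n_isoforms < 2:
        return None
    return profile.sd > thresholds.high_variance_sd


def distance_to_splice_junction(
    position: int, junction_positions_aa
) -> Optional[int]:
    """Minimum absolute residue distance to any junction; ``None`` when
    the isoform has no junctions (single exon)."""
    junctions = list(junction_positions_aa)
    if not junctions:
        return None
    return int(min(abs(position - j) for j in junctions))
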