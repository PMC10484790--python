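"""Effect scores for missense variants (LLR), in-frame indels (PLLR in
three modes) and stop-gains (minimum LLR over the lost region), plus the
50 bp nonsense-mediated-decay rule."""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .backend import (
    AA_INDEX,
    ALPHABET,
    BackendSpec,
    PositionLogProbs,
    ProteinSequence,
    score_sequence,
)
from .errors import (
    ReferenceMismatchError,
    UnsupportedVariantError,
    ValidationError,
)

#: The residue replaced by the stop codon is part of the lost region.
STOP_GAIN_LOST_REGION_INCLUDES_STOP = True

#: NMD is predicted when the stop lies strictly more than this many
#: nucleotides upstream of the last exon junction in the coding region.
NMD_RULE_DISTANCE_NT = 50


@dataclass(frozen=True)
class LLRMatrix:
    """20 x L matrix of log-likelihood-ratio scores (alt minus WT).

    Rows follow the canonical alphabet; columns are 1-based protein
    positions. Entries at the WT residue are exactly zero; more negative
    means predicted more damaging.
    """

    protein_id: str
    values: np.ndarray
    alphabet_order: str = ALPHABET

    def __post_init__(self):
        v = self.values
        if v.ndim != 2 or v.shape[0] != len(ALPHABET):
            raise ValidationError(
                f"LLR matrix must be {len(ALPHABET)} x L, got {v.shape}"
            )
        if not np.all(np.isfinite(v)):
            raise ValidationError("LLR matrix contains non-finite entries")

    @property
    def length(self) -> int:
        return self.values.shape[1]

    def entry(self, alt_aa: str, position: int) -> float:
        if alt_aa not in AA_INDEX:
            raise ValidationError(f"unknown amino acid {alt_aa!r}")
        if not 1 <= position <= self.length:
            raise ValidationError(
                f"position {position} out of range 1..{self.length}"
            )
        return float(self.values[AA_INDEX[alt_aa], position - 1])


def llr_from_log_probs(probs: PositionLogProbs, residues: str) -> np.ndarray:
    """20 x L LLR values from one scoring pass: log p(alt) - log p(WT)."""
    if len(residues) != probs.length:
        raise ValidationError("residues do not match log-probability matrix")
    wt = probs.wt_log_probs(residues)  # (L,)
    values = probs.matrix.T - wt  # (20, L)
    for j, aa in enumerate(residues):
        values[AA_INDEX[aa], j] = 0.0
    return values


def direct_llr(seq: ProteinSequence, backend: BackendSpec) -> LLRMatrix:
    """Single-pass LLR matrix for a sequence within the backend limit."""
    probs = score_sequence(backend, seq)
    return LLRMatrix(protein_id=seq.id, values=llr_from_log_probs(probs, seq.residues))


# ---------------------------------------------------------------------------
# Missense
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MissenseVariant:
    protein_id: str
    position: int
    ref_aa: str
    alt_aa: str

    def __post_init__(self):
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in AA_INDEX:
                raise ValidationError(f"unknown amino acid {aa!r}")
        if self.position < 1:
            raise ValidationError("position must be >= 1")


def validate_missense(variant: MissenseVariant, seq: ProteinSequence) -> None:
    observed = seq.residue_at(variant.position)
    if observed != variant.ref_aa:
        raise ReferenceMismatchError(
            seq.id, variant.position, variant.ref_aa, observed
        )


def score_missense(matrix: LLRMatrix, variant: MissenseVariant) -> float:
    """LLR of the substitution: matrix entry at (alt residue, position)."""
    if variant.ref_aa == variant.alt_aa:
        warnings.warn(
            f"degenerate variant at position {variant.position}: "
            "alt equals ref, LLR is 0 by definition",
            stacklevel=2,
        )
    return matrix.entry(variant.alt_aa, variant.position)


# ---------------------------------------------------------------------------
# In-frame indels
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IndelVariant:
    """In-frame deletion, insertion or delins.

    ``span`` is the 1-based inclusive interval of affected WT residues;
    for pure insertions it is ``None`` and ``anchor`` gives the WT
    position after which the new residues are inserted (0 means before
    the first residue).
    """

    protein_id: str
    kind: str  # deletion | insertion | delins
    span: Optional[tuple] = None
    inserted: str = ""
    anchor: Optional[int] = None

    def __post_init__(self):
        if self.kind not in ("deletion", "insertion", "delins"):
            raise ValidationError(f"unknown indel kind {self.kind!r}")
        for aa in self.inserted:
            if aa not in AA_INDEX:
                raise ValidationError(f"unknown amino acid {aa!r} in insertion")
        if self.kind == "deletion":
            if self.span is None or self.inserted:
                raise ValidationError("deletion requires a span and no insert")
        elif self.kind == "insertion":
            if self.span is not None or not self.inserted or self.anchor is None:
                raise ValidationError("insertion requires an anchor and an insert")
            if self.anchor < 0:
                raise ValidationError("insertion anchor must be >= 0")
        else:
            if self.span is None or not self.inserted:
                raise ValidationError("delins requires a span and an insert")
        if self.span is not None:
            s, e = self.span
            if s < 1 or e < s:
                raise ValidationError(f"bad span ({s}, {e})")

    @property
    def span_length(self) -> int:
        if self.span is None:
            return 0
        return self.span[1] - self.span[0] + 1


def apply_indel(seq: ProteinSequence, indel: IndelVariant) -> ProteinSequence:
    """Mutated sequence of length L_WT - |span| + |inserted|."""
    L = len(seq)
    res = seq.residues
    if indel.kind == "insertion":
        if indel.anchor > L:
            raise ValidationError(
                f"insertion anchor {indel.anchor} beyond sequence length {L}"
            )
        mut = res[: indel.anchor] + indel.inserted + res[indel.anchor :]
    else:
        s, e = indel.span
        if e > L:
            raise ValidationError(f"span ({s}, {e}) outside sequence of length {L}")
        mut = res[: s - 1] + indel.inserted + res[e:]
    if not mut:
        raise UnsupportedVariantError("indel deletes the entire sequence")
    return ProteinSequence(id=f"{seq.id}|mut", residues=mut)


@dataclass(frozen=True)
class PllValue:
    """Pseudo-log-likelihood: sum over positions of log p(observed residue)."""

    value: float
    sequence_length: int

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValidationError("PLL must be finite")
        if self.value > 1e-9:
            raise ValidationError("PLL must be <= 0")


def compute_pll(seq: ProteinSequence, backend: BackendSpec) -> PllValue:
    probs = score_sequence(backend, seq)
    return PllValue(
        value=float(probs.wt_log_probs(seq.residues).sum()),
        sequence_length=len(seq),
    )


def indel_context(
    wt: ProteinSequence,
    mut: ProteinSequence,
    indel: IndelVariant,
    window_length: int = 1022,
    upstream_context: int = 511,
):
    """Length-limited context subsequences around an indel.

    Both subsequences keep the full affected region, up to
    ``upstream_context`` unaffected residues before it (or as many as
    there are), and enough downstream residues that the longer of the
    two subsequences has length exactly ``window_length`` (fewer when
    the protein ends first). Sequences that both fit within the limit
    are returned unchanged.
    """
    L_wt, L_mut = len(wt), len(mut)
    if max(L_wt, L_mut) <= window_length:
        return wt, mut

    if indel.kind == "insertion":
        affected_start = indel.anchor + 1  # first WT residue after the insert
        wt_affected = 0
    else:
        affected_start = indel.span[0]
        wt_affected = indel.span_length
    mut_affected = len(indel.inserted)
    longest_affected = max(wt_affected, mut_affected)

    upstream = min(upstream_context, affected_start - 1)
    downstream_budget = window_length - upstream - longest_affected
    if downstream_budget < 0:
        raise UnsupportedVariantError(
            "affected region plus upstream context exceeds the window length"
        )
    after_wt = affected_start + wt_affected  # first unaffected WT residue downstream
    downstream = min(downstream_budget, L_wt - after_wt + 1)

    wt_sub = wt.residues[affected_start - upstream - 1 : after_wt + downstream - 1]
    mut_start = affected_start - upstream
    mut_after = affected_start + mut_affected
    mut_sub = mut.residues[mut_start - 1 : mut_after + downstream - 1]
    return (
        ProteinSequence(id=f"{wt.id}|ctx", residues=wt_sub),
        ProteinSequence(id=f"{mut.id}|ctx", residues=mut_sub),
    )


INDEL_MODES = ("vanilla", "weighted", "absolute")


@dataclass(frozen=True)
class IndelScore:
    pllr: float
    mode: str
    wt_pll: PllValue
    mut_pll: PllValue


def score_indel(
    wt: ProteinSequence,
    indel: IndelVariant,
    backend: BackendSpec,
    mode: str = "vanilla",
) -> IndelScore:
    """PLLR effect score of an in-frame indel.

    vanilla: PLL(mut) - PLL(wt); weighted: PLL(mut)/L_mut - PLL(wt)/L_wt;
    absolute: |vanilla|. Over-length sequences are routed through
    :func:`indel_context` first.
    """
    if mode not in INDEL_MODES:
        raise ValidationError(f"unknown PLLR mode {mode!r}")
    mut = apply_indel(wt, indel)
    wt_s, mut_s = indel_context(wt, mut, indel, backend.max_input_length)
    wt_pll = compute_pll(wt_s, backend)
    mut_pll = compute_pll(mut_s, backend)
    if mode == "weighted":
        pllr = (
            mut_pll.value / mut_pll.sequence_length
            - wt_pll.value / wt_pll.sequence_length
        )
    else:
        pllr = mut_pll.value - wt_pll.value
        if mode == "absolute":
            pllr = abs(pllr)
    return IndelScore(pllr=float(pllr), mode=mode, wt_pll=wt_pll, mut_pll=mut_pll)


# ---------------------------------------------------------------------------
# Stop-gains
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class StopGainVariant:
    protein_id: str
    stop_position: int

    def __post_init__(self):
        if self.stop_position < 1:
            raise ValidationError("stop position must be >= 1")


def score_stop_gain(matrix: LLRMatrix, variant: StopGainVariant) -> float:
    """Lowest missense LLR in the lost region (WT self-entries excluded)."""
    L = matrix.length
    p = variant.stop_position
    if p > L:
        raise ValidationError(f"stop position {p} beyond protein length {L}")
    start = p if STOP_GAIN_LOST_REGION_INCLUDES_STOP else p + 1
    if start > L:
        raise ValidationError("lost region is empty")
    region = matrix.values[:, start - 1 :]
    # WT entries are exactly 0 by construction; mask them out so only
    # actual substitutions compete for the minimum.
    masked = np.where(region == 0.0, np.inf, region)
    return float(masked.min())


def residues_lost(variant: StopGainVariant, L: int):
    """(count, fraction) of WT residues removed by the stop codon."""
    if variant.stop_position > L:
        raise ValidationError("stop position beyond protein length")
    count = L - variant.stop_position + 1
    return count, count / L


# ---------------------------------------------------------------------------
# 50 bp NMD rule
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure in transcript coordinates (5'->3', 1-based).

    ``exon_lengths`` are the spliced exon lengths in order; the CDS
    occupies transcript positions ``cds_start..cds_end`` inclusive.
    """

    transcript_id: str
    exon_lengths: tuple
    cds_start: int
    cds_end: int

    def __post_init__(self):
        if any(e < 1 for e in self.exon_lengths):
            raise ValidationError("exon lengths must be positive")
        total = sum(self.exon_lengths)
        if not 1 <= self.cds_start <= self.cds_end <= total:
            raise ValidationError(
                f"CDS {self.cds_start}..{self.cds_end} outside transcript "
                f"extent 1..{total}"
            )

    def junctions_transcript(self) -> tuple:
        """Transcript position of the last nt of each non-terminal exon."""
        out, acc = [], 0
        for length in self.exon_lengths[:-1]:
            acc += length
            out.append(acc)
        return tuple(out)

    def coding_junctions_cds(self) -> tuple:
        """Junction positions in CDS nt coordinates, within the CDS only."""
        return tuple(
            j - self.cds_start + 1
            for j in self.junctions_transcript()
            if self.cds_start <= j < self.cds_end
        )


def predict_nmd(transcript: TranscriptModel, stop_cds_position_nt: int) -> bool:
    """50 bp rule: NMD expected iff the stop codon lies strictly more
    than 50 nt upstream of the last exon junction in the coding region."""
    cds_len = transcript.cds_end - transcript.cds_start + 1
    if not 1 <= stop_cds_position_nt <= cds_len:
        raise ValidationError(
            f"stop position {stop_cds_position_nt} outside CDS of length {cds_len}"
        )
    junctions = transcript.coding_junctions_cds()
    if not junctions:
        return False
    return junctions[-1] - stop_cds_position_nt > NMD_RULE_DISTANCE_NT
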