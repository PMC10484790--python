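"""Scorer-backend contract and the deterministic synthetic backend.

Every downstream operation consumes per-position log-probability vectors
over the 20 canonical amino acids, produced here. The synthetic backend
is a pure function of ``(seed, sequence, position)`` built from seeded
hashes of local sequence context, so the whole pipeline is exercisable
and reproducible without model weights. An adapter for a real
transformer model can be plugged in behind the same contract (see
:mod:`plmvep.esm_adapter`).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np

from .errors import (
    NonCanonicalResidueError,
    SequenceLengthError,
    ValidationError,
)

#: Canonical amino-acid ordering used for every 20-wide axis in the package.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}
_AA_SET = frozenset(ALPHABET)

DEFAULT_MAX_INPUT_LENGTH = 1022

# Synthetic-backend shape parameters. The k-mer radius controls how far
# context effects propagate; the logit scale bounds the spread of LLR
# values outside planted domains to roughly [-scale, +scale].
_KMER_RADIUS = 5
_LOGIT_SCALE = 4.0
_PAD = "-"


@dataclass(frozen=True)
class ProteinSequence:
    """A protein isoform: identifier plus canonical residue string."""

    id: str
    residues: str

    def __post_init__(self):
        if len(self.residues) < 1:
            raise ValidationError(f"sequence {self.id!r} is empty")
        for pos0, aa in enumerate(self.residues):
            if aa not in _AA_SET:
                raise NonCanonicalResidueError(self.id, pos0 + 1, aa)

    def __len__(self) -> int:
        return len(self.residues)

    def residue_at(self, position: int) -> str:
        """Residue at a 1-based position."""
        if not 1 <= position <= len(self.residues):
            raise ValidationError(
                f"position {position} out of range 1..{len(self.residues)} "
                f"for sequence {self.id!r}"
            )
        return self.residues[position - 1]


@dataclass(frozen=True)
class PositionLogProbs:
    """L x 20 matrix of log-probabilities, one row per residue position.

    Rows are log-normalized: ``logsumexp(row) == 0`` within 1e-6.
    """

    sequence_id: str
    matrix: np.ndarray
    alphabet_order: str = ALPHABET

    def __post_init__(self):
        m = self.matrix
        if m.ndim != 2 or m.shape[1] != len(ALPHABET):
            raise ValidationError(
                f"log-probability matrix must be L x {len(ALPHABET)}, got {m.shape}"
            )

    @property
    def length(self) -> int:
        return self.matrix.shape[0]

    def wt_log_probs(self, residues: str) -> np.ndarray:
        """Log-probability of the observed residue at each position."""
        if len(residues) != self.length:
            raise ValidationError("residue string length does not match matrix")
        idx = np.fromiter((AA_INDEX[aa] for aa in residues), dtype=np.intp)
        return self.matrix[np.arange(self.length), idx]


def _normalize_domain_spec(domain_spec):
    """Validate and freeze a domain spec.

    Accepts either a flat list of ``(start, end, tolerance)`` triples
    (applied to every sequence) or a mapping of sequence id to such a
    list. Intervals must be 1-based, ordered and non-overlapping.
    """
    if domain_spec is None:
        return None

    def _check(intervals, label):
        out = []
        prev_end = 0
        for triple in intervals:
            start, end, tol = triple
            start, end = int(start), int(end)
            tol = float(tol)
            if start < 1 or end < start:
                raise ValidationError(
                    f"bad domain interval ({start}, {end}) for {label}"
                )
            if start <= prev_end:
                raise ValidationError(
                    f"overlapping or out-of-order domain intervals for {label}"
                )
            if not 0.0 < tol < 1.0:
                raise ValidationError(
                    f"domain tolerance must be in (0, 1), got {tol} for {label}"
                )
            out.append((start, end, tol))
            prev_end = end
        return tuple(out)

    if isinstance(domain_spec, dict):
        return {str(k): _check(v, k) for k, v in sorted(domain_spec.items())}
    return _check(domain_spec, "<all sequences>")


def _normalize_domain_motifs(domain_motifs):
    if domain_motifs is None:
        return ()
    out = []
    for motif, tol in domain_motifs:
        motif = str(motif)
        tol = float(tol)
        if len(motif) < 3:
            raise ValidationError("domain motifs must be at least 3 residues")
        if any(aa not in _AA_SET for aa in motif):
            raise ValidationError(f"non-canonical residue in motif {motif!r}")
        if not 0.0 < tol < 1.0:
            raise ValidationError(f"motif tolerance must be in (0, 1), got {tol}")
        out.append((motif, tol))
    return tuple(out)


@dataclass(frozen=True)
class BackendSpec:
    """Configuration for a scorer backend.

    kind
        ``"synthetic"`` or ``"real-model-adapter"``.
    seed
        Integer seed (synthetic backend only).
    max_input_length
        Hard limit on scoreable sequence length (1022 for the real model).
    domain_spec
        Optional planted low-tolerance regions for the synthetic backend:
        a list of ``(start, end, tolerance)`` triples applied to every
        sequence, or a dict keyed by sequence id. Positional planting is
        honored only when scoring the declaring sequence itself.
    domain_motifs
        Optional list of ``(motif, tolerance)`` pairs: wherever the
        motif occurs intact in a scored sequence, its span gets the
        low-tolerance bonus. Content-based planting survives windowing
        and sequence edits, so a deletion or splice event that breaks
        the motif also removes the planted intolerance.
    """

    kind: str = "synthetic"
    seed: int = 0
    max_input_length: int = DEFAULT_MAX_INPUT_LENGTH
    domain_spec: object = None
    domain_motifs: tuple = ()
    domain_intensity: float = field(default=3.0)

    def __post_init__(self):
        if self.kind not in ("synthetic", "real-model-adapter"):
            raise ValidationError(f"unknown backend kind {self.kind!r}")
        if self.max_input_length < 2:
            raise ValidationError("max_input_length must be >= 2")
        object.__setattr__(
            self, "domain_spec", _normalize_domain_spec(self.domain_spec)
        )
        object.__setattr__(
            self, "domain_motifs", _normalize_domain_motifs(self.domain_motifs)
        )

    def domains_for(self, sequence_id: str):
        spec = self.domain_spec
        if spec is None:
            return ()
        if isinstance(spec, dict):
            return spec.get(sequence_id, ())
        return spec


def make_synthetic_backend(
    seed: int,
    domain_spec=None,
    max_input_length: int = DEFAULT_MAX_INPUT_LENGTH,
    domain_motifs=None,
) -> BackendSpec:
    """Build a deterministic synthetic backend.

    Log-probabilities are a pure function of ``(seed, sequence,
    position)``: each position's logits are hashed from its local
    (2*radius+1)-mer, so changing any residue perturbs rows within the
    context radius. Inside planted domain intervals the WT residue gets
    an additional logit bonus of ``-intensity * log(tolerance)``, which
    pushes every non-WT substitution there to a strongly negative LLR.
    """
    if not isinstance(seed, (int, np.integer)):
        raise ValidationError("seed must be an integer")
    return BackendSpec(
        kind="synthetic",
        seed=int(seed),
        max_input_length=max_input_length,
        domain_spec=domain_spec,
        domain_motifs=domain_motifs or (),
    )


def plant_domain_motifs(backend: BackendSpec, sequences) -> BackendSpec:
    """Convert a backend's positional domain declarations into
    content-based motifs extracted from the given sequences.

    The returned backend applies the low-tolerance bonus wherever each
    extracted domain substring occurs intact, so derived sequences
    (windows, indel mutants, alternative isoforms) keep the domain
    behavior as long as the domain survives the edit.
    """
    by_id = {seq.id: seq for seq in sequences}
    motifs = list(backend.domain_motifs)
    for seq_id, seq in by_id.items():
        for start, end, tol in backend.domains_for(seq_id):
            motifs.append((seq.residues[start - 1 : end], tol))
    return BackendSpec(
        kind=backend.kind,
        seed=backend.seed,
        max_input_length=backend.max_input_length,
        domain_spec=None,
        domain_motifs=tuple(motifs),
        domain_intensity=backend.domain_intensity,
    )


@lru_cache(maxsize=200_000)
def _kmer_logits(seed: int, kmer: str) -> np.ndarray:
    """20 base logits for one local context, deterministic in (seed, kmer)."""
    digest = hashlib.blake2b(
        f"{seed}|{kmer}".encode("ascii"), digest_size=16
    ).digest()
    rng = np.random.Generator(
        np.random.PCG64(int.from_bytes(digest, "little"))
    )
    row = rng.uniform(0.0, _LOGIT_SCALE, size=len(ALPHABET))
    row.flags.writeable = False
    return row


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=1, keepdims=True))


def score_sequence(backend: BackendSpec, seq: ProteinSequence) -> PositionLogProbs:
    """Score a sequence, returning one log-probability row per residue.

    Deterministic for identical ``(backend, seq)`` inputs. Sequences
    longer than ``backend.max_input_length`` raise
    :class:`SequenceLengthError`; callers should tile (see
    :mod:`plmvep.tiling`).
    """
    L = len(seq)
    if L > backend.max_input_length:
        raise SequenceLengthError(
            f"sequence {seq.id!r} has length {L} > backend limit "
            f"{backend.max_input_length}; tile it into windows first"
        )
    if backend.kind != "synthetic":
        raise ValidationError(
            "only the synthetic backend is available here; use the "
            "real-model adapter module for transformer scoring"
        )

    r = _KMER_RADIUS
    padded = _PAD * r + seq.residues + _PAD * r
    logits = np.empty((L, len(ALPHABET)), dtype=np.float64)
    for i in range(L):
        logits[i] = _kmer_logits(backend.seed, padded[i : i + 2 * r + 1])

    for start, end, tol in backend.domains_for(seq.id):
        if end > L:
            raise ValidationError(
                f"domain interval ({start}, {end}) exceeds length {L} of "
                f"sequence {seq.id!r}"
            )
        bonus = -backend.domain_intensity * np.log(tol)
        for pos in range(start, end + 1):
            logits[pos - 1, AA_INDEX[seq.residues[pos - 1]]] += bonus

    for motif, tol in backend.domain_motifs:
        bonus = -backend.domain_intensity * np.log(tol)
        found = seq.residues.find(motif)
        while found != -1:
            for pos0 in range(found, found + len(motif)):
                logits[pos0, AA_INDEX[seq.residues[pos0]]] += bonus
            found = seq.residues.find(motif, found + len(motif))

    return PositionLogProbs(sequence_id=seq.id, matrix=_log_softmax(logits))
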