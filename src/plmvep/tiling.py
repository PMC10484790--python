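"""Tiling of over-length sequences into overlapping windows, and
aggregation of per-window scores with sigmoid edge weights.

Windows are built symmetrically from both ends of the sequence with an
exact step of ``window_length - min_overlap`` until the innermost pair
overlaps by at least ``min_overlap``; when the innermost pair meets but
overlaps by less than that, a single centered window is inserted. The
resulting set satisfies: every window has length exactly
``window_length``, consecutive windows overlap by at least
``min_overlap``, positions 1..L are fully covered, and no residue falls
in more than three windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .backend import ALPHABET, BackendSpec, ProteinSequence, score_sequence
from .errors import ValidationError

DEFAULT_WINDOW_LENGTH = 1022
DEFAULT_MIN_OVERLAP = 511

AGGREGATION_MODES = ("weighted", "mean", "min", "max")


@dataclass(frozen=True)
class Window:
    """1-based inclusive residue interval in the parent protein."""

    start: int
    end: int

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise ValidationError(f"bad window ({self.start}, {self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end

    def to_local(self, position: int) -> int:
        """Map a parent position to the window-local 1-based coordinate."""
        if not self.contains(position):
            raise ValidationError(
                f"position {position} outside window ({self.start}, {self.end})"
            )
        return position - self.start + 1


@dataclass(frozen=True)
class WindowSet:
    windows: tuple
    window_length: int = DEFAULT_WINDOW_LENGTH
    min_overlap: int = DEFAULT_MIN_OVERLAP

    def __len__(self) -> int:
        return len(self.windows)

    def covering(self, position: int) -> list:
        return [w for w in self.windows if w.contains(position)]


@dataclass(frozen=True)
class EdgeWeightParams:
    """Sigmoid edge-weight shape: w(p) = sigmoid(steepness * (d(p) - margin)) + eps
    with d(p) the distance from position p to the nearest window edge."""

    steepness: float = 0.1
    margin: int = 127
    eps: float = 1e-6

    def __post_init__(self):
        if self.steepness <= 0:
            raise ValidationError("steepness must be positive")
        if self.margin <= 0:
            raise ValidationError("margin must be positive")


@dataclass(frozen=True)
class AggregationInput:
    """Scores of one variant in each of the (up to three) windows covering it."""

    window_scores: tuple
    window_positions: tuple
    mode: str = "weighted"

    def __post_init__(self):
        if len(self.window_scores) == 0:
            raise ValidationError("empty score list")
        if len(self.window_scores) != len(self.window_positions):
            raise ValidationError("scores and positions must align")
        if not 1 <= len(self.window_scores) <= 3:
            raise ValidationError("a variant is covered by 1..3 windows")
        if self.mode not in AGGREGATION_MODES:
            raise ValidationError(f"unknown aggregation mode {self.mode!r}")


def tile_sequence(
    L: int,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> WindowSet:
    """Tile positions 1..L into fixed-length overlapping windows."""
    if window_length < 2:
        raise ValidationError("window_length must be >= 2")
    if not 1 <= min_overlap < window_length:
        raise ValidationError("min_overlap must satisfy 1 <= min_overlap < window_length")
    if L < 1:
        raise ValidationError("L must be >= 1")

    if L <= window_length:
        return WindowSet(
            windows=(Window(1, L),),
            window_length=window_length,
            min_overlap=min_overlap,
        )

    step = window_length - min_overlap
    left = [Window(1, window_length)]
    right = [Window(L - window_length + 1, L)]

    def inner_overlap():
        return left[-1].end - right[-1].start + 1

    # Grow symmetric pairs with exact-step overlap until the innermost
    # left/right pair overlaps enough; insert one centered window when
    # they meet short of min_overlap.
    while inner_overlap() < min_overlap:
        nxt_left = Window(left[-1].start + step, left[-1].end + step)
        nxt_right = Window(right[-1].start - step, right[-1].end - step)
        if inner_overlap() >= 0:
            # innermost windows already meet: one centered window closes the gap
            c_start = (L - window_length) // 2 + 1
            left.append(Window(c_start, c_start + window_length - 1))
            break
        left.append(nxt_left)
        right.append(nxt_right)

    windows = sorted(set(left + right), key=lambda w: (w.start, w.end))
    ws = WindowSet(
        windows=tuple(windows), window_length=window_length, min_overlap=min_overlap
    )
    _check_invariants(ws, L)
    return ws


def _check_invariants(ws: WindowSet, L: int) -> None:
    wins = ws.windows
    if any(w.length != ws.window_length for w in wins):
        raise ValidationError("window with wrong length produced")
    if wins[0].start != 1 or wins[-1].end != L:
        raise ValidationError("windows do not span the sequence")
    for a, b in zip(wins, wins[1:]):
        if a.end - b.start + 1 < ws.min_overlap:
            raise ValidationError("consecutive windows overlap less than min_overlap")
    coverage = np.zeros(L, dtype=np.int64)
    for w in wins:
        coverage[w.start - 1 : w.end] += 1
    if coverage.min() < 1:
        raise ValidationError("coverage gap in tiling")
    if coverage.max() > 3:
        raise ValidationError("a residue is covered by more than 3 windows")


def edge_weight(
    position_in_window: int,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    params: EdgeWeightParams = EdgeWeightParams(),
) -> float:
    """Positional weight in (0, 1], symmetric about the window center."""
    p = position_in_window
    if not 1 <= p <= window_length:
        raise ValidationError(
            f"position {p} out of window range 1..{window_length}"
        )
    d = min(p - 1, window_length - p)
    sig = 1.0 / (1.0 + np.exp(-params.steepness * (d - params.margin)))
    return float(sig + params.eps)


def aggregate_scores(
    agg: AggregationInput,
    window_length: int = DEFAULT_WINDOW_LENGTH,
    params: EdgeWeightParams = EdgeWeightParams(),
) -> float:
    """Combine 1..3 per-window scores of a variant into one score."""
    s = np.asarray(agg.window_scores, dtype=np.float64)
    if agg.mode == "mean":
        return float(s.mean())
    if agg.mode == "min":
        return float(s.min())
    if agg.mode == "max":
        return float(s.max())
    w = np.array(
        [edge_weight(p, window_length, params) for p in agg.window_positions]
    )
    return float((w * s).sum() / w.sum())


def tiled_llr(
    seq: ProteinSequence,
    backend: BackendSpec,
    params: EdgeWeightParams = EdgeWeightParams(),
    mode: str = "weighted",
    window_length: int | None = None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
):
    """Full 20 x L missense LLR matrix for a sequence of any length.

    For sequences that fit in a single window this is exactly the direct
    single-pass LLR matrix. Longer sequences are tiled; each window
    subsequence is scored independently and per-(position, alt) LLRs are
    aggregated across the windows covering the position.
    """
    from .scoring import LLRMatrix, llr_from_log_probs  # local: avoid cycle

    if mode not in AGGREGATION_MODES:
        raise ValidationError(f"unknown aggregation mode {mode!r}")
    wl = backend.max_input_length if window_length is None else window_length
    L = len(seq)
    if L <= wl:
        probs = score_sequence(backend, seq)
        return LLRMatrix(
            protein_id=seq.id,
            values=llr_from_log_probs(probs, seq.residues),
        )

    ws = tile_sequence(L, wl, min_overlap)
    n_aa = len(ALPHABET)
    num = np.zeros((n_aa, L), dtype=np.float64)
    den = np.zeros(L, dtype=np.float64)
    stack_min = np.full((n_aa, L), np.inf)
    stack_max = np.full((n_aa, L), -np.inf)
    count = np.zeros(L, dtype=np.float64)

    for w in ws.windows:
        sub = ProteinSequence(
            id=f"{seq.id}|{w.start}-{w.end}",
            residues=seq.residues[w.start - 1 : w.end],
        )
        probs = score_sequence(backend, sub)
        sub_llr = llr_from_log_probs(probs, sub.residues)  # 20 x window_length
        cols = slice(w.start - 1, w.end)
        if mode == "weighted":
            wts = np.array(
                [edge_weight(p, w.length, params) for p in range(1, w.length + 1)]
            )
            num[:, cols] += sub_llr * wts
            den[cols] += wts
        elif mode == "mean":
            num[:, cols] += sub_llr
            count[cols] += 1.0
        elif mode == "min":
            stack_min[:, cols] = np.minimum(stack_min[:, cols], sub_llr)
        else:
            stack_max[:, cols] = np.maximum(stack_max[:, cols], sub_llr)

    if mode == "weighted":
        values = num / den
    elif mode == "mean":
        values = num / count
    elif mode == "min":
        values = stack_min
    else:
        values = stack_max

    # WT entries are 0 in every window; force exact zeros post-aggregation.
    for j, aa in enumerate(seq.residues):
        values[ALPHABET.index(aa), j] = 0.0
    return LLRMatrix(protein_id=seq.id, values=values)


def windows_to_rows(protein_id: str, ws: WindowSet):
    """Flatten a WindowSet for TSV export."""
    return [
        {"protein_id": protein_id, "window_index": i, "start": w.start, "end": w.end}
        for i, w in enumerate(ws.windows)
    ]
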