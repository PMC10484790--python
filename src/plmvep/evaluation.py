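"""Benchmark statistics and baseline scores for method comparison.

All metrics take scores oriented lower = more pathogenic (the LLR/PLLR
convention); internally scores are negated so standard higher-is-positive
machinery applies. Pathogenic is the positive class throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import floor
from typing import Callable, Optional

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import rankdata, spearmanr
from sklearn.metrics import average_precision_score, roc_curve

from .errors import DegenerateFitError, ValidationError


@dataclass(frozen=True)
class LabeledScoreSet:
    """Aligned labels, per-method scores and gene ids for a benchmark."""

    variant_ids: tuple
    labels: np.ndarray  # bool, True = pathogenic
    scores: dict  # method name -> float array (lower = more pathogenic)
    gene_ids: tuple

    def __post_init__(self):
        n = len(self.variant_ids)
        if len(self.labels) != n or len(self.gene_ids) != n:
            raise ValidationError("labels/gene_ids must align with variant ids")
        for method, vec in self.scores.items():
            if len(vec) != n:
                raise ValidationError(f"scores for {method!r} have wrong length")
            if not np.all(np.isfinite(vec)):
                raise ValidationError(f"missing/non-finite scores for {method!r}")

    @property
    def n(self) -> int:
        return len(self.variant_ids)

    def method_scores(self, method: str) -> np.ndarray:
        if method not in self.scores:
            raise ValidationError(f"unknown method {method!r}")
        return np.asarray(self.scores[method], dtype=np.float64)


@dataclass(frozen=True)
class DmsAssay:
    """One deep-mutational-scanning assay: measurements per variant."""

    gene_id: str
    assay_id: str
    variant_ids: tuple
    measurements: np.ndarray
    x_wt: Optional[float] = None
    center_transform: bool = False

    def __post_init__(self):
        if len(self.measurements) != len(self.variant_ids):
            raise ValidationError("measurements must align with variant ids")
        if len(self.measurements) < 3:
            raise ValidationError("an assay needs at least 3 variants")
        if self.center_transform and self.x_wt is None:
            raise ValidationError(
                f"assay {self.assay_id!r} requests centering but has no WT value"
            )


@dataclass(frozen=True)
class MetricResult:
    name: str
    value: float
    n_items: int
    sd: Optional[float] = None
    p_value: Optional[float] = None
    metadata: dict = field(default_factory=dict)


def _require_both_classes(labels: np.ndarray) -> None:
    if labels.all() or not labels.any():
        raise ValidationError("both classes must be present")


def _auc_lower_pathogenic(labels: np.ndarray, scores: np.ndarray) -> float:
    """ROC-AUC with midrank tie handling (Mann-Whitney), where lower
    scores rank the positive (pathogenic) class higher."""
    _require_both_classes(labels)
    ranks = rankdata(-scores)  # negate: higher rank = more pathogenic
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    rank_sum = ranks[labels].sum()
    u = rank_sum - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def roc_auc_global(data: LabeledScoreSet, method: str) -> MetricResult:
    """Pooled single-task ROC-AUC over all variants."""
    labels = data.labels
    scores = data.method_scores(method)
    return MetricResult(
        name="roc_auc_global",
        value=_auc_lower_pathogenic(labels, scores),
        n_items=data.n,
        metadata={"method": method},
    )


def roc_auc_gene_average(data: LabeledScoreSet, method: str) -> MetricResult:
    """Unweighted mean of per-gene AUCs over genes with at least one
    variant of each class; other genes are excluded and counted."""
    labels = data.labels
    scores = data.method_scores(method)
    genes = np.asarray(data.gene_ids)
    per_gene = {}
    excluded = 0
    for gene in sorted(set(data.gene_ids)):
        mask = genes == gene
        sub_labels = labels[mask]
        if sub_labels.all() or not sub_labels.any():
            excluded += 1
            continue
        per_gene[gene] = _auc_lower_pathogenic(sub_labels, scores[mask])
    if not per_gene:
        raise ValidationError("no gene has variants of both classes")
    return MetricResult(
        name="roc_auc_gene_average",
        value=float(np.mean(list(per_gene.values()))),
        n_items=len(per_gene),
        metadata={
            "method": method,
            "per_gene": per_gene,
            "n_genes_excluded": excluded,
        },
    )


def tpr_at_fpr(data: LabeledScoreSet, method: str, fpr: float) -> MetricResult:
    """True-positive rate at the most permissive threshold whose
    false-positive rate does not exceed ``fpr``."""
    if not 0.0 < fpr < 1.0:
        raise ValidationError("fpr must be in (0, 1)")
    labels = data.labels
    _require_both_classes(labels)
    scores = data.method_scores(method)
    fpr_arr, tpr_arr, _ = roc_curve(
        labels.astype(int), -scores, drop_intermediate=False
    )
    ok = fpr_arr <= fpr
    value = float(tpr_arr[ok].max()) if ok.any() else 0.0
    return MetricResult(
        name="tpr_at_fpr",
        value=value,
        n_items=data.n,
        metadata={"method": method, "fpr": fpr},
    )


def balanced_prc_auc(
    data: LabeledScoreSet,
    method: str,
    repeats: int = 100,
    frac: float = 0.8,
    seed: int = 0,
) -> MetricResult:
    """Class-balanced PRC-AUC: mean average precision over repeated
    downsamples of ``floor(frac * minority size)`` variants per class."""
    labels = data.labels
    _require_both_classes(labels)
    scores = data.method_scores(method)
    pos_idx = np.flatnonzero(labels)
    neg_idx = np.flatnonzero(~labels)
    n_per = floor(frac * min(pos_idx.size, neg_idx.size))
    if n_per < 1:
        raise ValidationError("minority class too small for balanced downsampling")
    rng = np.random.default_rng(seed)
    values = np.empty(repeats)
    for i in range(repeats):
        take = np.concatenate(
            [
                rng.choice(pos_idx, size=n_per, replace=False),
                rng.choice(neg_idx, size=n_per, replace=False),
            ]
        )
        values[i] = average_precision_score(
            labels[take].astype(int), -scores[take]
        )
    return MetricResult(
        name="balanced_prc_auc",
        value=float(values.mean()),
        sd=float(values.std(ddof=0)),
        n_items=data.n,
        metadata={
            "method": method,
            "repeats": repeats,
            "frac": frac,
            "seed": seed,
            "n_per_class": n_per,
        },
    )


_METRIC_FUNCS: dict = {
    "roc_auc_global": roc_auc_global,
    "roc_auc_gene_average": roc_auc_gene_average,
}


def permutation_test_diff(
    data: LabeledScoreSet,
    method_a: str,
    method_b: str,
    metric: str | Callable = "roc_auc_global",
    n: int = 2000,
    seed: int = 0,
) -> MetricResult:
    """One-tailed permutation test for a metric difference (A minus B).

    Each iteration shuffles both methods' score vectors between the
    benchmark's variants with the same permutation and recomputes the
    metric difference; the p-value is the fraction of permutations whose
    difference is at least as large as the observed one (testing whether
    A outperforms B; swap arguments for the other tail). Zero
    exceedances are reported as an upper bound of 1/n.
    """
    metric_fn = _METRIC_FUNCS[metric] if isinstance(metric, str) else metric

    def diff(ds: LabeledScoreSet) -> float:
        return metric_fn(ds, method_a).value - metric_fn(ds, method_b).value

    observed = diff(data)
    rng = np.random.default_rng(seed)
    a = data.method_scores(method_a)
    b = data.method_scores(method_b)
    exceed = 0
    for _ in range(n):
        perm = rng.permutation(data.n)
        permuted = LabeledScoreSet(
            variant_ids=data.variant_ids,
            labels=data.labels,
            scores={method_a: a[perm], method_b: b[perm]},
            gene_ids=data.gene_ids,
        )
        exceed += diff(permuted) >= observed
    raw = exceed / n
    value = raw if exceed > 0 else 1.0 / n
    return MetricResult(
        name="permutation_test_diff",
        value=observed,
        p_value=value,
        n_items=data.n,
        metadata={
            "method_a": method_a,
            "method_b": method_b,
            "metric": metric if isinstance(metric, str) else metric.__name__,
            "n_permutations": n,
            "seed": seed,
            "raw_fraction": raw,
            "p_is_upper_bound": exceed == 0,
        },
    )


def bootstrap_roc_sd(
    data: LabeledScoreSet,
    method: str,
    n_pos: int = 140,
    n_neg: int = 140,
    iters: int = 20,
    seed: int = 0,
) -> MetricResult:
    """Mean and s.d. of ROC-AUC over repeated class-stratified samples."""
    labels = data.labels
    _require_both_classes(labels)
    scores = data.method_scores(method)
    pos_idx = np.flatnonzero(labels)
    neg_idx = np.flatnonzero(~labels)
    replace_pos = pos_idx.size < n_pos
    replace_neg = neg_idx.size < n_neg
    rng = np.random.default_rng(seed)
    aucs = np.empty(iters)
    for i in range(iters):
        take = np.concatenate(
            [
                rng.choice(pos_idx, size=n_pos, replace=replace_pos),
                rng.choice(neg_idx, size=n_neg, replace=replace_neg),
            ]
        )
        aucs[i] = _auc_lower_pathogenic(labels[take], scores[take])
    return MetricResult(
        name="bootstrap_roc_sd",
        value=float(aucs.mean()),
        sd=float(aucs.std(ddof=0)),
        n_items=data.n,
        metadata={
            "method": method,
            "n_pos": n_pos,
            "n_neg": n_neg,
            "iters": iters,
            "seed": seed,
            "sampled_with_replacement": bool(replace_pos or replace_neg),
        },
    )


# ---------------------------------------------------------------------------
# DMS
# ---------------------------------------------------------------------------


def dms_center_transform(assay: DmsAssay) -> DmsAssay:
    """Replace each measurement by its absolute deviation from the
    assay-wide WT value: x -> |x - x_WT|."""
    if assay.x_wt is None:
        raise ValidationError(f"assay {assay.assay_id!r} has no WT value")
    return DmsAssay(
        gene_id=assay.gene_id,
        assay_id=assay.assay_id,
        variant_ids=assay.variant_ids,
        measurements=np.abs(np.asarray(assay.measurements) - assay.x_wt),
        x_wt=0.0,
        center_transform=False,
    )


def dms_correlations(assays, predictions: dict) -> MetricResult:
    """Hierarchical Spearman summary of prediction-vs-assay agreement.

    ``predictions`` maps assay id to a prediction vector aligned with
    the assay's variants. Assays flagged ``center_transform`` are
    centered first. Reports per-assay correlations, per-gene means and
    the overall mean of per-gene means; assays with a constant vector
    are excluded and listed in the metadata.
    """
    per_assay: dict = {}
    per_gene_values: dict = {}
    excluded = []
    for assay in assays:
        if assay.assay_id not in predictions:
            raise ValidationError(f"no predictions for assay {assay.assay_id!r}")
        if assay.center_transform:
            assay = dms_center_transform(assay)
        preds = np.asarray(predictions[assay.assay_id], dtype=np.float64)
        if len(preds) != len(assay.measurements):
            raise ValidationError(
                f"prediction vector misaligned for assay {assay.assay_id!r}"
            )
        meas = np.asarray(assay.measurements, dtype=np.float64)
        if np.all(meas == meas[0]) or np.all(preds == preds[0]):
            excluded.append(assay.assay_id)
            continue
        rho = spearmanr(preds, meas).statistic
        per_assay[assay.assay_id] = float(rho)
        per_gene_values.setdefault(assay.gene_id, []).append(float(rho))
    if not per_assay:
        raise ValidationError("no assay yielded a defined correlation")
    per_gene = {g: float(np.mean(v)) for g, v in per_gene_values.items()}
    return MetricResult(
        name="dms_correlations",
        value=float(np.mean(list(per_gene.values()))),
        n_items=len(per_assay),
        metadata={
            "per_assay": per_assay,
            "per_gene": per_gene,
            "excluded_assays": excluded,
        },
    )


# ---------------------------------------------------------------------------
# Sequence-similarity baselines for indels
# ---------------------------------------------------------------------------


def levenshtein(wt: str, mut: str) -> int:
    """Minimal number of single-residue insertions, deletions or
    substitutions turning ``wt`` into ``mut``."""
    if not wt or not mut:
        raise ValidationError("sequences must be non-empty")
    prev = np.arange(len(mut) + 1)
    for i, a in enumerate(wt, start=1):
        cur = np.empty(len(mut) + 1, dtype=np.int64)
        cur[0] = i
        for j, b in enumerate(mut, start=1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a != b),
            )
        prev = cur
    return int(prev[-1])


def simple_alignment_score(
    wt: str, mut: str, match: float = 2.0, mismatch: float = -1.0, gap: float = -1.0
) -> float:
    """Optimal global alignment score with a linear gap penalty."""
    if not wt or not mut:
        raise ValidationError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap
    aligner.extend_gap_score = gap
    return float(aligner.score(wt, mut))


def blosum_alignment_score(
    wt: str, mut: str, gap_open: float = 11.0, gap_extend: float = 1.0
) -> float:
    """Optimal global alignment score under BLOSUM62 with affine gaps
    (a gap of length k costs gap_open + k * gap_extend)."""
    if not wt or not mut:
        raise ValidationError("sequences must be non-empty")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return float(aligner.score(wt, mut))
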