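import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from plmvep.errors import ValidationError
from plmvep.evaluation import (
    DmsAssay,
    LabeledScoreSet,
    balanced_prc_auc,
    blosum_alignment_score,
    bootstrap_roc_sd,
    dms_center_transform,
    dms_correlations,
    levenshtein,
    permutation_test_diff,
    roc_auc_gene_average,
    roc_auc_global,
    simple_alignment_score,
    tpr_at_fpr,
)


def make_set(labels, scores, genes=None, method="m"):
    labels = np.asarray(labels, dtype=bool)
    n = labels.size
    return LabeledScoreSet(
        variant_ids=tuple(f"v{i}" for i in range(n)),
        labels=labels,
        scores={method: np.asarray(scores, dtype=float)},
        gene_ids=tuple(genes) if genes else ("g",) * n,
    )


def pair_enumeration_auc(labels, scores):
    """Oracle: exhaustive concordant-pair count, ties worth 1/2.

    Lower score is treated as evidence for the positive class.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    pos = scores[labels]
    neg = scores[~labels]
    total = 0.0
    for p, q in itertools.product(pos, neg):
        if p < q:
            total += 1.0
        elif p == q:
            total += 0.5
    return total / (len(pos) * len(neg))


class TestRocAucGlobal:
    def test_perfect_separation(self):
        data = make_set([1, 1, 0, 0], [-10, -8, -2, -1])
        assert roc_auc_global(data, "m").value == 1.0

    def test_three_of_four_pairs(self):
        data = make_set([1, 1, 0, 0], [-10, -2, -8, -1])
        assert roc_auc_global(data, "m").value == 0.75

    def test_tie_costs_half_pair(self):
        data = make_set([1, 1, 0, 0], [-10, -5, -5, -1])
        assert roc_auc_global(data, "m").value == 1.0 - 0.5 / 4

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc_global(make_set([1, 1], [-1, -2]), "m")

    def test_oracle_equivalence_500_instances(self):
        rng = np.random.default_rng(17)
        for _ in range(500):
            n = int(rng.integers(4, 51))
            labels = rng.integers(0, 2, n).astype(bool)
            if labels.all() or not labels.any():
                labels[0] = ~labels[0]
            scores = np.round(rng.normal(0, 2, n), 1)  # rounding induces ties
            data = make_set(labels, scores)
            assert roc_auc_global(data, "m").value == pytest.approx(
                pair_enumeration_auc(labels, scores), abs=1e-12
            )


class TestRocAucGeneAverage:
    def test_single_gene_equals_its_auc(self):
        data = make_set([1, 0], [-5, -1], genes=["g1", "g1"])
        assert roc_auc_gene_average(data, "m").value == roc_auc_global(
            data, "m"
        ).value

    def test_unweighted_mean(self):
        labels = [1, 0, 1, 0, 1, 0, 1, 0]
        scores = [-9, -1, -9, -1, -9, -1, -1, -9]  # g2 inverted
        genes = ["g1"] * 6 + ["g2"] * 2
        result = roc_auc_gene_average(make_set(labels, scores, genes), "m")
        assert result.value == pytest.approx((1.0 + 0.0) / 2)
        assert result.n_items == 2

    def test_ineligible_genes_excluded(self):
        data = make_set([1, 0, 1], [-5, -1, -9], genes=["g1", "g1", "g2"])
        result = roc_auc_gene_average(data, "m")
        assert result.value == 1.0
        assert result.metadata["n_genes_excluded"] == 1

    def test_per_gene_calibration_beats_global(self):
        # within each gene the method separates perfectly, but per-gene
        # offsets scramble the pooled ranking
        rng = np.random.default_rng(3)
        labels, scores, genes = [], [], []
        for g, offset in enumerate([0.0, -20.0, 20.0, -40.0]):
            for _ in range(10):
                labels.append(1)
                scores.append(offset - 10 + rng.normal(0, 0.1))
                labels.append(0)
                scores.append(offset - 2 + rng.normal(0, 0.1))
                genes.append(f"g{g}")
                genes.append(f"g{g}")
        data = make_set(labels, scores, genes)
        assert (
            roc_auc_gene_average(data, "m").value
            > roc_auc_global(data, "m").value
        )

    def test_no_eligible_gene_rejected(self):
        data = make_set([1, 0], [-5, -1], genes=["g1", "g2"])
        with pytest.raises(ValidationError):
            roc_auc_gene_average(data, "m")


class TestTprAtFpr:
    def test_perfect(self):
        data = make_set([1, 1, 0, 0], [-9, -8, -2, -1])
        for fpr in (0.01, 0.05, 0.5):
            assert tpr_at_fpr(data, "m", fpr).value == 1.0

    def test_toy_staircase(self):
        # scores sorted ascending (most pathogenic first):
        # P(-10) P(-8) B(-6) P(-4) B(-3) B(-1)
        data = make_set([1, 1, 0, 1, 0, 0], [-10, -8, -6, -4, -3, -1])
        # at fpr<=0: threshold passes first two positives -> tpr 2/3
        assert tpr_at_fpr(data, "m", 0.1).value == pytest.approx(2 / 3)
        # allowing one false positive (fpr 1/3) captures all positives
        assert tpr_at_fpr(data, "m", 0.34).value == pytest.approx(1.0)

    def test_random_scores_tracks_fpr(self):
        rng = np.random.default_rng(5)
        n = 4000
        labels = np.repeat([True, False], n // 2)
        data = make_set(labels, rng.normal(size=n))
        for fpr in (0.05, 0.2):
            value = tpr_at_fpr(data, "m", fpr).value
            # noise from both the threshold (negatives) and the TPR (positives)
            se = np.sqrt(fpr * (1 - fpr) * (2 / (n // 2)))
            assert abs(value - fpr) < 3 * se + 2 / (n // 2)

    def test_invalid_fpr(self):
        data = make_set([1, 0], [-5, -1])
        with pytest.raises(ValidationError):
            tpr_at_fpr(data, "m", 0.0)


class TestBalancedPrcAuc:
    def test_perfect_separation(self):
        labels = [1] * 10 + [0] * 14
        scores = [-9.0] * 10 + [-1.0] * 14
        result = balanced_prc_auc(make_set(labels, scores), "m", repeats=20, seed=1)
        assert result.value == 1.0
        assert result.sd == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(9)
        n = 1000
        labels = np.repeat([True, False], n // 2)
        data = make_set(labels, rng.normal(size=n))
        value = balanced_prc_auc(data, "m", repeats=50, seed=9).value
        assert abs(value - 0.5) < 0.05

    def test_majority_duplication_invariance(self):
        rng = np.random.default_rng(13)
        n_pos, n_neg = 300, 500
        labels = np.array([True] * n_pos + [False] * n_neg)
        scores = np.concatenate(
            [rng.normal(-8, 2, n_pos), rng.normal(-3, 2, n_neg)]
        )
        base = balanced_prc_auc(make_set(labels, scores), "m", seed=2).value
        dup_labels = np.concatenate([labels, labels[~labels]])
        dup_scores = np.concatenate([scores, scores[~labels]])
        dup = balanced_prc_auc(make_set(dup_labels, dup_scores), "m", seed=2).value
        assert abs(base - dup) < 0.01

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(1)
        labels = np.repeat([True, False], 50)
        data = make_set(labels, rng.normal(size=100))
        a = balanced_prc_auc(data, "m", seed=77)
        b = balanced_prc_auc(data, "m", seed=77)
        assert a.value == b.value and a.sd == b.sd

    def test_downsample_size(self):
        labels = np.repeat([True, False], [10, 90])
        data = make_set(labels, np.arange(100, dtype=float))
        result = balanced_prc_auc(data, "m", repeats=2, seed=0)
        assert result.metadata["n_per_class"] == 8  # floor(0.8 * 10)


class TestPermutationTest:
    def two_method_set(self, scores_a, scores_b, labels):
        labels = np.asarray(labels, dtype=bool)
        return LabeledScoreSet(
            variant_ids=tuple(f"v{i}" for i in range(labels.size)),
            labels=labels,
            scores={"A": np.asarray(scores_a, float), "B": np.asarray(scores_b, float)},
            gene_ids=("g",) * labels.size,
        )

    def test_identical_methods_p_one(self):
        rng = np.random.default_rng(2)
        labels = np.repeat([True, False], 20)
        s = rng.normal(size=40)
        data = self.two_method_set(s, s.copy(), labels)
        result = permutation_test_diff(data, "A", "B", n=200, seed=0)
        assert result.value == 0.0
        assert result.p_value == 1.0

    def test_strong_method_beats_random(self):
        rng = np.random.default_rng(3)
        n = 400
        labels = np.repeat([True, False], n // 2)
        good = np.where(labels, -10.0, -1.0) + rng.normal(0, 0.5, n)
        rand = rng.normal(size=n)
        data = self.two_method_set(good, rand, labels)
        result = permutation_test_diff(data, "A", "B", n=2000, seed=0)
        assert result.metadata["p_is_upper_bound"]
        assert result.p_value == 1 / 2000

    def test_seed_reproducible(self):
        rng = np.random.default_rng(4)
        labels = np.repeat([True, False], 30)
        data = self.two_method_set(rng.normal(size=60), rng.normal(size=60), labels)
        r1 = permutation_test_diff(data, "A", "B", n=100, seed=5)
        r2 = permutation_test_diff(data, "A", "B", n=100, seed=5)
        assert r1.p_value == r2.p_value


class TestBootstrapRocSd:
    def test_perfect_separation(self):
        labels = np.repeat([True, False], 150)
        scores = np.where(labels, -9.0, -1.0)
        result = bootstrap_roc_sd(make_set(labels, scores), "m", seed=0)
        assert result.value == 1.0 and result.sd == 0.0

    def test_sd_shrinks_with_sample_size(self):
        rng = np.random.default_rng(6)
        n = 4000
        labels = np.repeat([True, False], n // 2)
        scores = np.where(labels, rng.normal(-6, 2, n), rng.normal(-3, 2, n))
        data = make_set(labels, scores)
        sds = [
            bootstrap_roc_sd(data, "m", n_pos=k, n_neg=k, iters=40, seed=1).sd
            for k in (20, 140, 1000)
        ]
        assert sds[0] > sds[1] > sds[2]

    def test_small_class_flagged(self):
        labels = np.repeat([True, False], [20, 200])
        data = make_set(labels, np.arange(220, dtype=float))
        result = bootstrap_roc_sd(data, "m", n_pos=140, n_neg=140, seed=0)
        assert result.metadata["sampled_with_replacement"]

    def test_reproducible(self):
        rng = np.random.default_rng(8)
        labels = np.repeat([True, False], 200)
        data = make_set(labels, rng.normal(size=400))
        a = bootstrap_roc_sd(data, "m", seed=3)
        b = bootstrap_roc_sd(data, "m", seed=3)
        assert a.value == b.value and a.sd == b.sd


class TestDms:
    def assay(self, measurements, x_wt=None, center=False, gene="g1", aid="a1"):
        m = np.asarray(measurements, dtype=float)
        return DmsAssay(
            gene_id=gene,
            assay_id=aid,
            variant_ids=tuple(f"v{i}" for i in range(m.size)),
            measurements=m,
            x_wt=x_wt,
            center_transform=center,
        )

    def test_center_transform_examples(self):
        assay = self.assay([1.0, 2.0, 3.0, 0.0, 2.5], x_wt=2.0)
        out = dms_center_transform(assay)
        assert np.allclose(out.measurements, [1.0, 0.0, 1.0, 2.0, 0.5])

    def test_symmetric_values_coincide(self):
        out = dms_center_transform(self.assay([1.0, 3.0, 2.0], x_wt=2.0))
        assert out.measurements[0] == out.measurements[1]

    def test_missing_wt_rejected(self):
        with pytest.raises(ValidationError):
            dms_center_transform(self.assay([1.0, 2.0, 3.0]))

    def test_identical_predictions_all_levels_one(self):
        assays = [
            self.assay([1.0, 2.0, 3.0, 4.0], gene="g1", aid="a1"),
            self.assay([5.0, 1.0, 3.0], gene="g2", aid="a2"),
        ]
        preds = {"a1": np.array([1.0, 2.0, 3.0, 4.0]), "a2": np.array([5.0, 1.0, 3.0])}
        result = dms_correlations(assays, preds)
        assert result.value == 1.0
        assert all(v == 1.0 for v in result.metadata["per_gene"].values())

    def test_nested_averaging(self):
        rng = np.random.default_rng(11)
        assays, preds, expected_by_gene = [], {}, {}
        for gene, n_assays in (("g1", 2), ("g2", 1)):
            rhos = []
            for k in range(n_assays):
                aid = f"{gene}.a{k}"
                meas = rng.normal(size=30)
                pred = meas + rng.normal(0, 1.5, 30)
                assays.append(self.assay(meas, gene=gene, aid=aid))
                preds[aid] = pred
                rhos.append(spearmanr(pred, meas).statistic)
            expected_by_gene[gene] = np.mean(rhos)
        result = dms_correlations(assays, preds)
        assert result.value == pytest.approx(
            np.mean(list(expected_by_gene.values())), abs=1e-12
        )

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(12)
        meas = rng.normal(size=25)
        pred = meas + rng.normal(0, 1, 25)
        assays = [self.assay(meas)]
        r1 = dms_correlations(assays, {"a1": pred}).value
        r2 = dms_correlations(assays, {"a1": np.exp(pred / 2)}).value
        assert r1 == pytest.approx(r2, abs=1e-12)

    def test_constant_assay_excluded(self):
        assays = [
            self.assay([1.0, 1.0, 1.0], aid="flat"),
            self.assay([1.0, 2.0, 3.0], aid="ok"),
        ]
        preds = {"flat": np.array([1.0, 2.0, 3.0]), "ok": np.array([1.0, 2.0, 3.0])}
        result = dms_correlations(assays, preds)
        assert result.metadata["excluded_assays"] == ["flat"]
        assert result.n_items == 1


class TestSequenceBaselines:
    def test_levenshtein_examples(self):
        assert levenshtein("MKTA", "MKTA") == 0
        assert levenshtein("MKTA", "MTA") == 1
        assert levenshtein("KITTEN", "SITTING") == 3

    def test_levenshtein_metric_axioms(self, rng):
        alphabet = list("ACDEFG")
        for _ in range(25):
            seqs = [
                "".join(rng.choice(alphabet, size=int(rng.integers(1, 8))))
                for _ in range(3)
            ]
            a, b, c = seqs
            assert levenshtein(a, b) == levenshtein(b, a)
            assert levenshtein(a, c) <= levenshtein(a, b) + levenshtein(b, c)
            assert levenshtein(a, a) == 0

    def test_simple_alignment_examples(self):
        assert simple_alignment_score("AAAA", "AAAA") == 8.0
        assert simple_alignment_score("AAAA", "AACA") == 5.0

    def test_simple_alignment_symmetry(self, rng):
        alphabet = list("ACDEFGHIKL")
        for _ in range(10):
            a = "".join(rng.choice(alphabet, size=int(rng.integers(2, 10))))
            b = "".join(rng.choice(alphabet, size=int(rng.integers(2, 10))))
            assert simple_alignment_score(a, b) == simple_alignment_score(b, a)

    def test_blosum_identity_is_diagonal_sum(self):
        from Bio.Align import substitution_matrices

        blosum = substitution_matrices.load("BLOSUM62")
        seq = "MKTAYWQH"
        expected = sum(blosum[aa, aa] for aa in seq)
        assert blosum_alignment_score(seq, seq) == expected

    def test_blosum_single_deletion_cost(self):
        seq = "MKTAYWQHLV"
        identity = blosum_alignment_score(seq, seq)
        deleted = seq[:4] + seq[5:]
        expected = identity - float(
            __import__("Bio.Align", fromlist=["substitution_matrices"])
            .substitution_matrices.load("BLOSUM62")["Y", "Y"]
        ) - (11.0 + 1.0)
        assert blosum_alignment_score(seq, deleted) == expected

    def test_blosum_identity_is_upper_bound(self, rng):
        alphabet = list("ACDEFGHIKLMNPQRSTVWY")
        for _ in range(10):
            a = "".join(rng.choice(alphabet, size=12))
            b = "".join(rng.choice(alphabet, size=12))
            assert blosum_alignment_score(a, b) <= blosum_alignment_score(a, a)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValidationError):
            levenshtein("", "A")
        with pytest.raises(ValidationError):
            simple_alignment_score("A", "")
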