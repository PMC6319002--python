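"""Marker filtering, TMM normalization, log-cpm and mean-variance weights."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import eqtlcross as eq
from eqtlcross.preprocess import MarkerStatus


def _map(n, chrom="chr1"):
    return pd.DataFrame({"marker": [f"m{i}" for i in range(n)],
                         "chrom": chrom, "pos": (np.arange(n) + 1) * 1000})


class TestFilterMarkers:
    def test_monomorphic_flagged(self):
        M = np.column_stack([np.full(20, 2), np.tile([0, 1, 2, 1], 5)])
        g = eq.filter_markers(M, _map(2))
        assert g.map["status"].tolist() == [MarkerStatus.REMOVED_MONO,
                                            MarkerStatus.KEPT]

    def test_maf_boundary_is_strict(self):
        # 1000 animals: MAF 0.009 removed, MAF 0.011 kept at threshold 0.01
        n = 1000
        col_low = np.zeros(n); col_low[:18] = 1    # freq 0.009
        col_hi = np.zeros(n); col_hi[:22] = 1      # freq 0.011
        keeper = np.tile([0, 1, 2, 1], n // 4)
        M = np.column_stack([col_low, col_hi, keeper]).astype(int)
        g = eq.filter_markers(M, _map(3), maf_min=0.01)
        assert g.map["status"].tolist() == [MarkerStatus.REMOVED_MAF,
                                            MarkerStatus.KEPT,
                                            MarkerStatus.KEPT]

    def test_duplicated_column_pruned_downstream(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 50)
        b = rng.integers(0, 3, 50)
        M = np.column_stack([a, a, b])
        g = eq.filter_markers(M, _map(3))
        assert g.map["status"].tolist() == [MarkerStatus.KEPT,
                                            MarkerStatus.PRUNED_LD,
                                            MarkerStatus.KEPT]

    def test_idempotent(self, small_panel):
        g1 = small_panel["geno"]
        kept_ids = g1.kept_map["marker"].tolist()
        g2 = eq.filter_markers(g1.M.astype(int),
                               g1.kept_map[["marker", "chrom", "pos"]])
        assert g2.kept_map["marker"].tolist() == kept_ids

    def test_all_removed_raises(self):
        M = np.full((10, 3), 2)
        with pytest.raises(ValueError, match="empty panel"):
            eq.filter_markers(M, _map(3))

    def test_missing_dosage_rejected(self):
        M = np.array([[0, 3], [1, 1]])
        with pytest.raises(ValueError):
            eq.filter_markers(M, _map(2))


class TestCountFilter:
    def _cm(self, rows):
        counts = np.asarray(rows, dtype=np.int64)
        genes = pd.DataFrame({"gene": [f"g{i}" for i in range(len(rows))],
                              "chrom": "chr1", "start": 1, "end": 10})
        return eq.CountMatrix(counts=counts, genes=genes,
                              samples=[f"s{i}" for i in range(counts.shape[1])])

    def test_strict_less_than_boundary(self):
        cm = self._cm([[167, 0], [168, 0], [0, 0]])
        out = eq.filter_low_count_genes(cm, min_total=168)
        assert out.genes["gene"].tolist() == ["g1"]

    def test_default_threshold_is_sample_count(self):
        cm = self._cm([[1, 0], [1, 1]])
        out = eq.filter_low_count_genes(cm)
        assert out.genes["gene"].tolist() == ["g1"]

    def test_all_zero_gene_dropped(self):
        cm = self._cm([[0, 0], [5, 5]])
        assert "g0" not in eq.filter_low_count_genes(cm, 1).genes["gene"].tolist()


def tmm_oracle(counts, ref, obs, trim_m=0.30, trim_a=0.05):
    """Independent loop-based evaluation of the trimmed weighted mean of
    M-values for one sample against a reference."""
    lib = counts.sum(axis=0)
    rows = []
    for g in range(counts.shape[0]):
        yo, yr = counts[g, obs], counts[g, ref]
        if yo == 0 or yr == 0:
            continue
        o, r = yo / lib[obs], yr / lib[ref]
        rows.append((np.log2(o / r), 0.5 * np.log2(o * r),
                     (lib[obs] - yo) / (lib[obs] * yo)
                     + (lib[ref] - yr) / (lib[ref] * yr)))
    n = len(rows)
    ms = sorted(r[0] for r in rows)
    as_ = sorted(r[1] for r in rows)
    lo_m, hi_m = int(np.floor(n * trim_m)), n - int(np.floor(n * trim_m))
    lo_a, hi_a = int(np.floor(n * trim_a)), n - int(np.floor(n * trim_a))
    m_keep = set()
    num = den = 0.0
    for M, A, w in rows:
        rank_m = sum(1 for x in ms if x < M) + (sum(1 for x in ms if x == M) + 1) / 2
        rank_a = sum(1 for x in as_ if x < A) + (sum(1 for x in as_ if x == A) + 1) / 2
        if lo_m + 1 <= rank_m <= hi_m and lo_a + 1 <= rank_a <= hi_a:
            num += w * M
            den += w
    return 2 ** (num / den)


class TestTMM:
    def test_identical_columns_unit_factors(self, toy_counts):
        cm = eq.CountMatrix(counts=np.tile(toy_counts.counts[:, :1], (1, 4)),
                            genes=toy_counts.genes,
                            samples=list("abcd"))
        f = eq.tmm_normalize(cm)
        assert np.allclose(f, 1.0, atol=1e-12)

    def test_pure_depth_change_absorbed_by_library_size(self, toy_counts):
        col = toy_counts.counts[:, 0]
        cm = eq.CountMatrix(counts=np.column_stack([col, 2 * col]),
                            genes=toy_counts.genes, samples=["a", "b"])
        f = eq.tmm_normalize(cm)
        assert np.allclose(f[0], f[1], atol=1e-12)

    def test_matches_bruteforce_trimmed_weighted_mean(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(200, size=(200, 4)).astype(np.int64)
        counts[rng.choice(200, 20, replace=False), 2] *= 10  # inflate 10% of genes
        genes = pd.DataFrame({"gene": [f"g{i}" for i in range(200)],
                              "chrom": "chr1", "start": 1, "end": 10})
        cm = eq.CountMatrix(counts=counts, genes=genes, samples=list("abcd"))
        f = eq.tmm_normalize(cm)
        # recompute the reference choice and raw factors independently
        lib = counts.sum(axis=0)
        uq = np.array([np.quantile(counts[counts[:, j] > 0, j] / lib[j], 0.75)
                       for j in range(4)])
        ref = int(np.argmin(np.abs(uq - uq.mean())))
        raw = np.array([1.0 if j == ref else tmm_oracle(counts, ref, j)
                        for j in range(4)])
        expected = raw / np.exp(np.mean(np.log(raw)))
        assert np.allclose(f, expected, rtol=1e-10)

    def test_gene_order_permutation_invariant(self, toy_counts):
        f1 = eq.tmm_normalize(toy_counts)
        rng = np.random.default_rng(1)
        perm = rng.permutation(toy_counts.counts.shape[0])
        cm = eq.CountMatrix(counts=toy_counts.counts[perm],
                            genes=toy_counts.genes.iloc[perm].reset_index(drop=True),
                            samples=toy_counts.samples)
        assert np.allclose(f1, eq.tmm_normalize(cm), atol=1e-12)

    def test_all_zero_sample_error_names_sample(self, toy_counts):
        counts = toy_counts.counts.copy()
        counts[:, 2] = 0
        cm = eq.CountMatrix(counts=counts, genes=toy_counts.genes,
                            samples=toy_counts.samples)
        with pytest.raises(ValueError, match="s2"):
            eq.tmm_normalize(cm)


class TestLogCpm:
    def test_zero_count_at_effective_million(self):
        # one gene at count 0 with effective library forced to 1e6
        counts = np.array([[0], [999_999]], dtype=np.int64)
        genes = pd.DataFrame({"gene": ["a", "b"], "chrom": "c",
                              "start": 1, "end": 2})
        cm = eq.CountMatrix(counts=counts, genes=genes, samples=["s"])
        y = eq.logcpm(cm, np.array([1.0]))
        assert y[0, 0] == pytest.approx(np.log2(0.5), abs=1e-12)

    def test_matches_hand_formula(self):
        counts = np.array([[3, 10], [0, 2], [7, 5]], dtype=np.int64)
        genes = pd.DataFrame({"gene": list("abc"), "chrom": "c",
                              "start": 1, "end": 2})
        cm = eq.CountMatrix(counts=counts, genes=genes, samples=["x", "y"])
        f = np.array([1.2, 0.8])
        lib = counts.sum(axis=0)
        expected = np.log2((counts + 0.5) / (lib * f + 1.0) * 1e6)
        assert np.allclose(eq.logcpm(cm, f), expected)

    def test_monotone_in_counts(self, toy_counts):
        f = eq.tmm_normalize(toy_counts)
        y1 = eq.logcpm(toy_counts, f)
        bumped = toy_counts.counts.copy()
        bumped[0, 0] += 10
        cm = eq.CountMatrix(counts=bumped, genes=toy_counts.genes,
                            samples=toy_counts.samples)
        assert eq.logcpm(cm, f)[0, 0] > y1[0, 0]


class TestWeights:
    def test_hand_example_two_trend_values(self):
        # trend variances {1, 4}: 1/sqrt = {1, .5}, mean .75 -> {4/3, 2/3}
        w = eq.standardize_weights(np.array([1.0, 4.0]))
        assert np.allclose(w, [4 / 3, 2 / 3])

    def test_flat_trend_gives_unit_weights(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=12)
        y = np.tile(base, (20, 1)) + np.linspace(0, 5, 20)[:, None]
        w_hat, w_std = eq.compute_weights(y, np.ones((12, 1)))
        assert np.allclose(w_std, 1.0, atol=1e-8)

    def test_unit_mean_on_real_normalization(self, small_panel):
        X = np.ones((300, 1))
        norm = eq.normalize_expression(small_panel["counts"], X)
        assert abs(norm.w_std.mean() - 1.0) < 1e-10
        assert np.all(norm.w_std > 0) and np.all(norm.w_hat > 0)

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(st.lists(st.floats(min_value=1e-3, max_value=1e3), min_size=2,
                    max_size=40))
    def test_standardized_weights_always_unit_mean(self, w_hat):
        w = eq.standardize_weights(np.array(w_hat))
        assert abs(w.mean() - 1.0) < 1e-10

    def test_nonfinite_input_rejected(self):
        y = np.zeros((12, 5))
        y[0, 0] = np.nan
        with pytest.raises(ValueError):
            eq.compute_weights(y, np.ones((5, 1)))
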