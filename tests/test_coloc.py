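"""pQTL mapping, interval overlap, conditional co-localization and the
variance-explained arithmetic."""

import numpy as np
import pandas as pd
import pytest

import eqtlcross as eq


def _rec(chrom, start, end, name="r", peak=None):
    return eq.EQTLRecord(response=name, chrom=chrom, start=start, end=end,
                         peak_marker="m", peak_pos=peak or start, n_snps=1,
                         peak_q=1e-4)


class TestOverlaps:
    def test_overlapping_same_chromosome(self):
        pairs = eq.find_overlaps([_rec("chr1", 120, 122)],
                                 [_rec("chr1", 121, 131)])
        assert len(pairs) == 1

    def test_disjoint_intervals(self):
        assert eq.find_overlaps([_rec("chr1", 10, 11)],
                                [_rec("chr1", 12, 13)]) == []

    def test_different_chromosomes(self):
        assert eq.find_overlaps([_rec("chr1", 10, 20)],
                                [_rec("chr2", 10, 20)]) == []

    def test_point_interval_touching(self):
        assert len(eq.find_overlaps([_rec("chr1", 10, 10)],
                                    [_rec("chr1", 10, 20)])) == 1

    def test_symmetric_in_roles(self):
        es = [_rec("chr1", 10, 20, "e1"), _rec("chr2", 5, 9, "e2")]
        ps = [_rec("chr1", 15, 30, "p1"), _rec("chr2", 1, 6, "p2")]
        fwd = {(e.response, p.response) for e, p in eq.find_overlaps(es, ps)}
        rev = {(e.response, p.response) for p, e in eq.find_overlaps(ps, es)}
        assert fwd == rev


class TestVarianceExplained:
    def test_zero_effect(self):
        assert eq.snp_variance_explained(0.0, 1.0, 0.3, 0.7) == 0.0

    def test_half_split(self):
        # b^2 var(Z) equals sigma_a^2 + sigma_e^2 -> one half
        assert eq.snp_variance_explained(1.0, 1.0, 0.4, 0.6) == pytest.approx(0.5)

    def test_hand_arithmetic(self):
        # b = .5, var 1, sa2 = .3, se2 = .45 -> .25 / (.25 + .75) = .25
        assert eq.snp_variance_explained(0.5, 1.0, 0.3, 0.45) == pytest.approx(0.25)

    def test_invariant_to_response_rescaling(self):
        c = 3.7
        v1 = eq.snp_variance_explained(0.5, 1.0, 0.3, 0.45)
        v2 = eq.snp_variance_explained(0.5 * c, 1.0, 0.3 * c**2, 0.45 * c**2)
        assert v1 == pytest.approx(v2)


class TestMapPqtl:
    def test_constant_phenotype_skipped(self, small_panel):
        phen = pd.DataFrame({"sex": np.zeros(small_panel["runner"].n),
                             "flat": np.ones(small_panel["runner"].n)})
        with pytest.warns(UserWarning, match="flat"):
            recs, fits = eq.map_pqtl(phen, ["flat"], small_panel["geno"],
                                     small_panel["runner"], covariates=())
        assert recs == [] and fits == {}

    def test_expression_trait_through_pqtl_path_matches_gwa_path(self, small_panel):
        """Unit-weight expression fed through map_pqtl equals the eQTL path."""
        runner, Z, geno = (small_panel["runner"], small_panel["Z"],
                           small_panel["geno"])
        rng = np.random.default_rng(17)
        y = eq.simulate_gaussian_traits(Z, 0.5, 1, rng)[0]
        n = len(y)
        phen = pd.DataFrame({"sex": np.zeros(n), "y": y})
        recs, fits = eq.map_pqtl(phen, ["y"], geno, runner, covariates=(),
                                 alpha=0.01)
        fit = runner.fit(y, np.ones((n, 1)), weight=1.0)
        ghat, vg = eq.backsolve_snp_effects(fit)
        _, p = eq.snp_test(ghat, vg)
        q = eq.gene_fdr([p], alpha=0.01)[0]
        expected = eq.call_eqtl("y", q, p, geno.kept_map, alpha=0.01)
        assert [(r.chrom, r.start, r.end) for r in recs] == \
            [(r.chrom, r.start, r.end) for r in expected]

    def test_null_phenotypes_rarely_yield_pqtl(self):
        from eqtlcross.evaluation import make_panel
        hits = 0
        for seed in range(12):
            cfg, panel = make_panel(seed, n_f2=150, n_chrom=5,
                                    markers_per_chrom=30, n_genes=10)
            rng = panel.rngs[3]
            n = panel.geno.M.shape[0]
            phen = pd.DataFrame({"sex": rng.integers(0, 2, n),
                                 "null": rng.normal(size=n)})
            recs, _ = eq.map_pqtl(phen, ["null"], panel.geno, panel.runner,
                                  alpha=0.05)
            hits += bool(recs)
        assert hits <= 2   # no pQTL in >= 10/12 null datasets


class TestConditionalColoc:
    def test_perfect_proxy_always_eliminates(self, small_panel):
        """Conditioning on a marker in complete LD with the causal SNP always
        removes the eQTL interval."""
        runner, Z, geno = (small_panel["runner"], small_panel["Z"],
                           small_panel["geno"])
        km = geno.kept_map
        rng = np.random.default_rng(23)
        j = 40
        n = Z.shape[0]
        dos = geno.M[:, j]
        y = (np.sqrt(0.3) * (dos - dos.mean()) / dos.std()
             + rng.normal(0, np.sqrt(0.7), n))
        X = np.ones((n, 1))
        fit = runner.fit(y, X)
        ghat, vg = eq.backsolve_snp_effects(fit)
        _, p = eq.snp_test(ghat, vg)
        q = eq.gene_fdr([p])[0]
        eqtls = [r for r in eq.call_eqtl("g", q, p, km, alpha=0.01)
                 if r.chrom == km["chrom"].iloc[j]]
        assert eqtls
        pqtl = eq.EQTLRecord(response="ph", chrom=eqtls[0].chrom,
                             start=eqtls[0].start, end=eqtls[0].end,
                             peak_marker=km["marker"].iloc[j],
                             peak_pos=int(km["pos"].iloc[j]), n_snps=1,
                             peak_q=1e-5)
        c = eq.conditional_coloc(y, X, runner, 1.0, (eqtls[0], pqtl), geno,
                                 n_tests=4)
        assert c.eliminated
        assert c.ld_r is not None
        assert c.bonferroni == pytest.approx(0.05 / 4)

    def test_significant_implies_eliminated(self, small_panel):
        runner, geno, Z = (small_panel["runner"], small_panel["geno"],
                           small_panel["Z"])
        km = geno.kept_map
        rng = np.random.default_rng(29)
        n = Z.shape[0]
        y = eq.simulate_gaussian_traits(Z, 0.4, 1, rng)[0]
        e = eq.EQTLRecord(response="g", chrom=km["chrom"].iloc[5],
                          start=int(km["pos"].iloc[3]), end=int(km["pos"].iloc[8]),
                          peak_marker=km["marker"].iloc[5],
                          peak_pos=int(km["pos"].iloc[5]), n_snps=3, peak_q=1e-3)
        p = eq.EQTLRecord(response="ph", chrom=e.chrom, start=e.start,
                          end=e.end, peak_marker=km["marker"].iloc[6],
                          peak_pos=int(km["pos"].iloc[6]), n_snps=2, peak_q=1e-3)
        c = eq.conditional_coloc(y, np.ones((n, 1)), runner, 1.0, (e, p),
                                 geno, n_tests=84)
        assert c.significant_coloc <= c.eliminated
        assert c.bonferroni == pytest.approx(5.952e-04, rel=1e-3)

    def test_zero_effect_snp_within_wald_bounds(self, small_panel):
        """A conditioning SNP with no planted effect has |b| < 3 SE in the
        overwhelming majority of replicates."""
        runner, geno = small_panel["runner"], small_panel["geno"]
        km = geno.kept_map
        rng = np.random.default_rng(31)
        n = runner.n
        e = eq.EQTLRecord(response="g", chrom=km["chrom"].iloc[0],
                          start=int(km["pos"].iloc[0]), end=int(km["pos"].iloc[2]),
                          peak_marker=km["marker"].iloc[1],
                          peak_pos=int(km["pos"].iloc[1]), n_snps=1, peak_q=1e-3)
        p = eq.EQTLRecord(response="ph", chrom=e.chrom, start=e.start,
                          end=e.end, peak_marker=km["marker"].iloc[-1],
                          peak_pos=int(km["pos"].iloc[len(km) - 1]), n_snps=1,
                          peak_q=1e-3)
        ok = 0
        for _ in range(20):
            y = rng.normal(size=n)
            c = eq.conditional_coloc(y, np.ones((n, 1)), runner, 1.0, (e, p),
                                     geno, n_tests=1)
            ok += abs(c.b_snp) < 3 * c.se_snp
        assert ok >= 18


class TestResidualCorrelations:
    def test_self_correlation_unity(self):
        x = np.random.default_rng(0).normal(size=30)
        df = eq.residual_correlations({"a": x, "b": x.copy()})
        assert df["r"].iloc[0] == pytest.approx(1.0)

    def test_t_arithmetic(self):
        # construct two vectors with exact r = 0.5 at n = 27
        rng = np.random.default_rng(1)
        n = 27
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        z -= z @ x / n * x
        z = (z - z.mean()) / z.std()
        y = 0.5 * x + np.sqrt(1 - 0.25) * z
        df = eq.residual_correlations({"a": x, "b": y})
        assert df["r"].iloc[0] == pytest.approx(0.5, abs=1e-10)
        assert df["t"].iloc[0] == pytest.approx(2.8868, abs=1e-3)
        assert df["p"].iloc[0] == pytest.approx(0.0079, abs=2e-4)

    def test_independent_residuals_mostly_small(self):
        rng = np.random.default_rng(2)
        res = {f"v{i}": rng.normal(size=168) for i in range(12)}
        df = eq.residual_correlations(res)
        assert (df["r"].abs() < 0.3).mean() > 0.95


class TestDosageLD:
    def test_self_unity_and_complement(self):
        rng = np.random.default_rng(3)
        m = rng.integers(0, 3, 100).astype(float)
        assert eq.dosage_ld(m, m) == pytest.approx(1.0)
        assert eq.dosage_ld(m, 2 - m) == pytest.approx(-1.0)

    def test_matches_haldane_oracle_at_10cm(self):
        from tests.test_simdata import f2_dosage_corr_oracle
        expected = f2_dosage_corr_oracle(0.10)
        rs = []
        for seed in range(20):
            cfg = eq.SimConfig(seed=seed, n_f2=500, n_chrom=1,
                               markers_per_chrom=2, genetic_length_cM=30.0,
                               founder_divergence=1.0, n_genes=1)
            f = eq.simulate_founder_haplotypes(cfg)
            g = eq.simulate_f2_cross(f, cfg)   # markers at 10 and 20 cM
            rs.append(eq.dosage_ld(g.M[:, 0], g.M[:, 1]))
        assert abs(np.mean(rs) - expected) < 0.05

    def test_constant_marker_rejected(self):
        with pytest.raises(ValueError):
            eq.dosage_ld(np.ones(10), np.arange(10.0))


class TestAdditiveDominance:
    def _setting(self, small_panel, kind, seed):
        runner, geno = small_panel["runner"], small_panel["geno"]
        rng = np.random.default_rng(seed)
        dos = geno.M[:, 10]
        n = len(dos)
        add = dos - 1.0
        dom = (dos == 1).astype(float)
        y = rng.normal(size=n)
        if kind == "additive":
            y = np.sqrt(0.15) * (add - add.mean()) / add.std() \
                + rng.normal(0, np.sqrt(0.85), n)
        elif kind == "dominant":
            y = np.sqrt(0.15) * (dom - dom.mean()) / dom.std() \
                + rng.normal(0, np.sqrt(0.85), n)
        return runner, dos, y, np.ones((n, 1))

    def test_pure_heterozygote_advantage(self, small_panel):
        hits = 0
        for seed in range(10):
            runner, dos, y, X = self._setting(small_panel, "dominant", seed)
            p_add, p_dom = eq.additive_dominance_test(y, dos, X, runner)
            hits += p_dom < 0.05
        assert hits >= 9

    def test_purely_additive_dominance_null(self, small_panel):
        ps = []
        for seed in range(10):
            runner, dos, y, X = self._setting(small_panel, "additive", seed)
            _, p_dom = eq.additive_dominance_test(y, dos, X, runner)
            ps.append(p_dom)
        assert 0.1 < np.mean(ps) < 0.9   # null-like dominance p

    def test_missing_class_drops_dominance(self, small_panel):
        runner = small_panel["runner"]
        n = runner.n
        rng = np.random.default_rng(7)
        dos = rng.integers(0, 2, n).astype(float) * 2  # only 0 and 2
        y = rng.normal(size=n)
        with pytest.warns(UserWarning):
            p_add, p_dom = eq.additive_dominance_test(y, dos, np.ones((n, 1)),
                                                      runner)
        assert np.isnan(p_dom) and 0 <= p_add <= 1
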