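"""Recovery studies on synthetic data with planted ground truth.

Each function runs the real pipeline end to end on generated F2 data and
measures how well a planted feature is recovered.  The simulation panel for
these studies is an 18-autosome genome (40 markers per chromosome, 100 cM
each, mirroring the pig karyotype) with a 150-gene expression background:
small per-chromosome genomes exaggerate proximal contamination of the
mixed-model marker test, and small gene panels let a planted driver leak into
the library size, so both are kept at realistic proportions.
"""

from __future__ import annotations

import numpy as np

from . import simdata
from .coloc import conditional_coloc, find_overlaps, map_pqtl
from .classify import DISTANT, LOCAL, PLAUSIBLE_LOCAL, classify_regulator
from .gwa import (backsolve_snp_effects, call_eqtl, conditional_peak_scan,
                  detect_hotspots, gene_fdr, snp_test)
from .mixedmodel import GBLUPRunner, compute_grm, lrt_heritability, standardize_genotypes
from .preprocess import filter_markers, normalize_expression
from .simdata import GeneSpec, PhenotypeSpec, SimConfig

__all__ = [
    "StudyPanel",
    "make_panel",
    "oracle_equivalence_study",
    "h2_recovery_study",
    "classification_recovery_study",
    "hotspot_recovery_study",
    "coloc_recovery_study",
    "pqtl_power_study",
    "secondary_peak_study",
]

# Recovery-study genome: pig-like autosome count at desk-scale marker density.
N_CHROM = 18
MARKERS_PER_CHROM = 40
N_BACKGROUND_GENES = 150


class StudyPanel:
    """One simulated F2 genotype panel plus the fitted GRM machinery."""

    def __init__(self, geno_raw, geno, runner, Z, rngs):
        self.geno_raw = geno_raw
        self.geno = geno
        self.runner = runner
        self.Z = Z
        self.rngs = rngs

    @property
    def kept_map(self):
        return self.geno.kept_map

    def proxy_r(self, marker: str, other: str | np.ndarray) -> float:
        """|dosage correlation| between a raw-map marker and a kept marker."""
        raw = self.geno_raw.map
        i = raw.index[raw["marker"] == marker][0]
        a = self.geno_raw.M[:, i]
        if isinstance(other, str):
            k = self.kept_map.index[self.kept_map["marker"] == other]
            if len(k) == 0:
                return 0.0
            b = self.geno.M[:, int(k[0])]
        else:
            b = other
        if a.std() == 0 or b.std() == 0:
            return 0.0
        return float(abs(np.corrcoef(a, b)[0, 1]))


def make_panel(seed: int, n_f2: int = 400, n_chrom: int = N_CHROM,
               markers_per_chrom: int = MARKERS_PER_CHROM,
               n_genes: int = N_BACKGROUND_GENES) -> tuple[SimConfig, StudyPanel]:
    cfg = SimConfig(seed=seed, n_f2=n_f2, n_chrom=n_chrom,
                    markers_per_chrom=markers_per_chrom, n_genes=n_genes)
    root = np.random.SeedSequence(seed)
    rngs = [np.random.default_rng(s) for s in root.spawn(4)]
    founders = simdata.simulate_founder_haplotypes(cfg, rngs[0])
    geno_raw = simdata.simulate_f2_cross(founders, cfg, rngs[1])
    geno_raw.map["fixed_diff"] = founders.map["fixed_diff"].to_numpy()
    geno = filter_markers(geno_raw.M.astype(int), geno_raw.map)
    Z = standardize_genotypes(geno.M, geno.p)
    runner = GBLUPRunner(compute_grm(Z))
    runner.set_markers(Z)
    return cfg, StudyPanel(geno_raw, geno, runner, Z, rngs)


def _design(phen):
    X = np.ones((len(phen), 1))
    if "sex" in phen:
        X = np.column_stack([X, phen["sex"].to_numpy(float)])
    return X


def _gene_scan(panel, norm, X, gi, alpha=0.01):
    w = float(norm.w_std[gi])
    fit = panel.runner.fit(norm.y[gi], X, weight=w)
    ghat, var_ghat = backsolve_snp_effects(fit)
    _, p = snp_test(ghat, var_ghat)
    q = gene_fdr([p], alpha=alpha)[0]
    recs = call_eqtl(str(norm.genes["gene"].iloc[gi]), q, p, panel.kept_map,
                     gene_annot=norm.genes.iloc[gi], alpha=alpha)
    for r in recs:
        r.h2 = fit.h2
    return fit, recs, q, p


# -- individual studies --------------------------------------------------------


def oracle_equivalence_study(seed: int, n_f2: int = 100, n_chrom: int = 3,
                             markers_per_chrom: int = 100) -> float:
    """Max |delta log10 p| between backsolved tests and a direct single-marker
    GLS refit at the same variance components, over every marker."""
    from scipy import stats
    cfg, panel = make_panel(seed, n_f2=n_f2, n_chrom=n_chrom,
                            markers_per_chrom=markers_per_chrom, n_genes=10)
    rng = panel.rngs[2]
    y = simdata.simulate_gaussian_traits(panel.Z, 0.4, 1, rng)[0]
    X = np.ones((n_f2, 1))
    fit = panel.runner.fit(y, X)
    ghat, var_ghat = backsolve_snp_effects(fit)
    _, p = snp_test(ghat, var_ghat)
    G = panel.runner.G
    V = fit.sigma2_a * G + fit.sigma2_e * np.eye(n_f2)
    Vi = np.linalg.inv(V)
    worst = 0.0
    for j in range(panel.Z.shape[1]):
        C = np.column_stack([X, panel.Z[:, j]])
        A = np.linalg.inv(C.T @ Vi @ C)
        b = A @ (C.T @ (Vi @ y))
        t = b[-1] / np.sqrt(A[-1, -1])
        pj = 2.0 * stats.norm.sf(abs(t))
        worst = max(worst, abs(np.log10(pj) - np.log10(p[j])))
    return worst


def h2_recovery_study(seed: int, levels=(0.0, 0.2, 0.5, 0.8),
                      n_traits: int = 200, n_f2: int = 500,
                      n_null: int = 1000, alpha: float = 0.05):
    """Mean REML h2 estimate per planted level plus null LRT rejection rate.

    Traits are simulated on the latent Gaussian scale (y = Zu + e with exact
    realized variance split), the scale on which h2 is defined.
    """
    cfg, panel = make_panel(seed, n_f2=n_f2)
    rng = panel.rngs[2]
    X = np.ones((n_f2, 1))
    means = {}
    for h2 in levels:
        ys = simdata.simulate_gaussian_traits(panel.Z, h2, n_traits, rng)
        means[h2] = float(np.mean([panel.runner.fit(y, X).h2 for y in ys]))
    ys = simdata.simulate_gaussian_traits(panel.Z, 0.0, n_null, rng)
    rej = float(np.mean([lrt_heritability(panel.runner.fit(y, X)) <= alpha
                         for y in ys]))
    return means, rej


def classification_recovery_study(seeds, n_f2: int = 400,
                                  n_local: int = 8, n_distant: int = 8,
                                  h2: float = 0.4):
    """Plant local and cross-chromosome regulated genes; report the fraction
    classed local/plausible_local and distant respectively (pooled over seeds)."""
    local_ok = local_tot = dist_ok = dist_tot = 0
    for seed in seeds:
        cfg, panel = make_panel(seed, n_f2=n_f2)
        rng = panel.rngs[2]
        arch = simdata.default_architecture(
            panel.geno_raw.map, N_BACKGROUND_GENES, rng,
            frac_local=n_local / N_BACKGROUND_GENES,
            frac_distant=n_distant / N_BACKGROUND_GENES,
            n_hotspot_targets=0, h2_range=(h2, h2),
            chrom_length_bp=cfg.chrom_length_bp)
        cfg.architecture = arch
        counts, _ = simdata.simulate_expression(panel.geno_raw, cfg, rng)
        phen = _dummy_phen(panel, cfg)
        X = _design(phen)
        norm = normalize_expression(counts, X)
        gene_idx = {g: i for i, g in enumerate(norm.genes["gene"])}
        mp = panel.geno_raw.map.set_index("marker")
        for g in arch:
            if g.gene_class not in ("local", "distant"):
                continue
            causal_chrom = mp.loc[g.causal_marker, "chrom"]
            _, recs, _, _ = _gene_scan(panel, norm, X, gene_idx[g.gene])
            rec = next((r for r in recs if r.chrom == causal_chrom), None)
            cls = classify_regulator(rec, panel.geno.map) if rec else None
            if g.gene_class == "local":
                local_tot += 1
                local_ok += cls in (LOCAL, PLAUSIBLE_LOCAL)
            else:
                dist_tot += 1
                dist_ok += cls == DISTANT
    return local_ok / local_tot, dist_ok / dist_tot


def hotspot_recovery_study(seeds, n_f2: int = 400, n_targets: int = 12,
                           h2: float = 0.5, min_genes: int = 10,
                           proxy_r: float = 0.95) -> float:
    """Fraction of seeds in which the planted hotspot marker (or a dosage
    proxy with |r| >= proxy_r) is flagged by the hotspot rule."""
    hits = 0
    for seed in seeds:
        cfg, panel = make_panel(seed, n_f2=n_f2)
        rng = panel.rngs[2]
        arch = simdata.default_architecture(
            panel.geno_raw.map, N_BACKGROUND_GENES, rng,
            frac_local=0.0, frac_distant=0.0, n_hotspot_targets=n_targets,
            h2_range=(h2, h2), chrom_length_bp=cfg.chrom_length_bp)
        cfg.architecture = arch
        hot = next(g.causal_marker for g in arch if g.gene_class == "hotspot-target")
        counts, _ = simdata.simulate_expression(panel.geno_raw, cfg, rng)
        phen = _dummy_phen(panel, cfg)
        X = _design(phen)
        norm = normalize_expression(counts, X)
        gene_idx = {g: i for i, g in enumerate(norm.genes["gene"])}
        pairs = []
        for g in arch:
            if g.gene_class != "hotspot-target":
                continue
            _, recs, _, _ = _gene_scan(panel, norm, X, gene_idx[g.gene])
            for r in recs:
                pairs.extend((m, g.gene) for m in r.sig_markers)
        hs = detect_hotspots(pairs, min_genes=min_genes)
        if any(panel.proxy_r(hot, m) >= proxy_r for m in hs["marker"]):
            hits += 1
    return hits / len(list(seeds))


def _dummy_phen(panel, cfg):
    import pandas as pd
    rng = np.random.default_rng(cfg.seed + 97)
    n = panel.geno.M.shape[0]
    return pd.DataFrame({"animal": np.arange(n),
                         "sex": rng.integers(0, 2, size=n)})


def _coloc_arch(panel, cfg, rng, shared: bool):
    mks = simdata._pick_causal_markers(panel.geno_raw.map, rng, 2)
    mp = panel.geno_raw.map.set_index("marker")
    if mp.loc[mks[0], "chrom"] == mp.loc[mks[1], "chrom"]:
        pool = panel.geno_raw.map[panel.geno_raw.map["fixed_diff"]
                                  & (panel.geno_raw.map["chrom"] != mp.loc[mks[0], "chrom"])]
        mks[1] = pool["marker"].iloc[len(pool) // 2]
    gene_mk = mks[0]
    phen_mk = mks[0] if shared else mks[1]
    row = mp.loc[gene_mk]
    arch = simdata.default_architecture(
        panel.geno_raw.map, N_BACKGROUND_GENES, rng, frac_local=0.0,
        frac_distant=0.0, n_hotspot_targets=0,
        chrom_length_bp=cfg.chrom_length_bp)
    # single-QTL gene: the causal marker carries the entire 15% genetic signal
    arch[0] = GeneSpec("G_target", "local", gene_mk, 0.15, row["chrom"],
                       int(row["pos"]) - 10_000, int(row["pos"]) + 10_000)
    cfg.causal_var_frac = 1.0
    cfg.architecture = arch
    cfg.phenotypes = [PhenotypeSpec("P1", causal_marker=phen_mk,
                                    causal_var_frac=0.15, poly_var_frac=0.2,
                                    sex_effect=0.2)]
    return gene_mk, phen_mk


def coloc_recovery_study(seeds, n_f2: int = 400):
    """Sensitivity (shared-causal pairs flagged significant) and specificity
    (unlinked pairs not eliminated) of the conditional co-localization test."""
    sens_hits = spec_hits = spec_tot = 0
    seeds = list(seeds)
    for seed in seeds:
        for shared in (True, False):
            cfg, panel = make_panel(seed, n_f2=n_f2)
            rng = panel.rngs[2]
            _coloc_arch(panel, cfg, rng, shared)
            counts, _ = simdata.simulate_expression(panel.geno_raw, cfg, rng)
            phen, _, _ = simdata.simulate_phenotypes(panel.geno_raw, cfg, panel.rngs[3])
            X = _design(phen)
            norm = normalize_expression(counts, X)
            gi = list(norm.genes["gene"]).index("G_target")
            w = float(norm.w_std[gi])
            _, eqtls, _, _ = _gene_scan(panel, norm, X, gi)
            pqtls, _ = map_pqtl(phen, ["P1"], panel.geno, panel.runner)
            if shared:
                pairs = find_overlaps(eqtls, pqtls)
                if pairs:
                    c = conditional_coloc(norm.y[gi], X, panel.runner, w,
                                          pairs[0], panel.geno, n_tests=1,
                                          phen_value=phen["P1"].to_numpy(float))
                    sens_hits += bool(c.significant_coloc)
            else:
                if eqtls and pqtls:
                    spec_tot += 1
                    c = conditional_coloc(norm.y[gi], X, panel.runner, w,
                                          (eqtls[0], pqtls[0]), panel.geno,
                                          n_tests=1)
                    spec_hits += (not c.eliminated)
    sens = sens_hits / len(seeds)
    spec = spec_hits / spec_tot if spec_tot else float("nan")
    return sens, spec


def pqtl_power_study(seeds, n_f2: int = 400, var_frac: float = 0.10,
                     alpha: float = 0.05, proxy_r: float = 0.5) -> float:
    """Fraction of seeds in which a planted pQTL is detected within its LD
    block (peak dosage correlation >= proxy_r with the causal marker)."""
    hits = 0
    seeds = list(seeds)
    for seed in seeds:
        cfg, panel = make_panel(seed, n_f2=n_f2, n_genes=10)
        rng = panel.rngs[2]
        mk = simdata._pick_causal_markers(panel.geno_raw.map, rng, 1)[0]
        cfg.phenotypes = [PhenotypeSpec("P1", causal_marker=mk,
                                        causal_var_frac=var_frac,
                                        poly_var_frac=0.2, sex_effect=0.2)]
        phen, _, _ = simdata.simulate_phenotypes(panel.geno_raw, cfg, panel.rngs[3])
        recs, _ = map_pqtl(phen, ["P1"], panel.geno, panel.runner, alpha=alpha)
        if any(panel.proxy_r(mk, r.peak_marker) >= proxy_r for r in recs):
            hits += 1
    return hits / len(seeds)


def secondary_peak_study(seeds, n_f2: int = 400, var_frac: float = 0.15) -> float:
    """Two causal markers >= 50 cM apart on one chromosome; fraction of seeds
    in which conditioning on the primary peak reveals the second."""
    hits = 0
    seeds = list(seeds)
    for seed in seeds:
        cfg, panel = make_panel(seed, n_f2=n_f2, n_genes=10)
        rng = panel.rngs[2]
        raw = panel.geno_raw.map
        chrom = raw["chrom"].iloc[0]
        on = raw[(raw["chrom"] == chrom) & raw["fixed_diff"]]
        mk1, mk2 = on["marker"].iloc[2], on["marker"].iloc[-3]
        i1 = raw.index[raw["marker"] == mk1][0]
        i2 = raw.index[raw["marker"] == mk2][0]
        y = np.zeros(n_f2)
        y += simdata._scale_to_var(panel.geno_raw.M[:, i1], var_frac)
        y += simdata._scale_to_var(panel.geno_raw.M[:, i2], var_frac)
        y += simdata._scale_to_var(rng.normal(size=n_f2), 1 - 2 * var_frac)
        X = np.ones((n_f2, 1))
        fit = panel.runner.fit(y, X)
        ghat, var_ghat = backsolve_snp_effects(fit)
        _, p = snp_test(ghat, var_ghat)
        q = gene_fdr([p])[0]
        recs = call_eqtl("trait", q, p, panel.kept_map, alpha=0.01)
        recs = [r for r in recs if r.chrom == chrom]
        if not recs:
            continue
        rec = recs[0]
        extra = conditional_peak_scan(y, X, panel.runner, 1.0, panel.kept_map,
                                      rec, alpha=0.01)
        other = mk2 if panel.proxy_r(mk1, rec.peak_marker) >= panel.proxy_r(mk2, rec.peak_marker) else mk1
        if any(panel.proxy_r(other, r.peak_marker) >= 0.5 for r in extra):
            hits += 1
    return hits / len(seeds)
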