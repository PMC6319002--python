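"""Phenotypic QTL mapping and conditional eQTL/pQTL co-localization.

pQTL are mapped with exactly the same GBLUP-backsolve machinery as eQTL
(unit residual weight, FDR <= 0.05).  An eQTL co-localizes with a pQTL when
their closed intervals overlap on the same chromosome; significance of the
co-localization is decided by a conditional analysis that fits the pQTL peak
SNP (standardized by its own sample mean and sd) as a fixed covariate:

    y = X b + Z_SNP b_SNP + a + e

The pair is significantly co-localized when b_SNP passes a Bonferroni cutoff
0.05 / n_tests AND conditioning completely eliminates the eQTL interval (no
marker inside the original interval remains significant at FDR <= 0.01).
The variance tied to the peak SNP is sigma2_SNP = b^2 var(Z_SNP), reported as
a proportion of sigma2_SNP + sigma2_a + sigma2_e from the conditional fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .gwa import EQTLRecord, backsolve_snp_effects, call_eqtl, gene_fdr, snp_test
from .mixedmodel import GBLUPRunner, bh_fdr
from .preprocess import GenotypeData

__all__ = [
    "ColocRecord",
    "map_pqtl",
    "find_overlaps",
    "conditional_coloc",
    "snp_variance_explained",
    "residual_correlations",
    "dosage_ld",
    "additive_dominance_test",
]


@dataclass
class ColocRecord:
    gene: str
    phenotype: str
    eqtl: EQTLRecord
    pqtl: EQTLRecord
    b_snp: float
    se_snp: float
    p_snp: float
    bonferroni: float
    eliminated: bool
    significant_coloc: bool
    sigma2_snp: float
    prop_expr_var: float
    prop_phen_var: float | None = None
    ld_r: float | None = None
    untestable: bool = False


def _wald_last(fit, runner, weight: float):
    """Wald z-test for the last fixed-effect coefficient of a GBLUP fit."""
    d = fit.lam * runner.delta + 1.0
    s2_model = fit.sigma2_e * weight
    Xu = fit._Xu
    cov = s2_model * np.linalg.inv(Xu.T @ (Xu / d[:, None]))
    b = float(fit.beta[-1])
    se = float(np.sqrt(cov[-1, -1]))
    p = 2.0 * float(stats.norm.sf(abs(b) / se)) if se > 0 else 1.0
    return b, se, p


def map_pqtl(phen: pd.DataFrame, traits, geno: GenotypeData,
             runner: GBLUPRunner, covariates=("sex",),
             alpha: float = 0.05, method: str = "reml"):
    """GBLUP + backsolve GWAS for each phenotype at FDR <= ``alpha``.

    Residual weight is 1 for phenotypes (the mean-variance coefficients apply
    to expression only).  Returns (records, fits) keyed by trait.
    """
    km = geno.kept_map
    n = geno.M.shape[0]
    X = np.column_stack([np.ones(n)] + [phen[c].to_numpy(float) for c in covariates])
    records, fits = [], {}
    for trait in traits:
        y = phen[trait].to_numpy(float)
        if np.std(y) == 0:
            warnings.warn(f"phenotype {trait} is constant; skipped")
            continue
        fit = runner.fit(y, X, weight=1.0, method=method)
        ghat, var_ghat = backsolve_snp_effects(fit)
        _, p = snp_test(ghat, var_ghat)
        q, _ = bh_fdr(p, alpha=alpha)
        recs = call_eqtl(trait, q, p, km, alpha=alpha)
        for r in recs:
            r.h2 = fit.h2
        records.extend(recs)
        fits[trait] = fit
    return records, fits


def find_overlaps(eqtls: list[EQTLRecord], pqtls: list[EQTLRecord]):
    """Same-chromosome pairs whose closed intervals intersect (points allowed)."""
    pairs = []
    for e in eqtls:
        for p in pqtls:
            if e.chrom == p.chrom and e.start <= p.end and p.start <= e.end:
                pairs.append((e, p))
    return pairs


def snp_variance_explained(b_snp: float, var_z: float,
                           sigma2_a: float, sigma2_e: float) -> float:
    """Proportion of variance tied to the peak SNP:
    b^2 var(Z_SNP) / (b^2 var(Z_SNP) + sigma_a^2 + sigma_e^2)."""
    s2 = b_snp**2 * var_z
    tot = s2 + sigma2_a + sigma2_e
    return s2 / tot if tot > 0 else 0.0


def conditional_coloc(y_gene, X, runner: GBLUPRunner, weight: float,
                      pair, geno: GenotypeData, n_tests: int,
                      phen_value=None, alpha_eqtl: float = 0.01,
                      genomewide: bool = False, method: str = "reml") -> ColocRecord:
    """Conditional co-localization test for one (eQTL, pQTL) pair.

    ``pair`` is (EQTLRecord, PQTLRecord); ``n_tests`` is the number of
    conditional tests in the batch (Bonferroni denominator).  When
    ``phen_value`` is given, the proportion of phenotypic variance explained by
    the same peak SNP is computed from the analogous conditional fit.
    """
    eqtl, pqtl = pair
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    km = geno.kept_map
    j = km.index[km["marker"] == pqtl.peak_marker]
    if len(j) == 0:
        raise ValueError(f"pQTL peak {pqtl.peak_marker} not in the kept map")
    j = int(j[0])
    dos = geno.M[:, j]
    sd = dos.std()
    if sd == 0:
        return ColocRecord(eqtl.response, pqtl.response, eqtl, pqtl,
                           np.nan, np.nan, 1.0, 0.05 / n_tests, False, False,
                           0.0, 0.0, untestable=True)
    z_snp = (dos - dos.mean()) / sd
    var_z = float(np.var(z_snp))           # 1 by construction; kept explicit

    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xc = np.column_stack([X, z_snp])
    fit = runner.fit(np.asarray(y_gene, float), Xc, weight=weight, method=method)
    b, se, p_snp = _wald_last(fit, runner, weight)

    ghat, var_ghat = backsolve_snp_effects(fit)
    _, p = snp_test(ghat, var_ghat)
    q = gene_fdr([p], alpha=alpha_eqtl)[0]
    if genomewide:
        still = bool(np.any(q <= alpha_eqtl))
    else:
        inside = (km["chrom"] == eqtl.chrom) & (km["pos"] >= eqtl.start) & (km["pos"] <= eqtl.end)
        still = bool(np.any(q[inside.to_numpy()] <= alpha_eqtl))
    eliminated = not still

    thr = 0.05 / n_tests
    significant = (p_snp <= thr) and eliminated
    s2_snp = b**2 * var_z
    prop_expr = snp_variance_explained(b, var_z, fit.sigma2_a, fit.sigma2_e)

    prop_phen = None
    if phen_value is not None:
        fit_p = runner.fit(np.asarray(phen_value, float), Xc, weight=1.0, method=method)
        bp, _, _ = _wald_last(fit_p, runner, 1.0)
        prop_phen = snp_variance_explained(bp, var_z, fit_p.sigma2_a, fit_p.sigma2_e)

    ld = None
    ek = km.index[km["marker"] == eqtl.peak_marker]
    if len(ek):
        ld = dosage_ld(geno.M[:, int(ek[0])], dos)

    return ColocRecord(eqtl.response, pqtl.response, eqtl, pqtl,
                       b, se, p_snp, thr, eliminated, significant,
                       float(s2_snp), float(prop_expr), prop_phen, ld)


def residual_correlations(residuals: dict[str, np.ndarray], alpha: float = 0.05):
    """Pairwise Pearson correlations of mixed-model residuals with t-test
    p-values and BH q-values at FDR ``alpha``."""
    names = list(residuals)
    rows = []
    for i in range(len(names)):
        for k in range(i + 1, len(names)):
            a = np.asarray(residuals[names[i]], float)
            b = np.asarray(residuals[names[k]], float)
            n = a.size
            if n < 3:
                rows.append((names[i], names[k], np.nan, np.nan, np.nan))
                continue
            r = float(np.corrcoef(a, b)[0, 1])
            t = r * np.sqrt((n - 2) / max(1e-300, 1.0 - r**2))
            p = 2.0 * float(stats.t.sf(abs(t), df=n - 2))
            rows.append((names[i], names[k], r, t, p))
    df = pd.DataFrame(rows, columns=["a", "b", "r", "t", "p"])
    ok = df["p"].notna()
    q = np.full(len(df), np.nan)
    if ok.any():
        q[ok.to_numpy()], _ = bh_fdr(df.loc[ok, "p"].to_numpy(), alpha=alpha)
    df["q"] = q
    df["significant"] = df["q"] <= alpha
    return df


def dosage_ld(marker_a, marker_b) -> float:
    """Signed Pearson correlation of two dosage vectors."""
    a = np.asarray(marker_a, float)
    b = np.asarray(marker_b, float)
    if a.std() == 0 or b.std() == 0:
        raise ValueError("LD undefined for a constant marker")
    return float(np.corrcoef(a, b)[0, 1])


def additive_dominance_test(y, dosage, X, runner: GBLUPRunner,
                            weight: float = 1.0, method: str = "reml"):
    """Joint additive (-1,0,1) and dominance (0,1,0) fixed-effect test of one
    marker in the GBLUP model; returns (p_additive, p_dominance).

    With a missing genotype class the dominance term is dropped (p = NaN).
    """
    dos = np.asarray(dosage, float)
    add = dos - 1.0
    dom = (dos == 1.0).astype(float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    have_all = len(np.unique(dos)) == 3
    if not have_all:
        warnings.warn("missing genotype class; dominance effect dropped")
        Xc = np.column_stack([X, add])
        fit = runner.fit(y, Xc, weight=weight, method=method)
        _, _, p_add = _wald_last(fit, runner, weight)
        return p_add, float("nan")
    Xc = np.column_stack([X, add, dom])
    fit = runner.fit(y, Xc, weight=weight, method=method)
    d = fit.lam * runner.delta + 1.0
    cov = fit.sigma2_e * weight * np.linalg.inv(fit._Xu.T @ (fit._Xu / d[:, None]))
    b = fit.beta
    p_add = 2.0 * float(stats.norm.sf(abs(b[-2]) / np.sqrt(cov[-2, -2])))
    p_dom = 2.0 * float(stats.norm.sf(abs(b[-1]) / np.sqrt(cov[-1, -1])))
    return p_add, p_dom
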