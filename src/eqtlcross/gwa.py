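"""Genome-wide association by SNP-effect backsolve from GBLUP breeding values.

Marker effects are recovered as a linear transformation of the fitted breeding
values, g_hat = Z' G^- a_hat, with Var(g_hat) from the prediction-error
variance of a_hat at the REML estimates.  Writing P for the REML projection
matrix P = V^-1 - V^-1 X (X'V^-1X)^-1 X'V^-1 this reduces to

    g_hat = sigma_a^2 Z' P y,        Var(g_hat)_j = sigma_a^4 (Z' P Z)_jj,

so the standardized statistic T_j = g_hat_j / sqrt(Var(g_hat)_j) equals the
GLS test of marker j fitted as a single fixed effect at the same variance
components (the EMMA-style single-marker mixed-model test).  p-values are
two-sided Gaussian, p = 2[1 - Phi(|T|)].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .mixedmodel import GBLUPFit, bh_fdr

__all__ = [
    "EQTLRecord",
    "AssociationTable",
    "backsolve_snp_effects",
    "snp_test",
    "gene_fdr",
    "call_eqtl",
    "conditional_peak_scan",
    "detect_hotspots",
    "enrichment_test",
]


@dataclass
class EQTLRecord:
    """One called QTL: a gene (or phenotype) with significant markers grouped
    on one chromosome.  The interval runs from the first to the last
    significant marker; a single significant marker gives a point interval."""

    response: str
    chrom: str
    start: int
    end: int
    peak_marker: str
    peak_pos: int
    n_snps: int
    peak_q: float
    gene_chrom: str | None = None
    gene_start: int | None = None
    gene_end: int | None = None
    h2: float | None = None
    reg_class: str | None = None
    distance_mb: float | None = None
    parent: str | None = None          # peak id of the parent when found conditionally
    sig_markers: list = field(default_factory=list)


@dataclass
class AssociationTable:
    response: str
    table: pd.DataFrame                # marker, chrom, pos, ghat, var_ghat, T, p [, q]
    conditioning: str | None = None


def backsolve_snp_effects(fit: GBLUPFit, Z: np.ndarray | None = None):
    """Backsolve per-marker effects and variances from a GBLUP fit.

    Uses the eigendecomposition cached on the fit's runner; ``Z`` defaults to
    the marker matrix registered on the runner with ``set_markers``.
    """
    runner = fit._runner
    if runner is None:
        raise ValueError("fit does not carry its runner; refit with fit_gblup")
    if Z is None:
        Zu = runner._Zu
        if Zu is None:
            raise ValueError("no marker matrix registered; call runner.set_markers(Z)")
    else:
        Z = np.asarray(Z, dtype=float)
        if Z.shape[0] != runner.n:
            raise ValueError("Z animal dimension does not match the fitted G")
        Zu = runner._Zu if Z is runner._Z else runner.U.T @ Z

    lam = fit.lam
    s2e = fit.sigma2_e * (fit.weight if np.ndim(fit.weight) == 0 else 1.0)
    sigma2_a = fit.sigma2_a
    d = lam * runner.delta + 1.0
    w = 1.0 / (s2e * d)                       # diag of V^-1 in the eigenbasis
    yu, Xu, b = fit._yu, fit._Xu, fit.beta

    if sigma2_a == 0.0:
        m = Zu.shape[1]
        return np.zeros(m), np.zeros(m)

    py = w * (yu - Xu @ b)                    # P y in the eigenbasis
    ghat = sigma2_a * (Zu.T @ py)

    t1 = np.einsum("ij,ij->j", Zu * w[:, None], Zu)
    A = Xu.T @ (Zu * w[:, None])              # p x m
    B = np.linalg.inv(Xu.T @ (Xu * w[:, None]))
    t2 = np.einsum("ij,ij->j", A, B @ A)
    var_ghat = sigma2_a**2 * np.clip(t1 - t2, 0.0, None)
    return ghat, var_ghat


def snp_test(ghat: np.ndarray, var_ghat: np.ndarray):
    """Standardized SNP-effect statistic and two-sided Gaussian p-value.

    Markers with zero effect variance (e.g. monomorphic after conditioning)
    get T = 0, p = 1.
    """
    ghat = np.asarray(ghat, dtype=float)
    var_ghat = np.asarray(var_ghat, dtype=float)
    if np.any(var_ghat < 0):
        raise ValueError("negative effect variance")
    T = np.zeros_like(ghat)
    ok = var_ghat > 0
    T[ok] = ghat[ok] / np.sqrt(var_ghat[ok])
    p = 2.0 * stats.norm.sf(np.abs(T))
    p[~ok] = 1.0
    return T, p


def gene_fdr(p_tables, alpha: float = 0.01):
    """Per-gene FDR over the merged p-values of all the gene's transcripts.

    ``p_tables`` is a sequence of per-marker p-value vectors (one per
    transcript).  BH is applied to the concatenation and q-values are mapped
    back to (transcript, marker).
    """
    p_tables = [np.asarray(p, dtype=float) for p in p_tables]
    if not p_tables:
        raise ValueError("need at least one transcript p-table")
    merged = np.concatenate(p_tables)
    q, _ = bh_fdr(merged, alpha=alpha)
    out, off = [], 0
    for p in p_tables:
        out.append(q[off:off + p.size])
        off += p.size
    return out


def call_eqtl(response: str, q: np.ndarray, p: np.ndarray,
              kept_map: pd.DataFrame, gene_annot=None,
              alpha: float = 0.01) -> list[EQTLRecord]:
    """Group markers significant at FDR <= alpha by chromosome into QTL records.

    The interval spans the first to last significant marker on the chromosome
    (no gap splitting); the peak is the marker with minimal q, ties broken by
    minimal p then leftmost position.
    """
    q = np.asarray(q, dtype=float)
    p = np.asarray(p, dtype=float)
    sig = np.flatnonzero(q <= alpha)
    records = []
    if sig.size == 0:
        return records
    km = kept_map.reset_index(drop=True)
    for chrom, grp in km.loc[sig].groupby("chrom", sort=False):
        idx = grp.index.to_numpy()
        pos = grp["pos"].to_numpy()
        order = np.argsort(pos, kind="stable")
        idx, pos = idx[order], pos[order]
        peak_local = min(range(len(idx)),
                         key=lambda t: (q[idx[t]], p[idx[t]], pos[t]))
        pk = idx[peak_local]
        rec = EQTLRecord(
            response=response, chrom=chrom,
            start=int(pos.min()), end=int(pos.max()),
            peak_marker=str(km.loc[pk, "marker"]), peak_pos=int(km.loc[pk, "pos"]),
            n_snps=int(len(idx)), peak_q=float(q[pk]),
            sig_markers=[str(m) for m in km.loc[idx, "marker"]],
        )
        if gene_annot is not None:
            rec.gene_chrom = gene_annot["chrom"]
            rec.gene_start = int(gene_annot["start"])
            rec.gene_end = int(gene_annot["end"])
        records.append(rec)
    return records


def conditional_peak_scan(y, X, runner, weight, kept_map: pd.DataFrame,
                          eqtl: EQTLRecord, gene_annot=None,
                          alpha: float = 0.01, method: str = "reml") -> list[EQTLRecord]:
    """Refit with the peak SNP as a fixed covariate and re-test the eQTL's
    chromosome for additional peaks.

    Any marker still significant (BH over the chromosome's markers at
    ``alpha``) defines a new record linked to the parent peak.
    """
    km = kept_map.reset_index(drop=True)
    j = km.index[km["marker"] == eqtl.peak_marker]
    if len(j) == 0:
        raise ValueError(f"peak marker {eqtl.peak_marker} not in the kept map")
    j = int(j[0])
    Z = runner._Z
    if Z is None:
        raise ValueError("runner has no registered marker matrix")
    x_new = Z[:, j]
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xc = np.column_stack([X, x_new])
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        import warnings
        warnings.warn("conditioning SNP collinear with the design; scan skipped")
        return []
    fit = runner.fit(y, Xc, weight=weight, method=method)
    ghat, var_ghat = backsolve_snp_effects(fit)
    _, p = snp_test(ghat, var_ghat)
    on_chrom = km.index[km["chrom"] == eqtl.chrom].to_numpy()
    q_sub, _ = bh_fdr(p[on_chrom], alpha=alpha)
    q_full = np.full(len(km), 1.0)
    p_full = np.ones(len(km))
    q_full[on_chrom] = q_sub
    p_full[on_chrom] = p[on_chrom]
    # the conditioning marker itself cannot define the new peak
    q_full[j] = 1.0
    recs = call_eqtl(eqtl.response, q_full, p_full, km, gene_annot, alpha=alpha)
    for r in recs:
        r.parent = eqtl.peak_marker
    return recs


def detect_hotspots(sig_pairs, min_genes: int = 10) -> pd.DataFrame:
    """Markers significantly associated with strictly more than ``min_genes``
    distinct genes.

    ``sig_pairs`` is an iterable of (marker, gene) significant associations.
    Returns a frame with columns marker, n_genes, genes.
    """
    by_marker: dict[str, set] = {}
    for marker, gene in sig_pairs:
        by_marker.setdefault(marker, set()).add(gene)
    rows = [(m, len(gs), sorted(gs)) for m, gs in by_marker.items()
            if len(gs) > min_genes]
    rows.sort(key=lambda r: -r[1])
    return pd.DataFrame(rows, columns=["marker", "n_genes", "genes"])


def enrichment_test(table) -> float:
    """Fisher's exact two-sided p for a 2x2 contingency table."""
    t = np.asarray(table)
    if t.shape != (2, 2) or np.any(t < 0):
        raise ValueError("need a non-negative 2x2 table")
    if np.any(t.sum(axis=0) == 0) or np.any(t.sum(axis=1) == 0):
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])
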