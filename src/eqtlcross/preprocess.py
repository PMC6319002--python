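"""Genotype filtering and RNA-seq count normalization.

Markers are filtered for monomorphism, minor allele frequency and adjacent-
marker LD (dosage correlation), mirroring the usual pre-GWAS cleaning of a
medium-density SNP panel in an F2 cross.  Counts are TMM-normalized, converted
to log2 counts-per-million, and a LOWESS mean-variance trend supplies one
standardized variance coefficient per gene that models heteroskedastic
residual variance in the downstream mixed model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MarkerStatus",
    "GenotypeData",
    "CountMatrix",
    "NormalizedExpression",
    "filter_markers",
    "filter_low_count_genes",
    "tmm_normalize",
    "logcpm",
    "compute_weights",
    "standardize_weights",
]


class MarkerStatus:
    KEPT = "kept"
    PRUNED_LD = "pruned_ld"
    REMOVED_MAF = "removed_maf"
    REMOVED_MONO = "removed_monomorphic"


@dataclass
class GenotypeData:
    """Dosage matrix for kept markers plus the full marker map with statuses.

    ``map`` retains pruned/removed markers (with positions); the regulator
    classification needs them to decide plausible-local calls.
    """

    M: np.ndarray                 # animals x kept markers, dosages {0,1,2}
    p: np.ndarray                 # reference-allele frequency per kept marker
    map: pd.DataFrame             # columns: marker, chrom, pos, status (all markers)
    animal_ids: list = field(default_factory=list)
    line_origin: np.ndarray | None = None   # diagnostics from the simulator

    @property
    def kept_map(self) -> pd.DataFrame:
        return self.map[self.map["status"] == MarkerStatus.KEPT].reset_index(drop=True)

    @property
    def kept_markers(self) -> list:
        return list(self.kept_map["marker"])


@dataclass
class CountMatrix:
    counts: np.ndarray            # genes x samples, non-negative integers
    genes: pd.DataFrame           # columns: gene, chrom, start, end (1-based closed)
    samples: list

    def __post_init__(self):
        if self.counts.shape[0] != len(self.genes):
            raise ValueError("one annotation row per gene required")
        if np.any(np.asarray(self.genes["start"]) > np.asarray(self.genes["end"])):
            raise ValueError("gene start must be <= end")


@dataclass
class NormalizedExpression:
    y: np.ndarray                 # genes x samples log2-cpm
    tmm_factors: np.ndarray
    w_hat: np.ndarray             # mean-variance trend value per gene (a variance)
    w_std: np.ndarray             # standardized variance coefficients, mean 1
    genes: pd.DataFrame
    samples: list
    n: int


def filter_markers(M_raw: np.ndarray, marker_map: pd.DataFrame,
                   maf_min: float = 0.01, ld_r_max: float = 0.95) -> GenotypeData:
    """Flag monomorphic / low-MAF markers and LD-prune adjacent markers.

    Scanning each chromosome in map order, when two adjacent surviving markers
    have dosage correlation > ``ld_r_max`` the downstream marker is flagged
    ``pruned_ld``.  The returned map carries every marker with its status so
    pruned positions remain available downstream.
    """
    M_raw = np.asarray(M_raw)
    mp = marker_map.reset_index(drop=True).copy()
    if M_raw.shape[1] != len(mp):
        raise ValueError("dosage columns must match the marker map")
    if not np.isin(M_raw, (0, 1, 2)).all():
        raise ValueError("dosages must be in {0,1,2} (no missing values)")

    freq = M_raw.mean(axis=0) / 2.0
    maf = np.minimum(freq, 1.0 - freq)
    status = np.full(len(mp), MarkerStatus.KEPT, dtype=object)
    status[(freq == 0.0) | (freq == 1.0)] = MarkerStatus.REMOVED_MONO
    low = (maf < maf_min) & (status == MarkerStatus.KEPT)
    status[low] = MarkerStatus.REMOVED_MAF

    for _, idx in mp.groupby("chrom", sort=False).groups.items():
        idx = [i for i in idx if status[i] == MarkerStatus.KEPT]
        if not idx:
            continue
        last = idx[0]
        for i in idx[1:]:
            r = np.corrcoef(M_raw[:, last], M_raw[:, i])[0, 1]
            if abs(r) > ld_r_max:
                status[i] = MarkerStatus.PRUNED_LD
            else:
                last = i

    mp["status"] = status
    kept = status == MarkerStatus.KEPT
    if not kept.any():
        raise ValueError("all markers removed by filtering (empty panel)")
    M = M_raw[:, kept].astype(float)
    p = M.mean(axis=0) / 2.0
    return GenotypeData(M=M, p=p, map=mp)


def filter_low_count_genes(cm: CountMatrix, min_total: int | None = None) -> CountMatrix:
    """Drop genes whose total count across samples is below ``min_total``
    (default: the number of samples)."""
    if min_total is None:
        min_total = len(cm.samples)
    if min_total < 0:
        raise ValueError("min_total must be >= 0")
    keep = cm.counts.sum(axis=1) >= min_total
    return CountMatrix(counts=cm.counts[keep],
                       genes=cm.genes.loc[keep].reset_index(drop=True),
                       samples=list(cm.samples))


def _tmm_pair(obs, ref, lib_obs, lib_ref, trim_m=0.30, trim_a=0.05):
    """Trimmed weighted mean of M-values of one sample against the reference."""
    pos = (obs > 0) & (ref > 0)
    if not pos.any():
        return 1.0
    o = obs[pos] / lib_obs
    r = ref[pos] / lib_ref
    M = np.log2(o / r)
    A = 0.5 * np.log2(o * r)
    w = (lib_obs - obs[pos]) / (lib_obs * obs[pos]) + (lib_ref - ref[pos]) / (lib_ref * ref[pos])
    n = M.size
    from scipy.stats import rankdata
    rM, rA = rankdata(M), rankdata(A)
    loM = np.floor(n * trim_m) + 1
    hiM = n + 1 - loM
    loA = np.floor(n * trim_a) + 1
    hiA = n + 1 - loA
    keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
    if not keep.any() or w[keep].sum() == 0:
        return 1.0
    f = np.sum(w[keep] * M[keep]) / np.sum(w[keep])
    return float(2.0 ** f)


def tmm_normalize(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Trimmed-mean-of-M-values normalization factors, geometric mean 1.

    The reference sample is the library whose upper quartile of nonzero cpm is
    closest to the mean upper quartile across samples.  M-values are trimmed by
    ``trim_m`` on each side, A-values by ``trim_a``, and the surviving M-values
    are averaged with inverse asymptotic-variance weights.
    """
    counts = np.asarray(cm.counts, dtype=float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0)
    zero = np.where(lib == 0)[0]
    if zero.size:
        raise ValueError(f"sample {cm.samples[zero[0]]!r} has all-zero counts")
    uq = np.array([np.quantile(counts[counts[:, j] > 0, j] / lib[j], 0.75)
                   for j in range(counts.shape[1])])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    factors = np.array([
        1.0 if j == ref else
        _tmm_pair(counts[:, j], counts[:, ref], lib[j], lib[ref], trim_m, trim_a)
        for j in range(counts.shape[1])
    ])
    return factors / np.exp(np.mean(np.log(factors)))


def logcpm(cm: CountMatrix, tmm_factors: np.ndarray) -> np.ndarray:
    """log2 counts per million with the standard +0.5 count / +1 library offsets:

        y[g, i] = log2( (count[g,i] + 0.5) / (libsize_i * factor_i + 1) * 1e6 )
    """
    f = np.asarray(tmm_factors, dtype=float)
    if np.any(f <= 0):
        raise ValueError("TMM factors must be positive")
    counts = np.asarray(cm.counts, dtype=float)
    eff = counts.sum(axis=0) * f + 1.0
    return np.log2((counts + 0.5) / eff[None, :] * 1e6)


def standardize_weights(w_hat: np.ndarray) -> np.ndarray:
    """Standardize per-gene variance coefficients so precision-like quantities
    1/sqrt(w_hat) have unit mean across genes:

        w_std_g = (1/sqrt(w_hat_g)) / mean_g(1/sqrt(w_hat_g))
    """
    w_hat = np.asarray(w_hat, dtype=float)
    if np.any(w_hat <= 0):
        raise ValueError("trend values must be positive")
    inv = 1.0 / np.sqrt(w_hat)
    return inv / inv.mean()


def compute_weights(y: np.ndarray, X: np.ndarray,
                    frac: float = 0.5, it: int = 3):
    """Per-gene LOWESS mean-variance trend and standardized variance coefficients.

    For each gene the log-cpm vector is regressed (OLS) on the fixed-effect
    design; the residual standard deviation s_g against the mean log-cpm m_g is
    smoothed with LOWESS and the squared trend value at m_g is the per-gene
    variance w_hat_g.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("log-cpm matrix contains non-finite values")
    if y.shape[0] < 10:
        raise ValueError("need at least 10 genes for a stable trend fit")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.shape[1]
    if X.shape[0] != n:
        raise ValueError("design rows must match samples")
    dof = n - X.shape[1]
    # One shared hat matrix: residual sd per gene via a single projection.
    Q, _ = np.linalg.qr(X)
    resid = y - (y @ Q) @ Q.T
    s = np.sqrt(np.sum(resid**2, axis=1) / dof)
    m = y.mean(axis=1)
    if np.allclose(s, s[0]):
        trend = np.full_like(s, s[0] if s[0] > 0 else 1.0)
    else:
        trend = sm.nonparametric.lowess(s, m, frac=frac, it=it,
                                        return_sorted=False)
    trend = np.clip(trend, 1e-6, None)
    w_hat = trend**2
    return w_hat, standardize_weights(w_hat)


def normalize_expression(cm: CountMatrix, X: np.ndarray,
                         min_total: int | None = None) -> NormalizedExpression:
    """Full normalization pipeline: low-count filter -> TMM -> log-cpm -> weights."""
    cm = filter_low_count_genes(cm, min_total=min_total)
    factors = tmm_normalize(cm)
    y = logcpm(cm, factors)
    w_hat, w_std = compute_weights(y, X)
    return NormalizedExpression(y=y, tmm_factors=factors, w_hat=w_hat,
                                w_std=w_std, genes=cm.genes,
                                samples=list(cm.samples), n=len(cm.samples))
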