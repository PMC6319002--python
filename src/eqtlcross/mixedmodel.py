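"""Genomic relationship matrix, weighted single-kernel GBLUP and heritability tests.

The model fitted throughout the package is

    y = X b + a + e,      a ~ N(0, sigma_a^2 G),    e ~ N(0, sigma_e^2 W),

with G = Z Z' the genomic relationship matrix built from standardized SNP
dosages and W a diagonal weight matrix (a single scalar per expression trait,
1 for organismal phenotypes).  Variance components are estimated by REML after
a single eigendecomposition of G, so the per-trait cost is a one-dimensional
likelihood search over the variance ratio lambda = sigma_a^2 / sigma_e^2.

Narrow-sense heritability is h^2 = sigma_a^2 / (sigma_a^2 + sigma_e^2) and its
significance is assessed with a likelihood-ratio test against the sigma_a^2=0
null, with the chi-square(1) tail probability halved to account for the
boundary null (the LR is asymptotically a 50:50 mixture of chi^2_0 and chi^2_1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GBLUPFit",
    "GBLUPRunner",
    "standardize_genotypes",
    "compute_grm",
    "fit_gblup",
    "estimate_h2",
    "lrt_heritability",
    "bh_fdr",
    "wilcoxon_rank_sum",
]

_LAMBDA_BOUNDS = (1e-6, 1e6)


def standardize_genotypes(M: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Center dosages at twice the reference-allele frequency and apply the
    single global scaling sqrt(sum_j 2 p_j (1-p_j)).

    Parameters
    ----------
    M : (n_animals, n_markers) dosage matrix with values in {0, 1, 2}.
    p : reference-allele frequency per marker, strictly inside (0, 1).
    """
    M = np.asarray(M, dtype=float)
    p = np.asarray(p, dtype=float)
    if M.ndim != 2 or p.shape != (M.shape[1],):
        raise ValueError("M must be (animals x markers) with one frequency per marker")
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("allele frequency at 0 or 1 for a kept marker; filter first")
    denom = np.sqrt(np.sum(2.0 * p * (1.0 - p)))
    return (M - 2.0 * p) / denom


def compute_grm(Z: np.ndarray) -> np.ndarray:
    """Genomic relationship matrix G = Z Z', symmetrized to float tolerance."""
    Z = np.asarray(Z, dtype=float)
    if not np.all(np.isfinite(Z)):
        raise ValueError("Z contains non-finite values")
    G = Z @ Z.T
    return 0.5 * (G + G.T)


@dataclass
class GBLUPFit:
    """Result of one REML (or ML) GBLUP fit."""

    sigma2_a: float
    sigma2_e: float
    h2: float
    beta: np.ndarray
    blup: np.ndarray
    residuals: np.ndarray
    logL_full: float
    logL_null: float
    weight: float | np.ndarray
    method: str
    lam: float
    boundary: str | None = None
    # Internals needed by the SNP-effect backsolve (eigenbasis quantities).
    _runner: "GBLUPRunner | None" = field(default=None, repr=False)
    _yu: np.ndarray | None = field(default=None, repr=False)
    _Xu: np.ndarray | None = field(default=None, repr=False)
    _scale: np.ndarray | None = field(default=None, repr=False)  # row whitening, if any


class GBLUPRunner:
    """Holds the eigendecomposition of one G so many traits can be fitted cheaply.

    The fixed-effect design is supplied per fit; scalar per-trait weights are
    absorbed analytically (they rescale sigma_e^2 only), so a single
    decomposition serves every expression trait analyzed against the same G.
    """

    def __init__(self, G: np.ndarray, psd_tol: float = 1e-8):
        G = np.asarray(G, dtype=float)
        n = G.shape[0]
        if G.shape != (n, n):
            raise ValueError("G must be square")
        asym = np.max(np.abs(G - G.T))
        if asym > 1e-8 * max(1.0, np.max(np.abs(G))):
            raise ValueError("G is not symmetric")
        delta, U = np.linalg.eigh(0.5 * (G + G.T))
        floor = -psd_tol * max(delta[-1], 1.0)
        if delta[0] < floor:
            raise ValueError(f"G is not positive semidefinite (min eigenvalue {delta[0]:.3g})")
        self.G = G
        self.n = n
        self.delta = np.clip(delta, 0.0, None)
        self.U = U
        self._Z: np.ndarray | None = None
        self._Zu: np.ndarray | None = None

    def set_markers(self, Z: np.ndarray) -> None:
        """Cache the eigenbasis projection of the standardized marker matrix."""
        Z = np.asarray(Z, dtype=float)
        if Z.shape[0] != self.n:
            raise ValueError("Z animal dimension does not match G")
        self._Z = Z
        self._Zu = self.U.T @ Z

    # -- restricted / full likelihood machinery -------------------------------

    @staticmethod
    def _profile_loglik(lam, yu, Xu, delta, method):
        n, p = Xu.shape
        d = lam * delta + 1.0
        Xd = Xu / d[:, None]
        XtDX = Xd.T @ Xu
        b = np.linalg.solve(XtDX, Xd.T @ yu)
        r = yu - Xu @ b
        rss = float(np.sum(r * r / d))
        if method == "reml":
            df = n - p
            s2 = rss / df
            sign, logdet = np.linalg.slogdet(XtDX)
            ll = -0.5 * (df * np.log(2.0 * np.pi * s2) + np.sum(np.log(d)) + logdet + df)
        else:
            s2 = rss / n
            ll = -0.5 * (n * np.log(2.0 * np.pi * s2) + np.sum(np.log(d)) + n)
        return ll, b, s2

    def fit(self, y, X, weight: float = 1.0, method: str = "reml") -> GBLUPFit:
        """REML/ML fit of y = Xb + a + e with Var(y) = sigma_a^2 G + sigma_e^2 * weight * I.

        ``weight`` is the scalar standardized variance coefficient of this
        trait (w_std[g]); it scales the residual variance only, so the reported
        sigma_e^2 is the coefficient of weight*I.
        """
        if method not in ("reml", "ml"):
            raise ValueError("method must be 'reml' or 'ml'")
        y = np.asarray(y, dtype=float).ravel()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] != self.n or y.shape[0] != self.n:
            raise ValueError("dimension mismatch between y, X and G")
        if not np.all(np.isfinite(y)):
            raise ValueError("response contains non-finite values")
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError("fixed-effect design is rank deficient")
        w = float(weight)
        if w <= 0:
            raise ValueError("weight must be positive")

        yu = self.U.T @ y
        Xu = self.U.T @ X
        delta = self.delta

        def neg(loglam):
            return -self._profile_loglik(np.exp(loglam), yu, Xu, delta, method)[0]

        lo, hi = np.log(_LAMBDA_BOUNDS[0]), np.log(_LAMBDA_BOUNDS[1])
        grid = np.linspace(lo, hi, 25)
        vals = np.array([neg(t) for t in grid])
        i = int(np.argmin(vals))
        a, b_ = grid[max(i - 1, 0)], grid[min(i + 1, len(grid) - 1)]
        res = minimize_scalar(neg, bounds=(a, b_), method="bounded",
                              options={"xatol": 1e-10})
        lam = float(np.exp(res.x))
        ll_opt = -float(res.fun)

        ll_null, b_null, s2_null = self._profile_loglik(0.0, yu, Xu, delta, method)

        boundary = None
        if ll_null >= ll_opt:
            lam, ll_full = 0.0, ll_null
            b, s2 = b_null, s2_null
            boundary = "lambda=0"
        else:
            ll_full, b, s2 = self._profile_loglik(lam, yu, Xu, delta, method)
            if lam <= _LAMBDA_BOUNDS[0] * 1.01:
                boundary = "lambda=lower"
            elif lam >= _LAMBDA_BOUNDS[1] * 0.99:
                boundary = "lambda=upper"

        sigma2_e_model = s2          # coefficient of I in Var(y) = sa2 G + se2' I
        sigma2_a = lam * s2
        sigma2_e = sigma2_e_model / w
        tot = sigma2_a + sigma2_e
        h2 = sigma2_a / tot if tot > 0 else 0.0

        # BLUP of a and GLS fixed effects at the optimum.
        d = lam * delta + 1.0
        r_eig = yu - Xu @ b
        blup = self.U @ ((lam * delta / d) * r_eig)
        resid = y - X @ b - blup

        return GBLUPFit(
            sigma2_a=float(sigma2_a), sigma2_e=float(sigma2_e), h2=float(h2),
            beta=b, blup=blup, residuals=resid,
            logL_full=float(ll_full), logL_null=float(ll_null),
            weight=w, method=method, lam=lam, boundary=boundary,
            _runner=self, _yu=yu, _Xu=Xu, _scale=None,
        )


def fit_gblup(y, X, G, weight=1.0, method: str = "reml",
              runner: GBLUPRunner | None = None) -> GBLUPFit:
    """Fit the weighted GBLUP model.

    ``weight`` may be a scalar (per-trait variance coefficient, the usual case)
    or a per-animal vector, in which case the data are pre-whitened by
    W^(-1/2) and a trait-specific eigendecomposition is performed.
    """
    w = np.asarray(weight, dtype=float)
    if w.ndim == 0:
        if runner is None:
            runner = GBLUPRunner(G)
        return runner.fit(y, X, weight=float(w), method=method)
    # Vector weight: whiten rows.
    y = np.asarray(y, dtype=float).ravel()
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    s = 1.0 / np.sqrt(w)
    Gw = (s[:, None] * np.asarray(G, dtype=float)) * s[None, :]
    rw = GBLUPRunner(Gw)
    fit = rw.fit(s * y, s[:, None] * X, weight=1.0, method=method)
    # Map whitened BLUP back to the original scale: a = a_white / s.
    fit.blup = fit.blup / s
    fit.residuals = y - X @ fit.beta - fit.blup
    fit.weight = w
    fit._scale = s
    return fit


def estimate_h2(fit: GBLUPFit) -> float:
    """Narrow-sense heritability sigma_a^2 / (sigma_a^2 + sigma_e^2)."""
    tot = fit.sigma2_a + fit.sigma2_e
    if tot <= 0:
        warnings.warn("both variance components are zero; h2 defined as 0")
        return 0.0
    return fit.sigma2_a / tot


def lrt_heritability(fit: GBLUPFit) -> float:
    """Likelihood-ratio p-value for H0: sigma_a^2 = 0.

    LR = 2(logL_full - logL_null) clipped at zero; the chi^2_1 upper-tail
    probability is halved for the boundary null, so LR = 0 gives p = 0.5.
    """
    lr = max(0.0, 2.0 * (fit.logL_full - fit.logL_null))
    return 0.5 * float(stats.chi2.sf(lr, df=1))


def bh_fdr(pvalues, alpha: float = 0.01):
    """Benjamini-Hochberg step-up q-values and significance flags at ``alpha``."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p.ravel(), method="fdr_bh")
    q = q.reshape(p.shape)
    return q, q <= alpha


def wilcoxon_rank_sum(group_a, group_b) -> float:
    """Two-sided Wilcoxon rank-sum p-value.

    Exact enumeration for small untied samples (both groups <= 20); otherwise
    the normal approximation with tie correction. Fully tied data give p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    small = max(a.size, b.size) <= 20
    method = "exact" if (small and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.pvalue)
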