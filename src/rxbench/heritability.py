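"""SNP heritability by single-component REML on a genetic relationship matrix.

The model is y = Xb + g + e with g ~ N(0, sigma2_g * A) for a GRM A built
from HWE-standardized dosages and e ~ N(0, sigma2_e * I). The restricted
likelihood is profiled over h2_obs = sigma2_g / (sigma2_g + sigma2_e) in
[0, 1] after one eigendecomposition of A, which makes the fit a 1-D
optimization; the variance-component significance test is a likelihood
ratio against sigma2_g = 0 referred to the boundary mixture
0.5*chi2_0 + 0.5*chi2_1. A binary trait is analyzed on the observed 0/1
scale and converted to the liability scale afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.stats import chi2, norm

from .cohort import GenotypeMatrix

__all__ = [
    "Grm",
    "VarianceComponents",
    "compute_grm",
    "reml_fit",
    "observed_to_liability",
]


@dataclass
class Grm:
    """Genetic relationship matrix over one SNP subset."""

    matrix: np.ndarray
    n_snps_used: int
    snp_subset_label: str = "whole genome"

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[0] != self.matrix.shape[1]:
            raise ValueError("GRM must be square")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    @property
    def n_subjects(self) -> int:
        return self.matrix.shape[0]


@dataclass
class VarianceComponents:
    sigma2_g: float
    sigma2_e: float
    h2_obs: float
    h2_liability: float | None
    loglik_full: float
    loglik_null: float
    lrt: float
    lrt_p: float
    degenerate: bool = False


def compute_grm(
    genotypes: GenotypeMatrix, snp_subset: np.ndarray | list | None = None,
    label: str | None = None,
) -> Grm:
    """GCTA-style GRM: A_jk = (1/M) sum_i (x_ij - 2 p_i)(x_ik - 2 p_i) / (2 p_i (1 - p_i)).

    Missing dosages are mean-imputed; monomorphic SNPs in the subset are
    excluded with a warning. ``snp_subset`` may be indices or SNP ids.
    """
    dos = genotypes.dosages
    ids = np.asarray(genotypes.snp_ids)
    if snp_subset is not None:
        subset = np.asarray(snp_subset)
        if subset.dtype.kind in "US":
            idx = np.flatnonzero(np.isin(ids, subset))
        else:
            idx = subset.astype(int)
        dos = dos[:, idx]
        ids = ids[idx]
    p = np.nanmean(dos, axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.all():
        warnings.warn(
            f"excluding {int((~poly).sum())} monomorphic SNPs from the GRM",
            stacklevel=2,
        )
    dos = dos[:, poly]
    p = p[poly]
    M = dos.shape[1]
    if M == 0:
        raise ValueError("no polymorphic SNPs available for the GRM")
    dos = np.where(np.isnan(dos), 2.0 * p, dos)
    Z = (dos - 2.0 * p) / np.sqrt(2.0 * p * (1.0 - p))
    A = (Z @ Z.T) / M
    return Grm(A, M, label or ("whole genome" if snp_subset is None else "subset"))


def _reml_loglik(h2: float, lam: np.ndarray, ty: np.ndarray, tX: np.ndarray) -> float:
    """Restricted log-likelihood profiled over the total variance.

    ``lam`` are GRM eigenvalues; ``ty``/``tX`` the rotated phenotype and
    covariates. V = sigma2 * (h2 * Lam + (1 - h2) * I).
    """
    n, p = tX.shape
    w = h2 * lam + (1.0 - h2)
    w = np.maximum(w, 1e-12)
    wi = 1.0 / w
    XtWiX = (tX * wi[:, None]).T @ tX
    XtWiy = (tX * wi[:, None]).T @ ty
    try:
        beta = np.linalg.solve(XtWiX, XtWiy)
    except np.linalg.LinAlgError:
        return -np.inf
    r = ty - tX @ beta
    rss = float(np.sum(r * r * wi))
    if rss <= 0:
        return -np.inf
    sigma2 = rss / (n - p)
    sign, logdet_XtWiX = np.linalg.slogdet(XtWiX)
    if sign <= 0:
        return -np.inf
    return -0.5 * (
        (n - p) * (np.log(2.0 * np.pi * sigma2) + 1.0)
        + float(np.sum(np.log(w)))
        + logdet_XtWiX
    )


def reml_fit(
    grm: Grm,
    phenotype: np.ndarray,
    covariates: np.ndarray | None = None,
    K: float | None = None,
    grid: np.ndarray | None = None,
) -> VarianceComponents:
    """REML variance components for one GRM.

    ``covariates`` (without intercept; one is added) are fixed effects.
    When ``K`` is given, h2_obs is also converted to the liability scale.
    ``grid`` optionally replaces the default coarse scan that brackets the
    1-D optimum before Brent refinement.
    """
    y = np.asarray(phenotype, dtype=float)
    n = grm.n_subjects
    if y.shape != (n,):
        raise ValueError("phenotype length must match the GRM")
    if np.var(y) <= 0:
        raise ValueError("phenotype variance must be positive")
    X = np.ones((n, 1))
    if covariates is not None:
        C = np.asarray(covariates, dtype=float)
        if C.ndim == 1:
            C = C[:, None]
        C = C[:, C.std(axis=0) > 0]  # constant columns are absorbed by the intercept
        X = np.hstack([X, C])

    lam, U = np.linalg.eigh(grm.matrix)
    if lam.min() < -1e-8:
        warnings.warn("GRM not PSD; clamping negative eigenvalues at 0", stacklevel=2)
    lam = np.maximum(lam, 0.0)
    degenerate = float(lam.max() - lam.min()) < 1e-10
    if degenerate:
        warnings.warn(
            "GRM is (a multiple of) the identity; h2 is unidentifiable", stacklevel=2
        )
    ty = U.T @ y
    tX = U.T @ X

    if grid is None:
        grid = np.linspace(0.0, 1.0 - 1e-6, 21)
    ll_grid = np.array([_reml_loglik(h, lam, ty, tX) for h in grid])
    i = int(np.argmax(ll_grid))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    if lo == hi:
        h2_hat, ll_full = grid[i], ll_grid[i]
    else:
        res = minimize_scalar(
            lambda h: -_reml_loglik(h, lam, ty, tX),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if not res.success:  # pragma: no cover
            raise RuntimeError(f"REML optimization failed: {res.message}")
        h2_hat, ll_full = float(res.x), -float(res.fun)
        if ll_grid[i] > ll_full:  # guard against a flat bracketing
            h2_hat, ll_full = float(grid[i]), float(ll_grid[i])
    if degenerate:
        h2_hat = 0.0

    ll_null = _reml_loglik(0.0, lam, ty, tX)
    lrt = max(0.0, 2.0 * (ll_full - ll_null))
    lrt_p = float(0.5 * chi2.sf(lrt, df=1)) if lrt > 0 else 0.5

    # recover total variance at the optimum to report raw components
    w = np.maximum(h2_hat * lam + (1.0 - h2_hat), 1e-12)
    wi = 1.0 / w
    XtWiX = (tX * wi[:, None]).T @ tX
    beta = np.linalg.lstsq(XtWiX, (tX * wi[:, None]).T @ ty, rcond=None)[0]
    r = ty - tX @ beta
    sigma2 = float(np.sum(r * r * wi)) / (n - X.shape[1])
    sigma2_g = h2_hat * sigma2
    sigma2_e = (1.0 - h2_hat) * sigma2

    return VarianceComponents(
        sigma2_g=sigma2_g,
        sigma2_e=sigma2_e,
        h2_obs=h2_hat,
        h2_liability=None if K is None else observed_to_liability(h2_hat, K),
        loglik_full=float(ll_full),
        loglik_null=float(ll_null),
        lrt=lrt,
        lrt_p=lrt_p,
        degenerate=degenerate,
    )


def observed_to_liability(h2_obs: float, K: float) -> float:
    """Convert observed-scale (0/1) heritability to the liability scale.

    h2_liab = h2_obs * K (1 - K) / z^2, with z the standard-normal density
    at the threshold Phi^-1(1 - K). Results above 1 are clamped with a
    warning.
    """
    if not 0.0 < K < 1.0:
        raise ValueError("K must be in (0, 1)")
    if h2_obs < 0:
        raise ValueError("h2_obs must be non-negative")
    z = norm.pdf(norm.isf(K))
    out = h2_obs * K * (1.0 - K) / (z * z)
    if out > 1.0:
        warnings.warn("liability-scale heritability clamped at 1", stacklevel=2)
        return 1.0
    return float(out)
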