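"""Feasibility theory for genetic predictors of a binary treatment-response trait.

Three linked pieces of liability-threshold arithmetic:

1. how much liability variance a single biallelic risk locus with
   per-allele relative risk lambda explains, and hence how many equal-effect
   loci are needed to account for a target heritability;
2. the power of a 1-df allelic case-control test to detect such a locus at
   a given significance threshold, and the median power over the (p, lambda)
   grid cells compatible with a given locus count -- read as the expected
   share of heritability a model built from detected loci captures;
3. the mapping between liability variance explained by a predictor and its
   theoretical AUROC (genomic-profile closed form), including the
   combination with an independent clinical predictor and the inversion
   that asks what fraction of the heritable component a model must explain
   to reach a target AUROC.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2, ncx2, norm

from .heritability import observed_to_liability

__all__ = [
    "PowerGridConfig",
    "locus_liability_variance",
    "n_loci_required",
    "detection_power",
    "expected_h2_explained",
    "auroc_from_h2",
    "variance_from_auroc",
    "combined_auroc",
    "min_h2_fraction_for_auroc",
]

#: AUROC of the best clinical-covariate model, used as the default baseline
#: when asking how much heritability a genetic component must add.
DEFAULT_CLINICAL_AUROC = 0.6214


@dataclass
class PowerGridConfig:
    """Grid of risk-allele frequencies and per-allele relative risks."""

    p_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(0.01, 0.995, 0.01), 10)
    )
    lambda_grid: np.ndarray = field(
        default_factory=lambda: np.round(np.arange(1.1, 2.405, 0.01), 10)
    )
    K: float = 0.217
    h2_liability: float = 0.354
    n_cases: int = 587
    n_controls: int = 2119
    alpha_levels: tuple[float, ...] = (5e-8, 5e-7, 5e-6, 5e-5, 5e-4)

    def __post_init__(self) -> None:
        self.p_grid = np.asarray(self.p_grid, dtype=float)
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if np.any(np.diff(self.p_grid) <= 0) or np.any(np.diff(self.lambda_grid) <= 0):
            raise ValueError("grids must be strictly increasing")
        if np.any(self.lambda_grid <= 1.0):
            raise ValueError("relative risks must exceed 1")
        if not 0.0 < self.K < 1.0:
            raise ValueError("K must be in (0, 1)")
        if any(not 0.0 < a < 1.0 for a in self.alpha_levels):
            raise ValueError("alpha levels must be in (0, 1)")
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("sample sizes must be positive")


def _genotype_model(p: float, lambda_rr: float, K: float):
    """Genotype frequencies and penetrances under the multiplicative model.

    Genotypes indexed by risk-allele count with relative risks (1, lambda,
    lambda^2); penetrances are normalized so the population risk equals K.
    """
    f = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    rr = np.array([1.0, lambda_rr, lambda_rr**2])
    pen = K * rr / float(f @ rr)
    if pen.max() >= 1.0:
        raise ValueError("penetrance exceeds 1 under this (p, lambda, K)")
    return f, pen


def locus_liability_variance(p: float, lambda_rr: float, K: float) -> float:
    """Liability variance attributable to one biallelic risk locus.

    Each genotype's penetrance is mapped to a mean shift on the liability
    scale (mu_g = T - Phi^-1(1 - K_g), unit residual); the locus heritability
    is the between-genotype variance over the total 1 + between.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    if lambda_rr < 1.0:
        raise ValueError("lambda must be >= 1 (risk-allele convention)")
    if not 0.0 < K < 1.0:
        raise ValueError("K must be in (0, 1)")
    if lambda_rr == 1.0:
        return 0.0
    f, pen = _genotype_model(p, lambda_rr, K)
    T = norm.isf(K)
    mu = T - norm.isf(pen)
    between = float(f @ mu**2 - (f @ mu) ** 2)
    return between / (1.0 + between)


def n_loci_required(p: float, lambda_rr: float, K: float, h2_target: float) -> float:
    """Number of equal-effect loci needed to explain ``h2_target``.

    round(h2_target / per-locus variance), at least 1; infinity when the
    locus explains nothing.
    """
    if h2_target <= 0:
        raise ValueError("h2_target must be positive")
    v = locus_liability_variance(p, lambda_rr, K)
    if v <= 0:
        return float("inf")
    return max(1.0, float(round(h2_target / v)))


def detection_power(
    p: float,
    lambda_rr: float,
    K: float,
    n_cases: int,
    n_controls: int,
    alpha: float,
) -> float:
    """Power of the 1-df allelic case-control chi-square test.

    Case/control risk-allele frequencies follow from the multiplicative
    penetrances at prevalence K; the non-centrality is that of the
    two-sample allele-frequency comparison at the stated sample sizes.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_cases <= 0 or n_controls <= 0:
        raise ValueError("sample sizes must be positive")
    f, pen = _genotype_model(p, lambda_rr, K)
    geno_case = f * pen / K
    geno_ctrl = f * (1.0 - pen) / (1.0 - K)
    dose = np.array([0.0, 1.0, 2.0])
    p1 = float(geno_case @ dose) / 2.0
    p0 = float(geno_ctrl @ dose) / 2.0
    m1, m0 = 2 * n_cases, 2 * n_controls  # allele counts
    pbar = (m1 * p1 + m0 * p0) / (m1 + m0)
    if pbar in (0.0, 1.0):
        return float(alpha)
    ncp = (p1 - p0) ** 2 / (pbar * (1 - pbar) * (1 / m1 + 1 / m0))
    crit = chi2.isf(alpha, df=1)
    return float(ncx2.sf(crit, df=1, nc=ncp)) if ncp > 0 else float(alpha)


def expected_h2_explained(
    config: PowerGridConfig, n_loci: int, alpha: float
) -> float | None:
    """Expected share of heritability captured at locus count ``n_loci``.

    Median detection power over every (p, lambda) grid cell whose required
    locus count rounds to ``n_loci``. None when no cell qualifies.
    """
    powers = []
    for p in config.p_grid:
        for lam in config.lambda_grid:
            try:  # skip infeasible cells (penetrance above 1)
                n = n_loci_required(p, lam, config.K, config.h2_liability)
                if np.isfinite(n) and int(n) == int(n_loci):
                    powers.append(
                        detection_power(
                            p, lam, config.K, config.n_cases, config.n_controls, alpha
                        )
                    )
            except ValueError:
                continue
    if not powers:
        return None
    return float(np.median(powers))


def _threshold_moments(K: float):
    T = norm.isf(K)
    z = norm.pdf(T)
    i_case = z / K
    i_ctrl = -z / (1.0 - K)
    return T, i_case, i_ctrl


def auroc_from_h2(h2_liab_explained: float, K: float) -> float:
    """Theoretical AUROC of a score explaining given liability variance.

    Genomic-profile closed form: conditional on case/control status the
    score is treated as normal with truncated-normal moments, giving
    AUC = Phi( (i - i2) v / sqrt(v(1 - v i (i - T)) + v(1 - v i2 (i2 - T))) )
    for v the liability variance explained, T the threshold, i and i2 the
    mean case and control liabilities.
    """
    if not 0.0 <= h2_liab_explained <= 1.0:
        raise ValueError("variance explained must be in [0, 1]")
    if not 0.0 < K < 1.0:
        raise ValueError("K must be in (0, 1)")
    v = float(h2_liab_explained)
    if v == 0.0:
        return 0.5
    T, i1, i2 = _threshold_moments(K)
    num = (i1 - i2) * v
    den = np.sqrt(v * (1 - v * i1 * (i1 - T)) + v * (1 - v * i2 * (i2 - T)))
    return float(norm.cdf(num / den))


def variance_from_auroc(auroc: float, K: float) -> float:
    """Invert :func:`auroc_from_h2`: liability variance explained by a score
    with the stated AUROC (exact algebraic inverse of the closed form)."""
    if not 0.5 <= auroc < 1.0:
        raise ValueError("AUROC must be in [0.5, 1)")
    if auroc == 0.5:
        return 0.0
    T, i1, i2 = _threshold_moments(K)
    x = norm.ppf(auroc)
    s = i1 * (i1 - T) + i2 * (i2 - T)
    return float(2 * x * x / ((i1 - i2) ** 2 + x * x * s))


def combined_auroc(clinical_auroc: float, h2_liab_explained: float, K: float) -> float:
    """AUROC of independent clinical + genetic components.

    The clinical AUROC is inverted to a liability variance, added to the
    genetic variance (independence), and mapped back to an AUROC. Combined
    variance >= 1 is clamped with a warning.
    """
    v_c = variance_from_auroc(clinical_auroc, K)
    v = v_c + h2_liab_explained
    if v >= 1.0:
        warnings.warn("combined liability variance clamped below 1", stacklevel=2)
        v = 1.0 - 1e-9
    return auroc_from_h2(v, K)


def min_h2_fraction_for_auroc(
    h2_obs: float,
    K: float,
    auroc_target: float,
    clinical_auroc: float = DEFAULT_CLINICAL_AUROC,
) -> float:
    """Smallest fraction of the heritable component a model must explain.

    The observed-scale heritability is converted to the liability scale;
    bisection then finds the smallest fraction f (3 decimals) such that a
    genetic score explaining f * h2_liab, combined with an independent
    clinical predictor of the stated AUROC, reaches ``auroc_target``. Pass
    ``clinical_auroc=0.5`` for the purely genetic version.

    Raises ValueError when the target is not achievable at f = 1.
    """
    if not 0.5 < auroc_target < 1.0:
        raise ValueError("auroc_target must be in (0.5, 1)")
    h2_liab = observed_to_liability(h2_obs, K)
    if combined_auroc(clinical_auroc, h2_liab, K) < auroc_target:
        raise ValueError(
            "AUROC target not achievable even when the full heritable "
            "component is explained"
        )
    lo, hi = 0.0, 1.0
    while hi - lo > 1e-7:
        mid = 0.5 * (lo + hi)
        if combined_auroc(clinical_auroc, mid * h2_liab, K) >= auroc_target:
            hi = mid
        else:
            lo = mid
    return float(np.ceil(hi * 1000 - 1e-9) / 1000)
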