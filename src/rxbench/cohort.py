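"""Synthetic rheumatoid-arthritis anti-TNF cohorts under a liability-threshold model.

The generator emulates the statistical structure of a pharmacogenetic
treatment-response study: common-SNP genotypes in Hardy-Weinberg
proportions, an equal-effect polygenic architecture on a latent liability
with prevalence K, DAS28 disease-activity dynamics, EULAR response
categories, and a train/leaderboard/test cohort layout with a prevalence
shift between cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import norm, truncnorm

__all__ = [
    "ANTI_TNF_DRUGS",
    "CohortConfig",
    "GenotypeMatrix",
    "simulate_genotypes",
    "assign_effects",
    "simulate_liability_outcome",
    "simulate_das28",
    "eular_classify",
    "split_cohort",
    "generate_cohort",
]

#: Anti-TNF agents seen across the two cohorts. Adalimumab, infliximab,
#: certolizumab and golimumab are monoclonal antibodies; etanercept is a
#: circulating receptor fusion protein.
ANTI_TNF_DRUGS = ("adalimumab", "etanercept", "infliximab", "certolizumab", "golimumab")

#: Monoclonal-antibody subset (stronger heritability in the study design).
MAB_DRUGS = ("adalimumab", "infliximab", "certolizumab", "golimumab")

_DAS28_MAX = 9.4
_DAS28_MODERATE = 3.2


def _default_drug_mix() -> dict[str, float]:
    return {
        "adalimumab": 0.30,
        "etanercept": 0.35,
        "infliximab": 0.25,
        "certolizumab": 0.10,
        "golimumab": 0.0,
    }


@dataclass
class CohortConfig:
    """Parameters of one simulated cohort.

    h2_liability is the SNP heritability of the non-response trait on the
    liability scale; prevalence_K the population non-response rate. Causal
    loci all receive the same standardized effect.
    """

    n_subjects: int = 2706
    n_snps: int = 2000
    maf_range: tuple[float, float] = (0.01, 0.5)
    n_causal: int | None = None  # default: min(20, n_snps)
    h2_liability: float = 0.354
    prevalence_K: float = 0.217
    drug_mix: dict[str, float] = field(default_factory=_default_drug_mix)
    mtx_rate: float = 0.6
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects <= 0 or self.n_snps < 0:
            raise ValueError("cohort dimensions must be positive")
        lo, hi = self.maf_range
        if not (0.01 - 1e-12 <= lo <= hi <= 0.5 + 1e-12):
            raise ValueError("maf_range must lie within [0.01, 0.5]")
        if not 0.0 <= self.h2_liability < 1.0:
            raise ValueError("h2_liability must be in [0, 1)")
        if not 0.0 < self.prevalence_K < 1.0:
            raise ValueError("prevalence_K must be in (0, 1)")
        if self.n_causal is None:
            self.n_causal = min(20, self.n_snps)
        if self.n_causal > self.n_snps:
            raise ValueError("n_causal cannot exceed n_snps")
        if abs(sum(self.drug_mix.values()) - 1.0) > 1e-9:
            raise ValueError("drug proportions must sum to 1")
        unknown = set(self.drug_mix) - set(ANTI_TNF_DRUGS)
        if unknown:
            raise ValueError(f"unknown drugs: {sorted(unknown)}")
        if not 0.0 <= self.mtx_rate <= 1.0:
            raise ValueError("mtx_rate must be in [0, 1]")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")

    def replace(self, **kwargs) -> "CohortConfig":
        return replace(self, **kwargs)


@dataclass
class GenotypeMatrix:
    """Subjects x SNPs dosage matrix (0/1/2, NaN for missing calls)."""

    dosages: np.ndarray
    snp_ids: list[str]
    allele_freqs: np.ndarray
    subject_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        self.allele_freqs = np.asarray(self.allele_freqs, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (subjects x SNPs)")
        if self.dosages.shape[1] != len(self.snp_ids):
            raise ValueError("snp_ids length does not match dosage columns")
        if len(self.allele_freqs) != self.dosages.shape[1]:
            raise ValueError("allele_freqs length does not match dosage columns")
        if np.any((self.allele_freqs < 0) | (self.allele_freqs > 1)):
            raise ValueError("allele frequencies must lie in [0, 1]")
        if self.subject_ids is None:
            self.subject_ids = [f"S{i:06d}" for i in range(self.dosages.shape[0])]

    @property
    def n_subjects(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    @property
    def missing_fraction(self) -> float:
        return float(np.isnan(self.dosages).mean()) if self.dosages.size else 0.0


def simulate_genotypes(config: CohortConfig) -> GenotypeMatrix:
    """Draw genotype dosages under Hardy-Weinberg proportions.

    Each SNP gets an allele frequency uniform on ``maf_range``; dosages are
    Binomial(2, p) draws, then missing calls are masked at
    ``config.missing_rate``.
    """
    if config.n_snps <= 0:
        raise ValueError("n_snps must be positive to simulate genotypes")
    rng = np.random.default_rng(config.seed)
    lo, hi = config.maf_range
    freqs = rng.uniform(lo, hi, size=config.n_snps)
    dosages = rng.binomial(2, freqs, size=(config.n_subjects, config.n_snps)).astype(float)
    if config.missing_rate > 0:
        mask = rng.random(dosages.shape) < config.missing_rate
        dosages[mask] = np.nan
    with np.errstate(invalid="ignore"):
        realized = np.nanmean(dosages, axis=0) / 2.0
    realized = np.where(np.isnan(realized), 0.0, realized)
    snp_ids = [f"rs{i:06d}" for i in range(config.n_snps)]
    return GenotypeMatrix(dosages, snp_ids, realized)


def assign_effects(
    genotypes: GenotypeMatrix,
    n_causal: int,
    h2_liability: float,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Equal-effect causal architecture on the liability scale.

    ``n_causal`` SNPs are sampled uniformly without replacement; every causal
    SNP receives the same allele-dosage effect beta chosen so that
    sum_i 2 p_i (1 - p_i) beta^2 = h2_liability on the realized allele
    frequencies. Non-causal SNPs get effect 0.
    """
    if not 0.0 <= h2_liability < 1.0:
        raise ValueError("h2_liability must be in [0, 1)")
    effects = np.zeros(genotypes.n_snps)
    if h2_liability == 0.0:
        return effects
    if n_causal < 1:
        raise ValueError("n_causal must be >= 1 when h2_liability > 0")
    if n_causal > genotypes.n_snps:
        raise ValueError("n_causal cannot exceed the number of SNPs")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    causal = rng.choice(genotypes.n_snps, size=n_causal, replace=False)
    p = genotypes.allele_freqs[causal]
    var_sum = float(np.sum(2.0 * p * (1.0 - p)))
    if var_sum <= 0:
        raise ValueError("causal SNPs are monomorphic; cannot place heritability")
    beta = np.sqrt(h2_liability / var_sum)
    effects[causal] = beta
    return effects


def simulate_liability_outcome(
    genotypes: GenotypeMatrix,
    effects: np.ndarray,
    K: float,
    seed: int | np.random.Generator = 0,
    exact_prevalence: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Binary non-response labels from the liability-threshold model.

    liability = centered genetic score + N(0, 1 - h2) residual, so the total
    liability variance is 1; a subject is a non-responder when the liability
    exceeds the threshold Phi^-1(1 - K). With ``exact_prevalence`` the
    threshold is the empirical quantile, yielding exactly round(K * n) cases.

    Returns (labels, liabilities).
    """
    if not 0.0 < K < 1.0:
        raise ValueError("K must be in (0, 1)")
    effects = np.asarray(effects, dtype=float)
    if effects.shape != (genotypes.n_snps,):
        raise ValueError("effects must align with the SNP axis")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = genotypes.allele_freqs
    dos = genotypes.dosages
    if np.isnan(dos).any():
        dos = np.where(np.isnan(dos), 2.0 * p, dos)  # mean-impute for the score
    score = (dos - 2.0 * p) @ effects
    h2 = float(np.sum(2.0 * p * (1.0 - p) * effects**2))
    h2 = min(h2, 1.0 - 1e-12)
    liability = score + rng.normal(0.0, np.sqrt(1.0 - h2), size=genotypes.n_subjects)
    if exact_prevalence:
        n_cases = int(round(K * genotypes.n_subjects))
        order = np.argsort(-liability, kind="stable")
        labels = np.zeros(genotypes.n_subjects, dtype=bool)
        labels[order[:n_cases]] = True
    else:
        labels = liability > norm.isf(K)
    return labels, liability


def eular_classify(das28_baseline, das28_followup):
    """EULAR response category from baseline and follow-up DAS28.

    improvement > 1.2: Good if follow-up <= 3.2 else Moderate;
    0.6 < improvement <= 1.2: Moderate if follow-up <= 5.1 else None;
    improvement <= 0.6: None. Baseline must exceed 3.2 (moderate disease
    activity, the cohort inclusion criterion).
    """
    b = np.asarray(das28_baseline, dtype=float)
    f = np.asarray(das28_followup, dtype=float)
    scalar = b.ndim == 0
    b, f = np.atleast_1d(b), np.atleast_1d(f)
    if np.any(b < 0) or np.any(f < 0):
        raise ValueError("DAS28 scores must be non-negative")
    if np.any(b <= _DAS28_MODERATE):
        raise ValueError("baseline DAS28 must exceed 3.2 (cohort inclusion)")
    imp = b - f
    cat = np.full(b.shape, "None", dtype=object)
    good = (imp > 1.2) & (f <= 3.2)
    mod = ((imp > 1.2) & (f > 3.2)) | ((imp > 0.6) & (imp <= 1.2) & (f <= 5.1))
    cat[mod] = "Moderate"
    cat[good] = "Good"
    out = pd.Categorical(cat, categories=["Good", "Moderate", "None"])
    if scalar:
        return str(out[0])
    return out


def _truncated_normal(rng, loc, scale, lower, upper):
    """Vectorized truncated-normal draws with per-element bounds."""
    loc = np.asarray(loc, dtype=float)
    a = (lower - loc) / scale
    b = (upper - loc) / scale
    u = rng.random(loc.shape)
    return truncnorm.ppf(u, a, b, loc=loc, scale=scale)


def simulate_das28(
    labels: np.ndarray,
    liabilities: np.ndarray | None = None,
    covariates: pd.DataFrame | None = None,
    seed: int | np.random.Generator = 0,
    baseline_mean: float = 5.5,
    baseline_sd: float = 1.2,
    delta_sd: float = 0.45,
) -> pd.DataFrame:
    """DAS28 trajectories consistent with given non-response labels.

    Baseline DAS28 is truncated normal on (3.2, 9.4]. The improvement
    ``delta_das28 = baseline - followup`` is placed inside the EULAR region
    dictated by the label (None region for non-responders, Good/Moderate for
    responders), so re-classifying the trajectories reproduces the labels
    exactly. Improvement decreases with the non-response liability and
    carries small clinical-covariate effects.
    """
    labels = np.asarray(labels, dtype=bool)
    n = len(labels)
    if n == 0:
        raise ValueError("labels must be non-empty")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if liabilities is None:
        liabilities = np.zeros(n)
    liab = np.asarray(liabilities, dtype=float)
    zliab = (liab - liab.mean()) / (liab.std() if liab.std() > 0 else 1.0)

    baseline = _truncated_normal(
        rng, np.full(n, baseline_mean), baseline_sd, _DAS28_MODERATE + 1e-6, _DAS28_MAX
    )

    clin = np.zeros(n)
    if covariates is not None:
        # small, fixed clinical effects on improvement so that clinical-only
        # regressors of delta-DAS28 beat random
        if "age" in covariates:
            clin = clin - 0.008 * (covariates["age"].to_numpy(float) - 55.0)
        if "mtx" in covariates:
            clin = clin + 0.20 * covariates["mtx"].to_numpy(float)
        if "sex" in covariates:
            clin = clin + 0.10 * (covariates["sex"].to_numpy() == "F")
        if "drug" in covariates:
            offsets = {d: 0.05 * i for i, d in enumerate(ANTI_TNF_DRUGS)}
            clin = clin + covariates["drug"].map(offsets).to_numpy(float)
        clin = clin - clin.mean()

    delta = np.empty(n)
    resp = ~labels
    # responders: improvement > 1.2 (Good or Moderate), bounded by follow-up >= 0
    if resp.any():
        loc = 2.4 - 0.5 * zliab[resp] + clin[resp]
        delta[resp] = _truncated_normal(rng, loc, delta_sd, 1.2 + 1e-6, baseline[resp])
    # non-responders: improvement <= 0.6 (EULAR None), follow-up capped at 9.4
    if labels.any():
        loc = 0.2 - 0.3 * zliab[labels] + clin[labels]
        lower = np.maximum(baseline[labels] - _DAS28_MAX, -2.5)
        delta[labels] = _truncated_normal(rng, loc, delta_sd, lower, 0.6)

    followup = baseline - delta
    eular = eular_classify(baseline, followup)
    nonresponse = np.asarray(eular) == "None"
    if not np.array_equal(nonresponse, labels):  # pragma: no cover - contract
        raise RuntimeError("EULAR placement failed to reproduce labels")

    table = pd.DataFrame(
        {
            "subject_id": [f"S{i:06d}" for i in range(n)],
            "das28_baseline": baseline,
            "das28_followup": followup,
            "delta_das28": delta,
            "eular": eular,
            "nonresponse": labels,
        }
    )
    if covariates is not None:
        for col in covariates.columns:
            table[col] = covariates[col].to_numpy()
    return table


def _simulate_covariates(config: CohortConfig, rng: np.random.Generator) -> pd.DataFrame:
    drugs, probs = zip(*config.drug_mix.items())
    return pd.DataFrame(
        {
            "age": np.clip(rng.normal(55.0, 12.0, config.n_subjects), 18, 90).round(1),
            "sex": np.where(rng.random(config.n_subjects) < 0.75, "F", "M"),
            "drug": rng.choice(drugs, p=probs, size=config.n_subjects),
            "mtx": rng.random(config.n_subjects) < config.mtx_rate,
        }
    )


def split_cohort(
    table: pd.DataFrame,
    sizes: tuple[int, int, int] = (2031, 675, 591),
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Assign disjoint train / leaderboard / test tags.

    ``sizes`` must not oversubscribe the table; leftover subjects (if any)
    stay untagged as "unused".
    """
    n_train, n_lead, n_test = sizes
    if min(sizes) < 0:
        raise ValueError("split sizes must be non-negative")
    n = len(table)
    if n_train + n_lead + n_test > n:
        raise ValueError("split sizes exceed the number of subjects")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    order = rng.permutation(n)
    split = np.full(n, "unused", dtype=object)
    split[order[:n_train]] = "train"
    split[order[n_train : n_train + n_lead]] = "leaderboard"
    split[order[n_train + n_lead : n_train + n_lead + n_test]] = "test"
    out = table.copy()
    out["split"] = split
    return out


def generate_cohort(
    config: CohortConfig, exact_prevalence: bool = False
) -> tuple[GenotypeMatrix, pd.DataFrame, np.ndarray]:
    """Full cohort draw: genotypes, phenotype/covariate table, effect vector.

    Byte-identical for a fixed config (all stages consume one seeded stream).
    """
    genotypes = simulate_genotypes(config)
    rng = np.random.default_rng(config.seed + 1)
    effects = assign_effects(genotypes, config.n_causal, config.h2_liability, rng)
    labels, liab = simulate_liability_outcome(
        genotypes, effects, config.prevalence_K, rng, exact_prevalence=exact_prevalence
    )
    covariates = _simulate_covariates(config, rng)
    table = simulate_das28(labels, liab, covariates, rng)
    table["liability"] = liab
    return genotypes, table, effects
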