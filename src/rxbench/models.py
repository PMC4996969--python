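"""Baseline predictive models used as deterministic stand-ins for teams.

Ridge-penalized logistic (classification of non-response) and ridge linear
(prediction of DAS28 improvement) fits on selected SNP dosages plus
clinical covariates. These are the callbacks plugged into the
random-feature null experiments and the full-vs-clinical comparisons; they
are intentionally simple, deterministic models, not re-creations of any
team's pipeline.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression, Ridge

from .cohort import ANTI_TNF_DRUGS, GenotypeMatrix

__all__ = [
    "clinical_design",
    "fit_classifier",
    "make_fit_and_score",
    "top_associated_snps",
]

CLINICAL_COLUMNS = ("age", "sex", "drug", "mtx", "das28_baseline")


def clinical_design(table: pd.DataFrame) -> np.ndarray:
    """Numeric design matrix of the clinical covariates."""
    cols = [
        (table["age"].to_numpy(float) - 55.0) / 12.0,
        (table["sex"].to_numpy() == "F").astype(float),
        table["mtx"].to_numpy(float),
        (table["das28_baseline"].to_numpy(float) - 5.5) / 1.2,
    ]
    for d in ANTI_TNF_DRUGS[1:]:  # first drug is the reference level
        cols.append((table["drug"].to_numpy() == d).astype(float))
    return np.column_stack(cols)


def _design(
    genotypes: GenotypeMatrix,
    table: pd.DataFrame,
    rows: np.ndarray,
    snp_idx: np.ndarray | None,
    use_clinical: bool,
) -> np.ndarray:
    parts = []
    if snp_idx is not None and len(snp_idx):
        dos = genotypes.dosages[np.ix_(rows, snp_idx)]
        p = genotypes.allele_freqs[snp_idx]
        dos = np.where(np.isnan(dos), 2.0 * p, dos)
        parts.append(dos - 2.0 * p)
    if use_clinical:
        parts.append(clinical_design(table.iloc[rows]))
    if not parts:
        raise ValueError("model needs SNPs or clinical covariates")
    return np.column_stack(parts)


def fit_classifier(
    genotypes: GenotypeMatrix,
    table: pd.DataFrame,
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    snp_idx: np.ndarray | None = None,
    use_clinical: bool = True,
    C: float = 1.0,
) -> np.ndarray:
    """Ridge-logistic non-response scores for the test rows."""
    Xtr = _design(genotypes, table, train_rows, snp_idx, use_clinical)
    Xte = _design(genotypes, table, test_rows, snp_idx, use_clinical)
    y = table["nonresponse"].to_numpy(bool)[train_rows]
    model = LogisticRegression(C=C, max_iter=2000)
    model.fit(Xtr, y)
    return model.predict_proba(Xte)[:, 1]


def fit_regressor(
    genotypes: GenotypeMatrix,
    table: pd.DataFrame,
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    snp_idx: np.ndarray | None = None,
    use_clinical: bool = True,
    alpha: float = 1.0,
) -> np.ndarray:
    """Ridge-regression predictions of DAS28 improvement for the test rows."""
    Xtr = _design(genotypes, table, train_rows, snp_idx, use_clinical)
    Xte = _design(genotypes, table, test_rows, snp_idx, use_clinical)
    y = table["delta_das28"].to_numpy(float)[train_rows]
    model = Ridge(alpha=alpha)
    model.fit(Xtr, y)
    return model.predict(Xte)


def _association_r(genotypes: GenotypeMatrix, table: pd.DataFrame, rows: np.ndarray):
    y = table["nonresponse"].to_numpy(float)[rows]
    dos = genotypes.dosages[rows]
    p = genotypes.allele_freqs
    dos = np.where(np.isnan(dos), 2.0 * p, dos)
    dos = dos - dos.mean(axis=0)
    yc = y - y.mean()
    denom = np.sqrt((dos**2).sum(axis=0) * (yc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.abs(dos.T @ yc) / np.where(denom > 0, denom, np.inf)


def top_associated_snps(
    genotypes: GenotypeMatrix, table: pd.DataFrame, rows: np.ndarray, k: int
) -> np.ndarray:
    """Indices of the k SNPs most associated with non-response in ``rows``
    (absolute point-biserial correlation on mean-imputed dosages)."""
    r = _association_r(genotypes, table, rows)
    return np.argsort(-r)[:k]


def screened_snps(
    genotypes: GenotypeMatrix,
    table: pd.DataFrame,
    rows: np.ndarray,
    k: int,
    alpha: float = 1e-3,
) -> np.ndarray:
    """Association-screened SNP selection: the strongest (at most k) SNPs
    whose point-biserial chi-square passes ``alpha`` in the training rows.

    With no true signal the screen usually admits nothing, so a "full"
    model degenerates to the clinical covariates instead of carrying
    overfitted noise features into the test set.
    """
    from scipy.stats import chi2

    r = _association_r(genotypes, table, rows)
    n = len(rows)
    pvals = chi2.sf(n * r**2, df=1)
    passing = np.flatnonzero(pvals < alpha)
    return passing[np.argsort(-r[passing])][:k]


def make_fit_and_score(
    genotypes: GenotypeMatrix,
    table: pd.DataFrame,
    train_rows: np.ndarray,
    test_rows: np.ndarray,
    metric_fn,
    use_clinical: bool = True,
    C: float = 1.0,
):
    """Callback for :func:`rxbench.robustness.random_feature_null`.

    Returns ``fit_and_score(snp_indices) -> test metric`` for the ridge
    logistic classifier trained on the given SNP set.
    """
    y_test = table["nonresponse"].to_numpy(bool)[test_rows]

    def fit_and_score(snp_idx) -> float:
        scores = fit_classifier(
            genotypes,
            table,
            train_rows,
            test_rows,
            snp_idx=np.asarray(snp_idx, dtype=int),
            use_clinical=use_clinical,
            C=C,
        )
        return float(metric_fn(scores, y_test))

    return fit_and_score
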