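"""Tie-aware challenge scoring: AUPR, AUROC, Pearson r, ranks, permutation p.

Submissions are real-valued score vectors over subjects; for the
classification endpoint a higher score means "predicted non-responder"
(the rarer, positive class). Both curve statistics are defined as the
exact expectation, over all orderings consistent with the scores (ties
broken uniformly at random), of the area under the empirical curve traced
rank by rank and anchored at the origin. For AUROC that expectation
coincides with the Mann-Whitney identity with half-credit for tied
case/control pairs; for AUPR it is computed in closed form per tie block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import pearsonr, rankdata

__all__ = [
    "Submission",
    "ScoreReport",
    "tie_aware_auroc",
    "tie_aware_aupr",
    "aupr_of_ordering",
    "aupr_monte_carlo",
    "pearson_score",
    "rank_submissions",
    "permutation_pvalue",
    "bonferroni",
    "score_submissions",
]


@dataclass
class Submission:
    """One team's prediction vector."""

    subject_ids: list[str]
    scores: np.ndarray
    team: str = ""
    subchallenge: str = "classification"  # or "quantitative"
    phase: str = "competitive"

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        if len(self.subject_ids) != len(self.scores):
            raise ValueError("subject_ids and scores must align")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids in submission")
        if np.any(~np.isfinite(self.scores)):
            raise ValueError("submission contains non-finite scores")

    def aligned_scores(self, subject_ids: list[str]) -> np.ndarray:
        idx = {s: i for i, s in enumerate(self.subject_ids)}
        missing = [s for s in subject_ids if s not in idx]
        if missing:
            raise ValueError(f"submission missing {len(missing)} subjects")
        return self.scores[[idx[s] for s in subject_ids]]


@dataclass
class ScoreReport:
    team: str
    aupr: float | None = None
    auroc: float | None = None
    pearson_r: float | None = None
    rank_aupr: float | None = None
    rank_auroc: float | None = None
    overall_rank: float | None = None
    permutation_p: float | None = None
    bonferroni_significant: bool | None = None


def _check_classes(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise ValueError("both classes must be present")
    return labels


def tie_aware_auroc(scores, labels) -> float:
    """Expected AUROC over uniformly random tie-breaking.

    Equals the pairwise statistic (1/(n+ n-)) * sum over case/control pairs
    of 1[s+ > s-] + 0.5 * 1[s+ = s-], i.e. the Mann-Whitney U identity.
    """
    labels = _check_classes(labels)
    scores = np.asarray(scores, dtype=float)
    r = rankdata(scores, method="average")
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = r[labels].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def aupr_of_ordering(labels) -> float:
    """AUPR of one strict ordering (labels sorted by descending score).

    Trapezoidal area under the rank-by-rank (recall, precision) path,
    anchored at (0, 0).
    """
    y = np.asarray(labels, dtype=float)
    P = y.sum()
    if P == 0:
        raise ValueError("no positives")
    tp = np.cumsum(y)
    prec = np.concatenate([[0.0], tp / np.arange(1, len(y) + 1)])
    rec = np.concatenate([[0.0], tp / P])
    return float(np.trapezoid(prec, rec))


def _tie_blocks(scores: np.ndarray, labels: np.ndarray):
    """Yield (n_before, tp_before, block_size, block_positives) per tie block,
    in descending score order."""
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    boundaries = np.flatnonzero(np.diff(s)) + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(s)]])
    tp0 = 0
    for a, b in zip(starts, ends):
        pb = int(y[a:b].sum())
        yield int(a), tp0, int(b - a), pb
        tp0 += pb


def tie_aware_aupr(scores, labels) -> float:
    """Exact expected AUPR over all orderings consistent with the scores.

    Within a tie block the positives occupy positions uniformly at random;
    the expectation of the trapezoid area is linear in the per-rank terms
    E[y_k * (prec_k + prec_{k-1})], each available in closed form from
    hypergeometric moments, so the whole computation is O(n log n).
    """
    labels = _check_classes(labels)
    scores = np.asarray(scores, dtype=float)
    P = int(labels.sum())
    total = 0.0
    for start, tp0, nb, pb in _tie_blocks(scores, labels):
        if pb == 0:
            continue
        j = np.arange(1, nb + 1, dtype=float)
        k = start + j  # global rank
        mu = (j - 1) * (pb - 1) / (nb - 1) if nb > 1 else np.zeros_like(j)
        term = (tp0 + 1 + mu) / k
        prev = np.empty_like(j)
        prev[1:] = (tp0 + mu[1:]) / (k[1:] - 1)
        prev[0] = (tp0 / start) if start > 0 else 0.0
        total += (pb / nb) * float(np.sum(term + prev))
    return total / (2.0 * P)


def aupr_monte_carlo(scores, labels, n_shuffles: int = 10000, seed: int = 0) -> float:
    """Monte-Carlo estimate of the tie expectation (cross-check path)."""
    labels = _check_classes(labels)
    scores = np.asarray(scores, dtype=float)
    rng = np.random.default_rng(seed)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order].astype(float)
    blocks = [
        (a, a + nb) for a, _, nb, _ in _tie_blocks(s, y.astype(bool))
    ]
    acc = 0.0
    yy = y.copy()
    for _ in range(n_shuffles):
        for a, b in blocks:
            if b - a > 1:
                yy[a:b] = rng.permutation(yy[a:b])
        acc += aupr_of_ordering(yy)
    return acc / n_shuffles


def pearson_score(predicted_delta, observed_delta) -> float:
    """Pearson correlation between predicted and observed DAS28 improvement."""
    x = np.asarray(predicted_delta, dtype=float)
    y = np.asarray(observed_delta, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need aligned vectors of length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in scores")
    return float(pearsonr(x, y).statistic)


def rank_submissions(reports: list[ScoreReport]) -> list[ScoreReport]:
    """Overall rank = mean of the AUPR rank and the AUROC rank (descending,
    average rank on ties). Mutates and returns the reports."""
    if not reports:
        raise ValueError("no reports to rank")
    aupr = np.array([r.aupr for r in reports], dtype=float)
    auroc = np.array([r.auroc for r in reports], dtype=float)
    r_aupr = rankdata(-aupr, method="average")
    r_auroc = rankdata(-auroc, method="average")
    for rep, ra, rc in zip(reports, r_aupr, r_auroc):
        rep.rank_aupr = float(ra)
        rep.rank_auroc = float(rc)
        rep.overall_rank = float((ra + rc) / 2.0)
    return reports


def permutation_pvalue(
    metric_fn, scores, labels, n_perm: int = 10000, seed: int = 0
) -> float:
    """One-sided permutation p: (1 + #{permuted >= observed}) / (n_perm + 1).

    Labels (or observed improvements) are permuted against the fixed scores.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = metric_fn(scores, labels)
    hits = 0
    for _ in range(n_perm):
        if metric_fn(scores, rng.permutation(labels)) >= observed:
            hits += 1
    return (1 + hits) / (n_perm + 1)


def bonferroni(p_values, m: int, alpha: float = 0.05) -> np.ndarray:
    """Significance calls at family-wise level ``alpha`` over ``m`` tests."""
    p = np.asarray(p_values, dtype=float)
    if m < len(p):
        raise ValueError("m must cover the number of tests")
    return p <= alpha / m


def score_submissions(
    submissions: list[Submission],
    label_table,
    subchallenge: str = "classification",
    n_perm: int = 10000,
    seed: int = 0,
) -> list[ScoreReport]:
    """Score a set of submissions against a label table.

    ``label_table`` is a DataFrame with ``subject_id`` plus ``nonresponse``
    (classification) or ``delta_das28`` (quantitative). Classification
    reports carry tie-aware AUPR/AUROC, ranks and the AUROC permutation p
    with a Bonferroni call across the submission set; quantitative reports
    carry the Pearson correlation.
    """
    ids = list(label_table["subject_id"])
    reports = []
    if subchallenge == "classification":
        y = label_table["nonresponse"].to_numpy(bool)
        for i, sub in enumerate(submissions):
            s = sub.aligned_scores(ids)
            rep = ScoreReport(
                team=sub.team,
                aupr=tie_aware_aupr(s, y),
                auroc=tie_aware_auroc(s, y),
                permutation_p=permutation_pvalue(
                    tie_aware_auroc, s, y, n_perm=n_perm, seed=seed + i
                ),
            )
            reports.append(rep)
        rank_submissions(reports)
        calls = bonferroni([r.permutation_p for r in reports], m=len(reports))
        for rep, c in zip(reports, calls):
            rep.bonferroni_significant = bool(c)
    elif subchallenge == "quantitative":
        y = label_table["delta_das28"].to_numpy(float)
        for i, sub in enumerate(submissions):
            s = sub.aligned_scores(ids)
            rep = ScoreReport(
                team=sub.team,
                pearson_r=pearson_score(s, y),
                permutation_p=permutation_pvalue(
                    lambda a, b: pearson_score(a, b), s, y, n_perm=n_perm, seed=seed + i
                ),
            )
            reports.append(rep)
        calls = bonferroni([r.permutation_p for r in reports], m=len(reports))
        for rep, c in zip(reports, calls):
            rep.bonferroni_significant = bool(c)
    else:
        raise ValueError("subchallenge must be 'classification' or 'quantitative'")
    return reports
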