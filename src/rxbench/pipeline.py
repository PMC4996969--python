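"""End-to-end synthetic study orchestration and submission validation.

``run_study`` composes the full benchmark on synthetic data: cohort
simulation (with the train/test prevalence shift), genotype QC, GRM/REML
heritability with liability conversion, the feasibility (power/AUROC)
summary, a panel of baseline "team" models with full (SNP + clinical) and
clinical-only variants, tie-aware scoring with permutation p-values,
bootstrap rank robustness, the random-SNP null experiment with KS
enrichment and its sensitivity bound, the paired full-vs-clinical
comparison (overall and per drug), and a stacked ensemble. Every stage
draws from an independently seeded stream keyed by the stage name.
"""

from __future__ import annotations

import dataclasses
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import models
from .cohort import (
    MAB_DRUGS,
    CohortConfig,
    GenotypeMatrix,
    assign_effects,
    simulate_das28,
    simulate_genotypes,
    _simulate_covariates,
)
from .heritability import compute_grm, reml_fit
from .power import (
    auroc_from_h2,
    min_h2_fraction_for_auroc,
)
from .qc import QcThresholds, apply_qc
from .robustness import (
    bootstrap_scores,
    ks_uniform_enrichment,
    paired_comparison_by_subset,
    paired_model_comparison,
    random_feature_null,
    robustly_better,
)
from .scoring import Submission, score_submissions, tie_aware_aupr, tie_aware_auroc
from .ensemble import stack
from .utils import stage_rng

__all__ = ["PipelineConfig", "validate_submission", "run_study", "simulate_challenge_cohort"]


@dataclass
class PipelineConfig:
    """Study configuration. The "challenge" preset carries the full-scale
    defaults (2031/675/591 cohorts, K = 0.217 vs 0.357, B = 1000, 100 null
    draws); the default instance is desk-scale."""

    n_train: int = 400
    n_leaderboard: int = 120
    n_test: int = 240
    n_snps: int = 600
    n_causal: int = 10
    h2_liability: float = 0.354
    prevalence_train: float = 0.217
    prevalence_test: float = 0.357
    maf_range: tuple[float, float] = (0.01, 0.5)
    missing_rate: float = 0.0
    qc: QcThresholds = field(default_factory=QcThresholds)
    n_teams: int = 5
    k_features: int = 10
    n_bootstrap: int = 200
    n_perm: int = 200
    n_null_draws: int = 30
    ensemble_loo_n: int = 120
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if min(self.n_train, self.n_test) < 20:
            raise ValueError("cohorts too small for the study stages")
        if self.n_teams < 3:
            raise ValueError("need >= 3 teams for paired inference")
        if not 0 < self.prevalence_train < 1 or not 0 < self.prevalence_test < 1:
            raise ValueError("prevalences must be in (0, 1)")

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(d["maf_range"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "qc" in d and isinstance(d["qc"], dict):
            d["qc"] = QcThresholds(**d["qc"])
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    @classmethod
    def preset(cls, name: str, seed: int = 0) -> "PipelineConfig":
        if name == "challenge":
            return cls(
                n_train=2031,
                n_leaderboard=675,
                n_test=591,
                n_snps=5000,
                n_causal=20,
                h2_liability=0.354,
                prevalence_train=0.217,
                prevalence_test=0.357,
                n_teams=7,
                k_features=50,
                n_bootstrap=1000,
                n_perm=10000,
                n_null_draws=100,
                ensemble_loo_n=300,
                seed=seed,
            )
        if name == "smoke":
            return cls(seed=seed)
        raise ValueError(f"unknown preset {name!r}")


def validate_submission(submission, label_table) -> list[str]:
    """Machine-readable validation of a submission against the label table.

    ``submission`` may be a file path or a :class:`Submission`. Checks id
    set equality, duplicates, and finite numeric scores; returns a list of
    error strings (empty when valid).
    """
    errors: list[str] = []
    if not isinstance(submission, Submission):
        try:
            df = pd.read_csv(
                submission, sep="\t", header=None, names=["subject_id", "score"]
            )
        except Exception as exc:  # noqa: BLE001
            return [f"unreadable submission file: {exc}"]
        ids = list(df["subject_id"].astype(str))
        scores = pd.to_numeric(df["score"], errors="coerce").to_numpy()
        for line, v in enumerate(scores, start=1):
            if not np.isfinite(v):
                errors.append(f"line {line}: non-numeric or missing score")
    else:
        ids = list(submission.subject_ids)
        scores = submission.scores

    seen = set()
    for line, sid in enumerate(ids, start=1):
        if sid in seen:
            errors.append(f"line {line}: duplicated subject id {sid!r}")
        seen.add(sid)
    expected = set(label_table["subject_id"].astype(str))
    extra = sorted(seen - expected)
    missing = sorted(expected - seen)
    errors.extend(f"unknown subject id {sid!r}" for sid in extra)
    if missing:
        errors.append(f"{len(missing)} label-table subjects absent from submission")
    return errors


def simulate_challenge_cohort(
    config: PipelineConfig,
) -> tuple[GenotypeMatrix, pd.DataFrame, np.ndarray]:
    """Two-cohort challenge layout with a shared causal architecture.

    Genotypes for all subjects share SNP frequencies and causal effects;
    non-response labels are thresholded per cohort so the discovery cohort
    has exactly its prevalence and the test cohort its (higher) one.
    """
    n_disc = config.n_train + config.n_leaderboard
    n_all = n_disc + config.n_test
    ccfg = CohortConfig(
        n_subjects=n_all,
        n_snps=config.n_snps,
        maf_range=config.maf_range,
        n_causal=config.n_causal,
        h2_liability=config.h2_liability,
        prevalence_K=config.prevalence_train,
        missing_rate=config.missing_rate,
        seed=int(stage_rng(config.seed, "cohort").integers(2**31)),
    )
    genotypes = simulate_genotypes(ccfg)
    rng = stage_rng(config.seed, "cohort-outcome")
    effects = assign_effects(genotypes, ccfg.n_causal, ccfg.h2_liability, rng)
    p = genotypes.allele_freqs
    dos = np.where(np.isnan(genotypes.dosages), 2.0 * p, genotypes.dosages)
    score = (dos - 2.0 * p) @ effects
    h2 = min(float(np.sum(2 * p * (1 - p) * effects**2)), 1 - 1e-12)
    liab = score + rng.normal(0.0, np.sqrt(1.0 - h2), n_all)

    labels = np.zeros(n_all, dtype=bool)
    for rows, K in (
        (np.arange(n_disc), config.prevalence_train),
        (np.arange(n_disc, n_all), config.prevalence_test),
    ):
        n_cases = int(round(K * len(rows)))
        order = rows[np.argsort(-liab[rows], kind="stable")]
        labels[order[:n_cases]] = True

    covariates = _simulate_covariates(ccfg, rng)
    table = simulate_das28(labels, liab, covariates, rng)
    split = np.full(n_all, "test", dtype=object)
    disc_order = rng.permutation(n_disc)
    split[disc_order[: config.n_train]] = "train"
    split[disc_order[config.n_train :]] = "leaderboard"
    table["split"] = split
    table["liability"] = liab
    return genotypes, table, effects


def run_study(config: PipelineConfig) -> dict:
    """Run the full synthetic study; returns (and optionally writes) a
    JSON-serializable report. Reproducible bit-for-bit from config + seed."""
    report: dict = {"config": config.to_dict(), "stages": {}}

    def log(stage, t0, **extra):
        report["stages"][stage] = {"wall_s": round(time.perf_counter() - t0, 3), **extra}

    # --- simulate -------------------------------------------------------
    t0 = time.perf_counter()
    genotypes, table, effects = simulate_challenge_cohort(config)
    log("simulate", t0, n_subjects=genotypes.n_subjects, n_snps=genotypes.n_snps)

    # --- qc -------------------------------------------------------------
    t0 = time.perf_counter()
    genotypes, qc_report = apply_qc(genotypes, config.qc)
    keep_ids = set(genotypes.subject_ids)
    keep_mask = table["subject_id"].isin(keep_ids).to_numpy()
    table = table.loc[keep_mask].reset_index(drop=True)
    report["qc"] = qc_report.to_dict()
    log("qc", t0)

    train_rows = np.flatnonzero((table["split"] == "train").to_numpy())
    test_rows = np.flatnonzero((table["split"] == "test").to_numpy())
    y_test = table["nonresponse"].to_numpy(bool)[test_rows]

    # --- heritability ---------------------------------------------------
    t0 = time.perf_counter()
    grm = compute_grm(
        GenotypeMatrix(
            genotypes.dosages[train_rows],
            genotypes.snp_ids,
            genotypes.allele_freqs,
            [genotypes.subject_ids[i] for i in train_rows],
        )
    )
    vc = reml_fit(
        grm,
        table["nonresponse"].to_numpy(float)[train_rows],
        covariates=models.clinical_design(table.iloc[train_rows]),
        K=config.prevalence_train,
    )
    report["heritability"] = {
        "h2_obs": vc.h2_obs,
        "h2_liability": vc.h2_liability,
        "lrt_p": vc.lrt_p,
        "n_snps": grm.n_snps_used,
    }
    log("heritability", t0)

    # --- feasibility ----------------------------------------------------
    t0 = time.perf_counter()
    h2_for_theory = max(vc.h2_liability, 1e-6)
    feasibility = {
        "max_auroc_genetic": auroc_from_h2(min(h2_for_theory, 1.0), config.prevalence_train),
    }
    try:
        feasibility["min_fraction_for_auroc_075"] = min_h2_fraction_for_auroc(
            vc.h2_obs, config.prevalence_train, 0.75
        )
    except ValueError:
        feasibility["min_fraction_for_auroc_075"] = None  # not achievable
    report["feasibility"] = feasibility
    log("feasibility", t0)

    # --- team models ----------------------------------------------------
    t0 = time.perf_counter()
    rng_teams = stage_rng(config.seed, "teams")
    ids_test = [table["subject_id"].iloc[i] for i in test_rows]
    k_grid = np.maximum(
        2, np.round(config.k_features * 2.0 ** np.arange(config.n_teams) / 4).astype(int)
    )
    c_grid = 10.0 ** np.linspace(-1, 1, config.n_teams)
    full_subs: dict[str, Submission] = {}
    clin_subs: dict[str, Submission] = {}
    team_feats: dict[str, np.ndarray] = {}
    for t in range(config.n_teams):
        team = f"team{t + 1}"
        k = int(min(k_grid[t], genotypes.n_snps))
        # each team screens its own random half of the genome (decorrelates
        # SNP-selection noise across teams); only significance-passing SNPs
        # enter the model
        pool = rng_teams.choice(
            genotypes.n_snps, size=max(k, genotypes.n_snps // 2), replace=False
        )
        pool_set = set(pool.tolist())
        scr = models.screened_snps(
            genotypes, table, train_rows, genotypes.n_snps, alpha=1e-3
        )
        feats = np.array([s for s in scr if s in pool_set][:k], dtype=int)
        team_feats[team] = feats
        full = models.fit_classifier(
            genotypes, table, train_rows, test_rows, snp_idx=feats, C=float(c_grid[t])
        )
        clin = models.fit_classifier(
            genotypes, table, train_rows, test_rows, snp_idx=None, C=float(c_grid[t])
        )
        full_subs[team] = Submission(ids_test, full, team=team)
        clin_subs[team] = Submission(ids_test, clin, team=f"{team}-clinical")
    log("teams", t0, n_teams=config.n_teams)

    label_test = table.iloc[test_rows][["subject_id", "nonresponse"]]

    # --- scoring --------------------------------------------------------
    t0 = time.perf_counter()
    reports = score_submissions(
        list(full_subs.values()),
        label_test,
        n_perm=config.n_perm,
        seed=int(stage_rng(config.seed, "score").integers(2**31)),
    )
    report["scores"] = [dataclasses.asdict(r) for r in reports]
    log("score", t0)

    # --- bootstrap ------------------------------------------------------
    t0 = time.perf_counter()
    boot = bootstrap_scores(
        list(full_subs.values()),
        label_test,
        B=config.n_bootstrap,
        seed=int(stage_rng(config.seed, "bootstrap").integers(2**31)),
    )
    order = np.argsort([r.overall_rank for r in reports])
    decision, wp = robustly_better(boot, int(order[0]), int(order[1]), metric="auroc")
    report["bootstrap"] = {
        "B": boot.B,
        "top_team": reports[order[0]].team,
        "second_team": reports[order[1]].team,
        "top_robustly_better": decision,
        "wilcoxon_p": wp,
        "mean_rank": boot.overall_rank.mean(axis=0).tolist(),
    }
    log("bootstrap", t0)

    # --- random-feature null -------------------------------------------
    t0 = time.perf_counter()
    null_seed = stage_rng(config.seed, "nullexp")
    null_ps = []
    nulls = {}
    for team in full_subs:
        feats = team_feats[team]
        fas = models.make_fit_and_score(
            genotypes, table, train_rows, test_rows, tie_aware_auroc
        )
        observed = tie_aware_auroc(full_subs[team].aligned_scores(ids_test), y_test)
        exp = random_feature_null(
            fas,
            np.arange(genotypes.n_snps),
            k=len(feats),
            observed_score=observed,
            n_draws=config.n_null_draws,
            seed=int(null_seed.integers(2**31)),
        )
        nulls[team] = {
            "empirical_p": exp.empirical_p,
            "p_upper": exp.p_upper,
            "observed": exp.observed_score,
            "null_mean": float(exp.null_scores.mean()),
        }
        null_ps.append(exp.empirical_p)
    report["null_experiment"] = {
        "per_team": nulls,
        "ks_enrichment_p": ks_uniform_enrichment(null_ps),
        "ks_enrichment_p_at_upper_bound": ks_uniform_enrichment(
            [min(1.0, nulls[t]["p_upper"]) for t in nulls]
        ),
    }
    log("nullexp", t0)

    # --- paired full vs clinical ---------------------------------------
    t0 = time.perf_counter()
    paired = {}
    for metric, fn in (("aupr", tie_aware_aupr), ("auroc", tie_aware_auroc)):
        fv = {
            t: fn(full_subs[t].aligned_scores(ids_test), y_test) for t in full_subs
        }
        cv = {
            t: fn(clin_subs[t].aligned_scores(ids_test), y_test) for t in full_subs
        }
        paired[metric] = {
            "p": paired_model_comparison(fv, cv),
            "mean_delta": float(np.mean([fv[t] - cv[t] for t in full_subs])),
        }
    drugs = table["drug"].iloc[test_rows].to_numpy()
    subsets = {d: drugs == d for d in np.unique(drugs)}
    subsets["MAB"] = np.isin(drugs, MAB_DRUGS)
    paired["per_drug_aupr"] = paired_comparison_by_subset(
        full_subs, {t: clin_subs[t] for t in full_subs}, label_test, subsets, "aupr"
    )
    report["paired_comparison"] = paired
    log("paired", t0)

    # --- ensemble -------------------------------------------------------
    t0 = time.perf_counter()
    rng_ens = stage_rng(config.seed, "ensemble")
    loo_n = min(config.ensemble_loo_n, len(train_rows))
    loo_rows = np.sort(rng_ens.choice(train_rows, size=loo_n, replace=False))
    y_loo = table["nonresponse"].to_numpy(bool)[loo_rows]
    base_train = np.empty((loo_n, config.n_teams))
    base_test = np.empty((len(test_rows), config.n_teams))
    for t_idx, team in enumerate(full_subs):
        feats = team_feats[team]
        for i in range(loo_n):
            keep = np.delete(loo_rows, i)
            base_train[i, t_idx] = models.fit_classifier(
                genotypes, table, keep, loo_rows[i : i + 1], snp_idx=feats
            )[0]
        base_test[:, t_idx] = full_subs[team].aligned_scores(ids_test)
    ens_scores = stack(base_train, y_loo, base_test, normalization="zscore", meta="nb_kde")
    report["ensemble"] = {
        "auroc": tie_aware_auroc(ens_scores, y_test),
        "best_base_auroc": float(max(r.auroc for r in reports)),
        "n_loo": loo_n,
    }
    log("ensemble", t0)

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "study_report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
        config.to_yaml(out / "config.yaml")
    return report
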