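"""Genotype quality control: missingness, MAF and Hardy-Weinberg filters."""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import chi2

from .cohort import GenotypeMatrix

__all__ = ["QcThresholds", "QcReport", "hwe_test", "apply_qc"]


@dataclass
class QcThresholds:
    """Default thresholds mirror a standard pre-imputation pipeline:
    drop subjects with >5% missing calls, SNPs with >1% missing calls,
    MAF < 1%, or HWE chi-square p < 1e-5."""

    max_subject_missing: float = 0.05
    max_snp_missing: float = 0.01
    min_maf: float = 0.01
    hwe_alpha: float = 1e-5

    def __post_init__(self) -> None:
        for name in ("max_subject_missing", "max_snp_missing", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


@dataclass
class QcReport:
    n_subjects_in: int
    n_snps_in: int
    subjects_removed_missing: int = 0
    snps_removed_missing: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0
    removed_subject_ids: list = field(default_factory=list)
    removed_snp_ids: dict = field(default_factory=dict)

    @property
    def n_subjects_out(self) -> int:
        return self.n_subjects_in - self.subjects_removed_missing

    @property
    def n_snps_out(self) -> int:
        return (
            self.n_snps_in
            - self.snps_removed_missing
            - self.snps_removed_maf
            - self.snps_removed_hwe
        )

    def to_dict(self) -> dict:
        return {
            "n_subjects_in": self.n_subjects_in,
            "n_snps_in": self.n_snps_in,
            "subjects_removed_missing": self.subjects_removed_missing,
            "snps_removed_missing": self.snps_removed_missing,
            "snps_removed_maf": self.snps_removed_maf,
            "snps_removed_hwe": self.snps_removed_hwe,
            "n_subjects_out": self.n_subjects_out,
            "n_snps_out": self.n_snps_out,
        }


def hwe_test(n_AA: int, n_Aa: int, n_aa: int) -> tuple[float, float]:
    """1-df chi-square of observed genotype counts against HWE proportions.

    Expected counts use the sample allele frequency. A monomorphic SNP is in
    trivial equilibrium: statistic 0, p 1.
    """
    counts = np.array([n_AA, n_Aa, n_aa], dtype=float)
    if np.any(counts < 0):
        raise ValueError("genotype counts must be non-negative")
    n = counts.sum()
    if n <= 0:
        raise ValueError("at least one genotype observation required")
    p = (2 * counts[2] + counts[1]) / (2 * n)  # frequency of the 'a' allele
    if p in (0.0, 1.0):
        return 0.0, 1.0
    expected = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    stat = float(np.sum((counts - expected) ** 2 / expected))
    return stat, float(chi2.sf(stat, df=1))


def _snp_stats(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (maf, hwe_p) on the non-missing hard calls."""
    n_snps = dosages.shape[1]
    maf = np.zeros(n_snps)
    hwe_p = np.ones(n_snps)
    for j in range(n_snps):
        col = dosages[:, j]
        col = col[~np.isnan(col)]
        if col.size == 0:
            continue
        counts = np.bincount(np.rint(col).astype(int), minlength=3)[:3]
        freq = (2 * counts[2] + counts[1]) / (2 * counts.sum())
        maf[j] = min(freq, 1 - freq)
        _, hwe_p[j] = hwe_test(*counts)
    return maf, hwe_p


def apply_qc(
    genotypes: GenotypeMatrix, thresholds: QcThresholds | None = None
) -> tuple[GenotypeMatrix, QcReport]:
    """Filter subjects then SNPs: subject missingness -> SNP missingness ->
    MAF -> HWE, with MAF and HWE computed on the post-missingness calls.

    Because each removal changes the denominators of the remaining
    missingness fractions, the four rules are swept in order until a fixed
    point, which makes the operation idempotent.
    """
    thr = thresholds or QcThresholds()
    report = QcReport(genotypes.n_subjects, genotypes.n_snps)
    dosages = genotypes.dosages
    subject_ids = list(genotypes.subject_ids)
    snp_ids = list(genotypes.snp_ids)
    report.removed_snp_ids = {"missing": [], "maf": [], "hwe": []}

    changed = True
    while changed:
        changed = False

        if dosages.shape[1]:
            subj_missing = np.isnan(dosages).mean(axis=1)
        else:
            subj_missing = np.zeros(dosages.shape[0])
        keep_subj = subj_missing <= thr.max_subject_missing
        if not keep_subj.all():
            changed = True
            report.subjects_removed_missing += int((~keep_subj).sum())
            report.removed_subject_ids += [
                sid for sid, k in zip(subject_ids, keep_subj) if not k
            ]
            subject_ids = [sid for sid, k in zip(subject_ids, keep_subj) if k]
            dosages = dosages[keep_subj]

        if dosages.shape[0]:
            snp_missing = np.isnan(dosages).mean(axis=0)
        else:
            snp_missing = np.ones(dosages.shape[1])
        keep = snp_missing <= thr.max_snp_missing
        report.removed_snp_ids["missing"] += [
            s for s, k in zip(snp_ids, keep) if not k
        ]
        report.snps_removed_missing += int((~keep).sum())

        maf, hwe_p = _snp_stats(dosages)
        maf_fail = keep & (maf < thr.min_maf)
        report.snps_removed_maf += int(maf_fail.sum())
        report.removed_snp_ids["maf"] += [s for s, f in zip(snp_ids, maf_fail) if f]
        keep &= ~maf_fail

        hwe_fail = keep & (hwe_p < thr.hwe_alpha)
        report.snps_removed_hwe += int(hwe_fail.sum())
        report.removed_snp_ids["hwe"] += [s for s, f in zip(snp_ids, hwe_fail) if f]
        keep &= ~hwe_fail

        if not keep.all():
            changed = True
            snp_ids = [s for s, k in zip(snp_ids, keep) if k]
            dosages = dosages[:, keep]

    if dosages.size == 0:
        warnings.warn("all genotypes removed by QC", stacklevel=2)
        freqs = np.zeros(dosages.shape[1])
    else:
        with np.errstate(invalid="ignore"):
            freqs = np.nanmean(dosages, axis=0) / 2.0
        freqs = np.where(np.isnan(freqs), 0.0, freqs)
    return GenotypeMatrix(dosages, snp_ids, freqs, subject_ids), report
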