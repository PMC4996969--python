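"""Plain-text interchange formats.

Genotypes travel as a tab-separated dosage matrix (header row of SNP ids,
first column the subject id, missing calls as "NA"); phenotypes as a
tab-separated table with one row per subject; submissions as two-column
(subject_id, score) files; GRMs as a lower-triangle (i, j, n_snps, value)
text file with a companion id list.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix
from .heritability import Grm
from .scoring import Submission

__all__ = [
    "write_genotypes",
    "read_genotypes",
    "write_cohort_table",
    "read_cohort_table",
    "read_submission",
    "write_submission",
    "write_grm",
    "read_grm",
]


def write_genotypes(genotypes: GenotypeMatrix, path: str | Path) -> None:
    df = pd.DataFrame(
        genotypes.dosages, index=genotypes.subject_ids, columns=genotypes.snp_ids
    )
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%g")


def read_genotypes(path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    dosages = df.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        freqs = np.nanmean(dosages, axis=0) / 2.0
    freqs = np.where(np.isnan(freqs), 0.0, freqs)
    return GenotypeMatrix(dosages, list(df.columns), freqs, list(df.index.astype(str)))


def write_cohort_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_cohort_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "nonresponse" in df:
        df["nonresponse"] = df["nonresponse"].astype(bool)
    return df


def read_submission(
    path: str | Path, team: str | None = None, subchallenge: str = "classification"
) -> Submission:
    df = pd.read_csv(path, sep="\t", header=None, names=["subject_id", "score"])
    return Submission(
        subject_ids=list(df["subject_id"].astype(str)),
        scores=df["score"].to_numpy(float),
        team=team or Path(path).stem,
        subchallenge=subchallenge,
    )


def write_submission(sub: Submission, path: str | Path) -> None:
    pd.DataFrame({"subject_id": sub.subject_ids, "score": sub.scores}).to_csv(
        path, sep="\t", header=False, index=False
    )


def write_grm(grm: Grm, subject_ids: list[str], prefix: str | Path) -> None:
    """Lower-triangle text GRM (``<prefix>.grm.txt``) plus id list
    (``<prefix>.grm.id``)."""
    prefix = Path(prefix)
    n = grm.n_subjects
    rows = []
    for i in range(n):
        for j in range(i + 1):
            rows.append((i + 1, j + 1, grm.n_snps_used, grm.matrix[i, j]))
    pd.DataFrame(rows).to_csv(
        prefix.with_suffix(".grm.txt"), sep="\t", header=False, index=False
    )
    pd.Series(subject_ids).to_csv(
        prefix.with_suffix(".grm.id"), sep="\t", header=False, index=False
    )


def read_grm(prefix: str | Path) -> tuple[Grm, list[str]]:
    prefix = Path(prefix)
    df = pd.read_csv(
        prefix.with_suffix(".grm.txt"),
        sep="\t",
        header=None,
        names=["i", "j", "m", "value"],
    )
    ids = list(
        pd.read_csv(prefix.with_suffix(".grm.id"), sep="\t", header=None)[0].astype(str)
    )
    n = int(df["i"].max())
    A = np.zeros((n, n))
    A[df["i"] - 1, df["j"] - 1] = df["value"]
    A = A + A.T - np.diag(np.diag(A))
    return Grm(A, int(df["m"].iloc[0])), ids
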