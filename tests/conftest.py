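import numpy as np
import pytest

from rxbench.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Shared desk-scale cohort with real genetic signal."""
    cfg = CohortConfig(
        n_subjects=400,
        n_snps=300,
        n_causal=10,
        h2_liability=0.4,
        prevalence_K=0.217,
        seed=7,
    )
    genotypes, table, effects = generate_cohort(cfg)
    return cfg, genotypes, table, effects


def enumerate_tie_orderings(scores, labels):
    """All distinguishable label orderings consistent with the scores."""
    from itertools import permutations

    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    seen = set()
    out = []
    for perm in permutations(range(len(s))):
        if tuple(s[list(perm)]) != tuple(s):
            continue  # must keep scores in descending order
        key = tuple(y[list(perm)])
        if key not in seen:
            seen.add(key)
            out.append(np.array(key))
    return out
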