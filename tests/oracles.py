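"""Independent brute-force oracles used only by the tests.

Everything here enumerates node subsets directly with itertools, never
touching the package's probability code, so agreement is a genuine
cross-check rather than a tautology.
"""

from itertools import combinations
from math import comb

import numpy as np


def brute_pmf(n: int, m: int, N: int, M: int) -> float:
    """P(observe m positives | n examined of N nodes, M involved) by
    enumerating every size-n subset of the node pool."""
    involved = set(range(M))
    hits = sum(1 for subset in combinations(range(N), n) if len(involved & set(subset)) == m)
    return hits / comb(N, n)


def brute_posterior(prior: np.ndarray, n: int, m: int, N: int) -> np.ndarray:
    """Posterior over the true involved count by enumerating the full joint
    (M, sampled subset) outcome space."""
    joint = np.zeros(N + 1)
    total_subsets = comb(N, n)
    for M in range(N + 1):
        if prior[M] == 0:
            continue
        involved = set(range(M))
        hits = sum(
            1 for subset in combinations(range(N), n) if len(involved & set(subset)) == m
        )
        joint[M] = prior[M] * hits / total_subsets
    assert joint.sum() > 0, "observation impossible under this prior"
    return joint / joint.sum()
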