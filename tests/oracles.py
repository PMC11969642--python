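"""Independent brute-force oracles used to cross-check the package.

These deliberately avoid the package's own code paths (and scipy's rankdata):
ranks are computed by explicit counting, permutations by exhaustive
enumeration.
"""

from __future__ import annotations

import itertools

import numpy as np


def midranks(values) -> list[float]:
    """Midranks by explicit counting (1-based)."""
    values = list(values)
    out = []
    for v in values:
        less = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(less + (equal + 1) / 2.0)
    return out


def brute_anosim_r(d: np.ndarray, labels) -> float:
    """ANOSIM R from first principles on a square dissimilarity matrix."""
    labels = list(labels)
    n = len(labels)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    vals = [d[i][j] for i, j in pairs]
    ranks = midranks(vals)
    within = [ranks[k] for k, (i, j) in enumerate(pairs)
              if labels[i] == labels[j]]
    between = [ranks[k] for k, (i, j) in enumerate(pairs)
               if labels[i] != labels[j]]
    r_w = sum(within) / len(within)
    r_b = sum(between) / len(between)
    c = n * (n - 1) / 4.0
    return (r_b - r_w) / c


def exhaustive_anosim_p(d: np.ndarray, labels) -> float:
    """Exact permutation p: fraction of distinct relabelings with R >= observed."""
    labels = list(labels)
    observed = brute_anosim_r(d, labels)
    seen = set(itertools.permutations(labels))
    n_ge = sum(1 for perm in seen
               if brute_anosim_r(d, perm) >= observed - 1e-12)
    return n_ge / len(seen)


def random_dissimilarity(n: int, rng: np.random.Generator) -> np.ndarray:
    """Random symmetric matrix with zero diagonal, values in (0, 100)."""
    d = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    d[iu] = rng.uniform(5.0, 95.0, size=len(iu[0]))
    return d + d.T
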