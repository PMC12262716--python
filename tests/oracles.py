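"""Independent brute-force oracles used to freeze expected values.

Everything here is deliberately naive — direct enumeration or closed-form
evaluation — and shares no code with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np


def entropy_by_hand(values) -> float:
    """H(X) = -sum p_i log p_i over empirical frequencies, natural log."""
    counts = Counter(values)
    n = sum(counts.values())
    return -sum((c / n) * math.log(c / n) for c in counts.values())


def pair_counting_ari(a, b) -> float:
    """Adjusted Rand index by direct enumeration of all observation pairs.

    Degenerate case (expected index equals maximum index): 1 if the two
    vectors induce the same set partition, else 0.
    """
    a, b = list(a), list(b)
    n = len(a)
    n11 = n_a = n_b = 0  # co-clustered in both / in a / in b
    for i, j in itertools.combinations(range(n), 2):
        sa, sb = a[i] == a[j], b[i] == b[j]
        n11 += sa and sb
        n_a += sa
        n_b += sb
    n_pairs = n * (n - 1) // 2
    expected = n_a * n_b / n_pairs
    maximum = (n_a + n_b) / 2
    if math.isclose(maximum, expected):
        part_a = frozenset(frozenset(i for i in range(n) if a[i] == v) for v in set(a))
        part_b = frozenset(frozenset(i for i in range(n) if b[i] == v) for v in set(b))
        return 1.0 if part_a == part_b else 0.0
    return (n11 - expected) / (maximum - expected)


def best_alignment_overlap(reference, other) -> int:
    """Maximum total overlap achievable by any bijective recoding of
    *other* onto the reference codes, by exhaustive permutation search."""
    reference = np.asarray(reference)
    other = np.asarray(other)
    size = max(int(reference.max()), int(other.max())) + 1
    conf = np.zeros((size, size), dtype=int)
    np.add.at(conf, (reference, other), 1)
    best = 0
    for perm in itertools.permutations(range(size)):
        best = max(best, sum(conf[perm[c], c] for c in range(size)))
    return best


def kmodes_optimum(X: np.ndarray, k: int) -> float:
    """Exact K-modes objective minimum by enumerating all k^N assignments."""
    n, m = X.shape
    best = math.inf
    for assign in itertools.product(range(k), repeat=n):
        a = np.asarray(assign)
        cost = 0
        for c in range(k):
            rows = X[a == c]
            if rows.shape[0] == 0:
                continue
            for j in range(m):
                cost += rows.shape[0] - np.bincount(rows[:, j]).max()
        if cost < best:
            best = cost
    return float(best)


def bernoulli_jsd_oracle(p: float, q: float) -> float:
    """Bernoulli JSD via the generic distribution-level JSD (scipy)."""
    from scipy.spatial.distance import jensenshannon

    return float(jensenshannon([p, 1 - p], [q, 1 - q], base=math.e) ** 2)


def grid_scan_resolutions(partitioner, target_k, lo, hi, seed=0, n=2000):
    """All grid resolutions achieving the target cluster count."""
    hits = []
    for r in np.linspace(lo, hi, n):
        labels = partitioner(float(r), seed)
        if len(np.unique(labels)) == target_k:
            hits.append(float(r))
    return hits
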