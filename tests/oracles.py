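"""Independent test oracles, deliberately kept separate from the package code.

- exhaustive enumeration of partial injective assignments,
- a naive multiplicative-domain semi-relaxed Sinkhorn reference,
- loop-based metric computations.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np


def enumerate_partial_assignments(m: int, n: int):
    """Yield every injective partial map as a tuple of (i, j) pairs."""
    for k in range(min(m, n) + 1):
        for rows in combinations(range(m), k):
            for cols in permutations(range(n), k):
                yield tuple(zip(rows, cols))


def enumerate_best_total(S: np.ndarray) -> tuple[float, tuple]:
    """Brute-force maximizer of the full gap-augmented objective.

    S is (m+1)×(n+1); unmatched rows/columns collect their gap entries.
    Returns (best full-objective total, a best pair tuple).
    """
    m, n = S.shape[0] - 1, S.shape[1] - 1
    best = -np.inf
    best_pairs = ()
    for pairs in enumerate_partial_assignments(m, n):
        used_i = {i for i, _ in pairs}
        used_j = {j for _, j in pairs}
        total = sum(S[i, j] for i, j in pairs)
        total += sum(S[i, n] for i in range(m) if i not in used_i)
        total += sum(S[m, j] for j in range(n) if j not in used_j)
        if total > best + 1e-12:
            best = total
            best_pairs = pairs
    return float(best), best_pairs


def full_objective(S: np.ndarray, pairs) -> float:
    """Full gap-augmented objective of a given pair set."""
    m, n = S.shape[0] - 1, S.shape[1] - 1
    used_i = {i for i, _ in pairs}
    used_j = {j for _, j in pairs}
    total = sum(S[i, j] for i, j in pairs)
    total += sum(S[i, n] for i in range(m) if i not in used_i)
    total += sum(S[m, j] for j in range(n) if j not in used_j)
    return float(total)


def reference_semi_relaxed_sinkhorn(C: np.ndarray, lam: float,
                                    iters: int = 200000, tol: float = 1e-10
                                    ) -> np.ndarray:
    """Multiplicative-domain reference: unit row marginals on rows 0..m-1,
    unit column marginals on cols 0..n-1, gap scalings frozen at 1,
    corner fixed at 1.  Independent of the package implementation."""
    m1, n1 = C.shape
    m, n = m1 - 1, n1 - 1
    K = np.exp(-lam * C)
    u = np.ones(m1)
    v = np.ones(n1)
    for _ in range(iters):
        u_old = u.copy()
        u[:m] = 1.0 / (K[:m, :] @ v)
        v[:n] = 1.0 / (u @ K[:, :n])
        if np.abs(u - u_old).max() / max(1.0, np.abs(u).max()) < tol:
            break
    P = u[:, None] * K * v[None, :]
    P[m, n] = 1.0
    return P


def naive_so(distances, threshold: float) -> float:
    """Loop-counting structure overlap (percent, inclusive boundary)."""
    ds = list(distances)
    if not ds:
        return 0.0
    count = 0
    for d in ds:
        if d <= threshold:
            count += 1
    return 100.0 * count / len(ds)


def longest_increasing_pairs(truth_map) -> int:
    """Max pairs any order-preserving alignment can share with a truth map.

    Equals the longest strictly increasing subsequence of the target
    positions when query indices are scanned in order.
    """
    seq = [j for _, j in sorted(truth_map)]
    tails: list[int] = []
    for x in seq:
        lo, hi = 0, len(tails)
        while lo < hi:
            mid = (lo + hi) // 2
            if tails[mid] < x:
                lo = mid + 1
            else:
                hi = mid
        if lo == len(tails):
            tails.append(x)
        else:
            tails[lo] = x
    return len(tails)


def random_similarity(rng: np.random.Generator, m: int, n: int,
                      gap: float = 0.0) -> np.ndarray:
    """U[0,1] interior similarities with constant gap borders, zero corner."""
    S = np.full((m + 1, n + 1), gap, dtype=float)
    S[:m, :n] = rng.uniform(0.0, 1.0, (m, n))
    S[m, n] = 0.0
    return S
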