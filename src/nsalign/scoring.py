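"""Similarity and cost matrices with gap states, and the SP-score.

The similarity matrix S is (m+1)×(n+1): interior cells score residue
pairs by a distance kernel with a hard cutoff at 2·d0, the last row and
column carry the gap score, and the gap-to-gap corner is 0.  The cost
matrix C is the non-negative dual transform of S used by the solver.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import DistanceTable


@dataclass
class SPParams:
    """SP-score parameters: scale factor alpha and fixed normalization d0 (Å)."""

    alpha: float = 0.3
    d0_sp: float = 4.0

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.d0_sp <= 0:
            raise ValueError("d0_sp must be positive")

    @property
    def cutoff(self) -> float:
        """Inclusion threshold 2·d0 (Å); pairs at or beyond it score 0."""
        return 2.0 * self.d0_sp


@dataclass
class SimilarityMatrix:
    """Gap-augmented (m+1)×(n+1) similarity matrix."""

    S: np.ndarray
    gap_score: float
    m: int
    n: int

    def __post_init__(self) -> None:
        self.S = np.asarray(self.S, dtype=float)
        if self.S.shape != (self.m + 1, self.n + 1):
            raise ValueError("S must be (m+1) x (n+1)")
        if (self.S < 0).any() or not np.all(np.isfinite(self.S)):
            raise ValueError("similarity entries must be finite and non-negative")
        if self.S[self.m, self.n] != 0.0:
            raise ValueError("gap-to-gap corner must be 0")


@dataclass
class CostMatrix:
    """Non-negative cost transform of a SimilarityMatrix.

    With c = max(S) + epsilon_shift and the gap-gap coefficient k fixed
    at 0: interior C = 2c − S, gap row/column C = c − S, corner 0.
    """

    C: np.ndarray
    c: float
    epsilon_shift: float
    k: float = 0.0

    def __post_init__(self) -> None:
        self.C = np.asarray(self.C, dtype=float)
        if (self.C < 0).any() or not np.all(np.isfinite(self.C)):
            raise ValueError("cost entries must be finite and non-negative")
        if self.C[-1, -1] != 0.0:
            raise ValueError("gap-to-gap corner cost must be 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.C.shape


def residue_similarity(d: float, params: SPParams | None = None) -> float:
    """Per-pair similarity 1/(1 + d²/d0²) − 0.2 for d < 2·d0, else 0."""
    if params is None:
        params = SPParams()
    if d < 0:
        raise ValueError("distance must be non-negative")
    if d >= params.cutoff:
        return 0.0
    return 1.0 / (1.0 + (d / params.d0_sp) ** 2) - 0.2


def _similarity_kernel(dist: np.ndarray, params: SPParams) -> np.ndarray:
    sim = 1.0 / (1.0 + (dist / params.d0_sp) ** 2) - 0.2
    return np.where(dist < params.cutoff, sim, 0.0)


def build_similarity_matrix(dist: DistanceTable, gap_score: float = 0.0,
                            params: SPParams | None = None) -> SimilarityMatrix:
    """Gap-augment the per-pair similarity kernel of a distance table."""
    if params is None:
        params = SPParams()
    if gap_score < 0:
        raise ValueError("gap_score must be non-negative")
    m, n = dist.shape
    s = np.zeros((m + 1, n + 1))
    s[:m, :n] = _similarity_kernel(dist.values, params)
    s[m, :n] = gap_score
    s[:m, n] = gap_score
    return SimilarityMatrix(s, gap_score, m, n)


def build_cost_matrix(sim: SimilarityMatrix, epsilon_shift: float = 0.5) -> CostMatrix:
    """Dual transform to a non-negative cost matrix (minimization form)."""
    if epsilon_shift <= 0:
        raise ValueError("epsilon_shift must be positive")
    m, n = sim.m, sim.n
    c = float(sim.S.max()) + epsilon_shift
    cost = np.empty((m + 1, n + 1))
    cost[:m, :n] = 2.0 * c - sim.S[:m, :n]
    cost[:m, n] = c - sim.S[:m, n]
    cost[m, :n] = c - sim.S[m, :n]
    cost[m, n] = 0.0
    return CostMatrix(cost, c, epsilon_shift)


def sp_score(distances, params: SPParams | None = None) -> float:
    """Size-independent superposition score over aligned pair distances.

    L counts the core pairs (d < 2·d0); the kernel sum over those pairs
    is normalized by L^(1−alpha).  Returns 0 when no pair is within the
    cutoff.
    """
    if params is None:
        params = SPParams()
    d = np.asarray(distances, dtype=float).ravel()
    if d.size == 0:
        return 0.0
    core = d[d < params.cutoff]
    if core.size == 0:
        return 0.0
    total = float(_similarity_kernel(core, params).sum())
    return total / core.size ** (1.0 - params.alpha)
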