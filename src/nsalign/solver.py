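"""Entropy-regularized partial assignment solver and alignment inference.

The correspondence problem is a partial linear sum assignment over a
gap-augmented (m+1)×(n+1) matrix: every real row/column must either
match a real partner or its gap state, and the gap-to-gap corner is
fixed.  The entropic relaxation is solved by a semi-relaxed Sinkhorn
iteration in the log domain (only the m real rows and n real columns
carry unit marginal constraints; the gap row/column scalings stay
frozen).  An exact LSAP-reduction oracle is provided alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import TMScoreParams, kabsch_superpose, pairwise_distances, tm_score
from .scoring import (
    CostMatrix,
    SimilarityMatrix,
    SPParams,
    build_cost_matrix,
    build_similarity_matrix,
    sp_score,
)
from .structio import ChainStructure, Superposition

logger = logging.getLogger(__name__)

# exact_plsap tie-breaking: prefer fewer pairs, then smaller indices
_PAIR_EPS = 1e-7
_IDX_EPS = 1e-10


@dataclass
class SolverParams:
    """Sinkhorn controls: sharpness lambda_entropy, tolerance, iteration cap."""

    lambda_entropy: float = 100.0
    tol: float = 1e-6
    tmax: int = 5000
    gap_modeling: bool = True

    def __post_init__(self) -> None:
        if self.lambda_entropy <= 0:
            raise ValueError("lambda_entropy must be positive")
        if self.tmax < 1:
            raise ValueError("tmax must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be positive")


@dataclass
class Coupling:
    """Gap-bi-stochastic matrix with its dual scaling vectors.

    ``P[i, j] = exp(-1/2 - dual_row[i]) * exp(-lam*C[i, j]) * exp(-1/2 - dual_col[j])``
    for constrained rows/columns; the corner is fixed at 1.
    """

    P: np.ndarray
    dual_row: np.ndarray
    dual_col: np.ndarray
    iterations_used: int
    converged: bool
    m: int
    n: int

    @property
    def entropy(self) -> float:
        """Σ P log P with 0·log 0 := 0."""
        p = self.P[self.P > 0]
        return float(np.sum(p * np.log(p)))


@dataclass
class AlignmentResult:
    """Injective partial residue correspondence (gap states never appear)."""

    pairs: list[tuple[int, int]]
    direction: str = "row"
    distances: np.ndarray | None = None
    total_similarity: float | None = None
    tm: float | None = None
    sp: float | None = None

    @property
    def nali(self) -> int:
        return len(self.pairs)


def _lse_axis1(a: np.ndarray) -> np.ndarray:
    """logsumexp over axis 1 (hand-rolled: called thousands of times)."""
    amax = a.max(axis=1)
    return amax + np.log(np.exp(a - amax[:, None]).sum(axis=1))


def _marginal_violation(p: np.ndarray, m: int, n: int) -> float:
    viol = 0.0
    if m:
        viol = float(np.abs(p[:m, :].sum(axis=1) - 1.0).max())
    if n:
        viol = max(viol, float(np.abs(p[:, :n].sum(axis=0) - 1.0).max()))
    return viol


def _sinkhorn_gapped(cost: np.ndarray, lam: float, tol: float, tmax: int):
    m1, n1 = cost.shape
    m, n = m1 - 1, n1 - 1
    k = -lam * cost
    kt = k[:, :n].T.copy()
    f = np.zeros(m1)  # log row scalings; gap row frozen at 0
    g = np.zeros(n1)  # log column scalings; gap column frozen at 0
    it = 0
    converged = False
    for it in range(1, tmax + 1):
        f_new = -_lse_axis1(k[:m, :] + g[None, :])
        df = float(np.abs(f_new - f[:m]).max()) if m else 0.0
        f[:m] = f_new
        g_new = -_lse_axis1(kt + f[None, :])
        dg = float(np.abs(g_new - g[:n]).max()) if n else 0.0
        g[:n] = g_new
        # dual changes bound the marginal violation; verify cheaply when small
        if max(df, dg) < tol:
            p = np.exp(f[:, None] + g[None, :] + k)
            p[m, n] = 1.0
            if _marginal_violation(p, m, n) < tol:
                converged = True
                break
    p = np.exp(f[:, None] + g[None, :] + k)
    p[m, n] = 1.0
    converged = converged or _marginal_violation(p, m, n) < tol
    return p, f, g, it, converged


def _sinkhorn_nogap(cost: np.ndarray, lam: float, tol: float, tmax: int):
    """Ablation: interior-only coupling, full marginals on the shorter side,
    at-most-one marginals on the longer side (no gap states)."""
    m1, n1 = cost.shape
    m, n = m1 - 1, n1 - 1
    inner = cost[:m, :n]
    transposed = m > n
    if transposed:
        inner = inner.T
    a, b = inner.shape  # a <= b
    k = -lam * inner
    kt = k.T.copy()
    f = np.zeros(a)
    g = np.zeros(b)
    it = 0
    converged = False

    def _viol(p: np.ndarray) -> float:
        v = float(np.abs(p.sum(axis=1) - 1.0).max())
        return max(v, float(np.maximum(p.sum(axis=0) - 1.0, 0.0).max()))

    for it in range(1, tmax + 1):
        f_new = -_lse_axis1(k + g[None, :])
        df = float(np.abs(f_new - f).max())
        f = f_new
        g_new = np.minimum(0.0, -_lse_axis1(kt + f[None, :]))
        dg = float(np.abs(g_new - g).max())
        g = g_new
        if max(df, dg) < tol and _viol(np.exp(f[:, None] + g[None, :] + k)) < tol:
            converged = True
            break
    p = np.exp(f[:, None] + g[None, :] + k)
    converged = converged or _viol(p) < tol
    if transposed:
        p = p.T
        f, g = g, f
    full = np.zeros((m1, n1))
    full[:m, :n] = p
    full[m, n] = 1.0
    return full, np.concatenate([f, [0.0]]), np.concatenate([g, [0.0]]), it, converged


def sinkhorn_partial(cost: CostMatrix, params: SolverParams | None = None) -> Coupling:
    """Solve the entropy-regularized partial assignment for a cost matrix.

    Returns the coupling and dual vectors; ``converged`` is False when the
    marginal violation is still above ``tol`` after ``tmax`` iterations
    (the best-effort coupling is returned regardless).
    """
    if params is None:
        params = SolverParams()
    c = np.asarray(cost.C, dtype=float)
    if not np.all(np.isfinite(c)):
        raise ValueError("cost matrix contains non-finite entries")
    m, n = c.shape[0] - 1, c.shape[1] - 1
    if params.gap_modeling:
        p, f, g, it, converged = _sinkhorn_gapped(c, params.lambda_entropy,
                                                  params.tol, params.tmax)
    else:
        p, f, g, it, converged = _sinkhorn_nogap(c, params.lambda_entropy,
                                                 params.tol, params.tmax)
    if not converged:
        logger.info("Sinkhorn did not reach tol=%g within %d iterations",
                    params.tol, params.tmax)
    # duals in the stationarity parameterization: f_i = -1/2 - a_i
    return Coupling(
        P=np.clip(p, 0.0, None),
        dual_row=-f[:m] - 0.5,
        dual_col=-g[:n] - 0.5,
        iterations_used=it,
        converged=converged,
        m=m,
        n=n,
    )


def infer_alignment(coupling: Coupling, direction: str = "row") -> AlignmentResult:
    """Read an injective correspondence off a coupling by row or column argmax.

    A residue whose argmax lands on the gap state is unaligned.  When
    several rows (columns) claim the same partner, the one with the
    largest coupling value keeps it (ties: smallest index).
    """
    p = coupling.P
    m, n = coupling.m, coupling.n
    if direction not in ("row", "col"):
        raise ValueError("direction must be 'row' or 'col'")
    best: dict[int, tuple[float, int]] = {}
    if direction == "row":
        choice = np.argmax(p[:m, :], axis=1)  # includes gap column n
        for i in range(m):
            j = int(choice[i])
            if j == n:
                continue
            v = float(p[i, j])
            if j not in best or v > best[j][0]:
                best[j] = (v, i)
        pairs = sorted((i, j) for j, (_, i) in best.items())
    else:
        choice = np.argmax(p[:, :n], axis=0)  # includes gap row m
        for j in range(n):
            i = int(choice[j])
            if i == m:
                continue
            v = float(p[i, j])
            if i not in best or v > best[i][0]:
                best[i] = (v, j)
        pairs = sorted((i, j) for i, (_, j) in best.items())
    return AlignmentResult(pairs=pairs, direction=direction)


def _rescored_tm(aln: AlignmentResult, query: ChainStructure, target: ChainStructure,
                 sup: Superposition) -> float:
    """TM-score of an alignment after Kabsch re-superposition on its own pairs."""
    if not aln.pairs:
        return 0.0
    qi = np.array([i for i, _ in aln.pairs])
    tj = np.array([j for _, j in aln.pairs])
    qc = query.coords[qi]
    tc = target.coords[tj]
    use = kabsch_superpose(qc, tc) if len(aln.pairs) >= 3 else sup
    d = np.linalg.norm(use.apply(qc) - tc, axis=1)
    return tm_score(d, TMScoreParams(min(len(query), len(target))))


def select_direction(row_aln: AlignmentResult, col_aln: AlignmentResult,
                     query: ChainStructure, target: ChainStructure,
                     sup: Superposition) -> AlignmentResult:
    """Keep whichever of the two inferred alignments re-superposes to a higher TM-score.

    Ties (including both empty) go to the row direction.
    """
    row_aln.tm = _rescored_tm(row_aln, query, target, sup)
    col_aln.tm = _rescored_tm(col_aln, query, target, sup)
    return col_aln if col_aln.tm > row_aln.tm else row_aln


def exact_plsap(sim: SimilarityMatrix) -> AlignmentResult:
    """Exact maximizer of the gap-augmented assignment objective.

    Reduces to a square (m+n)×(n+m) LSAP: real-real cells keep their
    similarity, each real row/column may only enter its own gap slot
    (scored by the gap entries), dummy-dummy cells are free.  Tiny
    penalties break ties toward fewer pairs, then smaller indices.
    """
    m, n = sim.m, sim.n
    s = sim.S
    size = m + n
    forbid = -1e9
    a = np.full((size, size), forbid)
    ii, jj = np.meshgrid(np.arange(m), np.arange(n), indexing="ij")
    codes = (ii * (n + 1) + jj) / ((m + 1) * (n + 1))
    a[:m, :n] = s[:m, :n] - _PAIR_EPS - _IDX_EPS * codes
    a[np.arange(m), n + np.arange(m)] = s[:m, n]
    a[m + np.arange(n), np.arange(n)] = s[m, :n]
    a[m:, n:] = 0.0
    rows, cols = linear_sum_assignment(a, maximize=True)
    pairs = sorted((int(i), int(j)) for i, j in zip(rows, cols) if i < m and j < n)
    total = float(sum(s[i, j] for i, j in pairs))
    return AlignmentResult(pairs=pairs, total_similarity=total)


def solve_from_superposition(query: ChainStructure, target: ChainStructure,
                             sup: Superposition,
                             sp_params: SPParams | None = None,
                             solver_params: SolverParams | None = None,
                             gap_score: float = 0.0,
                             epsilon_shift: float = 0.5,
                             direction: str = "auto") -> AlignmentResult:
    """Full pipeline for a fixed superposition.

    distances → similarity → cost → Sinkhorn → inference (row and column)
    → direction selection.  The returned distances and SP-score are
    measured under the input superposition; ``tm`` is the
    re-superposition TM-score used for direction selection.
    """
    if sp_params is None:
        sp_params = SPParams()
    if solver_params is None:
        solver_params = SolverParams()
    dist = pairwise_distances(query, target, sup)
    sim = build_similarity_matrix(dist, gap_score=gap_score, params=sp_params)
    cost = build_cost_matrix(sim, epsilon_shift=epsilon_shift)
    coupling = sinkhorn_partial(cost, solver_params)
    if direction == "auto":
        result = select_direction(infer_alignment(coupling, "row"),
                                  infer_alignment(coupling, "col"),
                                  query, target, sup)
    elif direction in ("row", "col"):
        result = infer_alignment(coupling, direction)
        result.tm = _rescored_tm(result, query, target, sup)
    else:
        raise ValueError("direction must be 'auto', 'row' or 'col'")
    if result.pairs:
        qi = np.array([i for i, _ in result.pairs])
        tj = np.array([j for _, j in result.pairs])
        result.distances = dist.values[qi, tj]
        result.total_similarity = float(sim.S[qi, tj].sum())
    else:
        result.distances = np.empty(0)
        result.total_similarity = 0.0
    result.sp = sp_score(result.distances, sp_params)
    return result
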