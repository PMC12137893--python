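"""Built-in rigid superposition seeding and alternating refinement.

A deliberately simple stand-in for external superposition engines:
gapless fragment pairs are Kabsch-superposed on a stride grid, ranked by
a greedy SP-score of the induced full-chain distance table, and the best
seeds are refined by alternating assignment and re-superposition.
For full fidelity to an external engine, import its matrix instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import kabsch_superpose, pairwise_distances
from .scoring import SPParams, sp_score
from .solver import AlignmentResult, SolverParams, solve_from_superposition
from .structio import ChainStructure, Superposition

logger = logging.getLogger(__name__)


@dataclass
class RefineParams:
    seed_window: int = 20
    seed_stride: int = 5
    max_rounds: int = 10
    keep_top: int = 5

    def __post_init__(self) -> None:
        if self.seed_window < 4:
            raise ValueError("seed_window must be >= 4")
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.seed_stride < 1:
            raise ValueError("seed_stride must be >= 1")
        if self.keep_top < 1:
            raise ValueError("keep_top must be >= 1")


def _greedy_sp(dist: np.ndarray, sp_params: SPParams) -> float:
    """SP-score of a greedy injective matching of a distance table.

    Pairs below the cutoff are accepted in ascending distance order while
    both residues are free; used only to rank candidate superpositions.
    """
    ii, jj = np.nonzero(dist < sp_params.cutoff)
    if ii.size == 0:
        return 0.0
    order = np.argsort(dist[ii, jj], kind="stable")
    used_i: set[int] = set()
    used_j: set[int] = set()
    kept: list[float] = []
    for k in order:
        i, j = int(ii[k]), int(jj[k])
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        kept.append(dist[i, j])
    return sp_score(np.array(kept), sp_params)


def seed_superpositions(query: ChainStructure, target: ChainStructure,
                        params: RefineParams | None = None,
                        sp_params: SPParams | None = None) -> list[Superposition]:
    """Fragment-pair Kabsch seeds ranked by greedy SP-score, best first."""
    if params is None:
        params = RefineParams()
    if sp_params is None:
        sp_params = SPParams()
    w = params.seed_window
    if len(query) < w or len(target) < w:
        # degenerate: single global gapless seed on the common prefix
        L = min(len(query), len(target))
        if L < 3:
            return [Superposition.identity()]
        return [kabsch_superpose(query.coords[:L], target.coords[:L])]
    scored: list[tuple[float, Superposition]] = []
    q_offsets = range(0, len(query) - w + 1, params.seed_stride)
    t_offsets = range(0, len(target) - w + 1, params.seed_stride)
    for qo in q_offsets:
        for to in t_offsets:
            sup = kabsch_superpose(query.coords[qo:qo + w], target.coords[to:to + w])
            dist = pairwise_distances(query, target, sup).values
            scored.append((_greedy_sp(dist, sp_params), sup))
    scored.sort(key=lambda t: -t[0])
    logger.info("ranked %d fragment seeds; best greedy SP %.4f",
                len(scored), scored[0][0])
    return [sup for _, sup in scored]


def refine_alternating(query: ChainStructure, target: ChainStructure,
                       initial: Superposition,
                       sp_params: SPParams | None = None,
                       solver_params: SolverParams | None = None,
                       params: RefineParams | None = None,
                       gap_score: float = 0.0,
                       epsilon_shift: float = 0.5,
                       direction: str = "auto") -> tuple[Superposition, AlignmentResult]:
    """Alternate assignment and Kabsch re-superposition to a fixed point.

    Each round solves the alignment under the current superposition, then
    re-fits the superposition on the resulting pairs and rescores the
    alignment under it.  Stops when the pair set repeats or after
    ``max_rounds``; returns the round with the highest SP-score.
    """
    if sp_params is None:
        sp_params = SPParams()
    if solver_params is None:
        solver_params = SolverParams()
    if params is None:
        params = RefineParams()
    sup = initial
    best: tuple[Superposition, AlignmentResult] | None = None
    seen: set[frozenset] = set()
    for rnd in range(params.max_rounds):
        res = solve_from_superposition(query, target, sup, sp_params, solver_params,
                                       gap_score=gap_score, epsilon_shift=epsilon_shift,
                                       direction=direction)
        if not res.pairs:
            break
        qi = np.array([i for i, _ in res.pairs])
        tj = np.array([j for _, j in res.pairs])
        if len(res.pairs) >= 3:
            sup = kabsch_superpose(query.coords[qi], target.coords[tj])
        res.distances = np.linalg.norm(sup.apply(query.coords[qi]) - target.coords[tj],
                                       axis=1)
        res.sp = sp_score(res.distances, sp_params)
        if best is None or res.sp > best[1].sp:
            best = (sup, res)
        key = frozenset(res.pairs)
        if key in seen:
            break
        seen.add(key)
    if best is None:
        empty = AlignmentResult(pairs=[], distances=np.empty(0),
                                total_similarity=0.0, tm=0.0, sp=0.0)
        return initial, empty
    return best


def auto_align(query: ChainStructure, target: ChainStructure,
               sp_params: SPParams | None = None,
               solver_params: SolverParams | None = None,
               params: RefineParams | None = None,
               gap_score: float = 0.0,
               epsilon_shift: float = 0.5,
               direction: str = "auto") -> tuple[Superposition, AlignmentResult]:
    """Seed, refine the top ``keep_top`` seeds, return the best by SP-score."""
    if params is None:
        params = RefineParams()
    seeds = seed_superpositions(query, target, params, sp_params)
    best: tuple[Superposition, AlignmentResult] | None = None
    for sup in seeds[:params.keep_top]:
        cand = refine_alternating(query, target, sup, sp_params, solver_params, params,
                                  gap_score=gap_score, epsilon_shift=epsilon_shift,
                                  direction=direction)
        if best is None or (cand[1].sp or 0.0) > (best[1].sp or 0.0):
            best = cand
    assert best is not None
    return best
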