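import math

import numpy as np
import pytest

from oracles import (
    enumerate_best_total,
    full_objective,
    random_similarity,
    reference_semi_relaxed_sinkhorn,
)
from nsalign.geometry import pairwise_distances
from nsalign.scoring import SimilarityMatrix, build_cost_matrix, build_similarity_matrix
from nsalign.solver import (
    AlignmentResult,
    Coupling,
    SolverParams,
    exact_plsap,
    infer_alignment,
    select_direction,
    sinkhorn_partial,
    solve_from_superposition,
)
from nsalign.structio import Superposition
from nsalign.synthetic import letter_problem, make_ground_truth_pair, make_helix_chain


def _coupling_from(p: np.ndarray) -> Coupling:
    m, n = p.shape[0] - 1, p.shape[1] - 1
    return Coupling(P=p, dual_row=np.zeros(m), dual_col=np.zeros(n),
                    iterations_used=1, converged=True, m=m, n=n)


def _check_feasible(coupling: Coupling, tol: float = 1e-6) -> None:
    p, m, n = coupling.P, coupling.m, coupling.n
    assert p.min() >= 0.0 and p.max() <= 1.0 + tol
    np.testing.assert_allclose(p[:m, :].sum(axis=1), 1.0, atol=tol)
    np.testing.assert_allclose(p[:, :n].sum(axis=0), 1.0, atol=tol)
    assert p[m, n] == 1.0


class TestSinkhornPartial:
    def test_1x1_closed_form(self):
        # S = [[1, 0], [0, 0]]: interior preferred; compare against the
        # analytic fixed point of the 1x1 semi-relaxed scaling equations.
        sim = SimilarityMatrix(np.array([[1.0, 0.0], [0.0, 0.0]]), 0.0, 1, 1)
        cost = build_cost_matrix(sim, 0.5)  # C = [[2, 1.5], [1.5, 0]]
        lam = 100.0
        coupling = sinkhorn_partial(cost, SolverParams(lambda_entropy=lam))
        k00, k01 = math.exp(-2 * lam), math.exp(-1.5 * lam)
        u = (-k01 + math.sqrt(k01 ** 2 + 4 * k00)) / (2 * k00)
        p00 = u * u * k00
        assert coupling.P[0, 0] > 0.99
        assert coupling.P[0, 0] == pytest.approx(p00, abs=1e-9)

    def test_symmetry_uniform_rows(self):
        # equal interior costs and equal gap costs: symmetry forces each
        # constrained row to spread uniformly over the interior alternatives
        s = np.zeros((3, 4))
        s[:2, :3] = 0.4
        s[2, :3] = 0.1
        s[:2, 3] = 0.1
        sim = SimilarityMatrix(s, 0.1, 2, 3)
        coupling = sinkhorn_partial(build_cost_matrix(sim), SolverParams())
        for i in range(2):
            row = coupling.P[i, :3]
            assert np.ptp(row) < 1e-6

    @pytest.mark.parametrize("lam", [10.0, 100.0])
    def test_against_reference_solver(self, rng, lam):
        s = random_similarity(rng, 5, 4)
        cost = build_cost_matrix(SimilarityMatrix(s, 0.0, 5, 4), 0.5)
        coupling = sinkhorn_partial(cost, SolverParams(lambda_entropy=lam,
                                                       tol=1e-9, tmax=200000))
        ref = reference_semi_relaxed_sinkhorn(cost.C, lam)
        np.testing.assert_allclose(coupling.P, ref, atol=1e-5)

    def test_feasibility_random_instances(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 10))
            n = int(rng.integers(2, 10))
            s = random_similarity(rng, m, n, gap=float(rng.uniform(0, 0.3)))
            cost = build_cost_matrix(SimilarityMatrix(s, float(s[m, 0]), m, n))
            coupling = sinkhorn_partial(cost, SolverParams())
            if coupling.converged:
                _check_feasible(coupling)

    def test_nonfinite_cost_rejected(self):
        sim = SimilarityMatrix(np.zeros((2, 2)), 0.0, 1, 1)
        cost = build_cost_matrix(sim)
        cost.C[0, 0] = np.inf
        with pytest.raises(ValueError):
            sinkhorn_partial(cost, SolverParams())

    def test_best_effort_on_tmax(self):
        sim = letter_problem("abedn", "ACDNB")
        coupling = sinkhorn_partial(build_cost_matrix(sim),
                                    SolverParams(tmax=5))
        assert not coupling.converged
        assert coupling.iterations_used == 5
        assert coupling.P.shape == (6, 6)

    def test_entropy_value(self):
        p = np.zeros((2, 2))
        p[0, 0] = 1.0
        p[1, 1] = 1.0
        assert _coupling_from(p).entropy == 0.0
        p2 = np.array([[0.5, 0.5], [0.0, 1.0]])
        assert _coupling_from(p2).entropy == pytest.approx(np.log(0.5))


class TestInferAlignment:
    def test_identity_permutation(self):
        p = np.zeros((4, 4))
        p[:3, :3] = np.eye(3) * 0.98 + 0.01
        p[3, 3] = 1.0
        aln = infer_alignment(_coupling_from(p), "row")
        assert aln.pairs == [(0, 0), (1, 1), (2, 2)]

    def test_conflict_elimination(self):
        p = np.zeros((3, 4))
        p[0, 2] = 0.6
        p[1, 2] = 0.5
        p[0, 0] = 0.1
        p[1, 1] = 0.1
        p[2, 3] = 1.0
        aln = infer_alignment(_coupling_from(p), "row")
        assert aln.pairs == [(0, 2)]

    def test_conflict_tie_smallest_row(self):
        p = np.zeros((3, 4))
        p[0, 1] = 0.5
        p[1, 1] = 0.5
        p[2, 3] = 1.0
        aln = infer_alignment(_coupling_from(p), "row")
        assert aln.pairs == [(0, 1)]

    def test_gap_mass_unaligned(self):
        p = np.zeros((3, 3))
        p[0, 0] = 0.9
        p[1, 2] = 0.9  # row 1 mass on the gap column
        p[2, 2] = 1.0
        aln = infer_alignment(_coupling_from(p), "row")
        assert aln.pairs == [(0, 0)]

    def test_col_direction(self):
        p = np.zeros((3, 3))
        p[0, 0] = 0.9
        p[1, 1] = 0.8
        p[2, 2] = 1.0
        aln = infer_alignment(_coupling_from(p), "col")
        assert aln.pairs == [(0, 0), (1, 1)]
        assert aln.direction == "col"

    def test_injective_both_ways(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 8))
            n = int(rng.integers(2, 8))
            p = rng.uniform(0, 1, (m + 1, n + 1))
            p[m, n] = 1.0
            for direction in ("row", "col"):
                aln = infer_alignment(_coupling_from(p), direction)
                qs = [i for i, _ in aln.pairs]
                ts = [j for _, j in aln.pairs]
                assert len(set(qs)) == len(qs)
                assert len(set(ts)) == len(ts)
                assert all(i < m and j < n for i, j in aln.pairs)


class TestSelectDirection:
    def test_identical_alignments(self):
        chain = make_helix_chain(10)
        a = AlignmentResult(pairs=[(i, i) for i in range(10)], direction="row")
        b = AlignmentResult(pairs=[(i, i) for i in range(10)], direction="col")
        chosen = select_direction(a, b, chain, chain, Superposition.identity())
        assert chosen.direction == "row"  # tie goes to row
        assert chosen.pairs == a.pairs

    def test_superset_wins(self):
        chain = make_helix_chain(12)
        row = AlignmentResult(pairs=[(i, i) for i in range(6)], direction="row")
        col = AlignmentResult(pairs=[(i, i) for i in range(12)], direction="col")
        chosen = select_direction(row, col, chain, chain, Superposition.identity())
        assert chosen.direction == "col"
        assert chosen.tm > row.tm

    def test_both_empty(self):
        chain = make_helix_chain(5)
        row = AlignmentResult(pairs=[], direction="row")
        col = AlignmentResult(pairs=[], direction="col")
        chosen = select_direction(row, col, chain, chain, Superposition.identity())
        assert chosen.direction == "row"
        assert chosen.pairs == []


class TestExactPLSAP:
    def test_letter_toy(self):
        sim = letter_problem("abedn", "ACDNB")
        result = exact_plsap(sim)
        # a-A, b-B, d-D, n-N; e (query 2) and C (target 1) unaligned
        assert result.pairs == [(0, 0), (1, 4), (3, 2), (4, 3)]
        assert result.total_similarity == pytest.approx(4.0)

    def test_all_zero(self):
        sim = SimilarityMatrix(np.zeros((4, 4)), 0.0, 3, 3)
        result = exact_plsap(sim)
        assert result.total_similarity == 0.0
        assert result.pairs == []

    def test_tie_prefers_empty(self):
        sim = letter_problem("x", "Y")
        assert exact_plsap(sim).pairs == []

    @pytest.mark.parametrize("m,n", [(3, 3), (3, 4), (4, 4)])
    def test_matches_enumeration(self, rng, m, n):
        for _ in range(15):
            gap = float(rng.choice([0.0, 0.1, 0.3]))
            s = random_similarity(rng, m, n, gap=gap)
            sim = SimilarityMatrix(s, gap, m, n)
            result = exact_plsap(sim)
            best, _ = enumerate_best_total(s)
            assert full_objective(s, result.pairs) == pytest.approx(best, abs=1e-9)


class TestSolveFromSuperposition:
    def test_self_alignment(self):
        chain = make_helix_chain(20, seed=3)
        res = solve_from_superposition(chain, chain, Superposition.identity())
        assert res.pairs == [(i, i) for i in range(20)]
        assert np.allclose(res.distances, 0.0)
        assert res.sp == pytest.approx(0.8 * 20 ** 0.3)

    def test_far_translation_empty(self):
        chain = make_helix_chain(10)
        shifted = Superposition(np.eye(3), np.array([50.0, 0.0, 0.0]))
        res = solve_from_superposition(chain, chain, shifted)
        assert res.pairs == []
        assert res.sp == 0.0

    def test_circular_permutation_recovery(self, cp_pair):
        res = solve_from_superposition(cp_pair.query, cp_pair.target,
                                       Superposition.identity())
        truth = set(cp_pair.truth_map)
        assert len(set(res.pairs) & truth) >= 0.95 * len(truth)

    def test_explicit_direction(self, cp_pair):
        for direction in ("row", "col"):
            res = solve_from_superposition(cp_pair.query, cp_pair.target,
                                           Superposition.identity(),
                                           direction=direction)
            assert res.direction == direction


class TestSolverProperties:
    def test_entropic_to_exact_limit(self, rng):
        matched = 0
        total = 25
        for _ in range(total):
            m = int(rng.integers(3, 13))
            n = int(rng.integers(3, 13))
            s = random_similarity(rng, m, n)
            sim = SimilarityMatrix(s, 0.0, m, n)
            cost = build_cost_matrix(sim, 0.5)
            exact = exact_plsap(sim)
            coupling = sinkhorn_partial(cost, SolverParams(lambda_entropy=800.0))
            aln = infer_alignment(coupling, "row")
            tot = sum(s[i, j] for i, j in aln.pairs)
            if abs(tot - exact.total_similarity) <= 1e-3:
                matched += 1
        assert matched >= 0.95 * total

    def test_gap_monotonicity(self):
        pair = make_ground_truth_pair(40, "circular", 20, sigma=0.5, seed=3)
        nalis = []
        for gap in (0.0, 0.1, 0.2, 0.4, 0.8):
            res = solve_from_superposition(pair.query, pair.target,
                                           Superposition.identity(),
                                           gap_score=gap)
            nalis.append(res.nali)
        assert all(a >= b for a, b in zip(nalis, nalis[1:]))

    def test_elsap_short_side_fully_aligned(self):
        pair = make_ground_truth_pair(25, "circular", 10, sigma=0.4, seed=5)
        query, target = pair.query, pair.target
        dist = pairwise_distances(query, target, Superposition.identity())
        cost = build_cost_matrix(build_similarity_matrix(dist))
        coupling = sinkhorn_partial(cost, SolverParams(gap_modeling=False))
        m = len(query)
        # no gap state: every shorter-chain residue has its argmax on a real
        # partner before the elimination step
        assert coupling.P[:m, coupling.n].max() == 0.0
        choices = np.argmax(coupling.P[:m, :], axis=1)
        assert (choices < coupling.n).all()

    def test_lambda_sweep_reports(self, cp_pair):
        # trade-off direction is recorded, not asserted
        rows = []
        for lam in (10.0, 100.0, 300.0):
            res = solve_from_superposition(cp_pair.query, cp_pair.target,
                                           Superposition.identity(),
                                           solver_params=SolverParams(
                                               lambda_entropy=lam))
            rows.append((lam, res.nali))
        assert len(rows) == 3
        assert all(nali >= 0 for _, nali in rows)


def test_solver_params_validation():
    with pytest.raises(ValueError):
        SolverParams(lambda_entropy=0.0)
    with pytest.raises(ValueError):
        SolverParams(tmax=0)
    with pytest.raises(ValueError):
        SolverParams(tol=-1e-6)
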