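"""Joint multi-population solver: grids, updates, reductions, oracle checks."""

import numpy as np
import pytest

from prosper_prs import prosper_core as pc
from prosper_prs import single_ancestry as sa
from prosper_prs._solver import solve_block
from prosper_prs.ld_reference import LDBlock, LDBlockSet, build_shared_index

from conftest import make_sumstats
from oracles import joint_objective, joint_oracle


def two_pop_setup(r1, r2, R=None, shared_all=True):
    """Dense arrays for a fully-shared two-population block."""
    p = len(r1)
    r = np.array([r1, r2], dtype=float)
    R_ = np.broadcast_to(np.eye(p) if R is None else R, (2, p, p)).copy()
    present = np.ones((2, p), dtype=bool)
    share = np.zeros((2, 2, p), dtype=bool)
    if shared_all:
        share[0, 1] = share[1, 0] = True
    return r, R_, present, share


class TestLambdaPath:
    def test_min_over_populations(self):
        ss1 = make_sumstats("P1", r=[0.1, -0.05])
        ss2 = make_sumstats("P2", r=[0.2, 0.0])
        path = pc.build_lambda_path([ss1, ss2], [0.05, 0.02], length=10)
        assert path[0] == pytest.approx(min(0.1 / 0.05, 0.2 / 0.02))  # = 2
        assert path[-1] == pytest.approx(0.002)

    def test_log_spacing_second_value(self):
        ss = make_sumstats(r=[0.2])
        path = pc.build_lambda_path([ss], [0.1], length=10)  # lam_max = 2
        assert path[1] == pytest.approx(2 * 0.001 ** (1 / 9), rel=1e-10)
        assert path[1] == pytest.approx(0.9283, abs=2e-4)

    def test_single_population(self):
        ss = make_sumstats(r=[0.3, -0.1])
        path = pc.build_lambda_path([ss], [0.06], length=5)
        assert path[0] == pytest.approx(0.3 / 0.06)

    def test_zero_sumstats_rejected(self):
        ss = make_sumstats(r=[0.0, 0.0])
        with pytest.raises(ValueError, match="all-zero"):
            pc.build_lambda_path([ss], [0.1])


class TestCPath:
    def test_endpoints_exact(self):
        path = pc.build_c_path()
        assert path[0] == pytest.approx(2.0, rel=1e-12)
        assert path[-1] == pytest.approx(100.0, rel=1e-12)

    def test_quad_root_midpoint(self):
        assert pc.build_c_path()[4] == pytest.approx(18.22, abs=0.005)

    def test_degenerate_length_two(self):
        np.testing.assert_allclose(pc.build_c_path(length=2), [2.0, 100.0])

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            pc.build_c_path(c_min=0.0)
        with pytest.raises(ValueError):
            pc.build_c_path(c_min=5, c_max=2)


class TestUpdateRule:
    @pytest.mark.parametrize("u,lam,delta,c_sum,expected", [
        (0.5, 0.2, 0.1, 0.0, 0.3 / 1.1),
        (-0.15, 0.2, 0.0, 0.0, 0.0),
        (-0.5, 0.2, 0.0, 1.0, -0.15),
    ])
    def test_printed_rule(self, u, lam, delta, c_sum, expected):
        assert pc.prosper_update(u, lam, delta, c_sum) == pytest.approx(expected)


class TestDistanceScaledC:
    def test_flagged_pair_scaled(self):
        assert pc.distance_scaled_c(10, 0.5, "AFR", ("AFR", "EUR")) == 5

    def test_unflagged_pair_unscaled(self):
        assert pc.distance_scaled_c(10, 0.5, "AFR", ("EAS", "EUR")) == 10

    def test_identity_scale(self):
        assert pc.distance_scaled_c(10, 1.0, "AFR", ("AFR", "EUR")) == 10


class TestSolveJointBlock:
    def test_symmetric_shared_snp(self):
        r, R, present, share = two_pop_setup([0.5], [0.5])
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        beta, _, conv, div = solve_block(r, R, present, share, C,
                                         np.array([0.1, 0.1]), np.zeros(2))
        assert conv and not div
        np.testing.assert_allclose(beta.ravel(), [0.4, 0.4], atol=1e-6)

    def test_asymmetric_shared_snp(self):
        r, R, present, share = two_pop_setup([0.5], [0.1])
        C = np.array([[0.0, 1.0], [1.0, 0.0]])
        beta, _, _, _ = solve_block(r, R, present, share, C,
                                    np.array([0.1, 0.1]), np.zeros(2))
        np.testing.assert_allclose(beta.ravel(), [4 / 15, 2 / 15], atol=1e-6)

    def test_fused_limit_by_continuation(self):
        """c -> 1e6 with warm-started continuation reaches the pooled
        soft-threshold solution ((r1+r2)-2*lam)/2 = 0.2."""
        r, R, present, share = two_pop_setup([0.5], [0.1])
        lam, delta = np.array([0.1, 0.1]), np.zeros(2)
        beta = None
        for c in np.geomspace(1, 1e6, 25):
            C = np.array([[0.0, c], [c, 0.0]])
            beta, _, _, _ = solve_block(r, R, present, share, C, lam, delta,
                                        beta0=beta, max_sweeps=2000)
        np.testing.assert_allclose(beta.ravel(), [0.2, 0.2], atol=1e-3)
        assert abs(beta[0, 0] - beta[1, 0]) < 1e-5

    def test_population_specific_snp_lasso_only(self):
        # SNP 1 only in population 0: no ridge pull, plain soft-threshold
        r = np.array([[0.3, 0.4], [0.3, 0.0]])
        R = np.broadcast_to(np.eye(2), (2, 2, 2)).copy()
        present = np.array([[True, True], [True, False]])
        share = np.zeros((2, 2, 2), dtype=bool)
        share[0, 1, 0] = share[1, 0, 0] = True
        C = np.array([[0.0, 2.0], [2.0, 0.0]])
        beta, _, _, _ = solve_block(r, R, present, share, C,
                                    np.array([0.1, 0.1]), np.zeros(2))
        assert beta[0, 1] == pytest.approx((0.4 - 0.1) / 1.0, abs=1e-6)
        assert beta[1, 1] == 0.0

    def test_monotone_objective_descent(self, rng):
        p = 10
        G = rng.standard_normal((60, p))
        R1 = np.corrcoef(G, rowvar=False)
        R2 = np.corrcoef(G + rng.standard_normal((60, p)), rowvar=False)
        r, R, present, share = two_pop_setup(rng.uniform(-0.4, 0.4, p),
                                             rng.uniform(-0.4, 0.4, p))
        R[0], R[1] = R1, R2
        C = np.array([[0.0, 5.0], [5.0, 0.0]])
        _, trace, _, div = solve_block(r, R, present, share, C,
                                       np.array([0.05, 0.05]),
                                       np.array([0.1, 0.1]))
        assert not div
        assert np.all(np.diff(trace) <= 1e-9 * np.maximum(1, np.abs(trace[:-1])))

    def test_oracle_equivalence_random_instances(self, rng):
        """Objective within 1e-8 of a generic convex minimizer on random
        small instances, with KKT certificates at every coordinate."""
        for trial in range(8):
            M = int(rng.integers(2, 4))
            p = int(rng.integers(2, 9))
            R = np.zeros((M, p, p))
            for i in range(M):
                G = rng.standard_normal((3 * p + 10, p))
                R[i] = np.corrcoef(G, rowvar=False)
            r = rng.uniform(-0.5, 0.5, (M, p))
            present = rng.random((M, p)) < 0.9
            present[:, 0] = True
            share = np.zeros((M, M, p), dtype=bool)
            for i1 in range(M):
                for i2 in range(M):
                    if i1 != i2:
                        share[i1, i2] = present[i1] & present[i2]
            c = float(rng.uniform(0.5, 20))
            C = np.full((M, M), c)
            np.fill_diagonal(C, 0.0)
            lam = rng.uniform(0.02, 0.2, M)
            delta = rng.uniform(0.0, 0.5, M)
            r = np.where(present, r, 0.0)
            beta, trace, conv, div = solve_block(r, R, present, share, C,
                                                 lam, delta, max_sweeps=5000)
            assert conv and not div
            _, obj_oracle = joint_oracle(r, R, present, share, C, lam, delta)
            obj_cd = joint_objective(beta, r, R, present, share, C, lam, delta)
            assert obj_cd == pytest.approx(obj_oracle, abs=1e-8)
            assert pc.kkt_max_violation(beta, r, R, present, share, C,
                                        lam, delta) < 1e-4


class TestGrid:
    def _inputs(self, rng, M=2, p=30, block=15):
        pops = [f"P{i}" for i in range(M)]
        sss, ld_by_pop = [], {}
        ids = np.array([f"rs{i}" for i in range(p)], dtype=object)
        for i, pop in enumerate(pops):
            r = rng.uniform(-0.2, 0.2, p)
            ss = make_sumstats(pop, r=r)
            sss.append(ss)
            blocks = []
            for bi, lo in enumerate(range(0, p, block)):
                sub = ids[lo:lo + block]
                n = len(sub)
                G = rng.standard_normal((80, n))
                blocks.append(LDBlock(str(bi), sub, np.corrcoef(G, rowvar=False)))
            ld_by_pop[pop] = LDBlockSet(pop, blocks)
        return sss, ld_by_pop

    def test_grid_cardinality(self, rng):
        sss, ld = self._inputs(rng)
        ref = {ss.population: (0.01, 0.05) for ss in sss}
        grid = pc.PenaltyGrid.from_reference(sss, ref, lambda_length=4, c_length=3)
        sol = pc.solve_prosper_grid(sss, ld, grid)
        assert len(sol.settings) == 12
        assert len(sol.candidate_keys()) == 12 * 2

    def test_c_zero_reduces_to_single_ancestry(self, rng):
        """Diagnostic c=0: joint solutions equal independent lassosum fits."""
        sss, ld = self._inputs(rng, p=20, block=10)
        shared = build_shared_index(sss)
        pops, blocks = pc._assemble_blocks(sss, ld, shared)
        lam, delta = 0.03, 0.05
        C = np.zeros((2, 2))
        for b in blocks:
            beta, _, _, _ = solve_block(b["r"], b["R"], b["present"],
                                        b["share"], C,
                                        np.array([lam, lam]),
                                        np.array([delta, delta]), tol=1e-12)
            for i, ss in enumerate(sss):
                path = sa.solve_lassosum_path(ss, ld[ss.population],
                                              delta_grid=[delta],
                                              lambda_grid=[lam], tol=1e-12)
                single = path.beta_series(0, 0)
                mask = b["present"][i]
                joint = dict(zip(b["union"][mask], beta[i][mask]))
                for snp, val in joint.items():
                    assert val == pytest.approx(single[snp], abs=1e-10)

    def test_warm_start_matches_cold_start(self, rng):
        """Warm starts are a speedup, not a different estimator."""
        sss, ld = self._inputs(rng, p=20, block=20)
        ref = {ss.population: (0.01, 0.05) for ss in sss}
        grid = pc.PenaltyGrid.from_reference(sss, ref, lambda_length=5, c_length=2)
        sol = pc.solve_prosper_grid(sss, ld, grid, tol=1e-11, max_sweeps=20_000)
        shared = build_shared_index(sss)
        pops, blocks = pc._assemble_blocks(sss, ld, shared)
        b = blocks[0]
        li, ci = 3, 1
        lam = grid.lambda_path[li] * np.array([0.05, 0.05])
        C = np.full((2, 2), grid.c_path[ci])
        np.fill_diagonal(C, 0.0)
        beta_cold, _, _, _ = solve_block(b["r"], b["R"], b["present"],
                                         b["share"], C, lam,
                                         np.array([0.01, 0.01]), tol=1e-11,
                                         max_sweeps=20_000)
        for i, pop in enumerate(pops):
            np.testing.assert_allclose(sol.betas[(li, ci)][pop],
                                       beta_cold[i][b["present"][i]], atol=1e-8)

    def test_nonzero_solution_at_lambda_max(self, rng):
        """At the top of the lambda path the minimizing population still
        produces a nonzero coefficient after the first step down."""
        sss, ld = self._inputs(rng, p=20, block=20)
        lam0 = {ss.population: 0.05 for ss in sss}
        ref = {p: (0.01, v) for p, v in lam0.items()}
        grid = pc.PenaltyGrid.from_reference(sss, ref, lambda_length=5, c_length=2)
        sol = pc.solve_prosper_grid(sss, ld, grid)
        any_nonzero = any(np.count_nonzero(sol.betas[(1, ci)][pop])
                          for ci in range(2) for pop in sol.populations)
        assert any_nonzero

    def test_divergence_flag_propagates(self, rng):
        sss, ld = self._inputs(rng, p=10, block=10)
        ref = {ss.population: (0.01, 0.05) for ss in sss}
        grid = pc.PenaltyGrid.from_reference(sss, ref, lambda_length=2, c_length=2)
        sol = pc.solve_prosper_grid(sss, ld, grid)
        sol.diverged[(0, 0)] = True
        keys = sol.candidate_keys()
        assert all((li, ci) != (0, 0) for li, ci, _ in keys)


class TestPenaltyGridValidation:
    def test_paths_must_be_monotone(self):
        with pytest.raises(ValueError):
            pc.PenaltyGrid(["A"], {"A": 0.1}, {"A": 0.1},
                           np.array([0.1, 0.2]), np.array([2.0, 10.0]))
        with pytest.raises(ValueError):
            pc.PenaltyGrid(["A"], {"A": 0.1}, {"A": 0.1},
                           np.array([0.2, 0.1]), np.array([10.0, 2.0]))
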