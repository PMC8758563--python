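"""EBM super-efficiency solver: oracles, limiting cases, invariances."""

import numpy as np
import pytest

from healthprod.ebm import (
    EBMParams,
    affinity_matrix,
    decompose_efficiency,
    determine_epsilon_weights,
    diversity_index,
    score_panel,
    solve_ebm_super,
)
from healthprod.oracles import brute_force_ebm, radial_super_score, sbm_score
from healthprod.panel import DEAPanel

from conftest import random_instance, uniform_params


class TestEpsilonWeights:
    def test_single_input_pure_radial(self):
        x = np.array([[1.0, 2.0, 3.0]])
        p = determine_epsilon_weights(x, np.ones((1, 3)), np.ones((1, 3)))
        assert p.epsilon_in == 0.0
        np.testing.assert_allclose(p.w_in, [1.0])

    def test_proportional_rows_zero_diversity(self):
        """Proportional series carry no non-radial information."""
        x = np.array([[1.0, 2.0, 3.0], [2.0, 4.0, 6.0]])
        assert diversity_index(x[0], x[1]) == 0.0
        p = determine_epsilon_weights(x, np.ones((1, 3)), np.ones((1, 3)))
        assert p.epsilon_in == 0.0

    def test_heterogeneous_rows_positive_epsilon(self):
        x = np.array([[1.0, 2.0, 3.0], [3.0, 1.0, 2.0]])
        # independent double-loop recomputation of the diversity index
        d = np.log(x[0]) - np.log(x[1])
        expect_d = np.abs(d - d.mean()).sum() / (len(d) * (d.max() - d.min()))
        assert diversity_index(x[0], x[1]) == pytest.approx(expect_d)
        S = affinity_matrix(x)
        assert S[0, 1] == pytest.approx(1 - 2 * expect_d)
        p = determine_epsilon_weights(x, np.ones((1, 3)), np.ones((1, 3)))
        assert 0.0 < p.epsilon_in <= 1.0
        assert p.w_in.sum() == pytest.approx(1.0)

    def test_weight_normalisation_split_outputs(self):
        rng = np.random.default_rng(0)
        x, y, u = random_instance(rng, n=6, m=3, s=2, q=2)
        p = determine_epsilon_weights(x, y, u)
        assert p.w_in.sum() == pytest.approx(1.0)
        assert p.w_out.sum() + p.w_bad.sum() == pytest.approx(1.0)
        assert len(p.w_out) == 2 and len(p.w_bad) == 2


class TestSolver:
    def test_two_unit_radial_worked_case(self):
        """A(1,1) dominates B(2,1): radial super scores 2 and 0.5."""
        x = np.array([[1.0, 2.0]])
        y = np.array([[1.0, 1.0]])
        u = np.array([[1.0, 1.0]])
        p = uniform_params(m=1)
        assert solve_ebm_super(x, y, u, 0, p).gamma_star == pytest.approx(2.0, abs=1e-8)
        assert solve_ebm_super(x, y, u, 1, p).gamma_star == pytest.approx(0.5, abs=1e-8)

    def test_identical_twins_score_one(self):
        x = np.array([[1.5, 1.5]])
        y = np.array([[2.0, 2.0]])
        u = np.array([[0.7, 0.7]])
        for eps in (0.0, 0.5, 1.0):
            p = uniform_params(m=1, eps_in=eps, eps_out=eps)
            r = solve_ebm_super(x, y, u, 0, p)
            assert r.gamma_star == pytest.approx(1.0, abs=1e-8)
            assert r.lambdas[0] == 0.0  # self excluded

    @pytest.mark.parametrize("seed", range(5))
    def test_radial_limit_matches_independent_oracle(self, seed):
        """epsilon = 0 collapses to the non-oriented radial measure."""
        rng = np.random.default_rng(seed)
        x, y, u = random_instance(rng)
        p = uniform_params()
        for k in range(x.shape[1]):
            got = solve_ebm_super(x, y, u, k, p).gamma_star
            want = radial_super_score(x, y, u, k)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_sbm_limit_matches_dinkelbach_oracle(self, seed):
        """theta = phi = 1 with epsilon = 1 reproduces the weighted SBM."""
        rng = np.random.default_rng(100 + seed)
        x, y, u = random_instance(rng)
        p = uniform_params(eps_in=1.0, eps_out=1.0)
        for k in range(x.shape[1]):
            got = solve_ebm_super(x, y, u, k, p, exclude_self=False,
                                  fix_radial=True).gamma_star
            want = sbm_score(x, y, u, k, exclude_self=False)
            assert got == pytest.approx(want, abs=1e-6)

    @pytest.mark.parametrize("seed", [7, 13])
    def test_brute_force_grid_oracle_tiny(self, seed):
        rng = np.random.default_rng(seed)
        x, y, u = random_instance(rng, n=3, m=2, s=1, q=1, spread=0.3)
        p = uniform_params(eps_in=0.5, eps_out=0.5)
        for k in range(3):
            got = solve_ebm_super(x, y, u, k, p).gamma_star
            want = brute_force_ebm(x, y, u, k, p, grid=24, refine=6)
            if np.isnan(want):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(want, abs=1e-4)

    def test_units_invariance(self):
        """Rescaling any input/output column leaves every score unchanged."""
        rng = np.random.default_rng(3)
        x, y, u = random_instance(rng, n=6)
        p = EBMParams(0.3, 0.5, [0.6, 0.4], [0.7], [0.3])
        base = [solve_ebm_super(x, y, u, k, p).gamma_star for k in range(6)]
        x2 = x * np.array([[37.5], [0.2]])
        y2, u2 = y * 2.25, u * 0.04
        alt = [solve_ebm_super(x2, y2, u2, k, p).gamma_star for k in range(6)]
        for a, b in zip(base, alt):
            if np.isnan(a):
                assert np.isnan(b)
            else:
                assert a == pytest.approx(b, abs=1e-8)

    def test_monotone_in_own_performance(self):
        """Worse inputs / outputs never raise the evaluated unit's score."""
        rng = np.random.default_rng(5)
        x, y, u = random_instance(rng, n=6)
        p = EBMParams(0.3, 0.5, [0.6, 0.4], [0.7], [0.3])
        r0 = solve_ebm_super(x, y, u, 0, p, exclude_self=False).gamma_star
        xw = x.copy(); xw[:, 0] *= 1.3
        r1 = solve_ebm_super(xw, y, u, 0, p, exclude_self=False).gamma_star
        yw = y.copy(); yw[:, 0] *= 0.8
        uw = u.copy(); uw[:, 0] *= 1.4
        r2 = solve_ebm_super(x, yw, uw, 0, p, exclude_self=False).gamma_star
        assert r1 <= r0 + 1e-9
        assert r2 <= r0 + 1e-9

    def test_super_and_standard_agree_below_one(self):
        rng = np.random.default_rng(11)
        x, y, u = random_instance(rng, n=8)
        p = uniform_params(eps_in=0.4, eps_out=0.4)
        for k in range(8):
            std = solve_ebm_super(x, y, u, k, p, exclude_self=False).gamma_star
            if std < 1 - 1e-6:
                sup = solve_ebm_super(x, y, u, k, p).gamma_star
                assert sup == pytest.approx(std, abs=1e-6)


class TestScorePanel:
    def _panel(self, seed=0, n=6, T=2):
        rng = np.random.default_rng(seed)
        x = np.exp(rng.normal(0, 0.4, (T, 2, n)))
        y = np.exp(rng.normal(0, 0.4, (T, 1, n)))
        u = np.exp(rng.normal(0, 0.4, (T, 1, n)))
        return DEAPanel([f"U{i}" for i in range(n)], list(range(2009, 2009 + T)), x, y, u)

    def test_deterministic(self):
        panel = self._panel()
        a = score_panel(panel).scores
        b = score_panel(panel).scores
        assert a.equals(b)

    def test_dominated_entrant_leaves_scores_unchanged(self):
        """With the slack weights held fixed, a strictly dominated entrant
        never supports an optimal reference mix, so other scores stand."""
        panel = self._panel(n=5, T=1)
        params = uniform_params(eps_in=0.4, eps_out=0.4)
        base = score_panel(panel, params).scores
        # append a unit strictly dominated by unit 0
        x = np.concatenate([panel.x, panel.x[:, :, :1] * 1.5], axis=2)
        y = np.concatenate([panel.y, panel.y[:, :, :1] * 0.5], axis=2)
        u = np.concatenate([panel.u, panel.u[:, :, :1] * 1.5], axis=2)
        bigger = DEAPanel(panel.unit_ids + ["dominated"], panel.years, x, y, u)
        grown = score_panel(bigger, params).scores
        got, want = grown.iloc[:5].to_numpy(), base.to_numpy()
        both_nan = np.isnan(got) & np.isnan(want)
        np.testing.assert_allclose(got[~both_nan], want[~both_nan], atol=1e-7)
        assert grown.iloc[5, 0] < 1.0


class TestDecomposition:
    def test_arithmetic(self):
        assert decompose_efficiency(0.6, 0.8) == pytest.approx(0.75)
        assert decompose_efficiency(0.9, 0.9) == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            decompose_efficiency(0.5, 0.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_crs_frontier_envelops_vrs(self, seed):
        """TE (CRS) never exceeds PTE (VRS) on the full-reference models."""
        rng = np.random.default_rng(200 + seed)
        x, y, u = random_instance(rng)
        pc = uniform_params(eps_in=0.4, eps_out=0.4)
        pv = uniform_params(eps_in=0.4, eps_out=0.4, rts="VRS")
        for k in range(x.shape[1]):
            te = solve_ebm_super(x, y, u, k, pc, exclude_self=False).gamma_star
            pte = solve_ebm_super(x, y, u, k, pv, exclude_self=False).gamma_star
            assert te <= pte + 1e-7
            assert decompose_efficiency(te, pte) <= 1 + 1e-7
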