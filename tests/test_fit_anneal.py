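import math

import numpy as np
import pytest

from nichefit.fit_anneal import (
    AnnealConfig,
    _layout,
    _Objective,
    fit,
    grid_search_oracle,
    propose,
)
from nichefit.pnm_core import (
    A_DEFAULT,
    R_FLOOR,
    ConstraintMask,
    ParamSet,
    log_likelihood,
    probability_matrix,
)
from nichefit.synthgen import generate_pnm_web, graded_params
from nichefit.variants import ModelSpec, expand_params, random_model
from nichefit.web_data import FoodWeb, web_stats

QUICK = AnnealConfig(stages=30, restarts=2, seed=0)


class TestPropose:
    def setup_method(self):
        self.lo = np.zeros(4)
        self.hi = np.ones(4)
        self.opt = np.arange(4)

    def test_zero_sigma_is_identity(self):
        cfg = AnnealConfig(step_sigma=0.0)
        state = np.array([0.2, 0.4, 0.6, 0.8])
        out = propose(state, cfg, np.random.default_rng(0), self.opt, self.lo, self.hi)
        np.testing.assert_array_equal(out, state)

    def test_single_coordinate_moves(self):
        cfg = AnnealConfig(step_sigma=0.1)
        state = np.full(4, 0.5)
        out = propose(state, cfg, np.random.default_rng(1), self.opt, self.lo, self.hi)
        assert (out != state).sum() == 1

    def test_reflection_keeps_candidate_inside_bounds(self):
        cfg = AnnealConfig(step_sigma=0.5)
        rng = np.random.default_rng(2)
        state = np.array([0.99, 0.01, 0.5, 0.999])
        for _ in range(200):
            out = propose(state, cfg, rng, self.opt, self.lo, self.hi)
            assert ((out >= 0) & (out <= 1)).all()
            state = out

    def test_metropolis_accepts_everything_at_infinite_temperature(self, rng):
        # acceptance probability exp(delta/T) -> 1 as T -> inf for any delta
        deltas = -rng.exponential(5.0, 1000)
        accepted = np.exp(deltas / 1e12) > rng.random(1000)
        assert accepted.mean() > 0.999


class TestIncrementalObjective:
    @pytest.mark.parametrize("name", ["pnm", "anm", "r_of_c", "c_of_n", "c_and_r_of_n"])
    def test_tracked_likelihood_matches_full_recompute(self, name, rng):
        truth = graded_params(8, basal_frac=0.25)
        sw = generate_pnm_web(truth, 5)
        web = sw.web
        web.body_mass = 10.0 ** (3 * truth.n)
        mask = ConstraintMask.from_web(web)
        spec = ModelSpec(name)
        n_allo = None
        if name == "anm":
            from nichefit.variants import allometric_niche

            n_allo = allometric_niche(web.body_mass)
        lo, hi, opt = _layout(spec, 8, mask)
        obj = _Objective(spec, web, mask, n_allo)
        cur = obj.set_state(lo + (hi - lo) * rng.random(lo.shape[0]))
        for _ in range(400):
            i = opt[rng.integers(opt.shape[0])]
            x = float(np.clip(obj.state[i] + rng.normal(0, 0.1), lo[i], hi[i]))
            delta = obj.propose_coord(i, x)
            if rng.random() < 0.7:
                obj.commit()
                cur += delta
        p = expand_params(spec, obj.state, 8, n_allometric=n_allo)
        full = log_likelihood(probability_matrix(p, mask), web)
        assert cur == pytest.approx(full, abs=1e-8)


class TestFit:
    def test_deterministic_given_seed(self, two_species_web):
        a = fit(two_species_web, "pnm", QUICK)
        b = fit(two_species_web, "pnm", QUICK)
        np.testing.assert_array_equal(a.params.n, b.params.n)
        np.testing.assert_array_equal(a.params.c, b.params.c)
        np.testing.assert_array_equal(a.params.r, b.params.r)
        assert a.lnl == b.lnl

    def test_trace_is_monotone_nondecreasing(self, chain_web):
        res = fit(chain_web, "pnm", QUICK)
        assert (np.diff(res.trace) >= -1e-12).all()

    def test_reported_lnl_consistent_with_params(self, chain_web):
        res = fit(chain_web, "pnm", QUICK)
        mask = ConstraintMask.from_web(chain_web)
        recomputed = log_likelihood(
            probability_matrix(res.params, mask), chain_web
        )
        assert res.lnl == pytest.approx(recomputed, abs=1e-9)
        assert res.aic == pytest.approx(2 * res.k - 2 * res.lnl)

    def test_specialist_limit_two_species(self, two_species_web):
        res = fit(two_species_web, "pnm", AnnealConfig(stages=40, restarts=2, seed=3))
        assert res.lnl == pytest.approx(math.log(A_DEFAULT), abs=1e-3)
        # the consumer's diet centre converges onto its prey's position
        assert abs(res.params.c[1] - res.params.n[0]) < 0.01

    def test_no_consumers_rejected(self):
        web = FoodWeb(["a", "b"], np.zeros((2, 2), dtype=int))
        with pytest.raises(ValueError, match="nothing to fit"):
            fit(web, "pnm", QUICK)

    def test_random_spec_rejected(self, chain_web):
        with pytest.raises(ValueError, match="closed form"):
            fit(chain_web, "random", QUICK)

    def test_anm_needs_masses(self, chain_web):
        with pytest.raises(ValueError, match="mass"):
            fit(chain_web, "anm", QUICK)

    def test_model_nesting_on_simulated_web(self):
        """The full model's MLE dominates its reduced variants and the
        random baseline on the same web (likelihoods are nested)."""
        sw = generate_pnm_web(graded_params(12, basal_frac=0.25), 9)
        cfg = AnnealConfig(stages=60, restarts=3, seed=4)
        full = fit(sw.web, "pnm", cfg)
        reduced = fit(sw.web, "c_and_r_of_n", cfg)
        stats = web_stats(sw.web)
        baseline = random_model(stats.S, stats.L)
        assert full.lnl >= reduced.lnl - 0.5   # annealer noise allowance
        assert full.lnl >= baseline.lnl


class TestGridSearchOracle:
    def test_single_link_optimum_is_specialist_peak(self, two_species_web):
        lnl, params = grid_search_oracle(two_species_web, "pnm", resolution=0.1)
        assert lnl == pytest.approx(math.log(A_DEFAULT), abs=1e-4)
        assert params.r[1] == R_FLOOR
        assert params.c[1] == pytest.approx(params.n[0], abs=1e-9)

    def test_refinement_never_worsens(self, two_species_web):
        coarse, _ = grid_search_oracle(two_species_web, "pnm", resolution=0.2)
        fine, _ = grid_search_oracle(two_species_web, "pnm", resolution=0.1)
        assert fine >= coarse - 1e-12

    def test_oversized_grid_rejected(self, chain_web):
        with pytest.raises(ValueError, match="budget"):
            grid_search_oracle(chain_web, "pnm", resolution=0.001)

    def test_annealer_agrees_on_three_species_web(self):
        """Two producers and one generalist: the continuous optimum merges
        the producers' positions, which the lattice can represent exactly,
        so annealer and exhaustive grid must agree closely."""
        web = FoodWeb(["a", "b", "z"], [[0, 0, 0], [0, 0, 0], [1, 1, 0]])
        grid_lnl, _ = grid_search_oracle(web, "pnm", resolution=0.05, r_hi=1.0)
        res = fit(web, "pnm", AnnealConfig(stages=80, restarts=3, seed=0))
        assert abs(res.lnl - grid_lnl) <= 1e-2
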