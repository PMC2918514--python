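import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nichefit.pnm_core import (
    A_DEFAULT,
    P_FLOOR,
    R_FLOOR,
    ConstraintMask,
    ParamSet,
    aic,
    count_parameters,
    link_probability,
    log_likelihood,
    probability_matrix,
    read_params,
    write_params,
)
from nichefit.variants import random_model
from nichefit.web_data import FoodWeb

from conftest import make_web, random_params


class TestLinkProbability:
    def test_peak_at_diet_centre(self):
        assert link_probability(0.5, 0.5, 0.3) == pytest.approx(A_DEFAULT)

    def test_half_range_is_e_folding_point(self):
        p = link_probability(0.6, 0.5, 0.2)
        assert p == pytest.approx(A_DEFAULT * math.exp(-1))

    def test_hand_evaluated_tail(self):
        # |n - c| = 0.3 with r = 0.2 puts the prey 3 half-widths out
        p = link_probability(0.6, 0.3, 0.2)
        assert p == pytest.approx(0.9999 * math.exp(-9), rel=1e-12)

    def test_floor_clamps_far_tail(self):
        assert link_probability(1.0, 0.0, 0.01) == P_FLOOR

    def test_rejects_nonpositive_range(self):
        with pytest.raises(ValueError, match="positive"):
            link_probability(0.5, 0.5, 0.0)

    @settings(deadline=None, max_examples=50)
    @given(
        n=st.floats(0, 1), c=st.floats(0, 1),
        r=st.floats(1e-6, 2.0), d=st.floats(0.0, 0.5),
    )
    def test_decreasing_in_niche_distance(self, n, c, r, d):
        near = link_probability(c + abs(n - c), c, r)
        far = link_probability(c + abs(n - c) + d, c, r)
        assert far <= near <= A_DEFAULT


class TestProbabilityMatrix:
    def test_matches_elementwise_kernel(self, rng):
        params = random_params(4, rng)
        P = probability_matrix(params)
        for i in range(4):
            for j in range(4):
                assert P[i, j] == pytest.approx(
                    link_probability(params.n[j], params.c[i], params.r[i])
                )

    def test_producer_rows_floored(self, chain_web):
        mask = ConstraintMask.from_web(chain_web)
        params = ParamSet(n=[0.1, 0.5, 0.9], c=[0.0, 0.1, 0.3], r=[0.5, 0.5, 0.5])
        P = probability_matrix(params, mask)
        assert (P[0] == P_FLOOR).all()

    def test_specialist_rows_use_range_floor(self, chain_web):
        mask = ConstraintMask.from_web(chain_web)
        params = ParamSet(n=[0.1, 0.5, 0.9], c=[0.0, 0.1, 0.3], r=[0.5, 0.5, 0.5])
        P = probability_matrix(params, mask)
        # specialist b has c exactly on prey a's n: peak survives the pinch
        assert P[1, 0] == pytest.approx(A_DEFAULT)
        # every other prey is astronomically far at r = R_FLOOR
        assert P[1, 1] == P_FLOOR and P[1, 2] == P_FLOOR

    def test_length_mismatch_rejected(self, chain_web):
        mask = ConstraintMask.from_web(chain_web)
        with pytest.raises(ValueError, match="match"):
            probability_matrix(ParamSet(n=[0.5, 0.5], c=[0.1, 0.1], r=[1, 1]), mask)


class TestConstraintMask:
    def test_flags_and_prey_index(self, chain_web):
        mask = ConstraintMask.from_web(chain_web)
        assert mask.producer.tolist() == [True, False, False]
        assert mask.specialist.tolist() == [False, True, False]
        assert mask.specialist_prey.tolist() == [-1, 0, -1]


class TestLogLikelihood:
    def test_empty_web_at_floor_is_near_zero(self):
        A = np.zeros((5, 5), dtype=int)
        P = np.full((5, 5), P_FLOOR)
        lnl = log_likelihood(P, A)
        assert lnl == pytest.approx(25 * math.log1p(-P_FLOOR))

    def test_two_species_hand_sum(self):
        A = np.array([[0, 1], [0, 0]])
        P = np.array([[P_FLOOR, 0.9999], [P_FLOOR, P_FLOOR]])
        expected = math.log(0.9999) + 3 * math.log1p(-P_FLOOR)
        assert log_likelihood(P, A) == pytest.approx(expected)

    def test_uniform_probability_closed_form(self):
        web = make_web(29, 203)
        C = 203 / 841
        lnl = log_likelihood(np.full((29, 29), C), web)
        closed = 841 * (C * math.log(C) + (1 - C) * math.log(1 - C))
        assert lnl == pytest.approx(closed)
        assert lnl == pytest.approx(-464.79, abs=0.01)

    def test_rejects_degenerate_probabilities(self):
        A = np.zeros((2, 2), dtype=int)
        with pytest.raises(ValueError, match="strictly"):
            log_likelihood(np.array([[0.5, 1.0], [0.5, 0.5]]), A)

    def test_never_positive(self, rng):
        for _ in range(20):
            params = random_params(6, rng)
            A = rng.integers(0, 2, (6, 6))
            assert log_likelihood(probability_matrix(params), A) <= 0

    def test_moving_entry_toward_observation_improves(self, rng):
        params = random_params(5, rng)
        A = rng.integers(0, 2, (5, 5))
        P = probability_matrix(params)
        base = log_likelihood(P, A)
        P2 = P.copy()
        # halve the distance to the observed value: a strict improvement
        P2[2, 3] = (P2[2, 3] + 1) / 2 if A[2, 3] == 1 else P2[2, 3] / 2
        assert log_likelihood(P2, A) > base

    def test_gauge_reflection_invariance(self, rng):
        for _ in range(10):
            params = random_params(8, rng)
            A = rng.integers(0, 2, (8, 8))
            mirrored = ParamSet(n=1 - params.n, c=1 - params.c, r=params.r)
            assert log_likelihood(probability_matrix(params), A) == pytest.approx(
                log_likelihood(probability_matrix(mirrored), A), rel=1e-9
            )

    def test_perfect_specialist_chain(self):
        # every consumer centred exactly on its sole prey: lnL -> L·ln(a)
        S = 6
        A = np.zeros((S, S), dtype=int)
        n = np.linspace(0, 1, S)
        c = np.zeros(S)
        for i in range(1, S):
            A[i, i - 1] = 1
            c[i] = n[i - 1]
        web = FoodWeb([f"s{i}" for i in range(S)], A)
        mask = ConstraintMask.from_web(web)
        params = ParamSet(n=n, c=c, r=np.full(S, R_FLOOR))
        lnl = log_likelihood(probability_matrix(params, mask), web)
        assert lnl == pytest.approx((S - 1) * math.log(A_DEFAULT), abs=1e-6)


class TestAicAndCounts:
    def test_aic_arithmetic(self):
        assert aic(0.0, 0) == 0.0
        assert aic(-10.0, 2) == 24.0

    def test_random_model_benguela_rounds_to_932(self):
        assert round(random_model(29, 203).aic) == 932

    @pytest.mark.parametrize("name,expected", [
        ("pnm", 87),
        ("anm", 58),
        ("r_of_c", 60),
        ("r_of_n", 60),
        ("c_of_n", 60),
        ("c_and_r_of_n", 33),
        ("random", 1),
    ])
    def test_nominal_counts_at_29_species(self, name, expected):
        assert count_parameters(name, 29) == expected

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            count_parameters("cascade", 29)


class TestParamsIO:
    def test_round_trip(self, tmp_path, rng):
        params = random_params(5, rng)
        species = [f"s{i}" for i in range(5)]
        write_params(params, species, tmp_path / "p.csv", meta={"model": "pnm"})
        back, names = read_params(tmp_path / "p.csv")
        assert names == species
        np.testing.assert_allclose(back.n, params.n)
        np.testing.assert_allclose(back.c, params.c)
        np.testing.assert_allclose(back.r, params.r)
        assert back.a == params.a
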