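"""Unit and distributional tests of the half-day branching step."""

import numpy as np
import pytest
from scipy import stats as sps

from clonewell import (
    ModelParams,
    WellState,
    birth_probability,
    draw_initial_state,
    half_step,
    simulate_final_totals,
    simulate_well,
)
from clonewell.likelihood import _pmf_power


class TestDrawInitialState:
    def test_empty_seeding(self, default_params, rng):
        s = draw_initial_state(0, default_params, rng)
        assert (s.F, s.M, s.S) == (0, 0, 0)

    def test_degenerate_type_distribution(self, rng):
        params = ModelParams(pF=1.0, pM=0.0, pS=0.0)
        s = draw_initial_state(5, params, rng)
        assert (s.F, s.M, s.S) == (5, 0, 0)

    def test_negative_seeding_rejected(self, default_params, rng):
        with pytest.raises(ValueError):
            draw_initial_state(-1, default_params, rng)

    def test_multinomial_moments(self, default_params):
        # mean F = pF*N0 = 4, mean S = pS*N0 = 2 within 3 standard errors
        rng = np.random.default_rng(5)
        n = 100_000
        draws = np.array(
            [
                (s.F, s.S)
                for s in (draw_initial_state(10, default_params, rng) for _ in range(n))
            ]
        )
        se_F = np.sqrt(10 * 0.4 * 0.6 / n)
        se_S = np.sqrt(10 * 0.2 * 0.8 / n)
        assert abs(draws[:, 0].mean() - 4.0) < 3 * se_F
        assert abs(draws[:, 1].mean() - 2.0) < 3 * se_S


class TestBirthProbability:
    @pytest.mark.parametrize(
        "cell_type,N,delta,expected",
        [
            ("fast", 0, 0.0, 0.5),
            ("fast", 40000, 0.0, 0.0),  # density term kills growth
            ("moderate", 0, 0.0, 0.5 / 1.5),
            ("slow", 0, 0.0, 0.5 / 3),
            ("fast", 0, 0.6, 0.99),  # clamped at 1 - d
        ],
    )
    def test_examples(self, default_params, cell_type, N, delta, expected):
        assert birth_probability(cell_type, N, default_params, delta) == pytest.approx(expected)

    def test_clamp_applied_before_type_division(self, default_params):
        # gF clamps to 1-d first, then divides: moderate = 0.99/1.5
        assert birth_probability("moderate", 0, default_params, 0.6) == pytest.approx(0.99 / 1.5)

    def test_monotone_in_population(self, default_params):
        probs = [birth_probability("fast", n, default_params, 0.05) for n in range(0, 50001, 1000)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))

    def test_unknown_type_rejected(self, default_params):
        with pytest.raises(ValueError):
            birth_probability("medium", 0, default_params)


def _exact_half_step_distribution(state, params, delta):
    """Joint next-state pmf by per-type convolution of the trinomial
    offspring law: independent oracle for half_step."""
    N = state.total
    dists = []
    for cell_type, n in zip(("fast", "moderate", "slow"), (state.F, state.M, state.S)):
        g = birth_probability(cell_type, N, params, delta)
        dists.append(_pmf_power(np.array([params.d, 1 - g - params.d, g]), n))
    return dists


class TestHalfStep:
    def test_extinction_absorbing(self, default_params, rng):
        s = half_step(WellState(0, 0, 0), default_params, 0.0, rng)
        assert s.total == 0 and s.t == 1

    def test_pure_stagnation(self, rng):
        params = ModelParams(d=0.0, g0=0.0, r=0.0)
        s = half_step(WellState(10, 0, 0), params, 0.0, rng)
        assert (s.F, s.M, s.S) == (10, 0, 0)

    def test_no_cross_type_flow(self, default_params, rng):
        state = WellState(5, 0, 0)
        for _ in range(40):
            state = half_step(state, default_params, 0.0, rng)
            assert state.M == 0 and state.S == 0

    def test_single_cell_offspring_probabilities(self, default_params):
        # one fast cell: next count 0/1/2 with probs (d, 1-g-d, g)
        rng = np.random.default_rng(23)
        counts = np.bincount(
            [half_step(WellState(1, 0, 0), default_params, 0.0, rng).F for _ in range(50_000)],
            minlength=3,
        )
        expected = np.array([0.01, 0.49, 0.50]) * 50_000
        assert sps.chisquare(counts, expected).pvalue > 1e-3

    def test_exact_distribution_oracle(self, default_params):
        """Empirical frequencies of one half-step from (2,1,0) match the
        enumerated next-state distribution (chi-square)."""
        state = WellState(2, 1, 0)
        dF, dM, _ = _exact_half_step_distribution(state, default_params, 0.0)
        joint = np.outer(dF, dM)  # P(F'=i, M'=j)
        rng = np.random.default_rng(99)
        n = 100_000
        obs = np.zeros_like(joint)
        for _ in range(n):
            s = half_step(state, default_params, 0.0, rng)
            obs[s.F, s.M] += 1
        # merge cells with tiny expected counts
        exp_counts = joint * n
        keep = exp_counts >= 10
        obs_merged = np.append(obs[keep], obs[~keep].sum())
        exp_merged = np.append(exp_counts[keep], exp_counts[~keep].sum())
        assert sps.chisquare(obs_merged, exp_merged).pvalue > 1e-3


class TestSimulateWell:
    def test_frozen_population(self):
        params = ModelParams(pF=0.0, pM=0.0, pS=1.0, g0=0.0, d=0.0, r=0.0)
        traj = simulate_well(1, params, t_end_days=10, rng=1)
        assert all(s.total == 1 for s in traj.states)

    def test_half_day_grid_and_reproducibility(self, default_params):
        t1 = simulate_well(4, default_params, t_end_days=23, rng=7)
        t2 = simulate_well(4, default_params, t_end_days=23, rng=7)
        assert len(t1.states) == 47  # t = 0, 0.5, ..., 23
        assert t1.delta == t2.delta
        assert [(s.F, s.M, s.S) for s in t1.states] == [(s.F, s.M, s.S) for s in t2.states]

    def test_delta_fixed_within_bounds(self, default_params):
        traj = simulate_well(1, default_params, t_end_days=5, rng=3)
        assert abs(traj.delta) <= default_params.r

    def test_extinction_stays_absorbed(self):
        params = ModelParams(d=0.99, g0=0.0, r=0.0)
        traj = simulate_well(3, params, t_end_days=10, rng=11)
        totals = [s.total for s in traj.states]
        first_zero = totals.index(0)
        assert all(t == 0 for t in totals[first_zero:])

    def test_invalid_duration(self, default_params):
        with pytest.raises(ValueError):
            simulate_well(1, default_params, t_end_days=0)


class TestEnsembleSimulation:
    def test_mean_growth_rate_in_fast_band(self):
        # per-day log growth of the mean is 2 ln(1 + g - d) ~ 0.80/day,
        # inside the fast-type band 0.6-0.9
        params = ModelParams(r=0.0)
        expected_rate = 2 * np.log(1 + 0.5 - 0.01)
        totals = simulate_final_totals(4000, 50, params, 5.0, rng=2, cell_type="fast")
        observed = np.log(totals.mean() / 50) / 5.0
        assert 0.6 < observed < 0.9
        assert observed == pytest.approx(expected_rate, abs=0.02)

    def test_forced_type_and_no_death_survival(self):
        params = ModelParams(d=0.0)
        totals = simulate_final_totals(2000, 1, params, 10.0, rng=4)
        assert np.all(totals > 0)  # no deaths, no extinction

    def test_reaches_carrying_capacity_plateau(self, default_params):
        totals = simulate_final_totals(50, 10, default_params, 23.0, rng=6)
        assert np.all(totals > 0.8 * default_params.C)
        assert np.all(totals < 1.15 * default_params.C)
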