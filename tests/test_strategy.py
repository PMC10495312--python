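import numpy as np
import pytest

from aize.fields import normative_field
from aize.grid import distance
from aize.observer import ObserverConfig
from aize.pmf import Pmf, build_prior, default_support, pmf_mean, update_pmf
from aize.strategy import (
    LocationState,
    StrategyConfig,
    WeightPolicy,
    apply_response,
    check_termination,
    preset,
    replay_trial,
    run_trial,
    select_next_location,
    select_stimulus,
    terminal_sigma,
    verification_pass,
    weighted_likelihood,
)

STEEP_OBSERVER = ObserverConfig(fp=0.0, fn=0.0, slope_coef=0.0, slope_intercept=np.log(0.01))


def _loc(x, y):
    from aize.grid import GridLocation

    return GridLocation(float(x), float(y), index=-1)


def point_mass(value):
    support = default_support()
    mass = np.zeros_like(support)
    mass[np.searchsorted(support, value)] = 1.0
    return Pmf(support, mass)


def two_point(a, b):
    support = default_support()
    mass = np.zeros_like(support)
    mass[np.searchsorted(support, a)] = 0.5
    mass[np.searchsorted(support, b)] = 0.5
    return Pmf(support, mass)


class TestWeightedLikelihood:
    @pytest.mark.parametrize("d,expected", [(0, 0.25), (4, 1 / 6), (12, 0.1)])
    def test_values(self, d, expected):
        assert weighted_likelihood(d) == pytest.approx(expected)

    def test_strictly_decreasing_with_max_at_zero(self):
        ds = np.linspace(0, 40, 81)
        vals = [weighted_likelihood(d) for d in ds]
        assert np.all(np.diff(vals) < 0)
        assert max(vals) == weighted_likelihood(0) == 0.25

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            weighted_likelihood(-1.0)


class TestTerminalSigma:
    @pytest.mark.parametrize(
        "db,r,expected", [(28, 0, 2.0), (0, 0, 4.8), (0, 30, 5.76)]
    )
    def test_formula_values(self, db, r, expected):
        assert terminal_sigma(db, r) == pytest.approx(expected)

    def test_sensitivity_argument_is_clamped(self):
        # values above the clamp cannot push the terminal spread below 2.0
        assert terminal_sigma(40.0, 0.0) == pytest.approx(2.0)
        assert terminal_sigma(-5.0, 0.0) == pytest.approx(4.8)

    def test_terminal_value_working_range(self, grid):
        # fixation (r=0) to the grid's edge: the terminal value spans 2.0-5.8
        radii = [0.0] + grid.eccentricities
        vals = [terminal_sigma(db, r) for r in radii for db in np.linspace(-2, 50, 14)]
        assert min(vals) == pytest.approx(2.0)
        assert max(vals) <= 5.8 + 1e-9


class TestSelectStimulus:
    def test_point_mass_and_uniform(self):
        cfg = StrategyConfig()
        assert select_stimulus(LocationState(pmf=point_mass(30)), cfg) == 30
        support = default_support()
        uniform = Pmf(support, np.full_like(support, 1 / len(support)))
        assert select_stimulus(LocationState(pmf=uniform), cfg) == 24
        assert select_stimulus(LocationState(pmf=two_point(10, 30)), cfg) == 20

    def test_rounding_modes(self):
        state = LocationState(pmf=two_point(10, 31))
        assert select_stimulus(state, StrategyConfig(stimulus_rounding="none")) == 20.5
        assert select_stimulus(state, StrategyConfig()) == 21.0

    def test_terminated_location_rejected(self):
        state = LocationState(pmf=point_mass(30), terminated=True)
        with pytest.raises(ValueError):
            select_stimulus(state, StrategyConfig())


class TestSelectNextLocation:
    def test_first_phase_restricted_to_central_region(self, grid):
        cfg = StrategyConfig()
        rng = np.random.default_rng(0)
        for _ in range(30):
            loc = select_next_location(list(grid), 10, cfg, rng)
            assert loc.r <= 15.0

    def test_after_first_phase_any_location_possible(self, grid):
        cfg = StrategyConfig()
        rng = np.random.default_rng(1)
        chosen = {select_next_location(list(grid), 60, cfg, rng).index for _ in range(300)}
        assert any(grid[i].r > 15.0 for i in chosen)

    def test_single_candidate(self, grid):
        cfg = StrategyConfig()
        loc = select_next_location([grid[0]], 0, cfg, np.random.default_rng(2))
        assert loc is grid[0]

    def test_empty_active_set_rejected(self, grid):
        with pytest.raises(ValueError):
            select_next_location([], 0, StrategyConfig(), np.random.default_rng(3))


class TestApplyResponse:
    def fresh_states(self, grid):
        cfg = StrategyConfig()
        ref = normative_field(grid, cfg.normative)
        return [LocationState(pmf=build_prior(cfg.prior, ref[i])) for i in range(len(grid))], cfg

    def test_zero_policy_touches_only_tested_location(self, grid):
        states, cfg = self.fresh_states(grid)
        before = [s.pmf.mass.copy() for s in states]
        tested = grid.find(9, 9)
        apply_response(states, tested, 20.0, True, WeightPolicy("zero"), grid, cfg.likelihood)
        for i, s in enumerate(states):
            if i == tested.index:
                assert not np.allclose(s.pmf.mass, before[i])
                assert s.presentations == 1
            else:
                assert np.allclose(s.pmf.mass, before[i])
                assert s.presentations == 0

    def test_aize_neighbor_weight_matches_update_oracle(self, grid):
        # the illustrative off-grid pair (9,9)-(15,21) gives WL = 0.0934;
        # on the canonical grid the same rule is checked at (9,9)-(15,15)
        assert 1.0 / (0.5 * distance(_loc(9, 9), _loc(15, 21)) + 4.0) == pytest.approx(
            0.0934, abs=1e-4
        )
        states, cfg = self.fresh_states(grid)
        tested, neighbor = grid.find(9, 9), grid.find(15, 15)
        d = distance(tested, neighbor)
        w = 1.0 / (0.5 * d + 4.0)
        expected = update_pmf(states[neighbor.index].pmf, 20.0, True, w, cfg.likelihood)
        apply_response(states, tested, 20.0, True, WeightPolicy("aize"), grid, cfg.likelihood)
        assert np.allclose(states[neighbor.index].pmf.mass, expected.mass)

    def test_other_quadrant_untouched(self, grid):
        states, cfg = self.fresh_states(grid)
        other = grid.find(9, -9)
        before = states[other.index].pmf.mass.copy()
        apply_response(states, grid.find(9, 9), 20.0, True, WeightPolicy("aize"), grid, cfg.likelihood)
        assert np.allclose(states[other.index].pmf.mass, before)

    def test_terminated_neighbor_untouched(self, grid):
        states, cfg = self.fresh_states(grid)
        neighbor = grid.find(15, 15)
        states[neighbor.index].terminated = True
        before = states[neighbor.index].pmf.mass.copy()
        apply_response(states, grid.find(9, 9), 20.0, True, WeightPolicy("aize"), grid, cfg.likelihood)
        assert np.allclose(states[neighbor.index].pmf.mass, before)


class TestCheckTermination:
    def test_point_mass_terminates_immediately(self, grid):
        state = LocationState(pmf=point_mass(30), presentations=1)
        assert check_termination(state, grid.find(9, 9), StrategyConfig())

    def test_cap_forces_termination(self, grid):
        state = LocationState(pmf=two_point(5, 35), presentations=5)
        assert check_termination(state, grid.find(9, 9), StrategyConfig())

    def test_wide_pmf_below_cap_keeps_going(self, grid):
        state = LocationState(pmf=two_point(5, 35), presentations=3)  # sd 15
        assert not check_termination(state, grid.find(9, 9), StrategyConfig())


class TestVerification:
    def capped_state(self, estimate):
        state = LocationState(pmf=point_mass(estimate), presentations=5)
        state.capped_unconverged = True
        state.estimate = float(estimate)
        return state

    def test_high_estimate_skips_verification(self, grid):
        state = self.capped_state(20)
        out = verification_pass(
            state, grid.find(9, 9), StrategyConfig(), STEEP_OBSERVER, 20.0, np.random.default_rng(0)
        )
        assert out.verification_presentations == 0
        assert out.estimate == 20.0

    def test_first_not_seen_keeps_estimate(self, grid):
        state = self.capped_state(8)
        # true threshold 0 with a near-step curve: stimulus at 8 is never seen
        out = verification_pass(
            state, grid.find(9, 9), StrategyConfig(), STEEP_OBSERVER, 0.0, np.random.default_rng(0)
        )
        assert out.verification_presentations == 1
        assert out.estimate == 8.0

    def test_seen_triggers_second_presentation_and_reestimate(self, grid):
        state = self.capped_state(8)
        state.pmf = two_point(5, 11)  # mean 8, but mass can shift under updates
        # true threshold 30: the verification stimuli are always seen
        out = verification_pass(
            state, grid.find(9, 9), StrategyConfig(), STEEP_OBSERVER, 30.0, np.random.default_rng(0)
        )
        assert out.verification_presentations == 2
        assert out.estimate == pytest.approx(pmf_mean(out.pmf))
        assert out.estimate > 8.0  # two seen responses pull the estimate up

    def test_unconverged_precondition_enforced(self, grid):
        state = LocationState(pmf=point_mass(8), presentations=3, estimate=8.0)
        with pytest.raises(ValueError):
            verification_pass(
                state, grid.find(9, 9), StrategyConfig(), STEEP_OBSERVER, 8.0,
                np.random.default_rng(0),
            )


class TestRunTrial:
    def test_same_seed_reproduces_trial(self, grid, cohort):
        cfg = preset("aize")
        obs = ObserverConfig(0.15, 0.15)
        a = run_trial(cohort[12], grid, cfg, obs, 77)
        b = run_trial(cohort[12], grid, cfg, obs, 77)
        assert np.array_equal(a.estimates, b.estimates)
        assert a.events == b.events
        assert a.total_presentations == b.total_presentations

    def test_presentation_caps_hold(self, grid, cohort):
        cfg = preset("aize")
        obs = ObserverConfig(0.15, 0.15)
        for seed in range(5):
            res = run_trial(cohort[10], grid, cfg, obs, seed)
            assert res.presentations.max() <= 5
            assert (res.presentations + res.verification_presentations).max() <= 7

    def test_zero_weight_equals_independent_per_location_zest(self, grid, cohort):
        """With no neighbor updates, the trial is per-location ZEST: replaying
        each location's own response sequence through the reference PMF
        operations must reproduce the trial's estimates exactly."""
        cfg = preset("nonweighted")
        obs = ObserverConfig(0.09, 0.09)
        res = run_trial(cohort[14], grid, cfg, obs, 5)
        ref = normative_field(grid, cfg.normative)
        for loc in grid:
            events = [e for e in res.events if e["location"] == loc.index]
            pmf = build_prior(cfg.prior, ref[loc.index])
            n_ver = 0
            for e in events:
                if e["phase"] == "main":
                    pmf = update_pmf(pmf, e["stimulus"], e["seen"], 1.0, cfg.likelihood)
                else:
                    n_ver += 1
                    if n_ver == 1 and not e["seen"]:
                        continue
                    pmf = update_pmf(pmf, e["stimulus"], e["seen"], 1.0, cfg.likelihood)
            expected = np.clip(pmf_mean(pmf), *cfg.clamp_range)
            assert res.estimates[loc.index] == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("arm", ["aize", "nonweighted", "fixedweighted"])
    def test_replay_matches_fast_path(self, grid, cohort, arm):
        cfg = preset(arm)
        obs = ObserverConfig(0.09, 0.09)
        res = run_trial(cohort[13], grid, cfg, obs, 9)
        replayed = replay_trial(res, grid, cfg)
        assert np.allclose(replayed, res.estimates, atol=1e-9)

    def test_converges_to_truth_with_deterministic_observer(self, grid, cohort):
        """With a near-step response curve, no response errors, the cap
        lifted and a tight terminal spread, estimates settle within 1 dB of
        the (clamped) true thresholds."""
        cfg = StrategyConfig(
            weight_policy=WeightPolicy("zero"),
            max_presentations=50,
            sigma_db_coef=0.0,
            sigma_intercept=0.5,
            sigma_ecc_coef=0.0,
        )
        for fld in (cohort[3], cohort[12]):
            res = run_trial(fld, grid, cfg, STEEP_OBSERVER, 123)
            truth = np.clip(fld.sensitivity, *cfg.clamp_range)
            assert np.abs(res.estimates - truth).max() <= 1.0

    def test_field_grid_mismatch_rejected(self, grid):
        with pytest.raises(ValueError):
            run_trial(np.zeros(10), grid, preset("aize"), ObserverConfig(), 0)


def test_presets_cover_the_three_arms():
    assert preset("aize").weight_policy.mode == "aize"
    assert preset("nonweighted").weight_policy.mode == "zero"
    assert preset("fixedweighted").weight_policy.fixed_value == 0.33
    with pytest.raises(ValueError):
        preset("sita")
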