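"""The AIZE/ZEST thresholding state machine.

A trial maintains one PMF per grid location.  Each presentation:

1. pick a random active location (the first fifty presentations of a trial
   are restricted to locations within fifteen degrees of fixation);
2. present the mean of that location's PMF as the stimulus;
3. update the tested location's PMF with the full likelihood and — in the
   spatially weighted variants — every non-terminated location in the same
   quadrant with the likelihood raised to a distance-decaying weight
   WL(d) = 1/(0.5 d + 4) (AIZE) or a fixed weight (comparator);
4. terminate a location once its PMF spread falls below a terminal value
   that depends on estimated sensitivity and eccentricity, or once it has
   received five presentations.

Locations that hit the five-presentation cap without meeting the spread
criterion, and whose estimate is below 15 dB, get one or two verification
presentations whose handling depends on the first response.

`run_trial` is the fast vectorized driver; the module-level operations
(`select_stimulus`, `apply_response`, ...) are the reference semantics,
and `replay_trial` re-derives a trial's estimates from its event log using
only those reference operations (used to cross-check the fast path).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np

from .fields import NormativeModel, SensitivityField, normative_field
from .grid import GridLocation, TestGrid, distance, same_quadrant
from .observer import ObserverConfig, probability_seen
from .pmf import (
    LikelihoodShape,
    Pmf,
    PriorSpec,
    build_prior,
    default_support,
    likelihood_of_seeing,
    pmf_mean,
    pmf_sd,
    update_pmf,
)

__all__ = [
    "WeightPolicy",
    "StrategyConfig",
    "LocationState",
    "TrialResult",
    "weighted_likelihood",
    "terminal_sigma",
    "select_stimulus",
    "select_next_location",
    "apply_response",
    "check_termination",
    "verification_pass",
    "run_trial",
    "replay_trial",
    "preset",
]


def weighted_likelihood(d: float) -> float:
    """Distance-decaying update weight WL(d) = 1/(0.5 d + 4).

    Maximal (0.25) at the tested location itself and strictly decreasing
    with distance, so nearby locations borrow more strength from each
    response than remote ones.
    """
    if d < 0:
        raise ValueError("distance must be non-negative")
    return 1.0 / (0.5 * d + 4.0)


@dataclass(frozen=True)
class WeightPolicy:
    """How strongly a response at one location updates its neighbors.

    mode "aize": same-quadrant neighbors get WL(d); "fixed": a constant
    weight (0.33 in the comparator arm); "zero": no neighbor updates (the
    plain per-location ZEST comparator).  The tested location itself is
    always updated with `self_weight` (default 1, the ordinary Bayesian
    update).
    """

    mode: str = "aize"
    fixed_value: float = 0.33
    self_weight: float = 1.0

    def __post_init__(self):
        if self.mode not in ("aize", "fixed", "zero"):
            raise ValueError(f"unknown weight-policy mode {self.mode!r}")
        if not 0.0 <= self.fixed_value <= 1.0 or not 0.0 <= self.self_weight <= 1.0:
            raise ValueError("weights must lie in [0, 1]")

    def neighbor_weight(self, d: float) -> float:
        if self.mode == "zero":
            return 0.0
        if self.mode == "fixed":
            return self.fixed_value
        return weighted_likelihood(d)


@dataclass(frozen=True)
class StrategyConfig:
    """All tunables of the thresholding strategy."""

    weight_policy: WeightPolicy = WeightPolicy()
    max_presentations: int = 5
    verification_cutoff: float = 15.0       # dB; capped locations below this get retests
    first_phase_count: int = 50             # trial-global presentations in the central phase
    first_phase_eccentricity: float = 15.0  # deg
    first_phase_metric: str = "euclidean"   # or "chebyshev" (|x|,|y| <= limit)
    sigma_db_coef: float = -0.1             # terminal-spread formula coefficients
    sigma_intercept: float = 4.8
    sigma_ecc_coef: float = 0.2
    sigma_ecc_scale: float = 30.0
    sigma_db_clamp: tuple = (0.0, 28.0)     # dB clamp of the formula's sensitivity argument
    compare_variance: bool = False          # compare PMF variance (not sd) to the terminal value
    stimulus_rounding: str = "nearest"      # or "none"
    clamp_range: tuple = (0.0, 40.0)        # dB clamp on reported estimates
    count_verification_presentations: bool = True
    prior: PriorSpec = PriorSpec()
    likelihood: LikelihoodShape = LikelihoodShape()
    normative: NormativeModel = NormativeModel()

    def __post_init__(self):
        if self.max_presentations < 1 or self.first_phase_count < 0:
            raise ValueError("presentation counts must be positive")
        if self.stimulus_rounding not in ("nearest", "none"):
            raise ValueError("stimulus_rounding must be 'nearest' or 'none'")
        if self.first_phase_metric not in ("euclidean", "chebyshev"):
            raise ValueError("first_phase_metric must be 'euclidean' or 'chebyshev'")


#: Named strategy arms of the simulation study.
_PRESETS = {
    "aize": WeightPolicy(mode="aize"),
    "nonweighted": WeightPolicy(mode="zero"),
    "fixedweighted": WeightPolicy(mode="fixed", fixed_value=0.33),
}


def preset(name: str, **overrides) -> StrategyConfig:
    """A named strategy arm: "aize", "nonweighted" or "fixedweighted"."""
    if name not in _PRESETS:
        raise ValueError(f"unknown preset {name!r}; expected one of {sorted(_PRESETS)}")
    return StrategyConfig(weight_policy=_PRESETS[name], **overrides)


def terminal_sigma(estimated_db: float, r: float, cfg: StrategyConfig = StrategyConfig()) -> float:
    """Terminal PMF-spread value as a function of sensitivity and eccentricity.

    (-0.1 dB + 4.8) * (1 + r/30 * 0.2) with the sensitivity argument
    clamped (default to [0, 28] dB) so the terminal value stays within its
    intended 2.0-5.8 working range: tight termination where sensitivity is
    high and central, looser in damaged or peripheral regions.
    """
    if r < 0:
        raise ValueError("eccentricity must be non-negative")
    db = min(max(estimated_db, cfg.sigma_db_clamp[0]), cfg.sigma_db_clamp[1])
    return (cfg.sigma_db_coef * db + cfg.sigma_intercept) * (
        1.0 + r / cfg.sigma_ecc_scale * cfg.sigma_ecc_coef
    )


@dataclass
class LocationState:
    """Per-location Bayesian state during a trial."""

    pmf: Pmf
    presentations: int = 0
    verification_presentations: int = 0
    terminated: bool = False
    capped_unconverged: bool = False  # hit the cap without meeting the spread criterion
    estimate: float | None = None     # unclamped posterior mean at termination
    history: list = dc_field(default_factory=list)  # (stimulus, seen, phase)


@dataclass
class TrialResult:
    """Outcome of one simulated test."""

    estimates: np.ndarray                 # reported (clamped) dB per location
    raw_estimates: np.ndarray             # unclamped posterior means
    presentations: np.ndarray             # direct presentations per location
    verification_presentations: np.ndarray
    total_presentations: int
    events: list                          # dicts: step, location, x, y, stimulus, seen, phase

    def events_frame(self):
        import pandas as pd

        return pd.DataFrame(self.events)


def _round_stimulus(value: float, cfg: StrategyConfig) -> float:
    if cfg.stimulus_rounding == "nearest":
        return float(math.floor(value + 0.5))
    return float(value)


def select_stimulus(state: LocationState, cfg: StrategyConfig) -> float:
    """Next stimulus: the PMF mean (ZEST rule), rounded per config."""
    if state.terminated:
        raise ValueError("cannot select a stimulus for a terminated location")
    return _round_stimulus(pmf_mean(state.pmf), cfg)


def _in_first_phase_region(loc: GridLocation, cfg: StrategyConfig) -> bool:
    if cfg.first_phase_metric == "euclidean":
        return loc.r <= cfg.first_phase_eccentricity
    return max(abs(loc.x), abs(loc.y)) <= cfg.first_phase_eccentricity


def select_next_location(
    active: list[GridLocation],
    presentations_so_far: int,
    cfg: StrategyConfig,
    rng: np.random.Generator,
) -> GridLocation:
    """Random location choice with the central first phase.

    While fewer than `first_phase_count` stimuli have been presented in
    the whole trial, selection is restricted to active locations within
    `first_phase_eccentricity` degrees (when any remain); afterwards all
    active locations are eligible.
    """
    if not active:
        raise ValueError("no active locations to select from")
    if presentations_so_far < cfg.first_phase_count:
        central = [loc for loc in active if _in_first_phase_region(loc, cfg)]
        if central:
            return central[int(rng.integers(len(central)))]
    return active[int(rng.integers(len(active)))]


def apply_response(
    states: list[LocationState],
    tested: GridLocation,
    stimulus: float,
    seen: bool,
    policy: WeightPolicy,
    grid: TestGrid,
    shape: LikelihoodShape = LikelihoodShape(),
) -> list[LocationState]:
    """Reference semantics of one response: self + same-quadrant updates.

    Mutates `states` in place (and returns it): the tested location's PMF
    gets the full-weight update and a presentation count increment; every
    non-terminated location in the same quadrant gets the weighted update;
    terminated and cross-quadrant locations are untouched.
    """
    i = tested.index
    if states[i].terminated:
        raise ValueError("cannot present to a terminated location")
    states[i].pmf = update_pmf(states[i].pmf, stimulus, seen, policy.self_weight, shape)
    states[i].presentations += 1
    states[i].history.append((stimulus, seen, "main"))
    for loc in grid:
        if loc.index == i or states[loc.index].terminated:
            continue
        if not same_quadrant(loc, tested):
            continue
        w = policy.neighbor_weight(distance(loc, tested))
        if w > 0:
            states[loc.index].pmf = update_pmf(states[loc.index].pmf, stimulus, seen, w, shape)
    return states


def check_termination(state: LocationState, location: GridLocation, cfg: StrategyConfig) -> bool:
    """True once the PMF spread criterion or the presentation cap is met."""
    spread = pmf_sd(state.pmf)
    if cfg.compare_variance:
        spread = spread**2
    if state.presentations >= cfg.max_presentations:
        return True
    return spread <= terminal_sigma(pmf_mean(state.pmf), location.r, cfg)


def verification_pass(
    state: LocationState,
    location: GridLocation,
    cfg: StrategyConfig,
    observer_cfg: ObserverConfig,
    true_threshold: float,
    rng: np.random.Generator,
) -> LocationState:
    """Retest a capped, unconverged location with a low estimate.

    Only locations that hit the presentation cap without meeting the
    spread criterion and whose estimate is below the cutoff (15 dB) are
    retested.  One stimulus is presented at the current estimate: if not
    seen, the estimate stands and the response is discarded from
    estimation; if seen, a second stimulus follows and both responses are
    applied as full-weight updates, the estimate becoming the resulting
    PMF mean.  Verification responses never propagate to neighbors.
    """
    if not state.capped_unconverged:
        raise ValueError("verification applies only to capped, unconverged locations")
    if state.estimate is None:
        raise ValueError("location has no estimate to verify")
    if state.estimate >= cfg.verification_cutoff:
        return state
    stim = _round_stimulus(state.estimate, cfg)
    seen = bool(rng.random() < probability_seen(true_threshold, stim, observer_cfg))
    state.verification_presentations += 1
    state.history.append((stim, seen, "verification"))
    if not seen:
        return state
    state.pmf = update_pmf(state.pmf, stim, True, 1.0, cfg.likelihood)
    stim2 = _round_stimulus(pmf_mean(state.pmf), cfg)
    seen2 = bool(rng.random() < probability_seen(true_threshold, stim2, observer_cfg))
    state.verification_presentations += 1
    state.history.append((stim2, seen2, "verification"))
    state.pmf = update_pmf(state.pmf, stim2, seen2, 1.0, cfg.likelihood)
    state.estimate = pmf_mean(state.pmf)
    return state


# --------------------------------------------------------------------------
# Fast vectorized trial driver


class _LikelihoodTable:
    """Cache of (log-)likelihood vectors over the support per stimulus."""

    def __init__(self, support: np.ndarray, shape: LikelihoodShape):
        self.support = support
        self.shape = shape
        self._cache: dict[tuple[float, bool], tuple[np.ndarray, np.ndarray]] = {}

    def get(self, stimulus: float, seen: bool) -> tuple[np.ndarray, np.ndarray]:
        key = (stimulus, seen)
        hit = self._cache.get(key)
        if hit is None:
            L = likelihood_of_seeing(self.support, stimulus, self.shape)
            if not seen:
                L = 1.0 - L
            hit = (L, np.log(L))
            self._cache[key] = hit
        return hit


# Trial-invariant tables, cached across trials on their frozen config keys.
_LIKELIHOOD_TABLES: dict = {}
_PRIOR_CACHE: dict = {}
_NEIGHBOR_CACHE: dict = {}


def _likelihood_table(step: float, shape: LikelihoodShape) -> _LikelihoodTable:
    key = (step, shape)
    table = _LIKELIHOOD_TABLES.get(key)
    if table is None:
        table = _LikelihoodTable(default_support(step), shape)
        _LIKELIHOOD_TABLES[key] = table
    return table


def _prior_mass(spec: PriorSpec, normative_value: float) -> np.ndarray:
    key = (spec, round(normative_value, 9))
    mass = _PRIOR_CACHE.get(key)
    if mass is None:
        mass = build_prior(spec, normative_value).mass
        mass.setflags(write=False)
        _PRIOR_CACHE[key] = mass
    return mass


def _neighbor_tables(grid: TestGrid, policy: WeightPolicy):
    """Per-location same-quadrant neighbor indices and update weights."""
    key = (grid, policy)
    hit = _NEIGHBOR_CACHE.get(key)
    if hit is None:
        nbr_idx, nbr_w = [], []
        for loc in grid:
            idx, w = [], []
            for other in grid:
                if other.index == loc.index or not same_quadrant(loc, other):
                    continue
                weight = policy.neighbor_weight(distance(loc, other))
                if weight > 0:
                    idx.append(other.index)
                    w.append(weight)
            nbr_idx.append(np.array(idx, dtype=int))
            nbr_w.append(np.array(w))
        hit = (nbr_idx, nbr_w)
        _NEIGHBOR_CACHE[key] = hit
    return hit


def _truth_array(true_field, grid: TestGrid) -> np.ndarray:
    if isinstance(true_field, SensitivityField):
        if len(true_field.sensitivity) != len(grid):
            raise ValueError("field and grid sizes differ")
        return np.asarray(true_field.sensitivity, dtype=float)
    arr = np.asarray(true_field, dtype=float)
    if arr.shape != (len(grid),):
        raise ValueError("true field must define a sensitivity for every grid location")
    return arr


def run_trial(
    true_field,
    grid: TestGrid,
    cfg: StrategyConfig,
    observer_cfg: ObserverConfig,
    seed,
) -> TrialResult:
    """Simulate one complete test of a field.

    `seed` may be an int or a numpy SeedSequence; the trial consumes a
    single seeded random stream (location draw then response draw per
    presentation, verification draws last, in ascending location order),
    so identical inputs replay bit-exactly.
    """
    truth = _truth_array(true_field, grid)
    rng = np.random.default_rng(seed)
    n = len(grid)
    support = default_support(cfg.prior.step)
    support2 = support**2
    normative = normative_field(grid, cfg.normative)

    mass = np.stack([_prior_mass(cfg.prior, normative[i]) for i in range(n)])
    means = mass @ support
    sds = np.sqrt(np.maximum(mass @ support2 - means**2, 0.0))
    ecc = np.array(grid.eccentricities)
    presentations = np.zeros(n, dtype=int)
    ver_presentations = np.zeros(n, dtype=int)
    active = np.ones(n, dtype=bool)
    capped_unconverged = np.zeros(n, dtype=bool)

    nbr_idx, nbr_w = _neighbor_tables(grid, cfg.weight_policy)
    first_phase = np.array([_in_first_phase_region(loc, cfg) for loc in grid])
    table = _likelihood_table(cfg.prior.step, cfg.likelihood)
    self_w = cfg.weight_policy.self_weight

    def spread(j) -> float:
        return sds[j] ** 2 if cfg.compare_variance else sds[j]

    def terminal(j) -> float:
        return terminal_sigma(means[j], ecc[j], cfg)

    events: list[dict] = []
    total = 0
    step = 0
    active_idx = list(range(n))
    while active_idx:
        if total < cfg.first_phase_count:
            central = [j for j in active_idx if first_phase[j]]
            pool = central if central else active_idx
        else:
            pool = active_idx
        i = pool[int(rng.integers(len(pool)))]

        stim = _round_stimulus(means[i], cfg)
        seen = bool(rng.random() < probability_seen(truth[i], stim, observer_cfg))
        L, logL = table.get(stim, seen)

        mass[i] = mass[i] * (L if self_w == 1.0 else np.exp(self_w * logL))
        mass[i] /= mass[i].sum()
        presentations[i] += 1
        total += 1

        touched = [i]
        sub = nbr_idx[i][active[nbr_idx[i]]]
        if sub.size:
            w = nbr_w[i][active[nbr_idx[i]]]
            mass[sub] *= np.exp(np.outer(w, logL))
            mass[sub] /= mass[sub].sum(axis=1, keepdims=True)
            touched.extend(sub.tolist())

        means[touched] = mass[touched] @ support
        sds[touched] = np.sqrt(np.maximum(mass[touched] @ support2 - means[touched] ** 2, 0.0))

        step += 1
        loc = grid[i]
        events.append(
            {"step": step, "location": i, "x": loc.x, "y": loc.y,
             "stimulus": stim, "seen": seen, "phase": "main"}
        )

        for j in touched:
            if not active[j]:
                continue
            met_spread = spread(j) <= terminal(j)
            capped = presentations[j] >= cfg.max_presentations
            if met_spread or capped:
                active[j] = False
                capped_unconverged[j] = capped and not met_spread
                active_idx.remove(j)

    raw_estimates = means.copy()

    # verification retests, ascending location order
    for i in range(n):
        if not capped_unconverged[i] or raw_estimates[i] >= cfg.verification_cutoff:
            continue
        stim = _round_stimulus(raw_estimates[i], cfg)
        seen = bool(rng.random() < probability_seen(truth[i], stim, observer_cfg))
        ver_presentations[i] += 1
        step += 1
        loc = grid[i]
        events.append(
            {"step": step, "location": i, "x": loc.x, "y": loc.y,
             "stimulus": stim, "seen": seen, "phase": "verification"}
        )
        if not seen:
            continue  # response discarded from estimation
        L, _ = table.get(stim, True)
        mass[i] = mass[i] * L
        mass[i] /= mass[i].sum()
        means[i] = mass[i] @ support
        stim2 = _round_stimulus(means[i], cfg)
        seen2 = bool(rng.random() < probability_seen(truth[i], stim2, observer_cfg))
        ver_presentations[i] += 1
        step += 1
        events.append(
            {"step": step, "location": i, "x": loc.x, "y": loc.y,
             "stimulus": stim2, "seen": seen2, "phase": "verification"}
        )
        L2, _ = table.get(stim2, seen2)
        mass[i] = mass[i] * L2
        mass[i] /= mass[i].sum()
        means[i] = mass[i] @ support
        raw_estimates[i] = means[i]

    reported = np.clip(raw_estimates, cfg.clamp_range[0], cfg.clamp_range[1])
    total_presentations = int(presentations.sum())
    if cfg.count_verification_presentations:
        total_presentations += int(ver_presentations.sum())
    return TrialResult(
        estimates=reported,
        raw_estimates=raw_estimates,
        presentations=presentations,
        verification_presentations=ver_presentations,
        total_presentations=total_presentations,
        events=events,
    )


def replay_trial(result: TrialResult, grid: TestGrid, cfg: StrategyConfig) -> np.ndarray:
    """Re-derive a trial's reported estimates from its event log.

    Uses only the reference PMF operations (no randomness, no fast path),
    applying the same self/neighbor weighting, termination bookkeeping and
    verification rules.  Serves as an independent consistency check of
    `run_trial`'s vectorized updates.
    """
    normative = normative_field(grid, cfg.normative)
    states = [LocationState(pmf=build_prior(cfg.prior, normative[i])) for i in range(len(grid))]
    for ev in result.events:
        i = ev["location"]
        if ev["phase"] == "main":
            apply_response(
                states, grid[i], ev["stimulus"], ev["seen"],
                cfg.weight_policy, grid, cfg.likelihood,
            )
            for j, st in enumerate(states):
                if not st.terminated and check_termination(st, grid[j], cfg):
                    st.terminated = True
                    st.estimate = pmf_mean(st.pmf)
        else:  # verification
            st = states[i]
            st.verification_presentations += 1
            st.history.append((ev["stimulus"], ev["seen"], "verification"))
            # a first "not seen" is discarded from estimation; a first "seen"
            # and the second response (whatever it is) are applied in full
            if st.verification_presentations == 1 and not ev["seen"]:
                continue
            st.pmf = update_pmf(st.pmf, ev["stimulus"], ev["seen"], 1.0, cfg.likelihood)
            st.estimate = pmf_mean(st.pmf)
    estimates = np.array(
        [st.estimate if st.estimate is not None else pmf_mean(st.pmf) for st in states]
    )
    return np.clip(estimates, cfg.clamp_range[0], cfg.clamp_range[1])
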