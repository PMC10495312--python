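"""Per-location Bayesian state: probability mass functions over candidate
thresholds and their (weighted) likelihood updates.

Each test location carries a discrete PMF over candidate sensitivity
thresholds on a fixed dB support (default -2..50 dB in 1 dB steps).  The
two bins outside the clinically reportable 0..40 dB range exist to keep
the posterior mean from being dragged toward the interior at the extremes.
A trial presents the PMF mean as the stimulus and multiplies the PMF by a
likelihood-of-seeing curve (or its complement) after each response; the
spatially weighted variant raises the likelihood to a fractional power
before multiplying, so weight 0 is a no-op and weight 1 the full Bayesian
update.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

__all__ = [
    "SUPPORT_MIN",
    "SUPPORT_MAX",
    "Pmf",
    "PriorSpec",
    "LikelihoodShape",
    "build_prior",
    "pmf_mean",
    "pmf_sd",
    "likelihood_of_seeing",
    "update_pmf",
]

SUPPORT_MIN = -2.0
SUPPORT_MAX = 50.0


def default_support(step: float = 1.0) -> np.ndarray:
    """The canonical threshold support: -2..50 dB inclusive at `step`."""
    n = int(round((SUPPORT_MAX - SUPPORT_MIN) / step)) + 1
    return np.linspace(SUPPORT_MIN, SUPPORT_MAX, n)


@dataclass(frozen=True)
class Pmf:
    """A discrete probability mass function over candidate thresholds.

    `support` is an ordered array of dB levels; `mass` the probability of
    each.  Mass is normalized (sum 1 within 1e-9) and non-negative.
    """

    support: np.ndarray
    mass: np.ndarray

    def __post_init__(self):
        support = np.asarray(self.support, dtype=float)
        mass = np.asarray(self.mass, dtype=float)
        if support.shape != mass.shape or support.ndim != 1:
            raise ValueError("support and mass must be 1-d arrays of equal length")
        if np.any(mass < 0):
            raise ValueError("PMF mass must be non-negative")
        total = mass.sum()
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"PMF mass must sum to 1 (got {total!r})")
        object.__setattr__(self, "support", support)
        object.__setattr__(self, "mass", mass)

    @property
    def mean(self) -> float:
        return pmf_mean(self)

    @property
    def sd(self) -> float:
        return pmf_sd(self)

    def to_json(self) -> str:
        return json.dumps({"support": self.support.tolist(), "mass": self.mass.tolist()})

    @classmethod
    def from_json(cls, text: str) -> "Pmf":
        d = json.loads(text)
        return cls(np.asarray(d["support"]), np.asarray(d["mass"]))


@dataclass(frozen=True)
class PriorSpec:
    """Parameters of the bimodal prior mixture.

    The prior mixes a "normal" component centred on the location's
    normative sensitivity with a "damaged" component near the floor, in a
    1:1 ratio by default (mirroring priors built from normal and
    glaucomatous reference data pooled equally), plus a small uniform
    floor so no candidate threshold is ever excluded outright.
    """

    normal_mode_offset: float = 0.0   # dB added to the normative sensitivity
    normal_spread: float = 4.0        # dB sd of the normal component
    damaged_mode: float = 5.0         # dB mode of the damaged component
    damaged_spread: float = 12.0      # dB sd of the damaged component
    mixture_weight: float = 0.5       # mass fraction on the normal component
    floor_mass: float = 1e-3          # per-bin uniform floor before renormalizing
    step: float = 1.0                 # support step in dB

    def __post_init__(self):
        if not 0.0 <= self.mixture_weight <= 1.0:
            raise ValueError("mixture_weight must lie in [0, 1]")
        if self.normal_spread < 0 or self.damaged_spread < 0:
            raise ValueError("component spreads must be non-negative")
        if self.mixture_weight < 1.0 and self.damaged_spread == 0 and self.floor_mass == 0:
            # a zero-spread damaged component is only meaningful as a point mass
            pass
        if self.floor_mass < 0:
            raise ValueError("floor_mass must be non-negative")


@dataclass(frozen=True)
class LikelihoodShape:
    """Shape of the internal likelihood-of-seeing curve used for updates.

    A cumulative Gaussian in (candidate threshold - stimulus) with slope
    `slope` (dB sd) and asymptotes `gamma` (lower) and `lam` (upper miss
    rate).  Distinct from the simulated observer's frequency-of-seeing
    curve: this is the strategy's own response model.
    """

    slope: float = 1.0
    gamma: float = 0.03
    lam: float = 0.03

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("likelihood slope must be positive")
        if not (0 <= self.gamma < 1 and 0 <= self.lam < 1 and self.gamma + self.lam < 1):
            raise ValueError("asymptotes must satisfy 0 <= gamma, lam and gamma + lam < 1")


def _discretized_gaussian(support: np.ndarray, mode: float, spread: float) -> np.ndarray:
    if spread == 0:
        w = np.zeros_like(support)
        w[int(np.argmin(np.abs(support - mode)))] = 1.0
        return w
    w = norm.pdf(support, loc=mode, scale=spread)
    total = w.sum()
    if total == 0:
        raise ValueError("degenerate component: no mass on support")
    return w / total


def build_prior(spec: PriorSpec, normative_sensitivity: float) -> Pmf:
    """Construct the bimodal prior PMF for one location.

    Parameters
    ----------
    spec:
        Mixture parameters.
    normative_sensitivity:
        The location's expected normal sensitivity in dB; the normal
        component is centred here (plus `spec.normal_mode_offset`).
    """
    support = default_support(spec.step)
    mode = normative_sensitivity + spec.normal_mode_offset
    if not (support[0] <= mode <= support[-1]):
        raise ValueError(f"normative sensitivity {mode} dB outside support")
    normal = _discretized_gaussian(support, mode, spec.normal_spread)
    damaged = _discretized_gaussian(support, spec.damaged_mode, spec.damaged_spread)
    mass = spec.mixture_weight * normal + (1 - spec.mixture_weight) * damaged + spec.floor_mass
    mass /= mass.sum()
    return Pmf(support, mass)


def pmf_mean(p: Pmf) -> float:
    """Probability-weighted mean of the support, dB."""
    return float(np.dot(p.support, p.mass))


def pmf_sd(p: Pmf) -> float:
    """Probability-weighted standard deviation of the support, dB."""
    m = pmf_mean(p)
    var = float(np.dot((p.support - m) ** 2, p.mass))
    return float(np.sqrt(max(var, 0.0)))


def likelihood_of_seeing(
    candidate_threshold, stimulus: float, shape: LikelihoodShape = LikelihoodShape()
):
    """Probability of a "seen" response under the strategy's response model.

    gamma + (1 - gamma - lam) * Phi((t - stimulus) / slope): increasing in
    the candidate threshold t, decreasing in stimulus dB (dimmer stimuli
    are less often seen by an observer of fixed sensitivity).
    """
    t = np.asarray(candidate_threshold, dtype=float)
    p = shape.gamma + (1 - shape.gamma - shape.lam) * norm.cdf((t - stimulus) / shape.slope)
    return float(p) if np.isscalar(candidate_threshold) else p


def update_pmf(
    prior: Pmf,
    stimulus: float,
    seen: bool,
    weight: float = 1.0,
    shape: LikelihoodShape = LikelihoodShape(),
) -> Pmf:
    """Weighted Bayesian update of a PMF after one response.

    posterior(t) proportional to prior(t) * L(t)**weight, with
    L(t) = P(seen | t) if the stimulus was seen and 1 - P(seen | t)
    otherwise.  weight = 1 is the ordinary ZEST update; weight = 0 leaves
    the prior untouched (the non-weighted comparator's neighbor rule);
    fractional weights implement the distance-decayed neighbor updates.
    """
    if not 0.0 <= weight <= 1.0:
        raise ValueError("update weight must lie in [0, 1]")
    if weight == 0.0:
        return prior
    L = likelihood_of_seeing(prior.support, stimulus, shape)
    if not seen:
        L = 1.0 - L
    post = prior.mass * np.power(L, weight)
    total = post.sum()
    if total <= 0 or not np.isfinite(total):
        raise ValueError(
            f"degenerate posterior (sum {total!r}) for stimulus {stimulus}, seen={seen}"
        )
    return Pmf(prior.support, post / total)
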