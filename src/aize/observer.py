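"""Simulated patient: frequency-of-seeing responses with FP/FN errors.

The simulated observer answers "seen"/"not seen" from a cumulative-Gaussian
frequency-of-seeing (FOS) curve around the true threshold.  The curve's
spread grows as sensitivity falls (responses become noisier in damaged
field regions), following the log-linear law sd = exp(a*t + b) capped at a
maximum, and is contaminated by a false-positive floor and a
false-negative ceiling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ObserverConfig",
    "ErrorCondition",
    "ERROR_CONDITIONS",
    "fos_slope_sd",
    "probability_seen",
    "respond",
]


@dataclass(frozen=True)
class ObserverConfig:
    """Tunables of the simulated patient.

    fp, fn:
        False-positive / false-negative response probabilities (the
        asymptotes of the contaminated FOS curve).
    slope_coef, slope_intercept:
        Coefficients (a, b) of the sensitivity-dependent FOS spread
        sd(t) = exp(a*t + b) dB.  Defaults follow the published
        log-linear variability law for perimetric thresholds.
    slope_cap:
        Maximum FOS spread in dB (default 4).
    """

    fp: float = 0.03
    fn: float = 0.03
    slope_coef: float = -0.081
    slope_intercept: float = 3.27
    slope_cap: float = 4.0

    def __post_init__(self):
        if self.fp < 0 or self.fn < 0 or self.fp + self.fn >= 1:
            raise ValueError("need fp, fn >= 0 and fp + fn < 1")
        if self.slope_cap <= 0:
            raise ValueError("slope_cap must be positive")

    def with_errors(self, fp: float, fn: float) -> "ObserverConfig":
        return ObserverConfig(fp, fn, self.slope_coef, self.slope_intercept, self.slope_cap)


@dataclass(frozen=True)
class ErrorCondition:
    """A named (FP, FN) response-error pair, rates as fractions."""

    label: str
    fp: float
    fn: float


#: The five canonical error conditions of the simulation study, percent FP/FN.
ERROR_CONDITIONS: tuple[ErrorCondition, ...] = (
    ErrorCondition("fp03_fn03", 0.03, 0.03),
    ErrorCondition("fp09_fn09", 0.09, 0.09),
    ErrorCondition("fp15_fn15", 0.15, 0.15),
    ErrorCondition("fp15_fn03", 0.15, 0.03),
    ErrorCondition("fp03_fn15", 0.03, 0.15),
)


def fos_slope_sd(true_threshold: float, cfg: ObserverConfig = ObserverConfig()) -> float:
    """FOS spread (cumulative-Gaussian sd, dB) at a given true sensitivity.

    min(exp(a*t + b), cap): spread shrinks with increasing sensitivity and
    is capped (default 4 dB) so deeply damaged locations do not become
    arbitrarily unreliable.
    """
    return float(min(np.exp(cfg.slope_coef * true_threshold + cfg.slope_intercept), cfg.slope_cap))


def probability_seen(
    true_threshold: float, stimulus: float, cfg: ObserverConfig = ObserverConfig()
) -> float:
    """Probability the observer reports a stimulus as seen.

    fp + (1 - fp - fn) * Phi((t - stimulus) / sd(t)); bounded in
    [fp, 1 - fn] and non-increasing in stimulus dB (dimmer = less seen).
    """
    sd = fos_slope_sd(true_threshold, cfg)
    phi = 0.5 * (1.0 + math.erf((true_threshold - stimulus) / (sd * math.sqrt(2.0))))
    return float(cfg.fp + (1 - cfg.fp - cfg.fn) * phi)


def respond(
    true_threshold: float,
    stimulus: float,
    cfg: ObserverConfig,
    rng: np.random.Generator,
) -> bool:
    """One Bernoulli response draw from the FOS curve."""
    return bool(rng.random() < probability_seen(true_threshold, stimulus, cfg))
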