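"""Synthetic validation samples and the deterministic case-study fixture.

``generate_sample`` produces individual-level (risk, outcome) data from a
logit-normal risk model: predicted risks are ``expit(X)`` with X normal,
which yields the right-skewed risk distributions typical of low-prevalence
clinical settings, and true event probabilities follow a logistic
calibration map ``expit(intercept + slope * logit(risk))`` so both
well-calibrated and miscalibrated models can be emulated.

``gusto_like_fixture`` is a hard-coded 500-record sample mimicking a pilot
validation of a 30-day mortality model after myocardial infarction: 43
events, and at the 0.02 risk threshold exactly TP=41, FN=2, TN=147,
FP=310.  Individual risk values are arbitrary fixed constants; only the
classification counts at z=0.02 are contractual.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import numpy as np
from scipy.special import expit, logit

from .nb import ValidationSample

__all__ = ["GeneratorSpec", "generate_sample", "gusto_like_fixture", "fixture_path"]


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of the logit-normal synthetic sample generator.

    ``mu`` / ``sigma`` are the location and scale of predicted risks on the
    logit scale; ``cal_intercept`` / ``cal_slope`` link predicted risk to
    the true event probability on the logit scale (0, 1 = a perfectly
    calibrated model).  Defaults emulate a low-prevalence mortality model
    with implied prevalence around 0.08.
    """

    n: int
    mu: float = -2.9
    sigma: float = 1.1
    cal_intercept: float = 0.0
    cal_slope: float = 1.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.sigma < 0:
            raise ValueError("sigma must be nonnegative")

    def implied_prevalence(self, n_quad: int = 200) -> float:
        """E[event probability] under this generator, by Gauss-Hermite quadrature."""
        nodes, weights = np.polynomial.hermite_e.hermegauss(n_quad)
        x = self.mu + self.sigma * nodes
        probs = expit(self.cal_intercept + self.cal_slope * x)
        return float(np.sum(weights * probs) / np.sum(weights))


def generate_sample(spec: GeneratorSpec) -> ValidationSample:
    """Draw a synthetic validation sample; bit-reproducible under a fixed seed."""
    rng = np.random.default_rng(spec.seed)
    linear = rng.normal(spec.mu, spec.sigma, size=spec.n)
    risks = expit(linear)
    true_prob = expit(spec.cal_intercept + spec.cal_slope * linear)
    outcomes = (rng.random(spec.n) < true_prob).astype(int)
    return ValidationSample(risks=risks, outcomes=outcomes)


def gusto_like_fixture() -> ValidationSample:
    """The fixed 500-record pilot sample (43 events; TP/FN/TN/FP = 41/2/147/310 at z=0.02)."""
    # events: 41 at or above the 0.02 threshold, 2 below
    event_risks = np.concatenate(
        [np.round(np.linspace(0.02, 0.60, 41), 6), [0.008, 0.015]]
    )
    # non-events: 310 at or above (false positives), 147 below (true negatives)
    nonevent_risks = np.concatenate(
        [
            np.round(np.linspace(0.02, 0.35, 310), 6),
            np.round(np.linspace(0.001, 0.0199, 147), 6),
        ]
    )
    risks = np.concatenate([event_risks, nonevent_risks])
    outcomes = np.concatenate([np.ones(43, dtype=int), np.zeros(457, dtype=int)])
    return ValidationSample(risks=risks, outcomes=outcomes)


def fixture_path() -> str:
    """Filesystem path of the packaged fixture CSV (synthetic risk values)."""
    return str(resources.files("nbvoi").joinpath("data/gusto_like_fixture.csv"))
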