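"""Net-benefit calculus for risk prediction models.

Decision-curve analysis compares three strategies for acting on a binary
risk prediction at a chosen risk threshold ``z``:

* ``TREAT_NONE`` — withhold treatment from everyone (net benefit 0 by
  definition),
* ``USE_MODEL`` — treat those whose predicted risk is at or above ``z``,
* ``TREAT_ALL`` — treat everyone.

Net benefit (NB) is measured in net true-positive units: the probability of
a true-positive classification minus the probability of a false positive
weighted by the exchange rate ``omega = z / (1 - z)``, the number of false
positives a decision maker considers equivalent in harm to the benefit of
one true positive.  With ``theta = (prevalence, sensitivity, specificity)``
at the threshold:

    NB(treat none)  = 0
    NB(use model)   = prev * sens - (1 - prev) * (1 - spec) * omega
    NB(treat all)   = prev - (1 - prev) * omega

Everything here is shared plumbing for the value-of-information algorithms:
typed containers, plug-in estimates from confusion counts, decision curves,
and population scaling of per-decision value.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd

__all__ = [
    "Strategy",
    "Threshold",
    "ThetaTriplet",
    "ConfusionCounts",
    "PopulationScale",
    "ValidationSample",
    "net_benefit",
    "nb_all_strategies",
    "enb_current_plugin",
    "scale_to_population",
    "decision_curve",
]


class Strategy(IntEnum):
    """The three default strategies of decision-curve analysis.

    Indices are part of the contract: argmax ties are always broken toward
    the lowest index, i.e. the less interventionist strategy.
    """

    TREAT_NONE = 0
    USE_MODEL = 1
    TREAT_ALL = 2


@dataclass(frozen=True)
class Threshold:
    """Risk threshold ``z`` with its implied exchange rate.

    ``z`` must lie strictly inside (0, 1); the exchange rate
    ``omega = z / (1 - z)`` is derived and never set by the user.
    Predicted risks exactly equal to ``z`` are classified positive.
    """

    z: float

    def __post_init__(self) -> None:
        z = float(self.z)
        if not np.isfinite(z) or not (0.0 < z < 1.0):
            raise ValueError(
                f"risk threshold must lie strictly in (0, 1); got {self.z!r}"
            )
        object.__setattr__(self, "z", z)

    @property
    def omega(self) -> float:
        """Exchange rate: false positives per true positive of equal utility."""
        return self.z / (1.0 - self.z)


def _check_probability(name: str, value: float) -> float:
    value = float(value)
    if not np.isfinite(value) or not (0.0 <= value <= 1.0):
        raise ValueError(f"{name} must be a probability in [0, 1]; got {value!r}")
    return value


@dataclass(frozen=True)
class ThetaTriplet:
    """(prevalence, sensitivity, specificity) at a fixed threshold.

    This is the parameter vector of the net-benefit model; the implied cell
    probabilities ``p_tp = prev * sens`` and ``p_fp = (1 - prev) * (1 - spec)``
    are exposed as properties.
    """

    prevalence: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        for name in ("prevalence", "sensitivity", "specificity"):
            object.__setattr__(self, name, _check_probability(name, getattr(self, name)))

    @property
    def p_tp(self) -> float:
        return self.prevalence * self.sensitivity

    @property
    def p_fp(self) -> float:
        return (1.0 - self.prevalence) * (1.0 - self.specificity)


@dataclass(frozen=True)
class ConfusionCounts:
    """Confusion-matrix counts of a binary validation sample at a threshold."""

    n_tp: int
    n_fn: int
    n_tn: int
    n_fp: int

    def __post_init__(self) -> None:
        for name in ("n_tp", "n_fn", "n_tn", "n_fp"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValueError(f"{name} must be a nonnegative integer; got {v!r}")
            object.__setattr__(self, name, int(v))

    @property
    def total(self) -> int:
        return self.n_tp + self.n_fn + self.n_tn + self.n_fp

    @property
    def n_events(self) -> int:
        return self.n_tp + self.n_fn

    @property
    def n_nonevents(self) -> int:
        return self.n_tn + self.n_fp

    def to_theta(self) -> ThetaTriplet:
        """Plug-in proportions.  Requires at least one event and one non-event;
        Bayesian workflows should go through priors instead."""
        if self.total == 0:
            raise ValueError("cannot form plug-in estimates from zero total count")
        if self.n_events == 0:
            raise ValueError("no events: plug-in sensitivity is undefined")
        if self.n_nonevents == 0:
            raise ValueError("no non-events: plug-in specificity is undefined")
        return ThetaTriplet(
            prevalence=self.n_events / self.total,
            sensitivity=self.n_tp / self.n_events,
            specificity=self.n_tn / self.n_nonevents,
        )


_POPULATION_UNITS = ("true_positive", "false_positive")


@dataclass(frozen=True)
class PopulationScale:
    """How often the decision is made per period, and the reporting unit.

    ``decisions_per_period`` is e.g. the annual number of events for which
    the model would be consulted; ``unit`` selects whether scaled value is
    reported as true positives gained or false positives averted.
    """

    decisions_per_period: float
    unit: str = "true_positive"

    def __post_init__(self) -> None:
        if self.decisions_per_period < 0:
            raise ValueError("decisions_per_period must be nonnegative")
        if self.unit not in _POPULATION_UNITS:
            raise ValueError(f"unit must be one of {_POPULATION_UNITS}; got {self.unit!r}")


@dataclass(frozen=True)
class ValidationSample:
    """Individual-level validation data: predicted risks and observed outcomes."""

    risks: np.ndarray
    outcomes: np.ndarray

    def __post_init__(self) -> None:
        risks = np.asarray(self.risks, dtype=float)
        outcomes = np.asarray(self.outcomes)
        if risks.ndim != 1 or outcomes.ndim != 1:
            raise ValueError("risks and outcomes must be one-dimensional")
        if risks.shape != outcomes.shape:
            raise ValueError("risks and outcomes must have equal length")
        if risks.size == 0:
            raise ValueError("validation sample must contain at least one record")
        bad = np.flatnonzero(~np.isfinite(risks) | (risks < 0) | (risks > 1))
        if bad.size:
            raise ValueError(
                f"row {bad[0] + 1}: predicted risk {risks[bad[0]]!r} outside [0, 1]"
            )
        bad = np.flatnonzero(~np.isin(outcomes, (0, 1)))
        if bad.size:
            raise ValueError(
                f"row {bad[0] + 1}: outcome {outcomes[bad[0]]!r} is not 0/1"
            )
        object.__setattr__(self, "risks", risks)
        object.__setattr__(self, "outcomes", outcomes.astype(np.int8))

    @property
    def n(self) -> int:
        return self.risks.size

    @property
    def n_events(self) -> int:
        return int(self.outcomes.sum())

    @property
    def prevalence(self) -> float:
        return self.n_events / self.n

    def counts_at(self, thr: Threshold) -> ConfusionCounts:
        """Confusion counts with the half-open convention: risk >= z is positive."""
        pos = self.risks >= thr.z
        event = self.outcomes == 1
        return ConfusionCounts(
            n_tp=int(np.sum(pos & event)),
            n_fn=int(np.sum(~pos & event)),
            n_tn=int(np.sum(~pos & ~event)),
            n_fp=int(np.sum(pos & ~event)),
        )

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "ValidationSample":
        """Read a two-column CSV with required columns ``risk`` and ``outcome``.

        Extra columns are ignored.  Validation failures report the offending
        (1-based) data row.
        """
        df = pd.read_csv(path)
        missing = {"risk", "outcome"} - set(df.columns)
        if missing:
            raise ValueError(f"{path}: missing required column(s) {sorted(missing)}")
        return cls(risks=df["risk"].to_numpy(), outcomes=df["outcome"].to_numpy())

    def to_csv(self, path: Union[str, Path]) -> None:
        pd.DataFrame({"risk": self.risks, "outcome": self.outcomes}).to_csv(
            path, index=False
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"risk": self.risks, "outcome": self.outcomes})


# ---------------------------------------------------------------------------
# Net benefit
# ---------------------------------------------------------------------------


def nb_model(prevalence, sensitivity, specificity, omega):
    """NB of the use-model strategy; broadcasts over array inputs."""
    return prevalence * sensitivity - (1.0 - prevalence) * (1.0 - specificity) * omega


def nb_treat_all(prevalence, omega):
    """NB of the treat-all strategy; broadcasts over array inputs."""
    return prevalence - (1.0 - prevalence) * omega


def net_benefit(strategy: Strategy, theta: ThetaTriplet, thr: Threshold) -> float:
    """Net benefit of one strategy at parameter ``theta`` and threshold ``thr``."""
    strategy = Strategy(strategy)
    if strategy is Strategy.TREAT_NONE:
        return 0.0
    if strategy is Strategy.USE_MODEL:
        return float(
            nb_model(theta.prevalence, theta.sensitivity, theta.specificity, thr.omega)
        )
    return float(nb_treat_all(theta.prevalence, thr.omega))


def nb_all_strategies(theta: ThetaTriplet, thr: Threshold) -> np.ndarray:
    """NB of all three strategies, indexed by :class:`Strategy`."""
    return np.array([net_benefit(s, theta, thr) for s in Strategy])


def enb_current_plugin(
    estimate: Union[ConfusionCounts, ThetaTriplet], thr: Threshold
) -> tuple[Strategy, float]:
    """Best strategy and its NB at a plug-in point estimate of theta.

    Accepts either a :class:`ThetaTriplet` (e.g. posterior means) or raw
    :class:`ConfusionCounts`; in the latter case NB is computed from the cell
    proportions directly, so samples without events are handled (the model
    then cannot generate true positives).  Ties break to the lowest index.
    """
    if isinstance(estimate, ConfusionCounts):
        if estimate.total == 0:
            raise ValueError("cannot form plug-in estimates from zero total count")
        n = estimate.total
        nbs = np.array(
            [
                0.0,
                estimate.n_tp / n - (estimate.n_fp / n) * thr.omega,
                nb_treat_all(estimate.n_events / n, thr.omega),
            ]
        )
    elif isinstance(estimate, ThetaTriplet):
        nbs = nb_all_strategies(estimate, thr)
    else:
        raise TypeError(f"expected ConfusionCounts or ThetaTriplet, got {type(estimate)!r}")
    best = int(np.argmax(nbs))  # first max -> lowest index on ties
    return Strategy(best), float(nbs[best])


def scale_to_population(
    per_decision_voi: float, thr: Threshold, scale: PopulationScale
) -> float:
    """Scale a per-decision value (in net TP units) to the population.

    True-positive units multiply by the number of decision instances; the
    false-positive unit additionally applies the exact exchange transform
    ``(1 - z) / z`` (false positives averted per true positive gained).
    """
    if per_decision_voi < 0:
        raise ValueError("per-decision value of information must be nonnegative")
    out = per_decision_voi * scale.decisions_per_period
    if scale.unit == "false_positive":
        out *= (1.0 - thr.z) / thr.z
    return out


def _as_thresholds(thresholds: Iterable[Union[Threshold, float]]) -> list[Threshold]:
    out = [t if isinstance(t, Threshold) else Threshold(float(t)) for t in thresholds]
    if not out:
        raise ValueError("at least one threshold is required")
    return out


def decision_curve(
    sample: ValidationSample, thresholds: Sequence[Union[Threshold, float]]
) -> pd.DataFrame:
    """Empirical decision curve: plug-in NB of each strategy per threshold.

    Returns a data frame with columns ``z, nb_none, nb_model, nb_all``.
    NB is computed from the cell proportions, so degenerate samples (e.g.
    no events) are fine: the model simply produces no true positives.
    """
    rows = []
    n = sample.n
    for thr in _as_thresholds(thresholds):
        c = sample.counts_at(thr)
        rows.append(
            {
                "z": thr.z,
                "nb_none": 0.0,
                "nb_model": c.n_tp / n - (c.n_fp / n) * thr.omega,
                "nb_all": nb_treat_all(c.n_events / n, thr.omega),
            }
        )
    return pd.DataFrame(rows)
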