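"""Two-level resampling algorithm for EVPI/EVSI from an individual-level sample.

The pilot validation sample ``d`` (predicted risks + binary outcomes) stands
in for the target population.  Each Monte Carlo iteration:

1. draws a Bayesian bootstrap replicate ``D*`` of ``d`` by assigning
   Dirichlet(1, ..., 1) weights to the records (generated as normalized
   exponential(1) variables); the ordinary bootstrap (multinomial counts
   scaled by 1/n) is available behind the same interface;
2. computes the weighted plug-in ``theta*`` — the "true" prevalence,
   sensitivity and specificity of the iteration — and the true NBs;
3. draws the future sample ``D`` of size N by sampling with replacement
   from ``D*``, i.e. with the Dirichlet weights as sampling probabilities;
4. pools ``D+ = d + D`` with unit weights, takes the plug-in ``theta+``
   from the pool, picks the strategy winning at ``theta+``, and scores it
   at ``theta*``.

At a fixed threshold only the four confusion cells of a record matter, so
the implementation aggregates record weights into cell masses and draws the
future sample as a multinomial over cells — algebraically identical to
record-level resampling, and it keeps 10^6 iterations tractable.

ENB_current is the max over strategies of the averaged bootstrapped NBs
(averaging keeps the VoI differences positively correlated with ENB_truth /
ENB_sample).  Degenerate replicates in which the weighted event (or
non-event) mass is zero keep a well-defined NB: the undefined sensitivity
(or specificity) multiplies a zero mass, so the affected term is zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .nb import (
    ThetaTriplet,
    Threshold,
    ValidationSample,
    nb_model,
    nb_treat_all,
    _as_thresholds,
)
from .results import VoIResult, resolve_seed, substream
from .beta_binomial import _assemble

__all__ = [
    "BootstrapWeights",
    "draw_weights",
    "weighted_theta",
    "evpi_evsi_bootstrap",
    "incremental_nb_ci",
]

_SCHEMES = ("bayesian", "ordinary")


@dataclass(frozen=True)
class BootstrapWeights:
    """Normalized resampling weights over the records of a sample."""

    weights: np.ndarray
    scheme: str

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size == 0:
            raise ValueError("weights must be a nonempty one-dimensional vector")
        if np.any(w < 0) or not np.isclose(w.sum(), 1.0):
            raise ValueError("weights must be nonnegative and sum to 1")
        if self.scheme not in _SCHEMES:
            raise ValueError(f"scheme must be one of {_SCHEMES}; got {self.scheme!r}")
        object.__setattr__(self, "weights", w)


def draw_weights(
    n: int, scheme: str = "bayesian", rng: Optional[np.random.Generator] = None
) -> BootstrapWeights:
    """One draw of bootstrap weights for a sample of size ``n``.

    ``bayesian``: Dirichlet(1, ..., 1), generated as n exponential(1)
    variables scaled to sum to 1.  ``ordinary``: multinomial(n, uniform)
    counts divided by n.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if scheme not in _SCHEMES:
        raise ValueError(f"scheme must be one of {_SCHEMES}; got {scheme!r}")
    rng = rng or np.random.default_rng()
    if scheme == "bayesian":
        e = rng.standard_exponential(n)
        w = e / e.sum()
    else:
        w = rng.multinomial(n, np.full(n, 1.0 / n)) / n
    return BootstrapWeights(weights=w, scheme=scheme)


def weighted_theta(
    sample: ValidationSample, w: BootstrapWeights, thr: Threshold
) -> ThetaTriplet:
    """Weighted plug-in (prevalence, sensitivity, specificity) at ``thr``.

    When the weighted event (or non-event) mass is zero, sensitivity (or
    specificity) is undefined; it is reported as 0.0, which leaves every NB
    well-defined because the undefined ratio only ever multiplies that zero
    mass.
    """
    if w.weights.size != sample.n:
        raise ValueError("weights and sample must have equal length")
    event = sample.outcomes == 1
    pos = sample.risks >= thr.z
    m_event = float(w.weights[event].sum())
    m_nonevent = float(w.weights[~event].sum())
    m_tp = float(w.weights[event & pos].sum())
    m_tn = float(w.weights[~event & ~pos].sum())
    sens = m_tp / m_event if m_event > 0 else 0.0
    spec = m_tn / m_nonevent if m_nonevent > 0 else 0.0
    return ThetaTriplet(
        prevalence=m_event, sensitivity=min(sens, 1.0), specificity=min(spec, 1.0)
    )


def _cell_indicators(sample: ValidationSample, thr: Threshold) -> np.ndarray:
    """(n, 4) one-hot matrix of record cells, ordered (tp, fn, tn, fp)."""
    event = sample.outcomes == 1
    pos = sample.risks >= thr.z
    cells = np.stack([event & pos, event & ~pos, ~event & ~pos, ~event & pos], axis=1)
    return cells.astype(float)


def evpi_evsi_bootstrap(
    sample: ValidationSample,
    thr: Threshold,
    n_future: int,
    n_sim: int = 10**6,
    scheme: str = "bayesian",
    seed: Optional[int] = None,
    chunk_size: int = 16384,
) -> VoIResult:
    """EVPI and EVSI by two-level resampling of an individual-level sample."""
    if n_sim < 1:
        raise ValueError("n_sim must be at least 1")
    if n_future < 0:
        raise ValueError("n_future must be nonnegative")
    if scheme not in _SCHEMES:
        raise ValueError(f"scheme must be one of {_SCHEMES}; got {scheme!r}")
    if sample.n_events == 0 or sample.n_events == sample.n:
        raise ValueError(
            "sample must contain at least one event and one non-event; for "
            "such degenerate data use the beta-binomial algorithm with "
            "informative priors instead"
        )
    seed = resolve_seed(seed)
    rng_w = substream(seed, 0, 0)
    rng_f = substream(seed, 1, n_future)
    ind = _cell_indicators(sample, thr)  # (n, 4): tp, fn, tn, fp
    n = sample.n
    counts0 = ind.sum(axis=0)  # original cell counts
    omega = thr.omega

    nb1_parts, nb2_parts, nbs_parts = [], [], []
    n_degenerate = 0
    done = 0
    while done < n_sim:
        c = min(chunk_size, n_sim - done)
        if scheme == "bayesian":
            e = rng_w.standard_exponential((c, n))
            masses = e @ ind
            masses /= masses.sum(axis=1, keepdims=True)
        else:
            draws = rng_w.multinomial(n, np.full(n, 1.0 / n), size=c)
            masses = (draws @ ind) / n
        m_tp, m_fn, m_tn, m_fp = masses.T
        m_event = m_tp + m_fn
        m_nonevent = m_tn + m_fp
        n_degenerate += int(np.sum((m_event == 0) | (m_nonevent == 0)))
        # theta*: NB needs only the cell masses (p_tp = m_tp, p_fp = m_fp),
        # so the zero-mass convention is automatic.
        nb1 = m_tp - m_fp * omega
        nb2 = nb_treat_all(m_event, omega)

        if n_future > 0:
            p = masses / masses.sum(axis=1, keepdims=True)
            fut = rng_f.multinomial(n_future, p)
            pooled = counts0[None, :] + fut
            tot = n + n_future
            nb1_plus = (pooled[:, 0] - pooled[:, 3] * omega) / tot
            nb2_plus = nb_treat_all((pooled[:, 0] + pooled[:, 1]) / tot, omega)
            stacked = np.stack([np.zeros(c), nb1_plus, nb2_plus])
            l = np.argmax(stacked, axis=0)
            scored = np.stack([np.zeros(c), nb1, nb2])
            nbs_parts.append(np.take_along_axis(scored, l[None, :], axis=0)[0])
        nb1_parts.append(nb1)
        nb2_parts.append(nb2)
        done += c

    nb1 = np.concatenate(nb1_parts)
    nb2 = np.concatenate(nb2_parts)
    diagnostics = {"scheme": scheme, "n_degenerate_draws": n_degenerate}
    if n_future == 0:
        means = np.array([0.0, nb1.mean(), nb2.mean()])
        nb_sample = (np.zeros_like(nb1), nb1, nb2)[int(np.argmax(means))]
    else:
        nb_sample = np.concatenate(nbs_parts)
    return _assemble(nb1, nb2, nb_sample, seed, n_future, diagnostics)


def incremental_nb_ci(
    sample: ValidationSample,
    thresholds: Sequence[Union[Threshold, float]],
    n_boot: int = 10**4,
    level: float = 0.95,
    seed: Optional[int] = None,
) -> pd.DataFrame:
    """Percentile-bootstrap CI for the incremental NB of the model.

    The incremental NB at a threshold is ``NB_model - max(NB_none,
    NB_treat_all)`` at the plug-in estimates.  The interval is the
    percentile interval over ordinary bootstrap resamples of the records.
    Returns columns ``z, inb, lower, upper``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if not (0.0 < level < 1.0):
        raise ValueError("level must lie in (0, 1)")
    thresholds = _as_thresholds(thresholds)
    seed = resolve_seed(seed)
    rng = substream(seed, 0, 0)
    n = sample.n
    boot_counts = rng.multinomial(n, np.full(n, 1.0 / n), size=n_boot)  # (B, n)
    alpha = (1.0 - level) / 2.0
    rows = []
    for thr in thresholds:
        ind = _cell_indicators(sample, thr)
        omega = thr.omega
        # point estimate from the original sample
        c0 = ind.sum(axis=0)
        inb0 = _inb_from_cells(c0[None, :], n, omega)[0]
        cells = boot_counts @ ind  # (B, 4)
        inb_b = _inb_from_cells(cells, n, omega)
        lo, hi = np.quantile(inb_b, [alpha, 1.0 - alpha])
        rows.append({"z": thr.z, "inb": inb0, "lower": float(lo), "upper": float(hi)})
    return pd.DataFrame(rows)


def _inb_from_cells(cells: np.ndarray, n: int, omega: float) -> np.ndarray:
    nb1 = (cells[:, 0] - cells[:, 3] * omega) / n
    nb2 = nb_treat_all((cells[:, 0] + cells[:, 1]) / n, omega)
    return nb1 - np.maximum(0.0, nb2)
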