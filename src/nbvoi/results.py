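"""Shared result container and Monte Carlo error machinery for the VoI algorithms."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np

__all__ = ["VoIResult", "batch_means_se", "resolve_seed", "substream"]


def resolve_seed(seed: Optional[int]) -> int:
    """Return ``seed`` as a plain int, drawing a fresh one from OS entropy if None."""
    if seed is None:
        return int(np.random.SeedSequence().generate_state(1)[0] % (2**31))
    return int(seed)


def substream(seed: int, *tag: int) -> np.random.Generator:
    """Independent, reproducible generator keyed by (seed, *tag).

    Keying by value (not position) means e.g. the future-data stream for a
    planned size N is identical wherever N appears in a grid.
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed), *map(int, tag))))


def batch_means_se(x: np.ndarray, n_batches: int = 100) -> float:
    """Monte Carlo standard error of ``mean(x)`` by the batch-means method.

    The draws are split into ``n_batches`` contiguous batches (trailing
    remainder trimmed); the SE is the standard deviation of batch means over
    ``sqrt(n_batches)``.  Used on the *paired difference* that each VoI
    estimator is a mean of, so correlation between the ENB terms is
    accounted for.
    """
    x = np.asarray(x, dtype=float)
    m = x.size
    if m < 2:
        return float("nan")
    b = min(n_batches, m)
    per = m // b
    means = x[: b * per].reshape(b, per).mean(axis=1)
    return float(means.std(ddof=1) / np.sqrt(b))


@dataclass(frozen=True)
class VoIResult:
    """Point estimates and Monte Carlo errors from one VoI computation.

    ``evpi == enb_truth - enb_current`` and, when a future sample size was
    analysed, ``evsi == enb_sample - enb_current`` (both up to floating
    arithmetic).  ``diagnostics`` carries algorithm-specific extras such as
    importance-weight effective sample sizes or degenerate-draw counts.
    """

    enb_current: float
    enb_truth: float
    evpi: float
    mcse_evpi: float
    n_sim: int
    seed: int
    enb_sample: Optional[float] = None
    evsi: Optional[float] = None
    mcse_evsi: Optional[float] = None
    n_future: Optional[int] = None
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "VoIResult":
        return cls(**d)

    def to_json(self, path: Union[str, Path]) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_json(cls, path: Union[str, Path]) -> "VoIResult":
        return cls.from_dict(json.loads(Path(path).read_text()))
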