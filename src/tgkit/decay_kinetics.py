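"""First-order decay model and half-life estimation.

The model is ``fraction(t) = 2^(-t / t_half)``.  The estimator is
zero-intercept least squares on ln(fraction) against time — the fraction is
forced to 1 at t = 0, matching ratio-to-surround normalization in which the
unblocked reference defines 100% — giving

    k_hat   = sum(t * ln f) / sum(t^2)         (decay rate, 1/min, < 0)
    t_half  = -ln 2 / k_hat

with the standard error propagated from the residual variance when n >= 2.
A free-intercept variant is available for diagnostics.  Fractions above 1
(noise) are retained, not clipped, to avoid bias.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd


class NoDecayError(ValueError):
    """Raised when the observations carry no decay signal (k_hat >= 0)."""


@dataclass(frozen=True)
class DecayObservation:
    time: float      # minutes since transcription block
    fraction: float  # remaining level relative to unblocked reference, > 0

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.fraction <= 0:
            raise ValueError("fraction must be > 0")


@dataclass(frozen=True)
class HalfLifeEstimate:
    t_half: float            # minutes
    se: float | None         # standard error, minutes (None when n < 2)
    n: int
    intercept: float = 0.0   # ln-scale intercept (0 for the zero-intercept fit)


def fraction_remaining(t: float, t_half: float) -> float:
    """Noise-free fraction remaining at time t for half-life t_half."""
    if t_half <= 0:
        raise ValueError("t_half must be > 0")
    return 2.0 ** (-t / t_half)


def fit_half_life(
    observations: Iterable[DecayObservation] | Sequence[tuple[float, float]],
    intercept: str = "zero",
) -> HalfLifeEstimate:
    """Estimate the half-life from (time, fraction) observations.

    Raises :class:`NoDecayError` when the fit implies no decay and
    ``ValueError`` on non-positive fractions or an unusable design.
    """
    obs = [
        o if isinstance(o, DecayObservation) else DecayObservation(*o)
        for o in observations
    ]
    t = np.array([o.time for o in obs], dtype=float)
    y = np.log([o.fraction for o in obs])
    informative = t > 0
    if not informative.any():
        raise ValueError("need at least one observation with t > 0")

    if intercept == "zero":
        t_, y_ = t[informative], y[informative]
        k = float(t_ @ y_ / (t_ @ t_))
        if k >= 0:
            raise NoDecayError("no decay detectable (fitted rate >= 0)")
        n = t_.size
        se = None
        if n >= 2:
            resid = y_ - k * t_
            var_k = float(resid @ resid) / (n - 1) / float(t_ @ t_)
            se = math.log(2.0) * math.sqrt(var_k) / k**2
        return HalfLifeEstimate(t_half=-math.log(2.0) / k, se=se, n=n)

    if intercept == "free":
        if t.size < 2:
            raise ValueError("free-intercept fit needs >= 2 observations")
        se = None
        if t.size > 2:
            (k, a), cov = np.polyfit(t, y, 1, cov=True)
            if k >= 0:
                raise NoDecayError("no decay detectable (fitted rate >= 0)")
            se = math.log(2.0) * math.sqrt(cov[0, 0]) / k**2
        else:
            k, a = np.polyfit(t, y, 1)
            if k >= 0:
                raise NoDecayError("no decay detectable (fitted rate >= 0)")
        return HalfLifeEstimate(t_half=-math.log(2.0) / k, se=se, n=t.size, intercept=float(a))

    raise ValueError("intercept must be 'zero' or 'free'")


def fit_groups(table: pd.DataFrame) -> pd.DataFrame:
    """Fit one half-life per group of a long table with columns
    (group, time_min, fraction); returns (group, t_half, se, n)."""
    rows = []
    for group, sub in table.groupby("group", sort=False):
        est = fit_half_life(zip(sub["time_min"], sub["fraction"]))
        rows.append((group, est.t_half, est.se, est.n))
    return pd.DataFrame(rows, columns=["group", "t_half", "se", "n"])
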