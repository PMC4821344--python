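"""FRAP normalization and single-exponential recovery fitting.

Fluorescence recovery after photobleaching of a small nuclear spot is
normalized to the mean of the pre-bleach frames and fitted with the
single exponential association model

    y(t) = offset + plateau * (1 - exp(-k t)) ,

where t runs from the first post-bleach frame.  The recovery half-time
is t_half = ln2 / k and the asymptotic recovery fraction is
offset + plateau (relative to the pre-bleach level 1).  Recoveries
faster than the frame interval can resolve are flagged rather than
reported as numbers.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger("fcskit")

#: A fitted t_half below this many frame intervals is below resolution.
MIN_RESOLVABLE_HALFTIMES = 2.0


@dataclass
class FrapCurve:
    """FRAP time series; ``bleach_time`` separates pre- and post-bleach."""

    times: np.ndarray
    intensities: np.ndarray
    n_prebleach: int
    bleach_time: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.times.shape != self.intensities.shape:
            raise ValueError("times and intensities must match")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        n_pre = int(np.sum(self.times < self.bleach_time))
        if self.n_prebleach < 1 or n_pre < self.n_prebleach:
            raise ValueError(
                "at least n_prebleach samples must precede bleach_time"
            )

    @property
    def prebleach_mask(self) -> np.ndarray:
        return self.times < self.bleach_time

    @property
    def postbleach_mask(self) -> np.ndarray:
        return ~self.prebleach_mask


@dataclass
class FrapFit:
    """Fitted recovery kinetics: rate, half-time, plateau and offset."""

    k: float
    t_half: float
    plateau: float
    offset: float
    recovery_fraction: float
    converged: bool
    below_resolution: bool = False


def normalize_frap(raw: FrapCurve, n_prebleach: int | None = None) -> FrapCurve:
    """Divide by the mean pre-bleach intensity; shift t=0 to first post frame."""
    n = raw.n_prebleach if n_prebleach is None else n_prebleach
    pre = raw.intensities[raw.prebleach_mask][-n:]
    if pre.size < n:
        raise ValueError(f"need at least {n} pre-bleach samples")
    divisor = float(pre.mean())
    if divisor <= 0:
        raise ValueError("pre-bleach mean must be positive")
    t_post0 = raw.times[raw.postbleach_mask][0]
    return FrapCurve(
        times=raw.times - t_post0,
        intensities=raw.intensities / divisor,
        n_prebleach=raw.n_prebleach,
        bleach_time=raw.bleach_time - t_post0,
    )


def fit_recovery(curve: FrapCurve) -> FrapFit:
    """Least-squares fit of the exponential association recovery.

    The fit uses only post-bleach samples (at least 8).  When the fitted
    half-time is shorter than MIN_RESOLVABLE_HALFTIMES frame intervals,
    the recovery is too rapid for the sampling and the result carries
    ``below_resolution=True`` with ``converged=False``.
    """
    t = curve.times[curve.postbleach_mask]
    y = curve.intensities[curve.postbleach_mask]
    if t.size < 8:
        raise ValueError("recovery fit requires at least 8 post-bleach samples")
    t = t - t[0]
    interval = float(np.median(np.diff(t)))

    def _model(tt, offset, plateau, k):
        return offset + plateau * (1.0 - np.exp(-k * tt))

    y0 = float(y[0])
    yinf = float(y[-max(1, y.size // 5):].mean())
    span = max(t[-1], interval)
    p0 = (y0, max(yinf - y0, 1e-3), math.log(2.0) / (span / 5.0))
    k_hi = math.log(2.0) / (interval / 50.0)  # generous; resolution handled below
    try:
        popt, _ = curve_fit(
            _model, t, y, p0=p0,
            bounds=([-np.inf, 0.0, 1e-9], [np.inf, np.inf, k_hi]),
            maxfev=20000,
        )
        offset, plateau, k = (float(v) for v in popt)
        converged = True
    except RuntimeError:
        logger.warning("FRAP recovery fit did not converge")
        offset, plateau, k = y0, max(yinf - y0, 0.0), float("nan")
        converged = False

    t_half = math.log(2.0) / k if k and k > 0 else float("inf")
    below = converged and t_half < MIN_RESOLVABLE_HALFTIMES * interval
    if below:
        logger.warning(
            "recovery too rapid to analyze: t_half %.3g s < %g frame intervals",
            t_half, MIN_RESOLVABLE_HALFTIMES,
        )
    return FrapFit(
        k=k,
        t_half=t_half,
        plateau=plateau,
        offset=offset,
        recovery_fraction=offset + plateau,
        converged=converged and not below,
        below_resolution=below,
    )
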