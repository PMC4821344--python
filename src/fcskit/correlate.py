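"""Normalized autocorrelation of intensity traces.

The autocorrelation function of a stationary intensity record,

    G(tau) = <I(t) I(t+tau)> / <I>^2 ,

decays from 1 + 1/N at short lags to 1 at full decorrelation.  It is
computed here on a quasi-logarithmic multi-tau grid: the first two
octaves at the native bin spacing, then one octave of lags per
coarsening level, the signal being averaged pairwise between levels.
Per-lag dispersion estimates come from averaging the curves of
consecutive trace segments.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .traces import IntensityTrace, TraceSegmentSet

logger = logging.getLogger("fcskit")

#: Floor applied to per-lag dispersion so degenerate lags never receive
#: infinite weight in the weighted chi^2.
SIGMA_FLOOR = 1e-6

#: Default upper lag bound (s); matches the upper end of the fit range.
DEFAULT_MAX_LAG = 3.4


@dataclass(frozen=True)
class MultiTauScheme:
    """Correlator settings.

    ``points_per_octave`` is the number of lags per factor-of-two in lag
    time (m); level 0 carries lags 1..2m at the native spacing and every
    further level carries lags m+1..2m at doubled spacing.  ``max_lag``
    of None means min(DEFAULT_MAX_LAG, duration / 10).  ``min_overlap``
    is the minimum number of overlapping sample pairs required for a lag
    to be reported.
    """

    points_per_octave: int = 16
    max_lag: float | None = None
    min_overlap: int = 8

    def __post_init__(self):
        if self.points_per_octave < 1:
            raise ValueError("points_per_octave must be >= 1")
        if self.max_lag is not None and self.max_lag <= 0:
            raise ValueError("max_lag must be positive")


@dataclass
class CorrelationCurve:
    """Autocorrelation curve with per-lag dispersion.

    ``sigma`` is the cross-segment standard deviation where available,
    and unit weights otherwise (chi^2 then loses its absolute meaning but
    model comparison remains valid).
    """

    lags: np.ndarray
    G: np.ndarray
    sigma: np.ndarray
    n_segments: int = 1
    mean_intensity: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.G = np.asarray(self.G, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if not (self.lags.shape == self.G.shape == self.sigma.shape):
            raise ValueError("lags, G and sigma must have equal length")
        if self.lags.size and (
            np.any(self.lags <= 0) or np.any(np.diff(self.lags) <= 0)
        ):
            raise ValueError("lags must be positive and strictly increasing")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")


def _multitau_lags(n_samples: int, scheme: MultiTauScheme, max_lag_bins: float):
    """Yield (level, coarse_lag_index) pairs of the multi-tau grid."""
    m = scheme.points_per_octave
    level = 0
    while True:
        idx = range(1, 2 * m + 1) if level == 0 else range(m + 1, 2 * m + 1)
        spacing = 1 << level
        n_level = n_samples >> level
        emitted = False
        for n in idx:
            if n * spacing > max_lag_bins:
                return
            if n_level - n < scheme.min_overlap:
                return
            emitted = True
            yield level, n
        if not emitted:
            return
        level += 1


def compute_acf(
    trace: IntensityTrace, scheme: MultiTauScheme | None = None
) -> CorrelationCurve:
    """Multi-tau autocorrelation of one trace.

    Uses the symmetric normalization G = <I(t) I(t+tau)> over the product
    of the means of the two overlapping windows, which removes the
    leading finite-length bias.  The trace must cover at least ten times
    the maximum lag.
    """
    scheme = scheme or MultiTauScheme()
    I = trace.counts.astype(float)
    if I.mean() <= 0:
        raise ValueError("zero-mean trace: ACF normalization undefined")
    duration = trace.duration
    if scheme.max_lag is None:
        max_lag = min(DEFAULT_MAX_LAG, duration / 10.0)
    else:
        max_lag = scheme.max_lag
        if duration < 10.0 * max_lag:
            raise ValueError(
                "trace duration must be at least 10x the maximum lag "
                f"(duration {duration:g} s, max_lag {max_lag:g} s)"
            )
    max_lag_bins = max_lag / trace.bin_width

    lags, G = [], []
    cur = I
    cur_level = 0
    for level, n in _multitau_lags(I.size, scheme, max_lag_bins):
        while cur_level < level:
            n_pairs = cur.size // 2
            cur = 0.5 * (cur[: 2 * n_pairs:2] + cur[1: 2 * n_pairs:2])
            cur_level += 1
        a, b = cur[:-n], cur[n:]
        g = float(np.dot(a, b) / a.size / (a.mean() * b.mean()))
        lags.append(n * (1 << level) * trace.bin_width)
        G.append(g)

    lags = np.asarray(lags)
    G = np.asarray(G)
    if lags.size == 0:
        raise ValueError("trace too short for any correlator lag")
    return CorrelationCurve(
        lags=lags,
        G=G,
        sigma=np.ones_like(G),
        n_segments=1,
        mean_intensity=trace.mean_rate,
        metadata=dict(trace.metadata),
    )


def average_segment_acfs(
    segments: TraceSegmentSet, scheme: MultiTauScheme | None = None
) -> CorrelationCurve:
    """Per-lag mean of segment ACFs with cross-segment dispersion.

    ``sigma`` is the per-lag standard deviation across segments, floored
    at SIGMA_FLOOR.  With a single segment dispersion is undefined; the
    segment's own curve is returned with unit weights and a warning.
    """
    curves = [compute_acf(s, scheme) for s in segments.segments]
    if len(curves) == 1:
        logger.warning(
            "single segment: cross-segment sigma undefined, using unit weights"
        )
        return curves[0]
    lags = curves[0].lags
    stack = np.vstack([c.G for c in curves])
    sigma = np.maximum(stack.std(axis=0, ddof=1), SIGMA_FLOOR)
    mean_rate = float(np.mean([c.mean_intensity for c in curves]))
    return CorrelationCurve(
        lags=lags,
        G=stack.mean(axis=0),
        sigma=sigma,
        n_segments=len(curves),
        mean_intensity=mean_rate,
        metadata=dict(curves[0].metadata),
    )


def normalize_amplitude(
    curve: CorrelationCurve,
    reference_amplitude: float,
    at_lag: float | None = None,
) -> CorrelationCurve:
    """Rescale G-1 so the amplitude at the first (or given) lag matches.

    Overlay/comparison aid only — never used for fitting.
    """
    if reference_amplitude <= 0:
        raise ValueError("reference_amplitude must be positive")
    idx = 0 if at_lag is None else int(np.searchsorted(curve.lags, at_lag))
    if idx >= curve.lags.size:
        raise ValueError("at_lag beyond the curve")
    amp = curve.G[idx] - 1.0
    if amp <= 0:
        raise ValueError("curve amplitude must be positive at the anchor lag")
    scale = reference_amplitude / amp
    return CorrelationCurve(
        lags=curve.lags.copy(),
        G=1.0 + (curve.G - 1.0) * scale,
        sigma=np.maximum(curve.sigma * scale, SIGMA_FLOOR),
        n_segments=curve.n_segments,
        mean_intensity=curve.mean_intensity,
        metadata=dict(curve.metadata),
    )
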