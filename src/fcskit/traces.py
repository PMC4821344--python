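"""Intensity traces and photobleach handling.

A fluorescence fluctuation measurement arrives as photon counts per time
bin.  Constructs that bind stably inside the detection volume photobleach
irreversibly, which shows up as an exponential decay of the mean intensity
over the first seconds of a record.  Before autocorrelation analysis the
decay is fitted with  y(t) = A*exp(-k*t) + y0,  the bleach window is
excised, and the remaining record is cut into equal-length segments whose
individual correlation curves are later averaged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger("fcskit")

#: Coarse re-binning width (s) used for the bleach-envelope fit.  The
#: exponential decay lives on the seconds scale; re-binning decouples it
#: from microsecond shot noise.
BLEACH_REBIN_WIDTH = 0.1

#: Minimum bleached fraction A/(A+y0) for a trace to count as bleaching.
BLEACH_AMPLITUDE_THRESHOLD = 0.05

#: Required fractional reduction of the residual norm of the exponential
#: fit relative to a constant fit.
BLEACH_RESIDUAL_IMPROVEMENT = 0.20


@dataclass
class IntensityTrace:
    """Binned photon-count record.

    Parameters
    ----------
    counts : array of float
        Photon counts per bin (non-negative; non-integer values occur for
        re-binned or ensemble-averaged envelopes).
    bin_width : float
        Bin width in seconds.
    start_time : float
        Acquisition time of the first bin, seconds.
    metadata : dict
        Free-form labels (cell context, laser setting, ``source``).
    """

    counts: np.ndarray
    bin_width: float
    start_time: float = 0.0
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.ndim != 1:
            raise ValueError("counts must be one-dimensional")
        if np.any(self.counts < 0) or not np.all(np.isfinite(self.counts)):
            raise ValueError("counts must be finite and non-negative")
        if not (self.bin_width > 0):
            raise ValueError("bin_width must be positive")

    @property
    def n_bins(self) -> int:
        return self.counts.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.n_bins * self.bin_width

    @property
    def times(self) -> np.ndarray:
        """Bin start times (s), absolute."""
        return self.start_time + np.arange(self.n_bins) * self.bin_width

    @property
    def mean_rate(self) -> float:
        """Mean intensity in counts per second."""
        return float(self.counts.mean()) / self.bin_width


@dataclass
class BleachFit:
    """Result of fitting y = A*exp(-k*t) + y0 to the intensity envelope.

    ``A`` and ``y0`` are in counts/s; ``k`` in 1/s.  ``residual_norm`` is
    the RMS fit residual relative to the mean envelope level
    (dimensionless); ``const_residual_norm`` is the same for a constant
    fit, so the improvement used by the bleach criterion is visible.
    """

    A: float
    k: float
    y0: float
    bleach_flag: bool
    residual_norm: float
    const_residual_norm: float = float("nan")
    converged: bool = True


@dataclass
class TraceSegmentSet:
    """Equal-length, contiguous, non-overlapping segments of one trace."""

    segments: list[IntensityTrace]
    excised_prefix: float = 0.0

    def __post_init__(self):
        if not self.segments:
            raise ValueError("segment set must contain at least one segment")
        n = self.segments[0].n_bins
        if any(s.n_bins != n for s in self.segments):
            raise ValueError("segments must have equal length")

    @property
    def n_segments(self) -> int:
        return len(self.segments)


def rebin(trace: IntensityTrace, new_bin_width: float) -> IntensityTrace:
    """Sum counts into coarser bins; a trailing partial bin is dropped."""
    if new_bin_width < trace.bin_width:
        raise ValueError("new bin width must not be finer than the trace's")
    factor = int(round(new_bin_width / trace.bin_width))
    n = (trace.n_bins // factor) * factor
    if n == 0:
        raise ValueError("trace shorter than one coarse bin")
    coarse = trace.counts[:n].reshape(-1, factor).sum(axis=1)
    return IntensityTrace(
        coarse,
        bin_width=factor * trace.bin_width,
        start_time=trace.start_time,
        metadata=dict(trace.metadata),
    )


def fit_photobleach(
    trace: IntensityTrace, rebin_width: float = BLEACH_REBIN_WIDTH
) -> BleachFit:
    """Fit the photobleach envelope y = A*exp(-k*t) + y0.

    The trace is re-binned to ``rebin_width`` and the binned rate
    (counts/s) is fitted by weighted-free least squares.  The returned
    ``bleach_flag`` is true when all three hold: the bleached fraction
    A/(A+y0) exceeds 5%, the decay time 1/k is shorter than the trace, and
    the exponential reduces the residual norm by at least 20% relative to
    a constant fit.
    """
    if trace.n_bins < 100:
        raise ValueError("bleach fit requires at least 100 bins")

    env = trace if trace.bin_width >= rebin_width else rebin(trace, rebin_width)
    t = np.arange(env.n_bins) * env.bin_width  # relative to trace start
    y = env.counts / env.bin_width  # counts/s
    duration = trace.duration

    mean_y = float(y.mean())
    scale = mean_y if mean_y > 0 else 1.0
    const_res = float(np.sqrt(np.mean((y - mean_y) ** 2))) / scale

    def _expdec(tt, A, k, y0):
        return A * np.exp(-k * tt) + y0

    head = float(y[: max(1, y.size // 10)].mean())
    tail = float(y[-max(1, y.size // 10):].mean())
    p0 = (max(head - tail, 1e-3 * scale), 3.0 / max(duration, 1e-9), max(tail, 0.0))
    try:
        popt, _ = curve_fit(
            _expdec,
            t,
            y,
            p0=p0,
            bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
        A, k, y0 = (float(v) for v in popt)
        exp_res = float(np.sqrt(np.mean((y - _expdec(t, *popt)) ** 2))) / scale
        converged = True
    except RuntimeError:
        logger.warning("photobleach fit did not converge; returning flat fit")
        return BleachFit(
            A=0.0, k=0.0, y0=mean_y, bleach_flag=False,
            residual_norm=const_res, const_residual_norm=const_res,
            converged=False,
        )

    amp_frac = A / (A + y0) if (A + y0) > 0 else 0.0
    decays_in_trace = k > 0 and (1.0 / k) < duration
    improves = exp_res <= (1.0 - BLEACH_RESIDUAL_IMPROVEMENT) * const_res
    flag = (amp_frac > BLEACH_AMPLITUDE_THRESHOLD) and decays_in_trace and improves
    return BleachFit(
        A=A, k=k, y0=y0, bleach_flag=bool(flag),
        residual_norm=exp_res, const_residual_norm=const_res,
        converged=converged,
    )


def excise_bleach_window(trace: IntensityTrace, window: float) -> IntensityTrace:
    """Remove the first ``window`` seconds (the photobleaching period)."""
    if window < 0:
        raise ValueError("window must be non-negative")
    if window >= trace.duration:
        raise ValueError("window must be shorter than the trace")
    n_drop = int(round(window / trace.bin_width))
    return IntensityTrace(
        trace.counts[n_drop:].copy(),
        bin_width=trace.bin_width,
        start_time=trace.start_time + n_drop * trace.bin_width,
        metadata=dict(trace.metadata),
    )


def segment_trace(trace: IntensityTrace, segment_length: float) -> TraceSegmentSet:
    """Cut the trace into maximal whole segments of ``segment_length`` s.

    A trailing remainder shorter than one segment is discarded (and
    logged).
    """
    if segment_length <= 0:
        raise ValueError("segment_length must be positive")
    if trace.duration < segment_length:
        raise ValueError("trace shorter than one segment")
    bins_per = int(round(segment_length / trace.bin_width))
    n_seg = trace.n_bins // bins_per
    leftover = trace.n_bins - n_seg * bins_per
    if leftover:
        logger.info(
            "segment_trace: discarding %.3g s trailing remainder",
            leftover * trace.bin_width,
        )
    segments = []
    for i in range(n_seg):
        sl = trace.counts[i * bins_per:(i + 1) * bins_per]
        segments.append(
            IntensityTrace(
                sl.copy(),
                bin_width=trace.bin_width,
                start_time=trace.start_time + i * bins_per * trace.bin_width,
                metadata=dict(trace.metadata),
            )
        )
    return TraceSegmentSet(segments=segments, excised_prefix=trace.start_time)
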