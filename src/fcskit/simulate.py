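"""Monte-Carlo generator of fluorescence fluctuation data.

Emulates a confocal FCS measurement: mobile fluorophores perform
independent Brownian steps in a periodic box and are observed through a
3D Gaussian detection profile centred in the box,

    W(r) = exp(-2 (x^2 + y^2)/omega^2 - 2 z^2/(S omega)^2) ,

immobile (chromatin-bound) fluorophores sit at fixed positions and
bleach irreversibly at rate k, and photon counts per bin are Poisson
with mean  brightness * sum_j W(r_j) * bin_width + background * bin_width.
The Brownian time step equals the bin width (15 us by default, the
illumination period of the emulated instrument); at nuclear-scale
diffusion coefficients the RMS step is well below the waist, so
sub-stepping is unnecessary.

Also generates exact model correlation curves with optional Gaussian
noise, and normalized FRAP recovery curves, both with known ground
truth for parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .correlate import SIGMA_FLOOR, CorrelationCurve
from .frap import FrapCurve
from .models import FitParams, model_curve
from .traces import IntensityTrace

#: Brownian propagation chunk (steps) balancing memory against speed.
_CHUNK_STEPS = 16384


@dataclass(frozen=True)
class DiffusingComponent:
    """One freely diffusing species: D (um^2/s), nominal amplitude
    fraction, and the number of simulated particles."""

    diffusion_coefficient: float
    fraction: float
    count: int


@dataclass
class SimulationConfig:
    """Study conditions of one simulated FCS measurement.

    Defaults mirror the emulated experiment: 60-s records made of six
    consecutive 10-s segments binned at the 15.0-us illumination period,
    a 0.2-um lateral waist with structure parameter S = 5 (detection
    volume roughly 400 nm wide and 2000 nm high), and a 3-um periodic
    cube — 15 waists laterally and 3 axial radii, large enough that the
    open-volume analytic ACF remains a valid oracle.
    """

    components: list = field(
        default_factory=lambda: [DiffusingComponent(25.0, 1.0, 100)]
    )
    box_dimensions: float = 3.0  # um, cubic periodic box
    lateral_waist: float = 0.2  # um
    structure_parameter: float = 5.0
    immobile_count: int = 0
    bleach_rate: float = 0.0  # 1/s
    brightness: float = 1.0e5  # counts/s per particle at focus centre
    background: float = 0.0  # counts/s
    bin_width: float = 15.0e-6  # s
    duration: float = 60.0  # s
    segment_length: float = 10.0  # s
    rng_seed: int = 0

    def __post_init__(self):
        if self.bin_width <= 0 or self.duration <= 0 or self.segment_length <= 0:
            raise ValueError("bin width, duration and segment length must be positive")
        n_seg = self.duration / self.segment_length
        if abs(n_seg - round(n_seg)) > 1e-9:
            raise ValueError("duration must be an integer multiple of segment_length")
        if self.box_dimensions <= 0 or self.lateral_waist <= 0:
            raise ValueError("box and waist must be positive")
        if self.structure_parameter <= 0:
            raise ValueError("structure parameter must be positive")
        if self.brightness < 0 or self.background < 0 or self.bleach_rate < 0:
            raise ValueError("rates must be non-negative")
        if self.immobile_count < 0:
            raise ValueError("immobile_count must be non-negative")
        for c in self.components:
            if c.diffusion_coefficient <= 0 or c.count < 0 or c.fraction < 0:
                raise ValueError("component D must be positive, count/fraction >= 0")
        if self.components:
            total = sum(c.fraction for c in self.components)
            if abs(total - 1.0) > 1e-9:
                raise ValueError("component fractions must sum to 1")

    @property
    def n_bins(self) -> int:
        return int(round(self.duration / self.bin_width))


@dataclass
class GroundTruth:
    """Generating parameters of a simulated trace.

    ``bleach_A``/``bleach_k``/``bleach_y0`` are the analytic envelope of
    the expected intensity: the immobile ensemble decays as
    A*exp(-k t) + y0 with A the initial expected immobile rate, k the
    per-particle bleach rate and y0 the mobile-plus-background level.
    """

    components: tuple  # (D, fraction) pairs
    immobile_fraction: float
    bleach_A: float
    bleach_k: float
    bleach_y0: float
    rng_seed: int


def _detection_weights(pos: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    """Gaussian detection weight of particle positions (…, 3) in the box."""
    half = cfg.box_dimensions / 2.0
    d = pos - half
    w2 = cfg.lateral_waist**2
    z2 = (cfg.structure_parameter * cfg.lateral_waist) ** 2
    return np.exp(
        -2.0 * (d[..., 0] ** 2 + d[..., 1] ** 2) / w2 - 2.0 * d[..., 2] ** 2 / z2
    )


def simulate_trace(config: SimulationConfig) -> tuple[IntensityTrace, GroundTruth]:
    """Simulate one binned photon-count record.

    All randomness derives from one generator seeded with
    ``config.rng_seed``; repeated calls are bit-identical.  Mobile
    particles take per-axis Gaussian steps of variance 2 D dt per bin in
    the periodic box; immobile particles bleach irreversibly with a
    geometric per-step survival matching rate k.
    """
    rng = np.random.default_rng(config.rng_seed)
    n_bins = config.n_bins
    L = config.box_dimensions
    dt = config.bin_width
    rate = np.full(n_bins, config.background, dtype=float)

    half = L / 2.0
    inv_w2 = 1.0 / config.lateral_waist**2
    inv_z2 = 1.0 / (config.structure_parameter * config.lateral_waist) ** 2
    for comp in config.components:
        if comp.count == 0:
            continue
        sigma_step = np.sqrt(2.0 * comp.diffusion_coefficient * dt)
        # coordinate-major (3*count, time) layout keeps the cumulative sum
        # contiguous; float32 is ample (position error << waist)
        pos = rng.uniform(0.0, L, size=3 * comp.count).astype(np.float32)
        start = 0
        while start < n_bins:
            n = min(_CHUNK_STEPS, n_bins - start)
            steps = rng.standard_normal(size=(3 * comp.count, n), dtype=np.float32)
            steps *= np.float32(sigma_step)
            steps[:, 0] += pos
            path = np.cumsum(steps, axis=1)
            path %= np.float32(L)
            pos = path[:, -1].copy()
            d = path.reshape(comp.count, 3, n)
            d -= np.float32(half)
            w = np.exp(
                -2.0 * ((d[:, 0] ** 2 + d[:, 1] ** 2) * np.float32(inv_w2)
                        + d[:, 2] ** 2 * np.float32(inv_z2))
            ).sum(axis=0)
            rate[start:start + n] += config.brightness * w
            start += n

    immobile_A = 0.0
    if config.immobile_count > 0:
        pos = rng.uniform(0.0, L, size=(config.immobile_count, 3))
        w = config.brightness * _detection_weights(pos, config)
        immobile_A = float(w.sum())
        if config.bleach_rate > 0:
            p_step = -np.expm1(-config.bleach_rate * dt)
            lifetimes = rng.geometric(p_step, size=config.immobile_count)
            for wj, life in zip(w, lifetimes):
                rate[: min(int(life), n_bins)] += wj
        else:
            rate += immobile_A

    counts = rng.poisson(rate * dt).astype(float)

    mobile_mean = sum(
        c.count * _mean_box_weight(config) * config.brightness
        for c in config.components
    )
    total0 = mobile_mean + immobile_A + config.background
    truth = GroundTruth(
        components=tuple(
            (c.diffusion_coefficient, c.fraction) for c in config.components
        ),
        immobile_fraction=immobile_A / total0 if total0 > 0 else 0.0,
        bleach_A=immobile_A,
        bleach_k=config.bleach_rate,
        bleach_y0=mobile_mean + config.background,
        rng_seed=config.rng_seed,
    )
    trace = IntensityTrace(
        counts,
        bin_width=dt,
        start_time=0.0,
        metadata={"source": "simulated", "rng_seed": config.rng_seed},
    )
    return trace, truth


def _mean_box_weight(cfg: SimulationConfig) -> float:
    """Box-averaged detection weight of a uniformly placed particle."""
    from scipy.special import erf

    L = cfg.box_dimensions
    half = L / 2.0

    def axis(width):
        # mean over [-half, half] of exp(-2 x^2 / width^2)
        integral = width * np.sqrt(np.pi / 2.0) * erf(np.sqrt(2.0) * half / width)
        return integral / (2.0 * half)

    lat = axis(cfg.lateral_waist)
    ax = axis(cfg.structure_parameter * cfg.lateral_waist)
    return float(lat * lat * ax)


def synthesize_acf(
    model_params: FitParams,
    lag_grid,
    noise_sd: float = 0.0,
    rng_seed: int | None = None,
    triplet: bool = False,
) -> CorrelationCurve:
    """Exact model curve on ``lag_grid`` plus optional Gaussian noise.

    ``sigma`` of the output is set to ``noise_sd`` (floored at a small
    positive value so it can serve as a chi^2 weight).
    """
    lags = np.asarray(lag_grid, dtype=float)
    if np.any(lags <= 0) or np.any(np.diff(lags) <= 0):
        raise ValueError("lag grid must be positive and strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    G = model_curve(model_params, lags, triplet=triplet)
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        G = G + rng.normal(0.0, noise_sd, size=lags.size)
    sigma = np.full(lags.size, max(noise_sd, SIGMA_FLOOR))
    return CorrelationCurve(
        lags=lags, G=G, sigma=sigma, n_segments=1,
        metadata={"source": "synthesized"},
    )


def simulate_frap(
    t_half: float,
    mobile_fraction: float,
    interval: float = 2.5,
    duration: float = 180.0,
    noise_sd: float = 0.0,
    rng_seed: int | None = None,
    bleach_depth: float = 0.3,
    n_prebleach: int = 3,
) -> FrapCurve:
    """Normalized FRAP curve with known kinetics.

    Pre-bleach samples sit at 1.0; the post-bleach signal follows
    offset + plateau * (1 - exp(-t ln2 / t_half)) with offset equal to
    ``bleach_depth`` and plateau = mobile_fraction * (1 - bleach_depth),
    so full mobility recovers to 1.  Gaussian noise of ``noise_sd`` is
    added to every sample.
    """
    if t_half <= 0:
        raise ValueError("t_half must be positive")
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ValueError("mobile_fraction must be within [0, 1]")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    if n_prebleach < 3:
        raise ValueError("at least 3 pre-bleach samples required")
    t_pre = -interval * np.arange(n_prebleach, 0, -1)
    t_post = np.arange(0.0, duration + 1e-12, interval)
    times = np.concatenate([t_pre, t_post])
    offset = bleach_depth
    plateau = mobile_fraction * (1.0 - offset)
    y = np.concatenate([
        np.ones(n_prebleach),
        offset + plateau * (1.0 - np.exp(-t_post * np.log(2.0) / t_half)),
    ])
    if noise_sd > 0:
        rng = np.random.default_rng(rng_seed)
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    return FrapCurve(
        times=times,
        intensities=y,
        n_prebleach=n_prebleach,
        bleach_time=-interval / 2.0,
    )
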