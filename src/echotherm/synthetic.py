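"""Synthetic microwave-hyperthermia heating experiments.

Generates B-mode-like image sequences plus thermocouple traces carrying the
statistical structure the thermometry method assumes: a saturating
exponential heating curve (25 -> 65 °C over 8 min by default), a mean gray
level linearly coupled to temperature, a small set of sinusoidal sub-period
modulations of the gray level (the multi-component heating hypothesis:
tissue constituents with different dielectric constants heat at different
rates, superimposing shorter heating periods on the main one), multiplicative
Rayleigh speckle, and a static mid-frequency spatial pattern so the gradient
texture is non-degenerate.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datatypes import TemperatureTrace, UltrasoundFrameSequence, ValidationError

__all__ = [
    "HeatingModel",
    "TextureModel",
    "SyntheticExperiment",
    "simulate_trace",
    "simulate_frames",
    "make_experiment_set",
    "draw_experiment_models",
]

#: default sub-period modulations: (period_s, amplitude in gray levels).
#: Periods are well separated, all far below the 480 s heating duration and
#: resolvable at 1 Hz; amplitudes are second-order relative to the ~20 gray
#: level trend rise so the trend remains the dominant signal.
DEFAULT_SUB_PERIODS = ((6.0, 1.0), (20.0, 0.6), (48.0, 0.4))


@dataclass(frozen=True)
class HeatingModel:
    """Saturating exponential heating curve T(t) = T0 + (Tmax-T0)(1-e^(-t/tau))."""

    T0: float = 25.0
    Tmax: float = 65.0
    tau: float = 120.0
    duration: float = 480.0
    sample_rate: float = 1.0

    def __post_init__(self):
        if not self.T0 < self.Tmax:
            raise ValidationError("require T0 < Tmax")
        if self.tau <= 0:
            raise ValidationError("require tau > 0")
        if self.duration <= 0:
            raise ValidationError("require duration > 0")
        if self.sample_rate <= 0:
            raise ValidationError("require sample_rate > 0")

    def temperature(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.T0 + (self.Tmax - self.T0) * (1.0 - np.exp(-t / self.tau))


@dataclass(frozen=True)
class TextureModel:
    """Texture/echogenicity model linking the image field to temperature.

    ``speckle_scale`` is the strength of unit-mean multiplicative Rayleigh
    speckle: each pixel is multiplied by ``1 + s*(R - 1)`` where R is a
    Rayleigh variate normalised to unit mean (s=1 gives fully developed
    speckle, s=0 none).  ``pattern_amplitude`` scales a static mid-frequency
    spatial pattern (period 16 px) giving the field non-trivial gradients.
    """

    base_mean: float = 120.0
    avgl_slope: float = 0.5
    sub_periods: tuple[tuple[float, float], ...] = DEFAULT_SUB_PERIODS
    sub_period_phases: tuple[float, ...] | None = None
    speckle_scale: float = 1.0
    frame_rate: float = 30.0
    roi_size: int = 64
    pattern_amplitude: float = 25.0

    def __post_init__(self):
        if not 0 <= self.base_mean <= 255:
            raise ValidationError("base_mean must lie in [0, 255]")
        for period, amp in self.sub_periods:
            if amp < 0:
                raise ValidationError("modulation amplitudes must be >= 0")
            if period < 2.0:
                raise ValidationError("sub-periods must span >= 2 s (2 trace samples)")
        if self.sub_period_phases is not None and len(self.sub_period_phases) != len(
            self.sub_periods
        ):
            raise ValidationError("one phase per sub-period required")
        if self.speckle_scale < 0:
            raise ValidationError("speckle_scale must be >= 0")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be positive")

    def mean_level(self, t: np.ndarray, temp: np.ndarray, t0_temp: float) -> np.ndarray:
        """Noiseless mean gray level at times t with temperatures temp."""
        level = self.base_mean + self.avgl_slope * (np.asarray(temp) - t0_temp)
        phases = self.sub_period_phases or (0.0,) * len(self.sub_periods)
        for (period, amp), phase in zip(self.sub_periods, phases):
            level = level + amp * np.sin(2 * np.pi * np.asarray(t) / period + phase)
        return level

    def spatial_pattern(self) -> np.ndarray:
        r = np.arange(self.roi_size)[:, None]
        c = np.arange(self.roi_size)[None, :]
        return self.pattern_amplitude * np.sin(2 * np.pi * r / 16.0) * np.cos(
            2 * np.pi * c / 16.0
        )


@dataclass
class SyntheticExperiment:
    """One simulated heating run: frames, trace and its hidden ground truth."""

    frames: UltrasoundFrameSequence
    trace: TemperatureTrace
    injected_periods: list[float]
    seed: int
    heating: HeatingModel | None = None
    texture: TextureModel | None = None


def simulate_trace(model: HeatingModel, noise_sd: float = 0.0,
                   seed: int = 0) -> TemperatureTrace:
    """Thermocouple trace: saturating exponential plus i.i.d. Gaussian noise."""
    if noise_sd < 0:
        raise ValidationError("noise_sd must be >= 0")
    n = int(round(model.duration * model.sample_rate)) + 1
    times = np.arange(n) / model.sample_rate
    temps = model.temperature(times)
    if noise_sd > 0:
        temps = temps + np.random.default_rng(seed).normal(0.0, noise_sd, size=n)
    return TemperatureTrace(times, temps)


def simulate_frames(trace: TemperatureTrace, tex: TextureModel,
                    seed: int = 0) -> UltrasoundFrameSequence:
    """Render the image sequence corresponding to a temperature trace.

    The noiseless field at frame time t has mean gray level
    ``base_mean + avgl_slope * (T(t) - T(0)) + sum_i a_i sin(2*pi*t/p_i)``;
    the static spatial pattern (zero mean over the patch) and multiplicative
    speckle are applied on top, then values are clipped to [0, 255] and
    quantised to 8 bits.
    """
    if tex.roi_size < 8:
        raise ValidationError("roi_size must be >= 8")
    span = trace.span
    for period, _amp in tex.sub_periods:
        if span > 0 and period > span / 2:
            raise ValidationError("sub-periods must be <= duration/2")
    n_frames = int(round(span * tex.frame_rate))
    if n_frames < 1:
        raise ValidationError("trace too short for one frame")
    t_rel = np.arange(n_frames) / tex.frame_rate
    temps = np.interp(t_rel, trace.times - trace.times[0], trace.temps)
    means = tex.mean_level(t_rel, temps, float(trace.temps[0]))
    pattern = tex.spatial_pattern()

    rng = np.random.default_rng(seed)
    size = tex.roi_size
    frames = np.empty((n_frames, size, size), dtype=np.uint8)
    # Rayleigh normalised to unit mean: sigma = sqrt(2/pi); drawn in float32
    # via the inverse CDF with in-place transforms (image stacks are large)
    sigma = np.float32(np.sqrt(2.0 / np.pi))
    means32 = means.astype(np.float32)
    pattern32 = pattern.astype(np.float32)
    chunk = max(1, int(2**24 // (size * size)))  # bound transient memory
    for lo in range(0, n_frames, chunk):
        hi = min(lo + chunk, n_frames)
        field = means32[lo:hi, None, None] + pattern32[None, :, :]
        if tex.speckle_scale > 0:
            u = rng.random(size=(hi - lo, size, size), dtype=np.float32)
            np.subtract(np.float32(1.0), u, out=u)
            np.log(u, out=u)
            u *= np.float32(-2.0)
            np.sqrt(u, out=u)          # u ~ Rayleigh(1)
            u *= sigma                 # unit mean
            u -= np.float32(1.0)
            u *= np.float32(tex.speckle_scale)
            u += np.float32(1.0)       # 1 + s*(R - 1)
            field *= u
        np.clip(field, 0.0, 255.0, out=field)
        field += np.float32(0.5)
        frames[lo:hi] = field.astype(np.uint8)  # trunc(x + 0.5) = round half-up
    return UltrasoundFrameSequence(frames, tex.frame_rate, t0=float(trace.times[0]))


def draw_experiment_models(
    n: int,
    heating: HeatingModel = HeatingModel(),
    tex: TextureModel = TextureModel(),
    seed: int = 0,
    jitter: bool = True,
) -> list[tuple[HeatingModel, TextureModel, int]]:
    """Deterministically draw per-experiment parameter variations.

    Heating onset/plateau/time-constant, baseline echogenicity, coupling
    slope, modulation amplitudes and phases are jittered between experiments;
    the sub-period *values* are held fixed (they encode material composition,
    assumed common across samples).
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        child_seed = int(rng.integers(0, 2**31 - 1))
        if jitter:
            # heating varies between runs (probe placement, tissue piece);
            # the measurement model (scanner gain -> base echogenicity and
            # gray/°C coupling) is fixed: one calibrated scanner, one tissue
            # type, so absolute temperature stays a recoverable ground truth
            h = HeatingModel(
                T0=heating.T0 + rng.uniform(-0.5, 0.5),
                Tmax=heating.Tmax + rng.uniform(-2.0, 2.0),
                tau=heating.tau * rng.uniform(0.9, 1.1),
                duration=heating.duration,
                sample_rate=heating.sample_rate,
            )
            periods = tuple(
                (p, a * rng.uniform(0.8, 1.2)) for p, a in tex.sub_periods
            )
            t = replace(
                tex,
                sub_periods=periods,
                sub_period_phases=tuple(
                    rng.uniform(0, 2 * np.pi) for _ in tex.sub_periods
                ),
            )
        else:
            h, t = heating, tex
        out.append((h, t, child_seed))
    return out


def make_experiment_set(
    n: int,
    heating: HeatingModel = HeatingModel(),
    tex: TextureModel = TextureModel(),
    seed: int = 0,
    trace_noise_sd: float = 0.05,
    jitter: bool = True,
) -> list[SyntheticExperiment]:
    """Generate ``n`` jittered heating experiments (frames materialised).

    For large sets prefer :func:`echotherm.datasets.simulate_feature_dataset`,
    which draws the same models but streams frames through preprocessing.
    """
    experiments = []
    for h, t, child_seed in draw_experiment_models(n, heating, tex, seed, jitter):
        trace = simulate_trace(h, noise_sd=trace_noise_sd, seed=child_seed)
        frames = simulate_frames(trace, t, seed=child_seed + 1)
        experiments.append(
            SyntheticExperiment(
                frames=frames,
                trace=trace,
                injected_periods=[p for p, _ in t.sub_periods],
                seed=child_seed,
                heating=h,
                texture=t,
            )
        )
    return experiments
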