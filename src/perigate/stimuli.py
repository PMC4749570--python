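"""Synthetic stimuli and ground-truth spike responses.

Every generator is a pure function of its arguments and a seed, so reruns are
byte-identical.  Intensities are in mean-relative units; contrast is defined
throughout as the standard deviation of the intensity divided by its mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "IntensityTrace",
    "PeripheralSchedule",
    "SequenceStimulus",
    "EyeTrajectory",
    "ImageEnsemble",
    "SpikeResponse",
    "gen_pink_noise",
    "gen_white_noise",
    "gen_sequence_stimulus",
    "gen_eye_trajectory",
    "gen_image_ensemble",
    "simulate_spikes",
    "de_bruijn_cycle",
    "um_to_deg",
    "deg_to_um",
]

# 50 µm on the retina corresponds to ~1 degree of visual field (salamander).
UM_PER_DEG = 50.0


def um_to_deg(um: float) -> float:
    """Convert retinal distance in micrometers to degrees of visual field."""
    return um / UM_PER_DEG


def deg_to_um(deg: float) -> float:
    """Convert degrees of visual field to retinal micrometers."""
    return deg * UM_PER_DEG


@dataclass
class IntensityTrace:
    """A single-region intensity time series.

    Attributes
    ----------
    values : per-frame intensity in mean-relative units.
    dt : frame duration in seconds.
    mean : nominal mean intensity.
    contrast : nominal SD/mean (dimensionless).
    meta : free-form provenance (seed, generator, warnings).
    """

    values: np.ndarray
    dt: float
    mean: float
    contrast: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def duration(self) -> float:
        return self.values.size * self.dt

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.values.size) * self.dt

    def realized_contrast(self) -> float:
        if self.mean == 0:
            raise ValueError("contrast undefined for zero-mean trace")
        return float(np.std(self.values) / self.mean)


@dataclass
class PeripheralSchedule:
    """Times and phases of abrupt peripheral shifts (checkerboard reversals).

    ``period`` is the full cycle of the peripheral stimulus: with reversals
    every half period the pattern returns to its original phase once per
    period.  The time-relative-to-shift label p of a sample is the elapsed
    time since the most recent shift, paired with the phase of that shift.
    """

    shift_times: np.ndarray
    phases: np.ndarray
    period: float

    def __post_init__(self) -> None:
        self.shift_times = np.asarray(self.shift_times, dtype=float)
        self.phases = np.asarray(self.phases, dtype=int)
        if self.period <= 0:
            raise ValueError("period must be positive")
        if self.shift_times.size != self.phases.size:
            raise ValueError("shift_times and phases must have equal length")
        if self.shift_times.size > 1:
            if not np.all(np.diff(self.shift_times) > 0):
                raise ValueError("shift_times must be strictly increasing")
            if np.any(self.phases[1:] == self.phases[:-1]):
                raise ValueError("phases must alternate")

    @classmethod
    def regular(cls, duration_s: float, period: float = 1.0,
                t0: float = 0.0) -> "PeripheralSchedule":
        """Reversals every ``period/2`` starting at ``t0``, alternating phase."""
        times = np.arange(t0, duration_s, period / 2.0)
        phases = np.arange(times.size) % 2
        return cls(times, phases, period)

    def time_since_shift(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (elapsed time since last shift, phase of that shift).

        Samples before the first shift get elapsed time NaN and phase -1.
        """
        t = np.asarray(t, dtype=float)
        idx = np.searchsorted(self.shift_times, t, side="right") - 1
        valid = idx >= 0
        p = np.full(t.shape, np.nan)
        ph = np.full(t.shape, -1, dtype=int)
        p[valid] = t[valid] - self.shift_times[idx[valid]]
        ph[valid] = self.phases[idx[valid]]
        return p, ph

    def time_in_period(self, t: np.ndarray) -> np.ndarray:
        """Time modulo the full peripheral period, relative to the first shift."""
        t = np.asarray(t, dtype=float)
        t0 = self.shift_times[0] if self.shift_times.size else 0.0
        return np.mod(t - t0, self.period)


@dataclass
class SequenceStimulus:
    """Binary de Bruijn sequence design at several contrasts.

    ``base_sequence`` is a cyclic ±1 sequence of length 2**order in which
    every length-``order`` binary window occurs exactly once per cycle.  The
    ``condition_table`` enumerates the (p-bin, window, contrast) design cells
    with their planned presentation counts.
    """

    base_sequence: np.ndarray
    order: int
    frame_s: float
    contrasts: np.ndarray
    mean: float
    condition_table: pd.DataFrame
    p_bin_s: float
    period: float

    @property
    def cycle_s(self) -> float:
        return self.base_sequence.size * self.frame_s

    def window_id(self, end_frame: int) -> int:
        """Identity of the length-``order`` window ending at ``end_frame`` (cyclic)."""
        n = self.base_sequence.size
        bits = [(self.base_sequence[(end_frame - k) % n] + 1) // 2
                for k in range(self.order)]
        return int(sum(int(b) << k for k, b in enumerate(bits)))


@dataclass
class EyeTrajectory:
    """2-D gaze path in degrees, with a single instantaneous saccade."""

    positions: np.ndarray  # (n_frames, 2)
    dt: float
    saccade_time: float
    saccade_amplitude: float

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]


@dataclass
class ImageEnsemble:
    """Stack of synthetic 2-D intensity images with a 1/f^k spatial spectrum."""

    images: np.ndarray  # (n_images, ny, nx)
    pixel_deg: float
    spectral_exponent: float
    mean: float = 1.0

    @property
    def size_deg(self) -> float:
        return self.images.shape[-1] * self.pixel_deg


@dataclass
class SpikeResponse:
    """Per-trial binned spike counts aligned to a stimulus/schedule."""

    counts: np.ndarray  # (n_trials, n_bins) non-negative integers
    bin_s: float
    alignment: float = 0.0

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.bin_s <= 0:
            raise ValueError("bin_s must be positive")
        if np.any(self.counts < 0):
            raise ValueError("spike counts must be non-negative")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Bin midpoints in seconds."""
        return (np.arange(self.counts.shape[1]) + 0.5) * self.bin_s + self.alignment

    def rebin(self, bin_s: float) -> "SpikeResponse":
        """Sum counts into coarser bins (bin_s must be a multiple of current)."""
        factor = int(round(bin_s / self.bin_s))
        if not np.isclose(factor * self.bin_s, bin_s):
            raise ValueError("new bin_s must be an integer multiple of bin_s")
        n = (self.counts.shape[1] // factor) * factor
        c = self.counts[:, :n].reshape(self.counts.shape[0], -1, factor).sum(axis=2)
        return SpikeResponse(c, bin_s, self.alignment)


# ---------------------------------------------------------------------------
# Generators
# ---------------------------------------------------------------------------

def gen_pink_noise(duration_s: float, dt_s: float, contrast: float,
                   mean: float = 1.0, seed: int = 0) -> IntensityTrace:
    """Gaussian pink noise (1/f amplitude spectrum) intensity trace.

    Synthesized in the frequency domain: independent Gaussian spectral
    coefficients shaped by 1/f, with the zero-frequency term pinned to the
    mean.  The realized SD is rescaled to ``contrast * mean`` exactly.
    """
    if duration_s <= 0 or dt_s <= 0 or duration_s < dt_s:
        raise ValueError("need duration_s >= dt_s > 0")
    if contrast < 0:
        raise ValueError("contrast must be non-negative")
    n = int(round(duration_s / dt_s))
    if contrast == 0:
        return IntensityTrace(np.full(n, mean), dt_s, mean, 0.0,
                              meta={"generator": "pink", "seed": seed})
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n, d=dt_s)
    amp = np.zeros_like(freqs)
    amp[1:] = 1.0 / freqs[1:]
    coef = amp * (rng.standard_normal(freqs.size)
                  + 1j * rng.standard_normal(freqs.size))
    coef[0] = 0.0
    if n % 2 == 0:
        coef[-1] = coef[-1].real
    x = np.fft.irfft(coef, n=n)
    sd = np.std(x)
    x *= (contrast * mean) / sd
    return IntensityTrace(mean + x, dt_s, mean, contrast,
                          meta={"generator": "pink", "seed": seed})


def gen_white_noise(duration_s: float, dt_s: float,
                    contrast_schedule: float | Sequence[tuple[float, float]],
                    mean: float = 1.0, binary: bool = False,
                    seed: int = 0) -> IntensityTrace:
    """Temporally white intensity trace with a piecewise contrast schedule.

    ``contrast_schedule`` is either a single contrast applied for the whole
    duration or a list of ``(contrast, segment_duration_s)`` pairs.  With
    ``binary=True`` each frame takes one of the two values mean*(1 ± contrast).
    Gaussian contrasts above 1 would produce negative intensities; a truncated
    Gaussian (clipped at zero) is used instead and recorded in metadata.
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if np.isscalar(contrast_schedule):
        segments = [(float(contrast_schedule), float(duration_s))]
    else:
        segments = [(float(c), float(d)) for c, d in contrast_schedule]
    rng = np.random.default_rng(seed)
    parts = []
    seg_info = []
    truncated = False
    for c, dur in segments:
        m = int(round(dur / dt_s))
        if m == 0:
            continue
        if binary:
            vals = mean * (1.0 + c * rng.choice([-1.0, 1.0], size=m))
        else:
            vals = mean * (1.0 + c * rng.standard_normal(m))
            if c > 1.0:
                warnings.warn("Gaussian contrast > 1: clipping at zero "
                              "(truncated-Gaussian fallback)")
                vals = np.clip(vals, 0.0, None)
                truncated = True
        parts.append(vals)
        seg_info.append({"contrast": c, "n_frames": m})
    values = np.concatenate(parts) if parts else np.empty(0)
    nominal = segments[0][0] if len(segments) == 1 else float("nan")
    meta = {"generator": "white", "seed": seed, "binary": binary,
            "segments": seg_info}
    if truncated:
        meta["truncated_gaussian"] = True
    return IntensityTrace(values, dt_s, mean, nominal, meta=meta)


def de_bruijn_cycle(order: int) -> np.ndarray:
    """Binary de Bruijn cycle B(2, order) as a ±1 array of length 2**order.

    Standard prefer-largest greedy construction via Lyndon words
    (FKM algorithm); every length-``order`` binary window occurs exactly once
    per cycle.
    """
    if order < 1:
        raise ValueError("order must be >= 1")
    k, n = 2, order
    a = [0] * k * n
    seq: list[int] = []

    def db(t: int, p: int) -> None:
        if t > n:
            if n % p == 0:
                seq.extend(a[1:p + 1])
        else:
            a[t] = a[t - p]
            db(t + 1, p)
            for j in range(a[t - p] + 1, k):
                a[t] = j
                db(t + 1, t)

    db(1, 1)
    return np.array([2 * b - 1 for b in seq], dtype=int)


def gen_sequence_stimulus(order: int = 4,
                          contrasts: Sequence[float] = (0.03, 0.06, 0.12, 0.24),
                          frame_s: float = 0.1, mean: float = 1.0,
                          schedule: PeripheralSchedule | None = None,
                          p_bin_s: float = 0.1, n_blocks: int = 10,
                          seed: int = 0) -> SequenceStimulus:
    """Design a cyclic binary sequence stimulus crossed with peripheral timing.

    The base sequence is a binary de Bruijn cycle of the given order.  The
    condition table enumerates every (p-bin, length-``order`` window, contrast)
    triple; with the default order 4, a 1 s peripheral period, and 100 ms
    p-bins this is 10 x 16 x 4 = 640 conditions, each planned ``n_blocks``
    times.  Because the 1.6 s cycle and 1 s period share a common divisor of
    0.2 s, consecutive presentation blocks are staggered by one frame so the
    census over blocks covers every condition exactly uniformly.
    """
    if order > 16:
        raise ValueError("order > 16 refused: condition table would explode")
    if frame_s <= 0:
        raise ValueError("frame_s must be positive")
    period = schedule.period if schedule is not None else 1.0
    base = de_bruijn_cycle(order)
    n_p = int(round(period / p_bin_s))
    n_win = base.size
    rows = []
    for p_bin in range(n_p):
        for w in range(n_win):
            for c in contrasts:
                rows.append((p_bin, w, c, n_blocks))
    table = pd.DataFrame(rows, columns=["p_bin", "window_id", "contrast",
                                        "count"])
    return SequenceStimulus(base, order, frame_s, np.asarray(contrasts, float),
                            mean, table, p_bin_s, period)


def gen_eye_trajectory(duration_s: float, dt_s: float,
                       drift_speed: float = 0.33, saccade_time: float | None = None,
                       saccade_amp: float = 6.0, seed: int = 0,
                       bounds_deg: float | None = None) -> EyeTrajectory:
    """Fixational drift (isotropic Gaussian random walk) plus one saccade.

    ``drift_speed`` is the mean frame-to-frame speed in degrees/s; steps are
    2-D Gaussian with the axis SD chosen so the mean step length matches.  The
    saccade is a single-frame step of ``saccade_amp`` degrees in a random
    orientation at ``saccade_time``.  If ``bounds_deg`` is given the path must
    stay within ±bounds_deg of the origin.
    """
    if dt_s <= 0 or duration_s < dt_s:
        raise ValueError("need duration_s >= dt_s > 0")
    n = int(round(duration_s / dt_s))
    if saccade_time is not None and not (0 <= saccade_time <= duration_s):
        raise ValueError("saccade_time must lie within the trajectory")
    rng = np.random.default_rng(seed)
    # mean |2-D Gaussian| = sigma * sqrt(pi/2)
    sigma = drift_speed * dt_s / np.sqrt(np.pi / 2.0)
    steps = sigma * rng.standard_normal((n, 2))
    steps[0] = 0.0
    if saccade_time is not None:
        k = min(int(round(saccade_time / dt_s)), n - 1)
        theta = rng.uniform(0, 2 * np.pi)
        steps[k] = saccade_amp * np.array([np.cos(theta), np.sin(theta)])
    pos = np.cumsum(steps, axis=0)
    if bounds_deg is not None:
        excess = np.abs(pos).max()
        if excess > bounds_deg:
            raise ValueError(
                f"trajectory exits bounds: needs margin of {excess:.2f} deg "
                f"but only {bounds_deg:.2f} deg available")
    return EyeTrajectory(pos, dt_s, saccade_time if saccade_time is not None
                         else float("nan"), saccade_amp)


def gen_image_ensemble(n_images: int, size_deg: float = 32.0,
                       pixel_deg: float = 0.25, spectral_exponent: float = 1.0,
                       rms_contrast: float = 0.3, mean: float = 1.0,
                       seed: int = 0) -> ImageEnsemble:
    """Synthetic image ensemble with a 1/f^k spatial amplitude spectrum.

    Stand-in for a natural-scene database: each image is Gaussian noise shaped
    in the 2-D frequency domain by 1/f^k, rescaled to a common RMS contrast,
    with all means pinned to ``mean`` exactly.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    if size_deg <= pixel_deg:
        raise ValueError("size_deg must exceed pixel_deg")
    npix = int(round(size_deg / pixel_deg))
    rng = np.random.default_rng(seed)
    fy = np.fft.fftfreq(npix, d=pixel_deg)
    fx = np.fft.rfftfreq(npix, d=pixel_deg)
    f = np.sqrt(fy[:, None] ** 2 + fx[None, :] ** 2)
    amp = np.zeros_like(f)
    nz = f > 0
    amp[nz] = f[nz] ** (-spectral_exponent)
    images = np.empty((n_images, npix, npix))
    for i in range(n_images):
        coef = amp * (rng.standard_normal(f.shape)
                      + 1j * rng.standard_normal(f.shape))
        coef[0, 0] = 0.0
        img = np.fft.irfft2(coef, s=(npix, npix))
        sd = np.std(img)
        if sd > 0:
            img *= (rms_contrast * mean) / sd
        images[i] = mean + img
    return ImageEnsemble(images, pixel_deg, spectral_exponent, mean)


def simulate_spikes(rate_trace: np.ndarray, n_trials: int, dt_s: float,
                    seed: int = 0) -> SpikeResponse:
    """Poisson spike counts: per-bin counts ~ Poisson(rate * dt), iid trials."""
    rate = np.asarray(rate_trace, dtype=float)
    if np.any(rate < 0):
        raise ValueError("rate must be non-negative")
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    rng = np.random.default_rng(seed)
    counts = rng.poisson(rate * dt_s, size=(n_trials, rate.size))
    return SpikeResponse(counts, dt_s)
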