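"""Reduced two-pathway model of peripheral gating.

A central intensity trace is passed through a linear temporal filter, summed
with a timed biphasic peripheral signal triggered by each peripheral shift,
thresholded with unit slope, and scaled by feedforward divisive adaptation:

    b(t) = (F * s)(t)
    c(t) = max(0, b(t) + a(t) - theta)
    y(t) = c(t) / (alpha + (F_alpha * c)(t))

where F_alpha is an exponentially decaying filter of unit integral.  The same
fixed peripheral amplitude reproduces gating at all central contrasts; its
differing effect with contrast arises downstream, from the threshold and the
adaptive stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, lfilter

from .stimuli import IntensityTrace, PeripheralSchedule, SpikeResponse, simulate_spikes

__all__ = [
    "PeripheralParams",
    "GatingParams",
    "default_temporal_filter",
    "linear_drive",
    "peripheral_signal",
    "threshold_rectify",
    "divisive_adaptation",
    "run_gating_model",
]


def default_temporal_filter(dt: float, length_s: float = 0.4,
                            tau_fast: float = 0.06,
                            tau_slow: float = 0.12,
                            polarity: int = -1) -> np.ndarray:
    """Biphasic temporal filter (difference of alpha functions), unit L2 norm.

    The default is Off-type (negative fast lobe); unit L2 norm makes the
    variance of the filtered signal equal the stimulus variance on white
    noise.
    """
    t = np.arange(int(round(length_s / dt))) * dt
    alpha = lambda tau: (t / tau) * np.exp(1.0 - t / tau)
    w = alpha(tau_fast) - (tau_fast / tau_slow) * alpha(tau_slow)
    w = polarity * w
    return w / np.linalg.norm(w)


@dataclass
class PeripheralParams:
    """Biphasic peripheral signal a(t): positive lobe then negative lobe.

    The kernel is a difference of alpha functions (t/tau)e^(1-t/tau) with
    time constants ``tau_on`` and ``tau_off``; ``lobe_ratio`` is the ratio of
    negative to positive lobe area, ``A`` the peak amplitude in drive units,
    and ``delay`` a fixed lateral conduction/synaptic latency before the
    kernel departs from zero.  The defaults put the excitatory lobe over the
    50-100 ms gating window (peak ~75 ms, zero crossing ~175 ms) and the
    suppressive lobe over ~175-450 ms, leaving 0-50 ms as a clean baseline.
    Identical for both shift phases.
    """

    A: float = 1.0
    tau_on: float = 0.05
    tau_off: float = 0.11
    lobe_ratio: float = 1.0
    delay: float = 0.03


@dataclass
class GatingParams:
    """Parameters of the full gating model."""

    F: np.ndarray            # central temporal filter weights
    dt: float                # time step (s)
    a_params: PeripheralParams = field(default_factory=PeripheralParams)
    theta: float | None = None      # threshold; default 0.9 * peak of a(t)
    alpha: float = 0.30             # divisive adaptation constant
    tau_adapt: float = 10.0         # adaptation time constant (s)
    rate_scale: float = 60.0        # Hz per output unit
    # drive units per unit stimulus contrast: sets where the threshold and
    # the adaptive stage sit relative to alpha.  The adaptation constant only
    # bites when the rectified drive is of order alpha, so the gain fixes how
    # strongly the cell adapts at a given contrast.
    drive_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.tau_adapt <= 0:
            raise ValueError("tau_adapt must be positive")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.theta is None:
            self.theta = 0.9 * self.a_params.A

    @classmethod
    def default(cls, dt: float = 1.0 / 30.0, **kw) -> "GatingParams":
        return cls(F=default_temporal_filter(dt), dt=dt, **kw)

    @property
    def burn_in(self) -> int:
        """Number of initial samples contaminated by the convolution edge."""
        return len(self.F)


def linear_drive(stimulus: IntensityTrace, F: np.ndarray,
                 normalize: bool = True) -> np.ndarray:
    """Causal discrete convolution of the mean-subtracted stimulus with F.

    With ``normalize`` the output is rescaled so its variance matches the
    stimulus variance (the filter then carries only relative temporal
    sensitivity, and the nonlinearity carries the overall gain).
    """
    F = np.asarray(F, dtype=float)
    s = stimulus.values - np.mean(stimulus.values)
    if s.size < F.size:
        raise ValueError("trace shorter than filter")
    b = fftconvolve(s, F, mode="full")[: s.size]
    if normalize:
        sd_b = np.std(b)
        if sd_b > 0:
            b *= np.std(s) / sd_b
    return b


def peripheral_kernel(t: np.ndarray, params: PeripheralParams) -> np.ndarray:
    """Causal biphasic kernel, zero for t < delay, peak value A."""
    t = np.asarray(t, dtype=float) - params.delay
    a = np.zeros_like(t, dtype=float)
    pos = t >= 0
    tp = t[pos]
    alpha = lambda tau: (tp / tau) * np.exp(1.0 - tp / tau)
    # equal-area lobes when lobe_ratio == 1: area of alpha(tau) is e*tau
    k = params.lobe_ratio * params.tau_on / params.tau_off
    raw = alpha(params.tau_on) - k * alpha(params.tau_off)
    peak = np.max(raw) if raw.size else 1.0
    a[pos] = params.A * raw / peak
    return a


def peripheral_signal(t_grid: np.ndarray, schedule: PeripheralSchedule,
                      a_params: PeripheralParams,
                      support_s: float = 1.5) -> np.ndarray:
    """Sum of biphasic kernels triggered at each shift (any phase).

    Kernels from shifts closer together than the kernel support superpose
    linearly.  a(t) = 0 before the first shift.
    """
    if schedule.shift_times.size == 0:
        raise ValueError("schedule must contain at least one shift")
    t_grid = np.asarray(t_grid, dtype=float)
    a = np.zeros_like(t_grid)
    for ts in schedule.shift_times:
        rel = t_grid - ts
        mask = (rel >= 0) & (rel <= support_s)
        if not np.any(mask):
            continue
        a[mask] += peripheral_kernel(rel[mask], a_params)
    return a


def threshold_rectify(b_plus_a: np.ndarray, theta: float) -> np.ndarray:
    """Threshold nonlinearity with unit slope above threshold."""
    if not np.isfinite(theta):
        raise ValueError("theta must be finite")
    return np.maximum(0.0, np.asarray(b_plus_a, dtype=float) - theta)


def divisive_adaptation(c_trace: np.ndarray, alpha: float, tau_adapt: float,
                        dt: float) -> np.ndarray:
    """Feedforward divisive adaptation y = c / (alpha + F_alpha * c).

    F_alpha is the discrete unit-sum exponential kernel with time constant
    ``tau_adapt``, evaluated recursively; for a constant input c0 the output
    settles at c0 / (alpha + c0).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive (division blows up at rest)")
    if tau_adapt <= 0 or dt <= 0:
        raise ValueError("tau_adapt and dt must be positive")
    c = np.asarray(c_trace, dtype=float)
    beta = 1.0 - np.exp(-dt / tau_adapt)
    # EMA with weights beta*(1-beta)^k, k >= 0 (unit total mass)
    m = lfilter([beta], [1.0, -(1.0 - beta)], c)
    return c / (alpha + m)


def run_gating_model(stimulus: IntensityTrace,
                     schedule: PeripheralSchedule | None,
                     params: GatingParams, n_trials: int = 1,
                     seed: int = 0) -> tuple[np.ndarray, SpikeResponse]:
    """Run the full gating cascade and draw Poisson spike trains.

    ``schedule=None`` models a still periphery (a(t) = 0).  Returns the
    firing-rate trace (Hz, one value per stimulus frame) and a
    :class:`SpikeResponse` of ``n_trials`` Poisson realizations.
    """
    if not np.isclose(params.dt, stimulus.dt):
        raise ValueError("params.dt must match stimulus.dt")
    b = params.drive_gain * linear_drive(stimulus, params.F)
    if schedule is None:
        a = np.zeros_like(b)
    else:
        a = peripheral_signal(stimulus.times, schedule, params.a_params)
    c = threshold_rectify(b + a, params.theta)
    y = divisive_adaptation(c, params.alpha, params.tau_adapt, params.dt)
    rate = params.rate_scale * y
    spikes = simulate_spikes(rate, n_trials, stimulus.dt, seed=seed)
    return rate, spikes
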