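"""Linear-nonlinear model estimation by reverse correlation.

The linear filter is the spike-triggered average expressed as the kernel
F(tau) of the causal convolution g(t) = sum_tau F(tau) s(t - tau); for
temporally correlated stimuli (pink noise) the cross-correlation is
normalized by the stimulus autocorrelation (whitening) with ridge and
optional smoothness regularization.  The
static nonlinearity N(g) is the mean firing rate in bins of the linear
prediction, and the cell's sensitivity is the occupancy-weighted average
slope of N.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .gating import linear_drive
from .stimuli import IntensityTrace, PeripheralSchedule, SpikeResponse

__all__ = [
    "LinearFilter",
    "Nonlinearity",
    "LNModel",
    "estimate_filter",
    "linear_prediction",
    "estimate_nonlinearity",
    "windowed_ln",
    "sensitivity",
    "luminance_slope",
]


@dataclass
class LinearFilter:
    weights: np.ndarray
    dt: float
    normalization: dict = field(default_factory=dict)


@dataclass
class Nonlinearity:
    """Binned nonlinearity: mean firing rate (Hz) per bin of the drive."""

    bin_centers: np.ndarray
    mean_rate: np.ndarray
    occupancy: np.ndarray

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size


@dataclass
class LNModel:
    filter: LinearFilter
    nonlinearity: Nonlinearity
    window: tuple[float, float] | None = None
    meta: dict = field(default_factory=dict)


def estimate_filter(stimulus: IntensityTrace, spikes: SpikeResponse,
                    length_s: float = 0.4,
                    whiten: bool = False, ridge: float = 1e-4,
                    smooth: float = 0.0) -> LinearFilter:
    """Spike-triggered-average filter, optionally whitened.

    The STA at lag tau is the spike-weighted average of s(t - tau).  With
    ``whiten`` the filter solves the lag-domain normal equations (Toeplitz
    stimulus autocorrelation times filter = cross-correlation), i.e. the
    cross-correlation is normalized by the stimulus autocorrelation; this
    removes the bias the raw STA carries on temporally correlated stimuli.
    A ridge of ``ridge * zero-lag power`` is added to the autocorrelation
    diagonal for conditioning; ``smooth`` adds a second-difference
    (smoothness) penalty of the same relative scale, useful when a windowed
    response leaves few effective samples for the deconvolution (the
    stimulus autocorrelation matrix of a 1/f stimulus is severely
    ill-conditioned).  The filter is scaled to unit L2 norm; on
    white noise the filtered signal then has the stimulus variance
    (variance-matching is re-applied in linear_prediction for correlated
    stimuli).
    """
    if spikes.bin_s and not np.isclose(spikes.bin_s, stimulus.dt):
        raise ValueError("spike bins must match the stimulus frame for "
                         "filter estimation; rebin first")
    r = spikes.counts.sum(axis=0).astype(float)
    n_spikes = r.sum()
    if n_spikes == 0:
        raise ValueError("cannot estimate a filter from zero spikes")
    if n_spikes < 100:
        warnings.warn(f"only {int(n_spikes)} spikes: filter estimate will be "
                      "noisy")
    s = stimulus.values - np.mean(stimulus.values)
    if np.std(s) == 0:
        raise ValueError("stimulus has zero variance")
    n = s.size
    L = int(round(length_s / stimulus.dt))
    # cross-correlation: cc[tau] = mean_t r(t) s(t - tau)
    cc = np.array([np.dot(r[tau:], s[: n - tau]) for tau in range(L)]) / n
    if whiten:
        ac = np.array([np.dot(s[tau:], s[: n - tau])
                       for tau in range(L)]) / n
        if smooth > 0:
            from scipy.linalg import solve, toeplitz
            d2 = np.diff(np.eye(L), 2, axis=0)
            lhs = (toeplitz(ac) + ridge * ac[0] * np.eye(L)
                   + smooth * ac[0] * (d2.T @ d2))
            w = solve(lhs, cc, assume_a="pos")
        else:
            from scipy.linalg import solve_toeplitz
            ac0 = ac.copy()
            ac0[0] *= (1.0 + ridge)
            w = solve_toeplitz(ac0, cc)
    else:
        w = cc * (n / n_spikes)
    norm = np.linalg.norm(w)
    if norm > 0:
        w = w / norm
    return LinearFilter(w, stimulus.dt,
                        normalization={"unit_l2": True, "whitened": whiten,
                                       "n_spikes": int(n_spikes)})


def linear_prediction(stimulus: IntensityTrace, filt: LinearFilter | np.ndarray,
                      normalize: bool = True) -> np.ndarray:
    """Linear prediction g(t): convolution of the filter with the stimulus.

    Shares its implementation with the gating model's central drive; with
    ``normalize`` the output variance is matched to the stimulus variance.
    """
    weights = filt.weights if isinstance(filt, LinearFilter) else filt
    return linear_drive(stimulus, weights, normalize=normalize)


def estimate_nonlinearity(g: np.ndarray, spikes_or_rate, n_bins: int = 12,
                          binning: str = "quantile",
                          bin_s: float | None = None) -> Nonlinearity:
    """Mean firing rate over bins of the linear prediction.

    ``spikes_or_rate`` is either a rate array (Hz, same length as g) or a
    :class:`SpikeResponse` whose trial-mean counts are converted to Hz.  Bins
    are equal-occupancy quantiles by default, or equal width
    (``binning="width"``).
    """
    g = np.asarray(g, dtype=float)
    if g.size == 0:
        raise ValueError("empty input")
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if isinstance(spikes_or_rate, SpikeResponse):
        rate = spikes_or_rate.counts.mean(axis=0) / spikes_or_rate.bin_s
    else:
        rate = np.asarray(spikes_or_rate, dtype=float)
        if bin_s is not None:
            rate = rate / bin_s
    if rate.size != g.size:
        raise ValueError("g and rate must be aligned")
    if binning == "quantile":
        edges = np.quantile(g, np.linspace(0, 1, n_bins + 1))
        edges = np.unique(edges)
    elif binning == "width":
        edges = np.linspace(g.min(), g.max(), n_bins + 1)
    else:
        raise ValueError(f"unknown binning strategy: {binning}")
    idx = np.clip(np.searchsorted(edges, g, side="right") - 1, 0,
                  len(edges) - 2)
    centers, rates, occ = [], [], []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        if n == 0:
            continue
        centers.append(float(g[mask].mean()))
        rates.append(float(rate[mask].mean()))
        occ.append(n)
    return Nonlinearity(np.array(centers), np.array(rates),
                        np.array(occ, dtype=int))


def windowed_ln(stimulus: IntensityTrace, spikes: SpikeResponse,
                schedule: PeripheralSchedule | None,
                window: tuple[float, float] | None,
                length_s: float = 0.4, whiten: bool = False,
                n_bins: int = 12, smooth: float = 0.0,
                filt: LinearFilter | None = None) -> LNModel:
    """LN model fit using only spikes whose bin midpoint falls in ``window``.

    ``window`` is a (start, stop) interval of time since the last peripheral
    shift; the stimulus history feeding the filter and the linear prediction
    remains full-resolution.  ``window=None`` fits on the whole record.  A
    precomputed ``filt`` (e.g. from the whole record) skips the windowed
    filter estimate — useful when a window holds too few spikes for reverse
    correlation but the nonlinearity is still wanted.
    """
    if window is None or schedule is None:
        mask = np.ones(spikes.counts.shape[1], dtype=bool)
    else:
        p, _ = schedule.time_since_shift(spikes.times)
        mask = (p >= window[0]) & (p < window[1])
        if not np.any(mask):
            raise ValueError("window selects no time bins")
    masked = SpikeResponse(np.where(mask[None, :], spikes.counts, 0),
                           spikes.bin_s, spikes.alignment)
    if filt is None:
        filt = estimate_filter(stimulus, masked, length_s=length_s,
                               whiten=whiten, smooth=smooth)
    g = linear_prediction(stimulus, filt)
    rate = spikes.counts.mean(axis=0) / spikes.bin_s
    nl = estimate_nonlinearity(g[mask], rate[mask], n_bins=n_bins)
    meta = {}
    n_window_spikes = int(masked.counts.sum())
    if n_window_spikes < 50:
        meta["low_data_warning"] = f"only {n_window_spikes} spikes in window"
    return LNModel(filt, nl, window=window, meta=meta)


def sensitivity(nl: Nonlinearity, weighted: bool = True) -> float:
    """Average slope of the nonlinearity (Hz per drive unit).

    Finite-difference slopes (centered in the interior, one-sided at the
    ends) averaged across bins, occupancy-weighted by default.
    """
    x, y, occ = nl.bin_centers, nl.mean_rate, nl.occupancy.astype(float)
    if x.size < 2:
        raise ValueError("sensitivity undefined with fewer than 2 bins")
    slopes = np.empty_like(y)
    slopes[0] = (y[1] - y[0]) / (x[1] - x[0])
    slopes[-1] = (y[-1] - y[-2]) / (x[-1] - x[-2])
    if x.size > 2:
        slopes[1:-1] = (y[2:] - y[:-2]) / (x[2:] - x[:-2])
    w = occ if weighted else np.ones_like(occ)
    return float(np.sum(w * slopes) / np.sum(w))


def luminance_slope(luminances: np.ndarray, window_rates: np.ndarray) -> float:
    """Sensitivity m to central luminance: OLS slope of rate vs log-luminance.

    ``window_rates`` are mean firing rates in the analysis window (one per
    luminance level, typically 50-150 ms after the shift).
    """
    lum = np.asarray(luminances, dtype=float)
    rates = np.asarray(window_rates, dtype=float)
    if lum.size < 2:
        raise ValueError("need at least 2 luminance levels")
    if np.any(lum <= 0):
        raise ValueError("luminances must be positive (log undefined)")
    x = np.log(lum)
    m, _ = np.polyfit(x, rates, 1)
    return float(m)
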