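"""Contrast-adaptation index and ideal-information capacity search.

The adaptation index compares the measured change in nonlinearity slope
across contrasts with the change expected from complete adaptation: slopes
and contrasts are normalized by a reference contrast, and the index is the
OLS slope of normalized slope versus normalized inverse contrast — 1 for an
ideally adapting cell (slope inversely proportional to contrast) and 0 for a
non-adapting cell.

The capacity search finds the sigmoid nonlinearity that maximizes mutual
information between a Gaussian-distributed linear prediction and the spike
count, given the cell's empirical count law P(r | <r>) and maximum rate; the
mean firing rate is deliberately left unconstrained.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .info import entropy, mutual_information
from .ln import sensitivity, windowed_ln
from .stimuli import IntensityTrace, PeripheralSchedule, SpikeResponse

__all__ = [
    "AdaptationMeasurement",
    "CapacityResult",
    "CountLaw",
    "adaptation_index",
    "adaptation_timecourse",
    "ideal_nonlinearity",
    "info_fraction",
]


@dataclass
class AdaptationMeasurement:
    contrasts: np.ndarray
    slopes: np.ndarray
    reference_idx: int
    index: float


@dataclass
class CapacityResult:
    x0: float               # optimal sigmoid midpoint (drive units)
    x1: float               # optimal sigmoid inverse-slope (drive units)
    r_max: float            # maximum firing rate (Hz)
    I_max: float            # channel information at the optimum (bits)
    grid: dict = field(default_factory=dict)
    achieved_fraction: float | None = None


@dataclass
class CountLaw:
    """Tabulated spike-count law P(r | <r>) with linear rate interpolation.

    ``mean_rates`` is the grid of average rates (Hz) and ``probs[i, r]`` the
    count distribution at mean rate ``mean_rates[i]``.
    """

    mean_rates: np.ndarray
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.mean_rates = np.asarray(self.mean_rates, dtype=float)
        self.probs = np.asarray(self.probs, dtype=float)
        if np.any(self.probs < 0):
            raise ValueError("count-law rows must be valid distributions")
        if not np.allclose(self.probs.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("count-law rows must sum to 1")

    @classmethod
    def poisson(cls, max_rate: float, bin_s: float, n_rates: int = 33,
                max_count: int | None = None) -> "CountLaw":
        """Poisson count law on a uniform rate grid (convenience)."""
        from scipy.stats import poisson as _poisson
        rates = np.linspace(0.0, max_rate, n_rates)
        if max_count is None:
            max_count = int(np.ceil(max_rate * bin_s + 6 *
                                    np.sqrt(max_rate * bin_s + 1)))
        counts = np.arange(max_count + 1)
        probs = _poisson.pmf(counts[None, :], rates[:, None] * bin_s)
        probs[:, -1] += 1.0 - probs.sum(axis=1)  # fold tail mass
        return cls(rates, probs)

    def __call__(self, mean_rate: np.ndarray) -> np.ndarray:
        """Interpolated count distribution(s) for the given mean rate(s)."""
        r = np.clip(np.asarray(mean_rate, dtype=float),
                    self.mean_rates[0], self.mean_rates[-1])
        idx = np.clip(np.searchsorted(self.mean_rates, r) - 1, 0,
                      self.mean_rates.size - 2)
        lo = self.mean_rates[idx]
        hi = self.mean_rates[idx + 1]
        w = np.where(hi > lo, (r - lo) / np.where(hi > lo, hi - lo, 1.0), 0.0)
        return ((1 - w)[..., None] * self.probs[idx]
                + w[..., None] * self.probs[idx + 1])


def adaptation_index(slopes: np.ndarray, contrasts: np.ndarray,
                     reference_idx: int = 0) -> float:
    """Adaptation index from per-contrast nonlinearity slopes.

    Normalizes slopes and contrasts by the reference (m~ = m/m0,
    sigma~ = sigma/sigma0) and returns the OLS slope (with intercept) of m~
    against 1/sigma~.
    """
    m = np.asarray(slopes, dtype=float)
    s = np.asarray(contrasts, dtype=float)
    if m.size != s.size or m.size < 2:
        raise ValueError("need >= 2 matched (slope, contrast) pairs")
    if np.any(s <= 0) or np.unique(s).size != s.size:
        raise ValueError("contrasts must be positive and distinct")
    m0 = m[reference_idx]
    if m0 == 0:
        raise ValueError("reference slope is zero: index undefined")
    m_t = m / m0
    x = s[reference_idx] / s  # 1 / (sigma/sigma0)
    slope, _ = np.polyfit(x, m_t, 1)
    return float(slope)


def adaptation_timecourse(stimuli: list[IntensityTrace],
                          spike_sets: list[SpikeResponse],
                          schedule: PeripheralSchedule,
                          contrasts: np.ndarray,
                          window_s: float = 0.05,
                          length_s: float = 0.4,
                          n_bins: int = 12,
                          reference_idx: int | None = None,
                          filters: list | None = None) -> np.ndarray:
    """Adaptation index per time window across the shift-aligned period.

    For each 50 ms window of time since the shift, LN models are fitted per
    contrast (one (stimulus, spikes) pair per contrast, sharing the shift
    schedule) and the adaptation index computed from their sensitivities.
    By convention the reference is the highest contrast.  ``filters``
    optionally supplies one whole-record filter per contrast so that windows
    with very few spikes still yield a (near-zero-slope) nonlinearity.
    """
    contrasts = np.asarray(contrasts, dtype=float)
    if contrasts.size < 2:
        raise ValueError("need >= 2 contrasts to measure adaptation")
    if len(stimuli) != contrasts.size or len(spike_sets) != contrasts.size:
        raise ValueError("one (stimulus, spikes) pair per contrast")
    if reference_idx is None:
        reference_idx = int(np.argmax(contrasts))
    if filters is None:
        filters = [None] * contrasts.size
    half = schedule.period / 2.0
    n_w = int(round(half / window_s))
    out = np.full(n_w, np.nan)
    for k in range(n_w):
        window = (k * window_s, (k + 1) * window_s)
        slopes = []
        for stim, spk, f in zip(stimuli, spike_sets, filters):
            model = windowed_ln(stim, spk, schedule, window,
                                length_s=length_s, n_bins=n_bins, filt=f)
            slopes.append(sensitivity(model.nonlinearity))
        try:
            out[k] = adaptation_index(np.array(slopes), contrasts,
                                      reference_idx=reference_idx)
        except ValueError:
            # a fully silenced window (zero reference slope): no measurable
            # sensitivity at any contrast, index undefined
            out[k] = np.nan
    return out


def _sigmoid(x: np.ndarray, x0: float, x1: float, r_max: float) -> np.ndarray:
    return r_max / (1.0 + np.exp(-(x - x0) / x1))


def channel_information(g_probs: np.ndarray, cond_probs: np.ndarray) -> float:
    """I(G;R') from P(g) and P(r'|g): joint = P(g) * P(r'|g)."""
    joint = g_probs[:, None] * cond_probs
    return mutual_information(joint)


def ideal_nonlinearity(g_samples: np.ndarray, count_law: CountLaw,
                       r_max: float,
                       x0_grid: np.ndarray | None = None,
                       x1_grid: np.ndarray | None = None,
                       n_g_bins: int = 33,
                       refine: bool = True) -> CapacityResult:
    """Grid search for the information-maximizing sigmoid nonlinearity.

    For each candidate sigmoid N0(g) = r_max / (1 + exp(-(g - x0)/x1)) the
    joint P(g, r') = P(g) P(r | N0(g)) is built from the empirical marginal
    of the linear prediction (discretized to ``n_g_bins`` bins) and the count
    law, and the mutual information computed; the maximizing (x0, x1) is
    returned.  The mean firing rate is not constrained.
    """
    g = np.asarray(g_samples, dtype=float)
    if g.size == 0:
        raise ValueError("empty g sample")
    mu, sd = g.mean(), g.std()
    if x0_grid is None:
        x0_grid = mu + sd * np.linspace(-4, 4, 81)
    if x1_grid is None:
        x1_grid = sd * np.logspace(np.log10(0.05), np.log10(2.0), 40)
    x0_grid = np.asarray(x0_grid, dtype=float)
    x1_grid = np.asarray(x1_grid, dtype=float)
    if x0_grid.size == 0 or x1_grid.size == 0:
        raise ValueError("empty grid")
    # discretize g: P(g) over bin representatives
    uniq = np.unique(g)
    if uniq.size <= n_g_bins:
        centers = uniq
        p_g = np.array([(g == u).mean() for u in uniq])
    else:
        edges = np.quantile(g, np.linspace(0, 1, n_g_bins + 1))
        edges = np.unique(edges)
        idx = np.clip(np.searchsorted(edges, g, side="right") - 1, 0,
                      len(edges) - 2)
        centers = np.array([g[idx == b].mean() for b in range(len(edges) - 1)
                            if np.any(idx == b)])
        p_g = np.array([(idx == b).mean() for b in range(len(edges) - 1)
                        if np.any(idx == b)])

    def search(x0s: np.ndarray, x1s: np.ndarray):
        best = (-np.inf, x0s[0], x1s[0])
        for x0 in x0s:
            for x1 in x1s:
                cond = count_law(_sigmoid(centers, x0, x1, r_max))
                i = channel_information(p_g, cond)
                if i > best[0]:
                    best = (i, float(x0), float(x1))
        return best

    i_best, x0_best, x1_best = search(x0_grid, x1_grid)
    if refine and x0_grid.size > 2 and x1_grid.size > 2:
        dx0 = np.median(np.diff(np.sort(x0_grid)))
        x0_fine = x0_best + dx0 * np.linspace(-1, 1, 9)
        x1_fine = x1_best * np.logspace(-0.1, 0.1, 9)
        i2, x0b2, x1b2 = search(x0_fine, x1_fine)
        if i2 > i_best:
            i_best, x0_best, x1_best = i2, x0b2, x1b2
    return CapacityResult(x0_best, x1_best, r_max, i_best,
                          grid={"x0": x0_grid, "x1": x1_grid,
                                "n_g_bins": n_g_bins})


def info_fraction(i_actual: float, capacity: CapacityResult) -> float:
    """Fraction of the cell's information capacity actually used."""
    if capacity.I_max == 0:
        raise ZeroDivisionError("capacity is zero: fraction undefined")
    return float(i_actual / capacity.I_max)
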