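"""Spatiotemporal simulation: bipolar-cell drive under natural-like images
with fixational drift and a sudden global shift.

A grid of identical model bipolar cells with separable center/surround
receptive fields (uniform spatial disks, biphasic temporal kernels) filters a
jittered image; contrast-dependent Gaussian noise is added per cell (noise SD
set so the population signal-to-noise ratio follows a configured SNR-vs-
contrast curve); each cell's noisy drive is rectified and divisively adapted.
Information dynamics are then measured as the mutual information between the
linear prediction and the response at each delay from the shift, and the
conditional mutual information given the previous response.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .gating import divisive_adaptation, threshold_rectify
from .info import conditional_mi_prev, joint_from_labels, mutual_information, quantize
from .stimuli import EyeTrajectory, ImageEnsemble

__all__ = [
    "BipolarRF",
    "PopulationDrive",
    "NoiseCurve",
    "default_bipolar_rf",
    "population_linear_prediction",
    "contrast_noise",
    "simulate_population",
    "info_dynamics",
    "patch_correlation",
]


def _biphasic_kernel(dt: float, length_s: float, tau_fast: float,
                     tau_slow: float) -> np.ndarray:
    t = np.arange(int(round(length_s / dt))) * dt
    alpha = lambda tau: (t / tau) * np.exp(1.0 - t / tau)
    w = alpha(tau_fast) - (tau_fast / tau_slow) * alpha(tau_slow)
    w -= w.mean()   # exactly zero DC: static luminance carries no drive
    return w / np.linalg.norm(w)


@dataclass
class BipolarRF:
    """Separable center/surround receptive field of a model bipolar cell.

    Spatial profiles are uniform disks of ``center_diam`` and
    ``surround_diam`` degrees; temporal kernels are per-tap weights at the
    frame rate.  The surround is subtracted with weight ``surround_weight``
    relative to the center gain.
    """

    center_diam: float = 1.0
    surround_diam: float = 2.5
    center_kernel: np.ndarray = None
    surround_kernel: np.ndarray = None
    surround_weight: float = 0.5
    dt: float = 1.0 / 30.0

    def __post_init__(self) -> None:
        if self.center_diam <= 0 or self.surround_diam <= self.center_diam:
            raise ValueError("need surround_diam > center_diam > 0")


def default_bipolar_rf(dt: float = 1.0 / 30.0) -> BipolarRF:
    """Fast-Off-like defaults: biphasic center peaking ~60 ms, surround
    delayed by ~20 ms, surround weight 0.5."""
    return BipolarRF(
        center_kernel=-_biphasic_kernel(dt, 0.4, 0.06, 0.12),
        surround_kernel=-_biphasic_kernel(dt, 0.4, 0.08, 0.16),
        dt=dt,
    )


@dataclass
class PopulationDrive:
    """Linear prediction g(x, t) for every model cell.

    ``g`` has shape (n_cells, n_frames) pooling the cell grid over all
    images; ``white_gain`` is the SD gain of the full receptive field on a
    spatially uniform unit-SD white-noise field (used to convert a population
    SD into an equivalent Gaussian contrast).
    """

    g: np.ndarray
    dt: float
    cell_grid: np.ndarray        # (n_cells_per_image, 2) positions in deg
    n_images: int
    mean_intensity: float
    white_gain: float
    meta: dict = field(default_factory=dict)


@dataclass
class NoiseCurve:
    """Signal-to-noise ratio (signal SD / noise SD) as a function of contrast.

    Linearly interpolated between grid points; the default constructor
    :meth:`linear` is a synthetic stand-in rising linearly through the origin.
    """

    contrasts: np.ndarray
    snr: np.ndarray

    def __post_init__(self) -> None:
        self.contrasts = np.asarray(self.contrasts, dtype=float)
        self.snr = np.asarray(self.snr, dtype=float)
        if np.any(self.snr < 0):
            raise ValueError("SNR must be non-negative")

    @classmethod
    def linear(cls, snr_at_10pct: float = 2.0,
               max_contrast: float = 2.0) -> "NoiseCurve":
        c = np.array([0.0, max_contrast])
        return cls(c, c * (snr_at_10pct / 0.10))

    def __call__(self, contrast: np.ndarray) -> np.ndarray:
        return np.interp(contrast, self.contrasts, self.snr)

    def scaled(self, factor: float) -> "NoiseCurve":
        """Multiply the SNR curve by a factor (halves/doubles the noise)."""
        return NoiseCurve(self.contrasts, self.snr * factor)


def _disk_kernel(diam_deg: float, pixel_deg: float) -> np.ndarray:
    radius = diam_deg / 2.0
    npx = int(np.ceil(radius / pixel_deg))
    ax = (np.arange(-npx, npx + 1)) * pixel_deg
    yy, xx = np.meshgrid(ax, ax, indexing="ij")
    disk = (yy ** 2 + xx ** 2 <= radius ** 2 + 1e-12).astype(float)
    return disk / disk.sum()


def population_linear_prediction(images: ImageEnsemble,
                                 trajectory: EyeTrajectory,
                                 rf: BipolarRF,
                                 grid_spacing_deg: float | None = None
                                 ) -> PopulationDrive:
    """Linear prediction g(x, t) for a grid of non-overlapping model cells.

    Each image is convolved with the center and surround spatial disks; the
    filtered images are sampled along the (shared) eye trajectory at each cell
    location, and the resulting spatial drives convolved with the temporal
    kernels: g = kc * center - w * (ks * surround), on mean-subtracted images.
    """
    if grid_spacing_deg is None:
        grid_spacing_deg = rf.center_diam
    px = images.pixel_deg
    imgs = images.images - images.mean
    n_img, ny, nx = imgs.shape
    kc = _disk_kernel(rf.center_diam, px)
    ks = _disk_kernel(rf.surround_diam, px)
    fc = np.stack([fftconvolve(im, kc, mode="same") for im in imgs])
    fs = np.stack([fftconvolve(im, ks, mode="same") for im in imgs])
    # margin: surround radius plus the trajectory's maximal excursion
    traj_px = np.round(trajectory.positions / px).astype(int)
    margin_px = (int(np.ceil(rf.surround_diam / 2.0 / px))
                 + np.abs(traj_px).max())
    lo, hi_y, hi_x = margin_px, ny - margin_px, nx - margin_px
    if hi_y <= lo or hi_x <= lo:
        raise ValueError(
            f"trajectory + receptive field exceed image bounds: need margin "
            f"{margin_px} px but image is only {ny}x{nx}")
    step = max(1, int(round(grid_spacing_deg / px)))
    gy = np.arange(lo, hi_y, step)
    gx = np.arange(lo, hi_x, step)
    cy, cx = np.meshgrid(gy, gx, indexing="ij")
    cell_grid = np.stack([cy.ravel() * px, cx.ravel() * px], axis=1)
    yy = cy.ravel()[:, None] + traj_px[None, :, 1]
    xx = cx.ravel()[:, None] + traj_px[None, :, 0]
    sc = fc[:, yy, xx]          # (n_img, n_cells, n_frames)
    ss = fs[:, yy, xx]
    n_frames = trajectory.n_frames
    drive_c = fftconvolve(sc, rf.center_kernel[None, None, :],
                          mode="full", axes=2)[:, :, :n_frames]
    drive_s = fftconvolve(ss, rf.surround_kernel[None, None, :],
                          mode="full", axes=2)[:, :, :n_frames]
    g = drive_c - rf.surround_weight * drive_s
    g = g.reshape(-1, n_frames)
    k_eff = np.zeros(max(rf.center_kernel.size, rf.surround_kernel.size))
    k_eff[: rf.center_kernel.size] += rf.center_kernel
    k_eff[: rf.surround_kernel.size] -= rf.surround_weight * rf.surround_kernel
    white_gain = float(np.linalg.norm(k_eff))
    return PopulationDrive(g, trajectory.dt, cell_grid, n_img,
                           images.mean, white_gain,
                           meta={"burn_in": rf.center_kernel.size})


def contrast_noise(drive: PopulationDrive, curve: NoiseCurve,
                   seed: int = 0) -> np.ndarray:
    """Add contrast-dependent independent Gaussian noise to every cell.

    At each time bin the population SD of the linear prediction defines an
    equivalent Gaussian contrast (the white-noise contrast whose filtered
    output would have the same SD); the noise SD is then population SD divided
    by the SNR at that contrast.  Each cell receives independent noise.
    """
    g = drive.g
    if g.shape[0] < 2:
        raise ValueError("need >= 2 cells to define a population SD")
    pop_sd = g.std(axis=0)
    equiv_contrast = pop_sd / (drive.mean_intensity * drive.white_gain)
    snr = curve(equiv_contrast)
    if np.any((snr == 0) & (pop_sd > 0)):
        raise ValueError("SNR curve is zero at a required contrast")
    noise_sd = np.where(snr > 0, pop_sd / np.where(snr > 0, snr, 1.0), 0.0)
    rng = np.random.default_rng(seed)
    return g + noise_sd[None, :] * rng.standard_normal(g.shape)


def simulate_population(images: ImageEnsemble, trajectory: EyeTrajectory,
                        rf: BipolarRF, curve: NoiseCurve,
                        theta_sd: float = 2.0, alpha: float = 0.30,
                        tau_adapt: float = 10.0, seed: int = 0,
                        drive: PopulationDrive | None = None
                        ) -> tuple[PopulationDrive, np.ndarray]:
    """Full population simulation: linear drive, noise, rectify, adapt.

    The noisy drive is standardized by its pre-shift (fixation) population SD
    so the threshold ``theta_sd`` is in fixation-SD units; each cell is then
    passed through the same rectification and feedforward divisive adaptation
    as the reduced gating model.  Returns (drive, responses r(x, t)).
    """
    if drive is None:
        drive = population_linear_prediction(images, trajectory, rf)
    noisy = contrast_noise(drive, curve, seed=seed)
    burn = drive.meta.get("burn_in", 0)
    if np.isfinite(trajectory.saccade_time):
        pre_end = int(round(trajectory.saccade_time / drive.dt))
    else:
        pre_end = noisy.shape[1]
    ref = noisy[:, burn:pre_end]
    sd0 = ref.std() if ref.size else noisy.std()
    if sd0 == 0:
        sd0 = 1.0
    z = noisy / sd0
    c = threshold_rectify(z, theta_sd)
    r = np.vstack([divisive_adaptation(row, alpha, tau_adapt, drive.dt)
                   for row in c])
    return drive, r


def _rebin_mean(x: np.ndarray, factor: int) -> np.ndarray:
    n = (x.shape[1] // factor) * factor
    return x[:, :n].reshape(x.shape[0], -1, factor).mean(axis=2)


def info_dynamics(drive: PopulationDrive, responses: np.ndarray,
                  saccade_time: float, delta_s: float = 0.05,
                  bin_s: float = 0.05, n_bins: int = 16,
                  permute_responses: bool = False,
                  seed: int = 0) -> dict:
    """Time-resolved information between linear prediction and response.

    Both the linear prediction and the responses are averaged over ``bin_s``
    bins and quantized into ``n_bins`` equal-occupancy bins held fixed across
    all delays; at each delay p from the shift, I(G_t;R_t|p) is the plug-in
    mutual information across the cell population, and
    I(G_t;R_t|R_{t-Delta},p) conditions on the response one ``delta_s``
    earlier.  ``permute_responses`` shuffles responses across cells within
    each time bin (sampling-noise control).
    """
    factor = int(round(bin_s / drive.dt))
    g = _rebin_mean(drive.g, factor)
    r = _rebin_mean(responses, factor)
    # temporal-convolution burn-in: the first filter length of the drive is
    # edge-contaminated and excluded from all statistics
    burn_bins = int(np.ceil(drive.meta.get("burn_in", 0) / factor))
    g = g[:, burn_bins:]
    r = r[:, burn_bins:]
    if permute_responses:
        rng = np.random.default_rng(seed)
        for j in range(r.shape[1]):
            r[:, j] = rng.permutation(r[:, j])
    gq = quantize(g.ravel(), n_bins).reshape(g.shape)
    rq = quantize(r.ravel(), n_bins).reshape(r.shape)
    lag = int(round(delta_s / bin_s))
    n_t = g.shape[1]
    times = (np.arange(n_t) + burn_bins + 0.5) * bin_s - saccade_time
    mi = np.full(n_t, np.nan)
    cmi = np.full(n_t, np.nan)
    for t in range(n_t):
        mi[t] = mutual_information(joint_from_labels(gq[:, t], rq[:, t]))
        if t >= lag:
            cmi[t] = conditional_mi_prev(gq[:, t], rq[:, t], rq[:, t - lag],
                                         n_bins=n_bins,
                                         quantize_inputs=False)
    return {"time_s": times, "mi": mi, "conditional_mi": cmi,
            "bin_s": bin_s, "delta_s": delta_s, "n_bins": n_bins}


def patch_correlation(images: ImageEnsemble, patch_deg: float,
                      distance_grid: np.ndarray, n_pairs: int = 2000,
                      seed: int = 0) -> np.ndarray:
    """Pearson correlation of patch-mean intensities vs center distance.

    Patches are disks of ``patch_deg`` diameter; for each distance, pairs of
    patch centers separated by that distance (random orientation) are sampled
    across the ensemble and the correlation of their mean intensities
    computed.  Distance 0 returns exactly 1.
    """
    px = images.pixel_deg
    kern = _disk_kernel(patch_deg, px)
    filt = np.stack([fftconvolve(im, kern, mode="same")
                     for im in images.images])
    n_img, ny, nx = filt.shape
    rng = np.random.default_rng(seed)
    out = np.empty(len(distance_grid))
    for i, d in enumerate(np.asarray(distance_grid, dtype=float)):
        if d == 0:
            out[i] = 1.0
            continue
        d_px = d / px
        margin = int(np.ceil(patch_deg / 2 / px + d_px)) + 1
        if 2 * margin >= min(ny, nx):
            raise ValueError("patches at this distance do not fit the images")
        ii = rng.integers(0, n_img, n_pairs)
        y1 = rng.integers(margin, ny - margin, n_pairs)
        x1 = rng.integers(margin, nx - margin, n_pairs)
        theta = rng.uniform(0, 2 * np.pi, n_pairs)
        y2 = np.clip(np.round(y1 + d_px * np.sin(theta)).astype(int),
                     0, ny - 1)
        x2 = np.clip(np.round(x1 + d_px * np.cos(theta)).astype(int),
                     0, nx - 1)
        a = filt[ii, y1, x1]
        b = filt[ii, y2, x2]
        out[i] = float(np.corrcoef(a, b)[0, 1])
    return out
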