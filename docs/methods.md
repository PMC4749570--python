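# Methods

## The model

A retinal ganglion cell's response to a local (center) stimulus under
peripheral stimulation is modeled as a two-pathway cascade:

1. **Central drive.** The center intensity trace s(t) (mean-relative units;
   contrast = SD/mean) is mean-subtracted and convolved with a biphasic
   temporal filter F (difference of alpha functions, ~400 ms support). The
   filter carries only relative temporal sensitivity: the output is rescaled
   so var(b) = var(s) (for white noise this is equivalent to a unit-L2
   filter). A drive gain (see *Calibration*) then converts contrast units to
   the drive units in which the threshold and adaptation operate.
2. **Peripheral signal.** Each abrupt peripheral shift triggers the same
   causal biphasic signal a(t): positive lobe first, then a negative lobe,
   identical for both shift phases, summing linearly when shifts are closer
   than the kernel support. The kernel is a difference of alpha functions
   (t/τ)e^(1−t/τ) with τ_on = 50 ms and τ_off = 110 ms, equal lobe areas by
   default, a 30 ms latency, and peak amplitude A. These constants place the
   excitatory lobe over the 50–100 ms gating window (peak ≈ 75 ms, zero
   crossing ≈ 175 ms) and the suppressive lobe over ~175–450 ms, leaving
   0–50 ms as a true baseline window; with the earlier-considered
   τ_off = 180 ms the suppressive lobe would not begin until ~200 ms and
   would still be strong at the next shift, contradicting the window
   structure the model is meant to reproduce. The relative size of the two
   lobes is not constrained beyond these timings and is configurable.
3. **Threshold.** c(t) = max(0, b + a − θ), slope one above threshold. By
   default θ = 0.9·max a(t), so weak central inputs cross threshold only
   with the help of peripheral excitation.
4. **Feedforward divisive adaptation.** y(t) = c(t)/(α + (F_α∗c)(t)) with
   α = 0.30 and F_α a unit-sum exponential with τ = 10 s, evaluated as a
   first-order recursive filter (exact unit mass, closed-form steady state
   y → c₀/(α + c₀)). Sweeping τ over 1–100 s leaves the adaptation-index
   time course qualitatively unchanged (tested). Firing rates are
   rate_scale·y and spikes are Poisson per bin — the count law of the real
   cells is not known, and all information machinery accepts any empirical
   count distribution.

## Calibration of the study conditions

The model has a scale freedom: (b, a, θ, α) can be scaled jointly. Since
α is fixed at 0.30, the drive scale decides how strongly the adaptive stage
engages. All experiment designs use one convention, **drive gain 60 per unit
contrast** (a 10%-contrast stimulus has drive SD 6), chosen so that the
rectified drive in the gating window is of order α and adaptation is
neither absent nor saturating. The peripheral amplitude A is then set per
design so the threshold 0.9·A sits a fixed number of drive-SDs above the
mean drive at the design's reference contrast:

- pink-noise gating design: 1.5 SD at 10% contrast. A 1/f stimulus
  concentrates its power at low frequencies, so the upper-tail mass of a
  finite record fluctuates strongly between realizations; 1.5 SD keeps the
  baseline state reliably (if sparsely) active at ~0.5–2 Hz.
- white-noise contrast series (3/6/12/24%): 1.75 SD at 24%, so the recovery
  window retains enough tail-driven spikes for windowed reverse correlation.
- binary sequence design: 1.0 SD at 24%. A binary drive has bounded
  (sub-Gaussian) tails; at higher thresholds the post-suppression windows
  are exactly silent and can carry no late contrast information.
- rate_scale = 6 Hz per output unit, giving gating-window rates of
  ~15–40 Hz and baseline rates of ~0.5–2 Hz.

These are study-condition choices fixed at design time, recorded here in
full so that every simulated experiment is reproducible from its config and
seed alone (each experiment also emits a manifest with a config hash).

## Stimulus generators

- **Pink noise** is synthesized in the frequency domain (Gaussian spectral
  coefficients shaped by 1/f, DC pinned to the mean; DC excluded from slope
  fits), then rescaled to the exact target contrast. Fitted log–log
  amplitude slopes fall in [−1.2, −0.8].
- **White noise** supports piecewise contrast schedules and a binary mode
  (μ ± σμ). Gaussian contrasts above 1 would produce negative intensities;
  a truncated-Gaussian fallback is used and recorded in the trace metadata.
- **Sequence design**: the "order-4 binary sequence" is a de Bruijn cycle of
  length 2⁴ = 16 (0.1 s × 16 = 1.6 s per cycle, every 4-frame window exactly
  once per cycle). With 100 ms p-bins over the 1 s peripheral period and four
  contrasts this yields 10 × 16 × 4 = 640 conditions. Because the 1.6 s
  cycle and the 1 s period share a divisor of 0.2 s, a single repeating
  alignment covers only half the (p, window) pairs; presentation blocks of
  five cycles are therefore rotated by one frame on alternating blocks
  (each preceded by three warm-up frames so every scored frame has a valid
  in-cycle history), making the census exactly uniform. Eleven block pairs
  are presented per contrast and the first pair after each contrast
  transition is discarded, leaving every condition measured exactly
  10 × n_trials times.
- **Eye trajectories**: fixational drift is an isotropic Gaussian random
  walk whose mean frame-to-frame speed equals the configured drift speed
  (0.33°/s default), interrupted by a single-frame saccade step (6°
  default, random orientation).
- **Image ensembles** are Gaussian random fields with a 1/f^k spatial
  amplitude spectrum, identical means (DC pinned) and a common RMS contrast
  — a synthetic stand-in for a natural-image database. They reproduce the
  one property the analyses rely on, spatial correlations decaying over a
  few degrees; they contain none of the higher-order structure (edges,
  objects, luminance skew) of real scenes, so passing tests demonstrate the
  machinery and the correlation-timing argument, not natural-image-specific
  statistics. Spatial units: 50 µm on the retina ≡ 1° of visual field
  (converters provided).

## Estimation choices

- **Filters** are spike-triggered averages; for correlated stimuli the
  cross-correlation is normalized by the stimulus autocorrelation by solving
  the lag-domain Toeplitz normal equations. A ridge of 1e−4 × zero-lag power
  conditions the solve (the autocorrelation matrix of a 1/f stimulus has
  condition number ~1e5; spectral division with a ridge proportional to the
  maximum power suppresses everything above ~0.5 Hz and was rejected for
  that reason). Windowed fits, which leave few effective samples for the
  deconvolution, accept an additional second-difference smoothness penalty
  (`smooth`, typically 0.03–0.1).
- **Nonlinearities** are mean rates over bins of the linear prediction,
  equal-occupancy by default (whether the original bins were equal-width or
  equal-occupancy is unspecified; both are supported). Sensitivity is the
  occupancy-weighted mean of centered finite-difference slopes (one-sided at
  the ends); an unweighted variant is available.
- **Window membership** uses response-bin midpoints; 50 ms bins are the
  default throughout, and a robustness check verifies the gating conclusions
  for 25–125 ms bins.
- **Information** uses plug-in histogram estimators in bits. Quantization is
  by equal-occupancy quantiles held fixed across all delays — a
  deterministic, reproducible surrogate for information-maximizing bin
  placement. When point masses (e.g. the mostly-zero rectified output)
  collapse the quantile edges, each heavy atom receives its own label and
  the remaining label budget is spread over the continuous part, preserving
  tail resolution. I(R;C|p) is reported as the mean over the two peripheral
  phases. Finite-data bias can be reduced by fitting a quadratic in the
  inverse data fraction and evaluating at zero; estimates at fractional data
  sizes should be averaged over disjoint splits. No advanced bias
  corrections (NSB and relatives) are implemented.
- **Capacity search** builds P(g, r′) = P(g)·P(r|N₀(g)) from the empirical
  marginal of g (which is approximately Gaussian in the intended designs)
  and a tabulated count law with linear interpolation between rate rows,
  then grid-searches the sigmoid midpoint (±4 SD of g, 81 steps) and
  inverse slope (0.05–2 SD, 40 log steps) with one refinement pass. The mean
  firing rate is deliberately unconstrained: for a high-threshold cell the
  optimal midpoint moves left of the measured one, buying information with
  extra spikes.
- **Adaptation index**: OLS **with intercept** of m̃ = m/m₀ against 1/σ̃.
  An intercept-free fit would force the index of a noisy ideal cell toward
  1 by construction. The index is invariant to rescaling all slopes; the
  highest contrast is the reference by convention. Windows in which even
  the reference contrast drives no measurable slope yield NaN.

## Natural-scene simulation

Model bipolar cells tile each image on a non-overlapping 1° grid (uniform
disks of 1.0° center / 2.5° surround, surround weight 0.5, biphasic
center/surround temporal kernels with exactly zero DC so static luminance
carries no drive). Images are sampled along a shared drift + 6° saccade
trajectory; center and surround spatial signals are convolved with their
temporal kernels and summed. Noise is independent Gaussian per cell with a
time-varying SD: the population SD of the linear prediction defines an
equivalent Gaussian contrast (the white-noise contrast whose filtered output
SD matches it, via the L2 norm of the effective temporal kernel), and the
SNR-vs-contrast curve sets noise SD = signal SD / SNR. The default curve is
linear through the origin with SNR 2 at 10% contrast — explicitly a
configurable stand-in, as no numeric curve is available; halving or doubling
it does not change the timing results (tested). The noisy drive is
standardized by its pre-saccade SD, thresholded at 2 fixation-SDs, and
divisively adapted per cell.

Information dynamics average drive and response over 50 ms bins, quantize
both to 16 bins fixed across delays, and compute I(G_t;R_t|p) and
I(G_t;R_t|R_{t−Δ},p) (Δ = 50 ms) across the cell population at each delay
p from the saccade; the first temporal-filter length is excluded as
convolution burn-in. Desk scale is 64 synthetic images of 40° at 0.25°/pixel
(~43,000 model cells over 3 s), which keeps the permutation control at the
plug-in bias floor (~0.01 bits) — about two orders of magnitude below the
post-saccadic peak.

## Experiment designs

- **Object vs global shifts**: the object-shift response of a model cell is
  a one-frame central transient at each shift with amplitude
  coupling × (L − background mean) — a stand-in for receptive-field/border
  overlap, with the same sign for both shift directions (rectified border
  response), so left- and right-shift sensitivities agree and are averaged.
  Luminance sensitivity m is the OLS slope of the 50–150 ms window rate
  against log luminance (four log-spaced luminances). The default cell is a
  weak responder (coupling 0.55); a family of couplings reproduces the
  negative trend of gain ratio against object-condition response.
- **Mask distance**: peripheral coupling decays as exp(−d/λ) with
  λ = 250 µm (the falloff is measured but not parameterized in the source
  experiments; λ is a model parameter). The mask is treated as a simple
  annulus-gap distance. Sensitivities are normalized by the no-background
  condition; the gating window additionally subtracts its 0–50 ms baseline
  deviation, the inhibitory window (250–350 ms) does not.
- All model experiments run at 40 Hz frames (25 ms) so 50 ms analysis bins
  tile the frames exactly; gating conclusions are insensitive to bin width.

## Known limitations

- The threshold nonlinearity never saturates, so gating shifts the fitted
  nonlinearity laterally but lets its fitted maximum grow with the window's
  drive range; statements about "unchanged maxima" require saturating cells.
- Poisson spiking understates the count-law structure of real cells; the
  capacity machinery accepts empirical count laws but the simulations do
  not generate them.
- The plug-in information estimators are biased at small trial counts; the
  analyses either compare like with like (same bias) or extrapolate.
- No photoreceptor/luminance adaptation, no mechanistic amacrine circuitry
  for the peripheral signal, no population or latency codes.
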