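# perigate

Peripheral gating of retinal information transmission: a tested, fully
synthetic re-implementation of the analysis pipeline around the "shift
effect" — the long-range excitation retinal ganglion cells receive when the
image far outside their receptive field moves abruptly, as during a saccade
or the motion of a large object.

The package is aimed at computational and systems neuroscientists who want
to study how a timed peripheral signal reshapes the neural code for a local
stimulus. It provides, end to end:

- **Synthetic stimuli and ground-truth model cells** (`perigate.stimuli`):
  Gaussian pink (1/f) and white-noise center intensities at controlled
  contrast (contrast = SD/mean), peripheral shift schedules, binary de Bruijn
  sequence designs, fixational-drift + saccade eye trajectories, 1/f-spectrum
  image ensembles, and Poisson spiking.
- **A reduced two-pathway gating model** (`perigate.gating`): the central
  stimulus s(t) is filtered, b(t) = (F∗s)(t), summed with a timed biphasic
  peripheral signal a(t) triggered by each shift, thresholded with unit
  slope, c(t) = max(0, b + a − θ) with θ = 0.9·max a, and scaled by
  feedforward divisive adaptation, y(t) = c/(α + F_α∗c), with α = 0.30 and a
  unit-integral exponential F_α (τ = 10 s).
- **LN-model estimation** (`perigate.ln`): reverse-correlation filters
  (whitened by the stimulus autocorrelation for temporally correlated
  stimuli), binned static nonlinearities N(g), windowed fits using only
  spikes at a given time since the shift, and sensitivity = the
  occupancy-weighted average slope of N.
- **Information theory** (`perigate.info`): plug-in histogram estimators for
  the time-resolved mutual information I(R;C|p) between the spike count and
  the central stimulus at time p since the shift, the chain-rule split
  I(R;P,C) = I(R;P) + ⟨I(R;C|p)⟩, the sequence/contrast decomposition
  {I(R;Σ|p), I(R;M⁽⁴⁾|p), I(R;M⁽⁴⁾|Σ,p)}, conditional information given the
  previous response, and quadratic extrapolation to the infinite-data limit.
- **Adaptation index and capacity bound** (`perigate.adaptation`): the index
  is the OLS slope of normalized nonlinearity slope against normalized
  inverse contrast (1 for an ideally adapting cell, 0 for a non-adapting
  one); the capacity search finds the sigmoid nonlinearity maximizing
  I(G;R) given a cell's count law P(r|⟨r⟩) and maximum rate, with the mean
  rate left unconstrained.
- **A spatiotemporal natural-scene simulation** (`perigate.natural`): a grid
  of model bipolar cells with 1.0°/2.5° center/surround disks and biphasic
  temporal kernels filters a jittered synthetic image ensemble; contrast-
  dependent Gaussian noise, rectification and divisive adaptation follow;
  conditional information I(G_t;R_t|R_{t−Δ},p) tracks the arrival of novel
  information after a 6° global shift.
- **Experiment designs** (`perigate.experiments`): object-vs-global shifts,
  pink-noise information gating, contrast-series adaptation, the 640-condition
  sequence/contrast design, and mask-distance scaling of the gating effect.

## Worked example

Run the pink-noise gating experiment on a model cell (10% contrast center,
periphery reversing every 0.5 s) and print the shift-aligned firing rate and
information time course:

```python
import numpy as np
from perigate.experiments import run_gating_info, ExperimentConfig
from perigate.adaptation import adaptation_index

res = run_gating_info(ExperimentConfig("gating_info", seed=1))
print("p_bin_s   rate_hz   info_bits")
for p, r, i in zip(res["info"].p_bins, res["psth"], res["info"].info):
    print(f"{p:7.2f} {r:9.2f} {i:11.3f}")

idx = adaptation_index(np.array([8.0, 4.0, 2.0, 1.0]),
                       np.array([0.03, 0.06, 0.12, 0.24]))
print("adaptation index of an ideally adapting cell:", round(idx, 6))
```

Output:

```
p_bin_s   rate_hz   info_bits
   0.00      0.36       0.070
   0.05     14.29       0.712
   0.10      6.84       0.493
   0.15      0.80       0.125
   0.20      0.17       0.040
   0.25      0.10       0.026
   0.30      0.11       0.029
   0.35      0.16       0.040
   0.40      0.17       0.040
   0.45      0.26       0.056
adaptation index of an ideally adapting cell: 1.0
```

Reading the table: each row is a 50 ms bin of time since the peripheral
shift. Firing and transmitted information about the central stimulus surge
in the 50–100 ms gating window (14.3 Hz, 0.71 bits per 50 ms count),
collapse during the suppression phase (~150–350 ms), and recover toward the
sparse baseline before the next shift — the periphery transiently gates the
cell's information transmission about its own receptive-field center. The
adaptation-index call shows the closed-form behavior of the index: slopes
exactly inversely proportional to contrast give 1.

A command-line interface mirrors the library
(`perigate simulate|ln|info|adapt-index|ideal-info|natural-scene|experiment`),
reading YAML configs and writing CSV/JSON plus an HDF5 array container.

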