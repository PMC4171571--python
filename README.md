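# streaklab

Quantitative analysis of primitive-streak-like differentiation in mouse
embryonic stem cell (mESC) culture. When mESCs are differentiated with
activin A (Act) and the GSK3 inhibitor CHIR99021 (Chi), cells undergo an
epithelial-to-mesenchymal transition (EMT), transiently express the
primitive-streak marker brachyury (Bra), and become highly motile — a
culture model of the cells that ingress through the primitive streak at
gastrulation. `streaklab` implements the four quantitative arms used to
characterise that system, together with a synthetic-data generator so that
every stage is testable without any microscope or cytometer output:

* **motility** — frame-to-frame instant velocities and their time-binned
  distributions, cumulative distance, time-averaged mean-squared
  displacement (MSD) per cell and per ensemble, effective diffusivity
  D_eff = slope/4 from straight-line MSD fits over 10-h windows,
  signed turning angles with a Kolmogorov–Smirnov uniformity test for
  directional persistence, and reporter-vs-motility association;
* **qia** — quantitative image analysis: nuclear segmentation on the
  Hoechst channel (Gaussian smoothing, Otsu threshold, area filter),
  per-nucleus mean intensity per channel, distribution timecourses and
  pairwise Pearson-correlation timecourses, plus a 10-μm circular-ROI
  reporter readout along a track;
* **population** — cytometry-style analysis: viability gating, a
  positivity threshold derived as an upper quantile of a negative
  control, replicate positive-percentage timecourses, and per-timepoint
  one-way ANOVA with Tukey's adjustment against the time-matched control;
* **qpcr** — kinetic qPCR quantification with the MAK2 amplification
  model D_n = D_{n−1} + k·ln(1 + D_{n−1}/k), F_n = Fb + s·D_n: per-reaction
  nonlinear fits of the initial template D₀, technical-replicate
  averaging, and reference-gene (GAPDH) normalisation with error
  propagation;
* **synth** — condition presets (Act/Chi, Act, Chi, CsA-blocked,
  β-catenin mutant, Bra-null, pluripotency control) generating confined
  persistent random walks with EMT onsets and speed-coupled reporter
  pulses, correlated-channel nuclear image stacks, replicate event
  tables, and noisy MAK2 amplification curves — all deterministic under a
  single seed.

The model behind the trajectory generator: each cell carries a log-normal
baseline speed s_base and a truncated-normal EMT time; its heading evolves
by wrapped-normal increments (persistence), its speed is
s_base·m_EMT(t)·(1 + β·g(t)/g_peak) where m_EMT ramps to the EMT speed
multiplier and g(t) is a piecewise-linear reporter pulse, and positions
reflect at a confinement disk that widens after the EMT. Tracks are
right-censored at the field-of-view boundary, as in live-imaging practice.

## Worked example

```python
import numpy as np
from streaklab import (simulate_trajectories, instant_velocities,
                       bin_velocities_by_start, ensemble_msd,
                       fit_effective_diffusivity, turning_angles,
                       ks_uniformity_test, get_preset)

preset = get_preset("act_chi")
tracks = simulate_trajectories(preset, n_cells=200, duration=96.0,
                               dt=1/6, seed=1)

series = [instant_velocities(t) for t in tracks]
bins = bin_velocities_by_start(series, np.arange(0, 98, 2.0))
peak = max((b for b in bins if b.n > 0), key=lambda b: b.mean)
print(f"peak population velocity: {peak.mean:.1f} um/h in the {peak.label} h bin")

msd = ensemble_msd(tracks, interval=(30.0, 60.0), max_lag=2.0)
d = fit_effective_diffusivity(msd, fit_window=(0.0, 2.0))
print(f"effective diffusivity (30-60 h): {d.d_eff:.0f} +/- {d.slope_se/4:.0f} um^2/h")

angles = np.concatenate([turning_angles(t) for t in tracks])
ks = ks_uniformity_test(angles)
print(f"turning angles: n={ks.n}, KS D={ks.ks_stat:.3f}, p={ks.p_value:.3g}")
```

prints

```
peak population velocity: 59.4 um/h in the 58-60 h bin
effective diffusivity (30-60 h): 287 +/- 20 um^2/h
turning angles: n=114196, KS D=0.259, p=0
```

The population-average instant velocity peaks near 60 μm/h once most cells
have completed their EMT; the effective diffusivity quantifies the same
motility as a random-motion coefficient; and the turning-angle test
rejects isotropy decisively (persistent motion — the angle distribution is
peaked at zero), with an asymptotic p-value that underflows to 0.

A command-line interface mirrors the library
(`streaklab simulate|motility|qia|population|qpcr|run|reproduce-targets`);
`streaklab run --config cfg.yaml` executes a full simulate→analyse→report
pipeline and writes CSV tables, a JSON summary and a reproducibility
manifest.

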