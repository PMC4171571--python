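# Methods

This note documents the models implemented in `streaklab`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that results depend on.

## Trajectory model

Cells move as confined persistent random walks on a uniform time grid
with Δt = 1/6 h (one frame per 10 minutes, the standard widefield
live-imaging rate for this system; up to 96 h per experiment).

Per cell, drawn once at birth:

| quantity | distribution | units |
| --- | --- | --- |
| baseline speed s_base | log-normal(median, gsd) | μm/h |
| EMT onset T_EMT | Normal(μ, σ) truncated ≥ 0 | h |
| expresses reporter | Bernoulli(p_express) | — |
| reporter onset T_on | Normal(μ, σ) truncated ≥ 12 | h |
| pulse duration | Normal(μ, σ) truncated ≥ rise | h |
| pulse peak g_peak | log-normal(median, gsd) | AFU |

Dynamics per frame: the heading gains a wrapped-normal increment with SD
σ_θ (rad/frame); the speed is s(t) = s_base · m_EMT(t) · (1 + β·g(t)/g_peak),
where m_EMT ramps linearly from 1 to the EMT speed multiplier over
`mult_ramp` hours after T_EMT (and stays 1 for motility-blocked
conditions, which model cyclosporine-A treatment and the β-catenin
mutants); g(t) is a piecewise-linear pulse (linear rise over `expr_rise`,
plateau, linear fall over the same time, zero outside [T_on, T_on+dur]).
The reporter pulse is piecewise-linear because only population-level
expression waves are observable in this system, not single-cell pulse
shapes; any unimodal transient would serve, and the linear form makes the
analytic positive-fraction oracle exact.

Positions reflect at a disk of radius `confine_radius_pre` before the
EMT and `confine_radius_post` after it (a reflecting disk stands in for
colony/monolayer confinement; colony geometry is not modelled). Tracks
are right-censored at the first frame with |x| or |y| beyond the
field-of-view half-width, mirroring the rule that only cells remaining in
the field of view are tracked; censoring makes long-lag MSD a systematic
underestimate, and a regression test asserts exactly that bias.

Randomness: a master seed spawns per-cell (and per-replicate)
sub-streams via `SeedSequence(entropy=seed, spawn_key=(stream, index))`,
so any subset of cells is reproducible in isolation and identical
arguments give bit-identical outputs.

## Condition presets and calibration

Presets bundle the generative parameters per culture condition. The
calibrated defaults (Act/Chi: p_express 0.37, reporter onset N(36, 8) h,
duration N(52, 12) h, EMT N(30, 8) h, base speed log-normal median
16 μm/h gsd 1.5, EMT multiplier 3.0 over 10 h, β = 0.6, σ_θ = 0.6
rad/frame, confinement 40 → 50 μm) were fixed once, by simulation, so
that the full analysis pipeline applied to generated data reproduces the
experimental system's headline numbers: a sustained ≈33% reporter-positive
fraction at 48–72 h in Act/Chi (Act alone ≈10% at 72 h, Chi alone ≈25% at
48 h), a peak population-average instant velocity of ≈60 μm/h, and an
ensemble MSD that leaves its initial linear regime at ≈3 h. The Act and
Chi presets shift onset/duration and reduce p_express and the speed
multiplier; CsA and β-catenin-mutant presets are motility-blocked with
p_express ≤ 0.1; the Bra-null preset undergoes the EMT but with a mild
multiplier (1.4) and no reporter–speed coupling (β = 0), i.e. EMT without
fast motion. Whether non-expressing cells also accelerate after the EMT
is not observable per cell; the presets assume a shared EMT speed-up plus
a Bra-coupled boost, consistent with fast movers being the
reporter-expressing cells.

Two knobs moved materially during calibration and are worth recording:
the post-EMT confinement radius sets the MSD plateau level L, and since
the plateau-onset statistic is L divided by the initial MSD slope, large
radii push the apparent onset far beyond the diffusive-regime estimate
(at 150 μm it lands near 14 h); 50 μm reproduces the ≈3 h transition.
The EMT speed multiplier sets the velocity peak almost linearly.

## Event (cytometry) and image models

Event tables draw each event as an independent cell from the same
onset/duration/peak pulse model evaluated at the sample timepoint, plus
log-normal autofluorescence background (median 10 AFU, gsd 1.6) for every
event; 5% of events are flagged non-viable (the DAPI-exclusion stand-in).
Replicates (default 3, matching the at-least-three-replicates design) use
spawned sub-seeds.

Image scenes render non-overlapping nuclear disks (radius 8–12 px) on as
many 320×320 tiles as needed, with per-nucleus channel means drawn from a
joint channel model and i.i.d. Gaussian pixel noise clipped at zero. The
concordance model draws protein B log-normal and reporter G = B + ε with
σ_ε = 0.822·sd(B), so the population Pearson correlation is
1/√(1+0.822²) ≈ 0.773 — the measured concordance between the knock-in
reporter and immunostained protein. Ground truth (centroids, radii, true
means) is recorded for every nucleus.

## Analysis conventions

* **Instant velocity**: |Δr|/Δt per consecutive frame pair, timestamped
  at the pair midpoint; time bins are half-open [lo, hi). Tracks with
  gaps are split into contiguous segments first.
* **MSD**: time-averaged with overlapping pairs,
  msd(kΔt) = mean_i |r(t_i+kΔt) − r(t_i)|²; an exhaustive double-loop
  oracle in the tests fixes these semantics. The ensemble MSD averages
  per-cell curves with equal weight per cell (not pair counts), because
  the per-cell curve is the analysis unit; cells contributing fewer than
  6 pairs at a lag are dropped at that lag.
* **Effective diffusivity**: OLS of MSD on lag over (0, 2 h] with free
  intercept, D_eff = slope/4 (2-D); the default window sits inside the
  initial linear regime, which ends around 3 h. The diffusivity
  timecourse repeats this per 10-h window of experiment time; empty
  windows yield NaN entries, not errors.
* **Turning angles**: signed angle between consecutive displacement
  vectors, counter-clockwise positive in an x-right/y-up frame, exact
  reversals mapped to +π; steps shorter than 1 μm are skipped and the
  chain restarts (the 1 μm floor suppresses angle noise from
  near-stationary jitter). Uniformity on (−π, π] is tested with the
  one-sample KS test (asymptotic p), pooled per condition.
* **MSD plateau onset**: fit MSD(τ) = L(1 − e^(−τ/τc)); report the
  intersection of the initial-slope line (OLS over lags ≤ 0.5 h) with L,
  i.e. L/slope — equal to τc when the data follow the model exactly.
* **QIA**: Gaussian smoothing σ = 2 px, global Otsu threshold,
  8-connected components, minimum area 50 px². No watershed splitting
  (fixtures are non-overlapping by construction and touching-nuclei
  separation is out of scope) and no background subtraction. Pixel
  convention: 0-based, origin top-left, y down. Histograms share one
  range per channel across timepoints so distribution timecourses are
  comparable. On noiseless fixtures, unsmoothed segmentation recovers
  counts and channel means exactly; with the default smoothing the Otsu
  boundary admits a sub-pixel annulus, which dilutes absolute means
  slightly but leaves between-channel correlations essentially intact.
* **Population gating**: the positivity gate is the 99.9th percentile of
  the negative-control intensities — a declared convention (the
  experimental gate-setting rule is not recoverable), exposed as a
  parameter. Fractions are reported in percent. ANOVA + Tukey HSD run
  within each timepoint independently, with no across-time multiplicity
  correction, and significance flags at 0.05 and 0.01.
* **MAK2**: the published recurrence is implemented as stated; any
  further in-house adaptation of the method is unpublished and therefore
  out of scope. The fit window runs to the last cycle before
  baseline + 85% of the total rise (plateau cycles violate the model);
  D₀ is multi-started over a log-spaced D₀/k grid (8 starts), best
  residual wins, ties to the smaller D₀. Because fluorescence is
  invariant under (D₀, k, s) → (cD₀, ck, s/c), the fit fixes s = 1 and
  reports D₀ in fluorescence units; downstream normalisation is
  ratio-based, so the unit cancels. The declared order of operations is
  fit per reaction → average technical replicates (mean ± sd/√n) →
  normalise to the reference gene with quadrature error propagation.
  Non-amplifying curves (rise below 5× a first-cycles noise estimate)
  raise a dedicated error rather than returning a spurious D₀.

## Problem sizes

The shipped verification runs use the sizes at which the statistics are
stable at desk scale: 200 cells × 96 h for velocity summaries, 200 × 60 h
for the ensemble MSD, 100 × 60 h for turning angles (>10⁵ pooled angles),
10,000 events × 3 replicates per condition for population fractions,
500 nuclei across 10 tiles for the concordance correlation, 45-cycle
triplicates for qPCR, and 400-replicate null calibrations for the KS and
ANOVA tests.

## Limitations

The generator emulates the statistical structure of the data, not the
biology or optics: no cell division or lineage, no cell–cell adhesion or
collision, no directed migration, 2-D motion only, no photobleaching or
flat-field artefacts, circular nuclei without texture, and colony
geometry reduced to a reflecting disk. Passing recovery tests therefore
demonstrates that the analysis measures what it claims on data with known
ground truth — not that real microscopy data satisfy the generator's
assumptions. On real tracks, manual-tracking jitter inflates short-lag
MSD and turning-angle noise; the 1 μm minimum step and the configurable
fit windows are the intended mitigations. The MSD fit range and
time-averaging convention are fixed by declaration (the analysis they
reproduce does not state them); both are configurable.
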