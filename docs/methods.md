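# Methods notes

## Scope and data model

The package analyses trial-structured widefield fluorescence movies of a
presynaptic exocytosis reporter (synaptopHluorin) in the piriform cortex.
A *trial* is a short movie (`ImageStack`) with complete acquisition
metadata: frame rate (5 Hz by default), spatial scale (mm/px), the frame
at which the stimulus was applied, and the stimulus description
(`StimulusSpec`: electrical glomerular microstimulation, odourant, or
blank). Acquisition is modelled as respiration-triggered, so stimulus
onset always falls on a known frame; no respiration waveform is
simulated. The original acquisition geometry is 336×256 px; the
simulation-based tests and the acceptance script use an 84×64 px field so
that a 50-experiment run takes seconds rather than hours — the statistical
properties checked (per-pixel test calibration, focus recovery, cluster
separation) do not depend on the field size, only on per-pixel trial
statistics.

The spatial scale default (0.02 mm/px) is an arbitrary but plausible value
for a 4× widefield objective; it is carried in every stack's metadata and
all spatial-frequency arithmetic reads it from there, never assumes it.

## Synthetic data generator

Each trial is generated as

```
F(x,y,t) = F0(x,y) · exp(−t/τ) · (1 + a·G(x,y)·m(t)) · (1 + R(x,y)·s(t)) + ε
```

- `F0`: spatially smooth baseline field (default 100 a.u. with 10%
  large-scale heterogeneity, correlation length 0.5 mm). The field is
  fixed per *preparation* (seeded by `rng_seed`) and shared by all trials
  of an experiment, as real anatomy is; only noise and slow fluctuations
  vary from trial to trial.
- `exp(−t/τ)`: multiplicative photobleaching, τ = 20 s by default
  (appreciable but not dominant decay over a 5–6 s trial); `τ = inf` is
  supported for closed-form tests.
- Global fluctuation: amplitude `a` (default 0.02, i.e. 2% of baseline)
  times a slow temporal modulation `m(t)` (Gaussian-smoothed white noise,
  correlation time 2 s, normalised *exactly* to unit variance per frame
  through the filter's weights so that trial-to-trial variability remains
  a linear map of Gaussian noise) times a spatial weighting `G(x,y)`.
  By default `G ≡ 1`: nonspecific fluctuations of excitation intensity
  and brain-wide hemodynamics modulate the whole imaged field coherently,
  which is exactly the component the σ_lo high-pass (equivalently DC
  rejection at the aperture scale) is designed to remove. An optional
  `global_fluct_spatial_contrast` adds a fixed anatomical large-scale
  pattern on top. Two modelling points matter here:
  (i) the spatial pattern is *fixed per preparation* — a per-trial random
  pattern times a per-trial random amplitude would make trial noise a
  product of Gaussians (heavy-tailed), which silently mis-calibrates any
  t-based map and does not correspond to the physics; (ii) per-frame
  renormalisation of `m` must stay linear in the underlying noise, or the
  evoked statistics stop being exactly Gaussian.
- Evoked response `R(x,y)`: sum of isotropic Gaussian blobs (per-condition
  foci) scaled by a saturating monotone stimulus gain
  `g(s) = s/(s+k)` in pulse count (k = 3 pulses) and current (k = 60 µA),
  normalised to 1 at the reference stimulus (5 pulses, 100 µA). The
  temporal envelope `s(t)` is a rectangle starting `latency` (0.5 s)
  after onset and lasting `duration` (1.0 s, a typical transient for this
  reporter at these stimuli); all temporal parameters are floored to
  whole frames.
- `ε`: additive Gaussian noise per pixel per frame (`shot_noise_sd`).
  Gaussian rather than Poisson keeps the t-test assumptions exact and
  matches the high-count regime of cooled-CCD widefield imaging.

Ground truth (`SyntheticTruth`) records, per condition, the pixels whose
noiseless peak ΔF/F reaches half the blob peak (the half-maximum disc,
area `2π ln2 σ²`), the blob centres, and per-trial realized amplitudes.

The generator does **not** model optics (PSF), hemodynamic absorption
signals, movement, or respiration-locked modulation of the baseline.
Consequently, passing tests demonstrate the correctness and calibration of
the analysis chain under its own statistical assumptions — not robustness
to those real-data nuisances.

The sequence generator emits gap-free aligned pairs: each column matches
with the background probability except inside planted blocks; consensus
motif instances are written into the reference with an exact substitution
count. Gapped alignments are fully supported by the analysis side and are
exercised with hand-built and randomly gapped fixtures.

## Mapping chain

- **Bleach correction** subtracts the frame-wise mean of the blank trials
  and adds back the blank grand mean, so the corrected baseline is flat in
  time but stays positive for the subsequent ratio. Correcting the blank
  trials with their own mean introduces a small negative within-group
  correlation, but both the group-mean difference and the per-group sample
  variances are unchanged in expectation, so the downstream t-test remains
  calibrated (verified empirically by the type-I acceptance test).
- **Windowed ΔF/F** uses floor(start·rate)/ceil(end·rate) half-open frame
  windows — deterministic, and never drops a partially covered frame at
  the window end. Pixels with non-positive baseline are zeroed and
  flagged rather than propagating infinities.
- **Band-pass**: the two cutoffs are interpreted as frequency-domain
  Gaussian standard deviations in cycles/mm, composed multiplicatively
  (`H = lowpass(σ_hi) · highpass(σ_lo)`), which keeps `H ∈ [0,1]` and
  `H(0) = 0`. Images are mean-padded to the next power of two per
  dimension before the FFT and cropped back, suppressing wrap-around
  artefacts; the filter is linear and removes the DC component, so
  filtered images have mean ≈ 0. On a pure sinusoid of frequency f the
  output amplitude equals the input times `H(f)` to better than 1%
  (exact when the period divides the padded grid).
- **Pixel t-test**: pooled-variance Student t with df = n₁+n₂−2 by
  default, matching the balanced 10-vs-10 design; Welch is available as a
  switch. Degenerate pixels (zero variance in both groups) get p = 1 when
  the means agree and p = 0 otherwise. No multiple-testing correction is
  applied, matching the original significance criterion; the map is a
  per-pixel error-rate statement, not a family-wise one.

An important property verified by simulation: *without* the band-pass,
the per-trial global fluctuation inflates every pixel's across-trial
variance and the t-test becomes conservative (empirical type-I ≈ 0.005 at
nominal 0.01); with the filter applied identically to stimulus and blank
trials the chain is calibrated (≈ 0.0097, inside the binomial 99% band of
0.01 for 50 desk-scale experiments).

## Quantification

- Time courses divide the binned ROI-mean fluorescence by the pre-onset
  ROI baseline mean (bins floored to whole frames; trailing partial bins
  dropped).
- Stimulus–response curves take the per-trial maximum of post-onset bins
  and report mean ± SE per parameter value.
- Subregions are rectangular quadrants from one anterior–posterior column
  split and one dorsal–ventral row split. The anatomical boundaries of
  the real piriform subdivisions are not reproducible from first
  principles, so the splits are explicit configuration inputs (image
  centre by default).
- The clustering feature vector is the 8-element subregion summary
  (4 subregion ΔF/F means + 4 significant-pixel fractions). The fraction
  entries (0–1) dominate the ΔF/F entries (~0.05) in the Euclidean
  metric, which matches what the published figure plots (significantly
  responsive area per subregion). Distances are Euclidean; linkage is
  average (UPGMA) by default with single/complete as switches; the
  within- versus between-condition comparison uses a two-sample t-test on
  pair distances with a label-permutation alternative. The published
  absolute linkage distances depend on the unavailable raw recordings and
  are deliberately not targets; the package reproduces the qualitative
  structure (within ≪ between, top split separates conditions).
- Expression rates are positive/total counts with percentages rounded to
  the nearest integer. The packaged per-line table is a synthetic
  reconstruction: the per-construct aggregates match the published
  summary exactly, but individual row assignments are arbitrary.

## Enhancer scan

Window identity is anchored on reference bases: a window is 100
consecutive reference bases; partner gaps opposite reference bases count
as mismatches; partner insertions (reference gaps) are skipped, so window
width is always defined in reference bp, as VISTA-style plots draw it.
Whether the original tool counts alignment columns or reference bases is
not documented; the reference-base convention is this package's fixed,
documented choice. Windows slide by one reference base. `N` never
matches anything.

Conserved elements are maximal unions of windows with identity *strictly*
above the threshold (80%), kept at width ≥ 100 bp; coordinates are
1-based closed internally and converted to 0-based half-open BED on
output. Element calling is idempotent and yields disjoint, sorted
intervals.

The motif scan is consensus-plus-Hamming-distance (`TCACACCT`, ≤1
substitution, both strands); position-weight-matrix scoring is out of
scope because the commercial matrix library is proprietary. Minus-strand
hits are reported at their forward-strand start coordinate with the
matched substring read on the minus strand.

The upstream-extraction helper uses TSS-relative coordinates with −1 the
base immediately 5′ of the TSS and closed intervals; the published MCE
coordinate range (−3462…−3045) spans 418 bp while the element is called
"307 bp" in the text — the package takes coordinates as explicit inputs
and does not attempt to resolve that inconsistency.

## Numerical and testing choices

- All generators are bit-deterministic under a fixed seed; experiment
  generation derives per-trial seeds from a single seed via one RNG draw.
- Simulation-based checks run at 84×64 px with 25 frames (5 s at 5 Hz,
  onset at 2 s) and 10 trials per group. The type-I check uses 50
  experiments and a binomial 99% acceptance band around 0.01; the focus
  recovery check uses 10 seeds and asserts per-seed mask centroids within
  2 px plus a seed-mean Jaccard ≥ 0.5 against the half-maximum disc (the
  significance boundary sits at the detection limit by construction —
  the planted peak is 5× the per-trial noise SD — so per-seed Jaccard
  fluctuates around the bound while the centroid is stable).
- Oracle tests re-derive windowed identity, motif hits and the pooled t
  statistic by direct enumeration/textbook arithmetic and require exact
  (1e-10 relative) agreement with the vectorised implementations.

## Known limitations

- Rectangular response time course and deterministic trial amplitude; no
  adaptation, trial-to-trial gain variability, or onset jitter.
- Bleach correction assumes stimulus and blank trials share the bleaching
  curve (true by construction here; approximately true in practice).
- The mean-padded FFT leaves small edge transients for structure touching
  the border; foci are assumed to lie inside the field.
- The significance map controls the per-pixel error rate only; the
  `correction='bonferroni'`/`'fdr_bh'` options on `pixel_ttest` give
  family-wise/FDR control, but deviate from the original criterion and
  are off by default.
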