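# Methods

This note documents the generative model behind the synthetic assay, the
analysis conventions that must be fixed for results to be reproducible, the
numerical choices in the estimators, and the known limitations.

## The synthetic cohort model

**Study design.** A cohort is a set of experimental groups (constructs), each
with `n_neurons_per_group` neurons distributed over wells of
`neurons_per_well` (default 40) on 512×512 frames, imaged at 10 timepoints
spaced 24 h apart (frame k, 0-based, is acquired at 24·(k+1) h
post-transfection). Each group is parameterized by an aggregate probability,
a per-interval baseline death hazard, and an aggregate hazard multiplier.

**Death process.** Death is generated in discrete 24 h intervals as a
geometric process matched to the imaging cadence: a neuron with aggregate
flag *a* in group *g* dies in interval *k* ∈ {1, 2, …} with per-interval
hazard h = h_g · (m_g if *a* else 1), truncated to censoring after interval
10. Continuous-time generation would add nothing observable at a 24 h
sampling grid. The constraint h_g · m_g < 1 is enforced at configuration
time. A neuron dying in interval 1 is never imaged alive; it exists in the
ground truth but is invisible to the tracker, matching the analysis
convention that only neurons present at timepoint 1 are analyzed. Hazards
are memoryless, so conditioning on timepoint-1 survival does not distort
downstream hazard ratios; it does slightly deplete the aggregate-bearing
fraction whenever m_g > 1 (faster-dying aggregated neurons are less likely
to reach the first frame). At the default h = 0.03, m = 2 this depletion is
under one percentage point.

**Aggregation.** Aggregate status is planted as a static pre-existing
property, present from the first frame: the assay gives no information about
inclusion onset times, and a time-varying onset model would be pure
invention. The alternative is recorded as a limitation below.

**Rendering.** The tracking channel draws each live soma as a filled disc
(radius ~ N(6, 0.8²) px, clipped to [4, mean+3sd]) of uniform intensity; the
reporter channel draws diffuse neurons as uniform discs and aggregated
neurons with `aggregate_flux_fraction` (default 0.6) of the *same total
flux* concentrated into 1–3 Gaussian puncta (σ = 0.16 soma radii, centers
within 0.55 radii of the soma center, flux split equally and renormalized
over the in-soma pixel grid, so flux conservation between phenotypes is
exact before noise). Per-neuron brightness is lognormal (log-sd 0.3 reporter,
0.2 tracking); mean-1 multiplicative per-pixel texture (CV 0.25 reporter,
0.08 tracking) emulates intracellular heterogeneity and gives diffuse ROIs a
realistic nonzero CV (~0.3). Each frame adds a constant background
(20 DN), Poisson shot noise (`photon_scale` = 1 expected count per DN;
`None` disables shot noise for noise-free fixtures), Gaussian read noise
(sd 2 DN), and 16-bit quantization. Dead neurons emit nothing from their
death interval on — the simplest model consistent with death calling by
signal loss; no fragmentation or debris is modeled. Per-interval centroid
drift is N(0, 2²) px per axis; initial placement keeps ≥ 4 mean soma radii
between centers (so somata never merge by construction) and reserves an edge
margin of one max radius plus six random-walk standard deviations, making
escape from the frame (an error) negligible.

**Calibration contract.** The defaults above were calibrated once so that
the synthetic assay reproduces the structure the CV rule assumes: diffuse
ROI CVs fall well below 1.0 (~0.25–0.4), aggregated ROI CVs above
(~0.9–2.6, lowest for three-puncta somata), and the class crossover — hence
the Youden-optimal threshold on a 50+50 labeled set — lands near CV = 1.0.
The punctum width (0.16 soma radii) is the parameter that sets the crossover
and was chosen for that centering; it was frozen before the acceptance seeds
were chosen and is not adjusted per run.

**Determinism.** All randomness flows from one integer seed through named
CRC32-keyed substreams (`cohort:<group>`, `well:<well>`, `render:<well>`,
`labeled_roiset`), so identical config + seed gives bit-identical tables and
movies, and stages can be re-run independently.

## Imaging analysis conventions

- **Background subtraction** is the scalar frame median, clipped at zero:
  robust for sparse bright objects and free of rolling-ball parameters.
- **Segmentation** runs on the *tracking* channel (so the ROI pixel set is
  independent of reporter distribution): connected components
  (8-connectivity) above max(Otsu threshold, 4 robust noise sigmas), kept if
  30 ≤ area ≤ 600 px. The noise floor, estimated from the 84.13th percentile
  of the clipped background (the half-normal quantile equal to σ), prevents
  Otsu from hallucinating objects on blank frames. Reporter statistics are
  measured over the same pixel set. Touching somata merge into one component;
  this is documented behaviour.
- **CV** uses the population (divide-by-N) standard deviation. This choice
  must be fixed — and is, prominently — for the CV = 1.0 threshold to be
  reproducible. CV is undefined (and the ROI unusable) when the
  background-subtracted mean is non-positive or the ROI has < 2 pixels.
- **Linking** is greedy mutual-nearest-neighbour between consecutive frames
  with a 15 px displacement gate (≈ 5× the per-interval drift sd), ties
  broken by smaller distance then smaller ROI id. Only timepoint-1 ROIs seed
  tracks; there is no gap closing. Global assignment would add complexity
  without benefit at these densities.
- **Death calling**: first timepoint with the ROI absent, or present at
  < 0.2× the neuron's timepoint-1 tracking intensity; otherwise censored at
  timepoint 10. The intensity criterion is a stated convention of this
  package, not a published rule.
- **Classification**: ROI call is CV ≥ threshold (boundary counts as
  aggregated — a fixed convention chosen for bit-reproducible calls);
  neuron call is "aggregated at ANY live timepoint". The operating threshold
  is 1.0; the ROC/Youden machinery (ties toward the larger, more specific,
  threshold) validates it rather than replacing it, unless
  `use_calibrated_threshold` is set.

## Survival analysis

Records carry time in hours on the {24, …, 240} grid, an event flag, and
binary covariates (group indicators against an explicit reference group;
aggregate status). Deaths observed on the grid are treated as exact
right-censorable event times, the established practice for this assay
family, not interval-censored.

Kaplan–Meier is the standard product-limit estimator; cumulative risk is
1 − Ŝ(t); deaths at a time are counted against the full at-risk set there.

The Cox partial likelihood uses the **Efron** tie correction by default:
with ~10 distinct event times, ties are pervasive and the correction is
material; Breslow is available and coincides with Efron exactly on untied
data (tested). Newton–Raphson starts at β = 0 with step halving; convergence
at max|score| < 1e-8 or step norm < 1e-10; covariance is the inverse
observed information at β̂; Wald z = β̂/SE with two-sided normal p; LR
statistic 2ΔlogPL against a χ² on Δdf; CIs are 95% normal on the log-HR
scale. A coefficient passing |β| > 15 (hazard ratio ≈ 3×10⁶) is diagnosed as
a monotone likelihood — perfect separation drives the score below tolerance
while β still grows — and raises a flagged convergence error rather than
returning a silently meaningless estimate.

For generative-model oracles, the planted log hazard ratio of two geometric
per-interval hazards (h₁, h₂) is defined on the complementary-log-log scale,
β = log(log(1−h₂)/log(1−h₁)): this is the exact continuous-time
proportional-hazards coefficient whose 24 h grouping produces those
geometric hazards. At the default conditions Efron estimation recovers it
with negligible bias (simulated coverage of the 95% Wald CI ≈ 94% over 200
replicates at n = 500/group).

Aggregate status enters the stratified model as a static baseline covariate.
Because a neuron must live long enough to display an aggregate, this design
carries an immortal-time caveat, which the pipeline report states
explicitly.

## Colocalization

Pearson's r and Manders' coefficients are computed over masked pixels of
background-subtracted channel pairs with explicit thresholds (default 0).
Intensity-weighted M1 = ΣA over {B > t_B} / ΣA (M2 symmetric) and the
pixel-count M2 variant |{A > t_A and B > t_B}| / |{B > t_B}| are reported
side by side, since both readings of "M2" are in circulation. Costes
automatic thresholding, randomization tests and object-based methods are
out of scope.

## Problem sizes and what the tests show

The validation harness uses a 50 + 50 labeled ROI set for the classifier
operating point, a ≥1000-neuron diffuse-only control cohort and
2500/1500-neuron planted cohorts (48.5% / 25.0%) for end-to-end fraction
recovery, 200 seeded replicates at n = 500/group for CI coverage, and 1000
replicates at n = 150/group for the Wald test's type-I error. These sizes
give binomial/sampling errors comfortably inside the tolerances being
checked while keeping a full run to minutes on one CPU.

Passing tests demonstrate that the pipeline recovers exactly the structure
the generator plants. Real movies differ in ways the generator deliberately
omits: neurite morphology and non-disc somata, focus drift and illumination
gradients, media-change artifacts, debris and fragmentation after death,
aggregate *formation* during the imaging window, and optics beyond Gaussian
puncta. Results on synthetic cohorts bound what the algorithms can do under
the stated model; they do not certify performance on real data.

## Known limitations

- Aggregate onset is not modeled; neuron-level status is effectively
  "ever-aggregated", and the stratified hazard ratios inherit the
  immortal-time caveat.
- The death criterion (signal loss / 0.2× intensity collapse) is a package
  convention; other implementations may call death from morphology.
- Merged ROIs from neurons drifting into contact are segmented as one
  object and can truncate a track; at default densities this affects well
  under 1% of neurons.
- The Youden threshold is reported from a finite labeled set and varies by
  roughly ±0.05 across seeds at n = 50/class.
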