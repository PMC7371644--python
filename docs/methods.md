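# Methods

`gliaflow` re-implements, as a reusable and fully tested package, a
flow-cytometry analysis workflow for rat microglial activation after focal
traumatic brain injury (controlled cortical impact, CCI): hierarchical gating
to isolate microglia, bead-based absolute quantification, event-level
differential marker statistics, differential inter-marker correlation,
classifier-based group discrimination, and tSNE visualization. Because raw
acquisition files for this kind of study are rarely redistributable, the
package ships a synthetic-cohort generator with ground truth so that every
downstream stage is testable end to end.

## Data model and scales

Each sample is an events x channels matrix (`EventTable`) with an explicit,
forward-only transform state: raw -> compensated -> transformed. Spillover
compensation inverts the linear mixing `observed = S @ true` per event
(scatter untouched; negative compensated values retained, since clipping
biases intensity summaries). Analysis intensities are arcsinh-transformed,
`x -> asinh(x / cofactor)` with a default cofactor of 150 — the community
convention for conventional (non-mass) cytometers — while scatter channels
stay linear. All statistical outputs carry a scale annotation, because
upstream acquisition software differs in whether exported values are
compensated-linear or display-transformed.

FCS input/output is a minimal, self-contained implementation of list-mode
FCS 3.0/3.1 (read, `$DATATYPE` F/D, both byte orders; write 3.1
single-precision float). `$PnS` stain names are preferred over `$PnN`
detector names as canonical channel labels. CSV interchange is one row per
event with a mandatory header.

## Synthetic cohorts

The generator emulates a CD11b/c-enriched single-cell suspension from one
brain hemisphere: debris, doublet aggregates, dead cells, resident microglia,
other live myeloid cells ("infiltrate"), and counting beads.

* **Intensity model.** Each singlet population is multivariate normal on the
  arcsinh scale (a Gaussian copula with normal marginals, so injected
  inter-marker correlations are exact by construction), inverse-transformed
  to raw intensities; scatter channels are linear-scale normals. FSC-H is
  derived from FSC-A through a pulse-ratio model (ratio ~ N(0.97, 0.02) for
  singlets), and doublets are raw-scale sums of two random singlet events in
  which FSC-A adds but FSC-H keeps the larger pulse height — reproducing the
  FSC-A-vs-FSC-H exclusion geometry.
* **Study design.** The default cohort is 3 animals per group (sham / CCI),
  both hemispheres, both staining panels, 10,000 cell-stream events per
  sample (the acquisition minimum of this kind of study), 1,000 counting
  beads added and fully recovered (bead quantity per tube is an acquisition
  convention, not a published fact; the recovery fraction is a parameter),
  and 50 mg nominal tissue mass.
* **Baseline mixture.** debris 25%, doublets 6%, dead 14%, microglia 5%,
  infiltrate 50%. Microglia are a small minority at baseline; the injured
  ipsilateral hemisphere multiplies their fraction by 16, with the other
  populations rescaled so the total stays 1 — under this convention the
  realized microglia event-count ratio equals the multiplier exactly at fixed
  acquisition depth, which is what the bead-based fold-change readout
  measures.
* **Injury effects** (injured ipsilateral vs everything else): scatter up
  (FSC-A +3e4, SSC-A +2e4 raw units on microglia), CD45 +0.25 and
  CD11b/c +0.25, P2y12 -0.30, CD32 +0.40, CD86 -0.25, RT1B -0.25,
  CD163 +0.30 (arcsinh units), CD200R unchanged; pairwise inter-marker
  correlation among microglia rises from 0.10 to 0.45. Marker-shift
  magnitudes were calibrated once, by a normal-theory Mahalanobis
  calculation, so that a linear classifier on panel markers lands in the
  0.75-0.90 AUC band (with marker scale 0.5 the standardized shifts are
  0.5-0.8 sigma; the pooled-covariance Mahalanobis distance is ~1.5, giving
  a theoretical AUC near 0.86).
* **Contralateral hemisphere.** Modelled as null by default. The original
  study reports mild contralateral changes, but a null contralateral default
  makes the near-random contralateral discrimination reproducible and doubles
  as a built-in negative control; contralateral effects are fully
  configurable.
* **Animal intercepts.** Each animal carries a lognormal random intercept on
  population locations (additive on the arcsinh scale, multiplicative on
  linear scatter), shared by its hemispheres and panels. The default sigma is
  0.005 — deliberately small. With the default event-pooled statistical unit
  (below), animal-level variance inflates the Mann-Whitney z statistic by a
  factor that grows with pooled event count; at the cohort's pooled sizes
  (1.5k-25k events per condition) a sigma of 0.05 would make a truly
  unchanged marker "significant" in a large fraction of runs. The default
  keeps that inflation below ~0.3 z-units, i.e. negligible against
  event-level sampling error. Users who want realistic between-animal
  biology should raise `animal_sigma` and switch the tests to the
  animal-level unit.
* **Ground truth.** Every sample is emitted with a manifest of per-event
  population labels and realized counts, which tests use as the oracle.

What the generator does **not** emulate: instrument-noise physics (photon
statistics, baseline restoration), autofluorescence and spectral spillover
(generated samples are born compensated), tissue-dissociation yield
variation, non-Gaussian marker distributions (e.g. bimodal activation
subpopulations), or time-drift within an acquisition. Passing tests
therefore demonstrate the correctness and calibration of the analysis
machinery under a controlled model of the data, not robustness to every
artifact of real acquisitions.

## Gating

The strategy is a rooted tree; each node's population is its parent's
population intersected with the node's gate, so child-subset-of-parent holds
by construction and is asserted on every run. The default tree is
`beads | cells -> singlets -> live -> CD45+ -> CD11b/c+ -> microglia`:

* main cell population: rectangle on FSC-A x SSC-A (default FSC-A in
  [3e4, 4.5e5]), excluding low-scatter debris;
* singlets: FSC-H/FSC-A pulse ratio in [0.75, 1.10]; non-positive FSC-A
  excluded;
* live: viability dye strictly below a threshold placed at the KDE valley
  between the live and dead modes, falling back to a configured value
  (logged) when the dye distribution is unimodal;
* microglia: CD45, CD11b/c and P2y12 positivity with strict `>` thresholds,
  default 1.5 arcsinh units, overridable per channel.

Fixed conventions (the underlying assay publishes no gate coordinates):
strict `>` for positivity; rectangle/polygon boundaries included; polygons
use the even-odd fill rule. Counting beads in synthetic data carry a
dedicated flag channel; for real data the bead gate is a configurable region
on an instrument-specific channel pair.

Absolute quantification uses the bead ratio,
`cells_per_mg = events * (beads_added / bead_events) / tissue_mass_mg`,
and the injury enrichment readout is the fold change of the injured
ipsilateral count over the mean of the other three conditions.

## Statistics

* **Statistical unit.** By default, events are pooled across animals within a
  condition and cells are treated as independent observations. This mirrors
  how event-level cytometry bioinformatics is usually done, and it
  pseudoreplicates the n = 3 biological design: with animal-level variance
  present, event-pooled tests are anticonservative. An animal-level mode
  (tests on per-animal MFIs) is provided and clearly labelled; with three
  animals per group it has very little power.
* **Marker screen.** Mann-Whitney U per parameter (FSC and SSC are screened
  alongside the markers) for injured-vs-sham within each hemisphere, with
  Benjamini-Hochberg control at 0.05 within each comparison family. U uses
  midranks; p is exact by enumeration when min(n) <= 8 with no ties,
  otherwise normal approximation with tie and continuity correction.
  Reported p-values are floored at 1e-300. MFI defaults to the median
  (robust), with the mean available.
* **QQ curves.** Quantiles at an even probe grid i/(n+1) with linear
  interpolation; shift summaries are the median vertical displacement from
  the identity line and the signed area of that displacement integrated over
  the probe grid.
* **Differential correlation.** Pearson correlations across gated microglia
  events; the injury-vs-sham contrast per unordered marker pair is
  summarized by Cohen's q = |atanh(r1) - atanh(r2)| and tested with the
  two-sample Fisher-z normal test,
  z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3)), one-sided for
  "injury higher", BH-controlled at 0.01 across all pairs. Cohen's q is an
  effect size, not a test; the Fisher-z test is the minimal standard
  machinery consistent with reporting pairs "significantly higher" at an
  FDR. Identification markers participate in pairs. n is the pooled event
  count per condition; an animal-balanced downsampling option prevents one
  animal from dominating.
* **Discrimination.** L2-penalized logistic regression (C = 1, within-fold
  standardization), random forest (200 trees, seeded), and RBF-SVM
  (gamma = 1/(d * var), C = 1; decision values as scores) under stratified
  k-fold cross validation (default k = 10), re-split over 10 runs; AUC is
  computed by the rank formula (exactly U/(n1*n0)), reported as the mean
  and SD over run-level means. Folds are event-level, faithful to common
  practice but leaking animal identity; an animal-grouped mode would be the
  conservative alternative. Feature contributions are absolute standardized
  logistic coefficients, or permutation importance for the nonlinear models.
  The logistic model's predicted injury-class probability per cell is the
  propensity score for deviation from sham.
* **tSNE.** Markers only (scatter excluded), perplexity 30, 1,000
  iterations, PCA initialization, seed-deterministic; per-condition
  downsampling (default 5,000 events) before embedding. Maps are 2-D
  histograms (density) and per-bin channel means (masked where empty).

## Numerical and degenerate-input conventions

Non-PSD correlation targets, fraction vectors not summing to 1, singular or
ill-conditioned spillover (condition number reported), empty intensity
vectors, single-class label vectors, and infeasible perplexities are all
rejected with diagnostics. Constant pooled data in the U test yields p = 1
(logged). Zero-variance markers get undefined correlations and are excluded
from the pair screen. |r| >= 1 in the Fisher transform is an error, with an
explicit clamp option at 1 - 1e-12. BH handles NaN p-values by never
rejecting them. Classifier folds are reduced (with a warning) when a class
is smaller than k.

## Problem sizes used by the test suite and acceptance script

Simulation-backed checks run at sizes chosen to keep each check's
Monte-Carlo error several-fold smaller than its tolerance: gating recovery
and direction recovery on full default cohorts (24 samples x 10,000 events);
fold-change recovery over 10 seeds; direction recovery over 20 seeds; null
calibration of the screens over 200 (tests) / 50 (script) zero-effect
cohorts at 2,000 events per sample, with the null classifier check at 10,000
events per sample so the CV-AUC sampling SD (~0.01) is small against the
0.45-0.55 chance window; embedding separability at 1,500 events with two
populations 6 sigma apart. Zero-effect cohorts disable animal intercepts:
they calibrate the event-exchangeability assumption of the pooled tests, and
the anticonservatism introduced by animal variance is a documented property
of the event-pooled design, not a bug the null check should absorb.

## Known limitations

* The arcsinh transform is the only supported analysis scale (no
  logicle/biexponential), and compensation is applied, never estimated.
* The pooled-event statistical unit overstates confidence whenever
  between-animal variance is non-negligible; the animal-level mode is the
  honest alternative but is underpowered at n = 3.
* Default gate geometry is tuned to the generator's populations; real data
  requires per-channel threshold configuration (or the valley-finding
  policy) and a bead gate for the instrument at hand.
* The generator's effect magnitudes are a calibrated working point, not
  estimates from any particular dataset; quantities like AUC and
  significant-pair fractions on synthetic cohorts characterize the
  machinery, not any real cohort.
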