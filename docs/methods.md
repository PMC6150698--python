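# Methods

## Scope and model

`cxscreen` implements the analysis of an all-optical connectivity screen:
for each ordered cell-type pair, the presynaptic type is stimulated with
LED pulse trains (30 Hz, 2 ms pulses; 1, 5, 10, 20 or 30 pulses per train)
while the postsynaptic type's calcium signal is recorded. The experimental
unit hierarchy is experiment → run (one stimulation strength, 4 repeats of
~16 s) → repeat, with at least six flies per pair. The analysis makes no
attempt to model biophysics (indicator kinetics, opsin photocycle,
cable properties): responses are treated phenomenologically, and the
statistical question is purely whether a pair's evoked response separates
from the anatomically impossible (non-overlapping) pairs.

## Synthetic screens

The simulator generates complete screens with a planted ground-truth
connectome so every downstream stage is testable without external data.

* **Response kernel.** Each pulse contributes a difference of exponentials
  (rise τ then decay τ), summed linearly over the train; the summed kernel
  is normalised to unit peak so a class's `peak_amplitude` *is* the
  noiseless trace extremum in ΔF/F₀ units. An optional soft ceiling
  (`saturation`, tanh compression) emulates response saturation at strong
  stimulation; it is off by default.
* **Response classes.** Strong excitation (amplitude 1.5 ΔF/F₀,
  reliability 0.9), weak excitation (0.3, 0.6), inhibition (−0.8 from an
  elevated baseline of 1.0 — a dip is only visible from an excited state;
  the class validator enforces this), rebound (a positive kernel starting
  one decay τ after train offset, amplitude 0.8, reliability 0.8) and none.
  Default kinetics: rise 0.15 s, decay 1 s (2 s for inhibition) — typical
  GCaMP6m-scale transients.
* **Noise model.** White noise (sd 0.05 ΔF/F₀), a slow "brain-state"
  baseline fluctuation (random walk smoothed over 2 s, sd 0.05), an
  optional per-repeat baseline offset (`baseline_jitter_sd`) and a
  per-repeat amplitude jitter (10 %). Responses are gated per repeat by a
  Bernoulli draw at the class reliability. `state_coupling` scales the
  response amplitude with the pre-stimulus baseline offset, emulating
  brain-state-dependent responses.
* **Timing.** The sampling rate defaults to 10 Hz and the repeat to 16 s
  with stimulation at 4 s; both are free parameters (frame rate and exact
  trace length are acquisition details, not part of the method). Because a
  10 Hz grid cannot resolve a 30 Hz train, repeats are built by evaluating
  the continuous-time kernel at the sample times rather than convolving a
  discretised stimulus vector; `make_pulse_train` (which *does* discretise)
  refuses sampling rates that merge adjacent pulses.
* **Determinism.** One master seed; per-repeat generators derive from
  `SeedSequence([seed, pair, fly, protocol, repeat])`, so datasets are
  bit-identical under a fixed seed and independent of iteration order.
* **Movies.** Optionally, traces are rendered as 16-bit movies: a disk ROI
  whose intensity follows `base + gain·ΔF/F₀` over a dimmer background,
  Poisson photon noise, and a whole-run translation recorded as ground
  truth. Movies exercise the preprocessing stage; they contain no
  within-run motion, matching the assumption that only run-to-run drift is
  corrected.

What passing tests on these screens do **not** show: robustness to
non-rigid motion, bleaching, neuropil contamination, overlapping expression
of actuator and indicator, or non-stationary noise — none of which the
generator emulates.

## Preprocessing

Registration estimates the translation between run-average images and a
reference (the first run's average) by phase cross-correlation with
Fourier upsampling (default factor 10, i.e. 0.1 px resolution); shifts
larger than 25 % of the frame trigger a warning. The experiment-wide ROI is
the higher-mean cluster of a 2-means split of the overall mean image;
centroids are initialised at the intensity extremes, making the clustering
deterministic. The ΔF/F₀ definition follows the quotient
(F − F₀)/(F₀ − B); F₀ ≤ B is an error. Two published ambiguities are
resolved as configurable defaults: the "intensity of the dimmest 10 % of
pixels" is their **mean** (median available), and frames are ranked for the
F₀ quantile by their **mean ROI fluorescence** (F₀ is defined in the ROI).
With fewer than ~34 frames the 3 % dim-frame set is empty; the dimmest
single frame is used and a warning emitted. ROI, B and F₀ are computed once
per experiment and reused for every run.

## Statistics

The peak is the post-onset sample with the largest |deviation| from
F_base (the pre-onset mean), sign preserved — required so inhibition shows
up as a negative excursion and a negative integral. τ½ is measured
relative to F_base and is *undefined* (excluded from medians, not
zero-filled) when the trace never re-crosses half-peak. Integration uses
the trapezoidal rule on the uniform grid. Normalised statistics divide by
max(F_base, 0.05): F_base can legitimately sit at ~0 because F₀ is a dim
quantile, and the floor (configurable) prevents division blow-ups; a
per-repeat flag records when it binds. Correlations are Pearson
throughout; traces with zero variance are excluded, and a correlation with
fewer than two usable traces is undefined. R_state uses one point per fly
(the run-level medians of ItoPeak and F_base). The [−1, 1] scaling divides
positive values by the batch maximum and negative values by |batch
minimum|, independently for each of the four integral statistics; it is
idempotent once the extrema sit at ±1.

## Anatomical overlap

Type descriptions are parsed by a small grammar: hyphen-separated region
tokens (hyphens inside numeric ranges such as `G2-9` are kept), `.s` spiny
/ `.b` bouton polarity suffixes, `.`-chained region lists, and variant
modifiers (`Type1`, `contra`). Suffix-less tokens inherit the nearest
following polarity, or mixed polarity if none follows. PB glomerulus
ranges expand to sets; overlap is evaluated at glomerulus (PB), layer (FB)
and individual-nodulus (NO) resolution, with laterality markers ignored.
Elsewhere an unqualified region token matches any qualified one — the
permissive default; in particular the three-zone LAL subdivision used for
the original labelling is not public, so an undivided `LAL` token counts
any LAL–LAL contact as overlap (zone tokens `LAL1..3` are accepted when a
user supplies them). Names with internal micro-structure the grammar does
not cover (the Δ7 interneuron, ring neurons, a Gall-surround type and one
multi-neuropil type) are registered as curated special cases and can be
overridden. Overlap is directional (pre boutons vs post spines), and the
catalog of the screen's 37 driver lines / 24 type descriptions ships with
the package.

## Inference

The null model is a minimum-covariance-determinant (MCD) location/scatter
fit of the non-overlapping pairs' feature points (support fraction 0.75,
fixed internal seed, consistency-corrected and reweighted); at least five
null points are required and collinear null samples are rejected. The
reported strength is the **squared** quadratic form
(x − μ)ᵀ S⁻¹ (x − μ) — note that "Mahalanobis distance" conventionally
refers to its square root. Pairs with undefined reliability (a single fly)
are excluded from fitting and classification with a warning.
Classification uses the strongest (30-pulse) protocol by default.

**Bootstrap threshold.** B = 10,000 replicates (minimum 1000): each
resamples the null points with replacement and refits the robust model.
Refits use the FAST-MCD concentration step (rank by distance, keep the h
closest, recompute, iterate to convergence) warm-started from the
full-sample MCD support, with the same consistency correction and
reweighting as the full estimator — a full multi-start MCD search per
replicate adds nothing at these sample sizes and three orders of magnitude
of cost; a unit test checks the warm-started refit against the full
estimator on resamples. Two threshold estimators are implemented. The
default (`replicate_quantile`) lets each replicate contribute its own
(1 − α) quantile of its distance distribution and averages them: at
screen-sized null samples (tens of pairs) an extreme quantile is heavily
discretised, and averaging over replicates — with the refit propagating the
model's estimation noise — is what brings the realised false-positive rate
on all-null screens to the nominal α = 0.01 (verified by the calibration
test over 50 screens). The alternative (`pooled`) pools all replicate
distances and takes the pooled quantile; on small null samples the pooled
quantile collapses onto the largest observed distance and the test becomes
conservative (observed rate ≈ 0), so it is kept only for comparison. No
multiple-testing correction is applied beyond the single bootstrap
threshold.

## Problem sizes and tolerances

The packaged fixture screen uses 10 candidate pairs (4 strong excitatory,
2 inhibitory, 4 unconnected) and 20 controls at 6 flies — small enough to
run in seconds yet large enough that the null fit is stable. The
calibration study uses 50 screens of 60 null pairs with B = 1000, chosen so
the binomial interval around α is a few units wide. Closed-form checks use
the 10 Hz default grid, so time-domain assertions carry a one-sample
(0.1 s) tolerance; the chi-square-limit check at 100,000 points carries the
Monte-Carlo error of an extreme quantile (±0.15). Registration accuracy is
asserted at the 0.1 px resolution implied by upsampling factor 10.

## Known limitations

* The pre/post-drug pharmacology comparisons of such screens have no
  formal statistic here (none is defined for them); drug runs are out of
  scope.
* Overlap labels derived purely from name strings are permissive where the
  published nomenclature lacks sub-regions (LAL, Gall qualifiers); curated
  overrides are the intended escape hatch.
* The bootstrap threshold is calibrated for null samples of a few dozen
  pairs; with fewer than ~10 null pairs the quantile estimate is fragile
  and the fit precondition (≥5 points) is a hard floor, not a
  recommendation.
* Dose-response structure across stimulation strengths is simulated only
  coarsely (per-protocol kernels, optional saturation) and is not
  modelled in inference, which uses a single protocol.
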