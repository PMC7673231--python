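# Methods

This note records the models, parameter choices, and numerical decisions
behind `tonespace`, and what its synthetic validation does and does not
establish about real recordings.

## Acoustic front end

**Pitch tracking.** F0 is estimated per frame from the peak of the
mean-removed, biased autocorrelation within the lag range corresponding to
`[f0_min, f0_max]`, with parabolic interpolation of the peak lag. Frames
whose normalized peak falls below `voicing_threshold` are unvoiced. Defaults
(`PitchParams`): `f0_min` 75 Hz, `f0_max` 800 Hz — wide enough for child
voices from young children through adolescents — frame 40 ms (≥ 3 periods at
75 Hz), hop 10 ms, threshold 0.45. Input below 8·`f0_max` samples/s is
rejected rather than silently under-resolved; silent or aperiodic input
yields a contour with zero voiced frames, not an error.

**Octave-error repair.** Autocorrelation trackers occasionally report 2× or
½× the true F0. Repair is automated: a voiced frame deviating from the
running median of its 5-frame voiced neighborhood by ≥ 7 semitones is
replaced by the octave transposition (repeated ×2 or ×½) that re-enters the
threshold, or unvoiced when every such transposition leaves the search
range. Since octaves are 12 semitones apart, some transposition always lies
within 6 st of the median, so un-repairable frames occur only near the range
edges. Altered frame indices are kept on the contour as an audit trail and
surface in the feature table as `n_corrected_frames`.

**Landmarks.** Onset/offset are the first/last voiced frames; the midpoint
is the voiced frame nearest the temporal midpoint of the voiced span, with
the later frame taken on a tie (a tolerance of 10⁻⁹·span absorbs float
rounding so the tie-break is deterministic). Tokens with fewer than three
voiced frames are excluded, not imputed; exclusions are counted per subject.
No boundary-frame trimming is applied by default: synthetic validation shows
the frame-centered tracker already samples voicing edges adequately, and
trimming would discard information on very short tokens.

**Normalization.** The speaker anchor *M* is the equal-weight mean over
tone-1 tokens of each token's mean voiced F0, so long and short tokens
contribute equally (the alternative — pooling frames — would overweight
long productions; token means are the default, and the choice only matters
when token durations vary). Landmarks become `12·log₂(F0/M)` semitones.
Normalization is exactly invariant to global pitch transposition, and a
speaker's tone-1 cloud centers near 0 st by construction.

## Tone regions and overlap

A tone's region is the mean-centered ellipse/ellipsoid whose principal axes
are the sample-covariance eigenvectors with semiaxes `sd_multiplier`
(default 2.0) sample SDs — the Mahalanobis-radius-2 contour. An
axis-aligned variant is available (`orientation="axis_aligned"`) since
scatter-plot ellipses are sometimes drawn that way; covariance orientation
is the default because the axes of a scatter distribution are naturally its
principal axes. A ridge of 10⁻⁶ st² on the covariance diagonal keeps
near-degenerate clouds (e.g. a perfectly flat speaker) invertible. Regions
need at least dim+1 tokens; identical point sets are rejected as degenerate.

**Overlap.** The intersection measure Aᵢ of two regions is estimated by
uniform sampling inside the smaller region (unit-ball draws mapped
affinely) and counting the fraction inside the other, scaled by the smaller
measure — an unbiased estimator whose binomial standard error is reported.
Default 2×10⁵ samples gives relative error well under 1%, verified against
the closed-form circle-lens and sphere-lens formulas. Disjoint bounding
spheres short-circuit to an exact 0. An exact ellipse–ellipse intersection
was deliberately avoided as numerically fragile; Monte Carlo with a fixed
seed is deterministic, dimension-agnostic, and self-diagnosing. Boundary
points count as inside (≤).

## Scores

Differentiability of a contrast is `[(1 − Aᵢ/A₁) + (1 − Aᵢ/A₂)]/2`, clipped
to [0, 1] because estimator noise can push Aᵢ marginally above the smaller
measure. Regions are fitted per subject — the subject is the unit of
analysis — and contrasts whose tones lack enough tokens are undefined (NaN)
and excluded from the six-contrast average. The hit-rate confusion matrix
counts every token in every region that contains it (the definition implies
no exclusivity); defined columns sum to 1 exactly, and columns over empty
or unfittable regions are undefined and excluded from the diagonal average.

**Finite-sample bias.** With few tokens per tone, fitted regions differ by
sampling variability even when the underlying tone distributions are
identical, so differentiability under the null is well above 0 at n = 9
tokens/tone (≈ 0.33 in 2D, ≈ 0.49 in 3D in simulation) and approaches 0
only as n grows. Scores should therefore be compared at matched token
counts, and the 3D method's systematically higher scores partly reflect the
faster growth of this bias with dimension. Group contrasts (NH vs CI at
equal n) are unaffected.

## Statistics

Proportion scores are arcsine-square-root transformed before inference.
The two-way ANOVA uses Type II sums of squares by default (robust to the
mildly unbalanced NH/CI counts; Types I/III selectable) with both main
effects and the interaction, treated factorially. The repeated-measures
ANOVA reports the uncorrected and Greenhouse–Geisser-corrected p (sphericity
is rarely tenable for six contrasts) and Bonferroni-corrected paired t tests
as post hocs; a degenerate design with literally no condition effect is
reported as F = 0, p = 1 rather than a 0/0 ratio. Pearson correlations
report raw and optionally Bonferroni-adjusted p. The demographic model is
ordinary least squares of transformed scores on age at implantation,
duration of use, and their product, with intercept; chronological age is
excluded as the exact sum of the two predictors. Simulation places the
two-way ANOVA's main-effect type-I error at the nominal 5% (within
[0.03, 0.07] over 1,000 null replicates at 8 observations/cell) and shows
the OLS recovers a planted duration effect within a few percent at n = 200.

## Synthetic cohorts

A subject is a vocal-pitch anchor (reference F0 ~ U(220, 320) Hz, spanning
typical child voices), per-tone landmark templates, a flattening parameter
λ ∈ [0, 1] interpolating each template toward its own time-mean, and i.i.d.
Gaussian landmark noise. Templates (semitones re anchor): tone 1 (0, 0, 0)
high-flat; tone 2 (−4, −4.5, −1) low-rising; tone 3 (−5, −7, −3) low with a
mid dip; tone 4 (4.5, 2, −0.5) high-falling. The values encode the
canonical Mandarin contour shapes, place the tones in the four quadrants of
the onset–offset plane, make tones 2 and 3 the closest pair in both the 2D
and 3D projections (the contrast real speakers separate worst), and keep
the four template time-means mutually distinct so flattening degrades 2 vs 3
first instead of colliding other pairs.

Cohort defaults: NH λ ~ U(0, 0.1) with 1 st noise; CI λ ~ U(0.5, 0.9) with
2 st noise — flattened, variable productions — with CI λ additionally
decreasing at 0.02/year of device use (clipped to [0, 1]), so longer users
score modestly better, reproducing the direction of the reported
duration–outcome association. CI demographics: age at implantation
~ U(0.5, 8) y, duration ~ U(0.5, 9) y, chronological age their exact sum.
Each subject produces the balanced 36-word list (9 tokens per tone). The
whole cohort is a deterministic function of one seed.

Optional audio rendering drives the pitch front end end to end: each
token's F0 path is piecewise-linear through its landmarks with 20 ms
endpoint holds (half an analysis frame, so a frame-centered tracker
observes the true onset/offset), synthesized as a 1/k-weighted harmonic sum
with 10 ms cosine ramps. Landmark round trips recover truth within 0.5 st
across 85–600 Hz.

**What the generator does not emulate:** segmental/coarticulatory effects
on F0, tone sandhi, creaky voice in tone 3 (which breaks pitch tracking in
real recordings), duration and amplitude cues, age-dependent F0, and
correlated (non-i.i.d.) production errors. Passing tests therefore
establish the correctness and calibration of the measurement pipeline under
idealized production, not the clinical sensitivity of the scores on real
speech.

## Problem sizes in the shipped checks

The test suite and acceptance script use a 50 + 50 subject default cohort at
2×10⁵ Monte-Carlo samples per overlap, 1,000 null replicates at 8
observations/cell for ANOVA calibration, and n = 200 for OLS recovery —
sizes at which every stochastic check is stable across seeds while the whole
battery completes in about a minute on one CPU.

## Known limitations

- Differentiability and hit rate are biased upward at small token counts
  (see above); the package reports scores, not bias-corrected estimates.
- The Monte-Carlo overlap is exact only in expectation; at the default
  sample count the residual jitter (~0.2% relative) is far below
  between-subject variation but visible in exact-reproducibility
  comparisons across different seeds.
- The pitch tracker is a clean-speech autocorrelation tracker; it has no
  noise robustness features (no spectral subtraction, no HMM smoothing) and
  is validated on synthetic harmonic signals only.
- The two-way ANOVA treats method (2D/3D) factorially, matching common
  practice for this design; a within-subject treatment of method would
  need the mixed-model machinery deliberately left out of scope.
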