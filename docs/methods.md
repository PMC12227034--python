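# Methods

## Data model and geometry

Fixation tables carry one row per fixation (participant, trial, 1-based
order, screen-pixel x/y, duration in ms, onset in ms); trial tables carry
the metadata (emotion, presentation condition, identity, per-trial image
center, response, response time). Pixels are 0-based, origin top-left,
half-open bins: a real-valued coordinate (x, y) belongs to cell
(⌊x⌋, ⌊y⌋). The image frame places the 384 × 576 px face image's top-left
corner at (0, 0); because the image is centered on the trial's fixation
cross, screen→image is a pure per-trial translation and within-trial
distances are frame-invariant.

Angular quantities are carried as the three literal pixel constants the
analyses use — smoothing σ = 13 px (0.5°), recurrence radius 62 px (2.5°),
trigger window 30 px (1.2°) — not as a single px/° scalar, because the
three conversions imply slightly different scalars (≈24.8–26 px/°).
The tracker's minimum fixation duration (100 ms) is applied inclusively:
a fixation of exactly 100 ms is kept, since a stated minimum is attained.
The fixation that triggers stimulus onset (on the cross) is not part of
the recorded sequence, so "first fixation" is the lowest recorded index.

## Fixation density maps

Raw maps accumulate fixation durations at floor-binned cells.
Out-of-bounds fixations are excluded and counted rather than clipped —
clipping would fabricate border density. Category maps divide the
accumulated map by the number of contributing trials (each trial weighted
equally), then smooth, then z-score; the pipeline order
raw → smoothed → z-scored → marginal is enforced through a stage flag.

Smoothing is a discrete isotropic Gaussian with zero padding (the field
outside the image carries no density) and kernel radius 4σ; the kernel is
normalised, so interior mass is preserved essentially exactly.
Z-scoring uses the population SD over cells; the difference from the
sample SD is a constant factor that cancels in correlations and in argmax
decoding. Marginal maps subtract the *unweighted* cellwise mean of the K
category maps, so the marginals sum to zero at every cell; weighting the
grand mean by trial counts would let an unbalanced scope (e.g.
correct-only trials) leak category base rates into every marginal map.

Map correlations are plain Pearson correlations over all cells of two
equal-shaped maps. The within/between-category similarity contrast builds
individual-participant category maps under two scoping specifications,
averages same-category and cross-category correlations per participant,
Fisher-z-transforms both means, and compares them with a paired t-test
(one-sided, within > between, as that is the directional hypothesis).
The cross-condition table computes, per participant, one map per
(emotion, condition) and reports for each of the six condition pairs the
mean over emotions of the same-emotion correlation, averaged over
participants.

Refixation maps count revisits, not pairs and not durations: a fixation
adds 1 at its cell if *any* earlier fixation of its trial lies within the
recurrence radius, and it adds 1 only once however many earlier fixations
it recurs with.

## Gaze decoding

For each held-out participant, category marginal maps are computed from
the remaining participants only; the held-out participant's scoped trials
are scored by summing marginal-map values over fixated cells weighted by
duration, using the same floor binning as map construction so train and
test geometry are identical. Exact score ties are broken by the canonical
category order (anger, disgust, fear, surprise, sadness; unrestricted,
blindspot, neutral_blindspot, spotlight) and counted. Emotion decoding
"within a condition" filters both the training and the test trials to
that condition; correct-only/incorrect-only scoping likewise applies to
both sides. A training fold with an empty category is an error — the
decoder never silently drops a class. Training trials enter the category
average with equal weight regardless of their fixation counts.

Accuracies are compared to chance 1/K with a one-sided one-sample t-test;
Cohen's d = (mean − chance)/SD is reported with a one-sided 95% interval
(lower bound, +∞) obtained by inverting the noncentral t distribution.
If every accuracy is identical (e.g. all 1.0 on separable data) the test
is undefined; the exact accuracies are reported and the statistics are
NaN.

## Recurrence quantification

The recurrence matrix is boolean, symmetric, diagonal excluded, with an
*inclusive* distance boundary (exactly 62 px recurs). Measures follow the
eye-movement RQA toolbox conventions, counting in the upper triangle with
minimum line length 2 (exposed as a parameter): REC = 100·2R/(N(N−1));
DET = 100·|D_L|/R over diagonal runs; LAM = 100·(|H_L|+|V_L|)/(2R) over
horizontal plus vertical runs; CORM = 100·Σ(j−i)·r_ij/((N−1)·R). Trials
with fewer than two fixations are excluded; trials with R = 0 contribute
REC = 0 but no DET/LAM/CORM (missing, excluded measure-wise from cell
means). Duration plays no role. Positions are taken in the image frame,
which is translation-equivalent to the screen frame within a trial.

## Behavioral performance

Unbiased hit rates are computed per participant × condition from that
cell's 5 × 5 confusion matrix, Hu_e = n_ee²/(S_e·R_e); a response label
never used in scope yields Hu = 0 (absent evidence treated as zero
performance) rather than an undefined value. No arcsine transform is
applied before the ANOVA; the identity Hu = hit rate × precision is the
tested invariant. The RT outlier rule uses each participant's mean and SD
of *all* correct-trial RTs across conditions (not per-condition) and
removes correct trials beyond 5 SD; the rule is not formally idempotent,
but at realistic RT scales a second pass removes nothing. The response
bias test is a Pearson goodness-of-fit of label-usage counts against a
uniform expectation, df = K − 1.

## Inference

Repeated-measures ANOVA is implemented on per-subject cell means (one or
two within factors, replicates averaged, participants with missing cells
excluded listwise). Greenhouse–Geisser ε comes from the covariance of
orthonormally contrast-transformed scores (Helmert contrasts; Kronecker
products for the interaction); Mauchly's W uses the standard χ²
approximation. Both corrected and uncorrected p-values are emitted; the
*reported* p applies the GG correction only where Mauchly's p < 0.05,
which is the study's stated rule. The implementation is cross-checked in
the test suite against pingouin (F, partial η², main-effect ε, Mauchly W);
pingouin is a test-only dependency.

Effect-size confidence intervals for t-tests invert the noncentral t
distribution (the upper-tail probability of the observed t is monotone in
the noncentrality). The Wilcoxon fallback reports the matched rank-biserial
correlation r_rb = (T⁺ − T⁻)/(T⁺ + T⁻) with a normal-approximation CI on
the signed-rank statistic, labelled as such — exact conventions for this
interval vary across packages. The normality gate routes to Wilcoxon when
a Shapiro–Wilk test (delegated to scipy) has p < 0.05.

The sensitivity solver bisects on d for the exact noncentral-t power of a
one-sample/paired t-test (both tails included for two-tailed tests) to
tolerance 1e-6. At n = 35, α = 0.05, power = 0.80, two-tailed, it yields
d = 0.4875; the analogous one-tailed computation yields 0.4289. A paired
design on difference scores is formally identical with n = number of
pairs.

## Synthetic scanpath generator

The generator emulates the study's structure, not its stimuli: no face
images are rendered and no saccade kinematics or gaze-contingent display
is simulated. Defaults follow the experimental design (35 participants,
12 identities × 5 emotions × 4 conditions = 240 trials each; image
centers jittered over the 25 cross locations at 0/±25/±50 px per axis).
Where the design prescribes no value, defaults are fixed at plausible
free-viewing magnitudes and are configuration-exposed, not hard-coded:
5–12 fixations per 3-s trial, log-normal durations (median 250 ms,
σ_log 0.35), hotspot SD 18 px, center-bias weight 0.15 with SD 55 px, a
first fixation just above-left of the face center (offset (−10, −20) px,
SD 8 px).

Hotspot draws are isotropic Gaussians truncated to the image by redraw,
keeping all synthetic fixations in bounds and mass accounting simple.
Refixations copy a previously generated fixation plus a uniform-disk
jitter of at most half the recurrence radius, so REC is directly
steerable by the per-condition refixation probability (defaults 0.45 /
0.45 / 0.43 / 0.30, spotlight suppressed; spotlight lags are drawn
recent-biased, the rest uniform, steering CORM). Response rows follow the
qualitative confusion structure of five-way emotion classification —
disgust→anger and fear→surprise inflated, spotlight markedly less
accurate — without asserting any particular study's exact rates.
Response times are slower in the spotlight condition and for
fear/surprise/disgust, with participant- and trial-level noise.

Each participant consumes an RNG stream keyed by (master seed,
participant index), so per-participant data are byte-stable under changes
to `n_participants`. Degenerate factory configurations support the
validation suite: a *disjoint-hotspot* configuration (one-hot mixtures on
five distinct landmarks, zero hotspot/first-fixation noise, no
refixation process) on which leave-one-subject-out decoding provably
reaches accuracy 1.0; a *category-free* configuration (all emotions share
one mixture) under which decoding must fall to chance and
within-/between-emotion similarity becomes exchangeable; and a
*spotlight-divergent* configuration whose spotlight maps come from a
distinct mouth-dominated mixture.

What passing tests on these data do **not** show: real scanpaths have
serial dependencies (saccade-amplitude statistics, drift, anticipatory
re-fixation), idiosyncratic per-observer biases that persist across
categories, and calibration error; none of these are modelled, so the
suite validates the *pipeline arithmetic and its discriminative
machinery*, not claims about human gaze.

## Numerical choices and edge cases

- Constant maps cannot be z-scored or correlated (degenerate-map errors);
  empty fixation selections yield zero maps with a logged count, not
  errors.
- Score ties in decoding, zero-variance accuracy vectors, participants
  with no scoped trials, and participants lacking a category in a
  similarity spec are all surfaced (tie counts, NaN statistics with
  warnings, documented drops) rather than silently absorbed.
- Problem sizes in the test suite are scaled to the property being
  demonstrated: decoding properties run at 10 participants × 60 trials,
  similarity recovery at 8 participants × 80 trials over 20 seeds — sizes
  at which the tested effects are decisive under the generator's default
  conditions.
- The analysis drivers run at the full design size (35 × 240).

## Known limitations

- The rank-biserial CI is a normal approximation, not an exact or
  bootstrap interval.
- Mauchly's p can differ in the third decimal from other packages that
  use slightly different χ² correction constants; W itself agrees to
  machine precision.
- `rm_anova` handles at most two within factors and no between factors.
- The generator's refixation copies earlier fixations verbatim (plus
  jitter); it does not model memory decay or inhibition of return.
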