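# Methods

`affectstates` implements a complete analysis of picture-induced affective
brain states, exercised end to end on synthetic data with planted ground
truth. This note describes the model behind each stage, the parameters
that matter, what the synthetic generator does and does not emulate, and
the numerical and design choices a maintainer would want to know.

## The underlying model

The working hypothesis is a one-to-one mapping between each picture
stimulus and a temporally succinct, spatially distributed neural
activation pattern (a *brain state*) that simultaneously encodes the
stimulus's dimensional affect — valence v and arousal a, normed on a
9-point Likert scale — and its autonomic consequence, the skin-conductance
response (SCR). Binary affect labels are the normative means thresholded
against the scale midpoint: label = +1 if mean > 5, else −1 (an exact 5.0
maps to −1 by convention; the synthetic pool never produces exact 5.0, so
labels are never ambiguous).

The generative model used throughout the synthetic data is linear:

    beta_t = P_v * s_v(t) + P_a * s_a(t) + noise_t

where `P_v`, `P_a` are unit-norm, mutually orthogonal voxel patterns
shared by all subjects of one study, and the per-trial amplitudes
`s_v, s_a` are either centred normative scores (`gain * (score − 5)`,
"continuous" mode) or signed constants (`±amp`, "signed" mode — the mode
in which a target discriminability d′ = 2·amp/σ can be planted exactly,
giving a closed-form oracle accuracy Φ(d′/2) for the ideal linear
discriminant). An optional *incongruent* subset of stimuli has the sign of
its amplitudes flipped: the induced state contradicts the normative label,
the mechanism the unreliable-stimulus-set analysis is designed to detect.

## Stimulus pool and selection

`gen_stimulus_pool` draws valence means uniformly on [1, 9] and arousal
means as `3.1 + 1.3·coupling·|v − 5|` plus unit-ish scatter (SD 1.1),
clipped to [1, 9] — the "boomerang" coupling of normed affective picture
sets, in which arousal rises with valence extremity. The coupling strength
is exposed as a parameter (real normative databases do not publish one
canonical value); the default 0.5 yields a sample correlation of ≈ 0.55
between |v − 5| and arousal and roughly one third of the pool above the
arousal midpoint.

`select_max_separation` is the greedy maximum-separation heuristic: each
step adds the candidate whose summed Euclidean distance (in the
valence–arousal mean plane) to all already-selected stimuli is largest.
When no seed stimuli are given, the first pick is the stimulus farthest
from the pool centroid; all ties break toward the smallest stimulus id, so
selection is fully deterministic. The default study draws 120 stimuli: the
first 90 presented in the *extrinsic* format (2-s passive viewing, the
analysed condition), the next 30 in the *intrinsic* format (2 s image +
2 s cue + 10 s volitional re-experiencing); intrinsic trials enter the
design and trial-wise GLM only to be sub-selected away afterwards.

## Constrained design construction

Candidate designs (trial order and U(2, 6) inter-trial intervals, two
runs) are rejection-sampled until four criteria hold simultaneously:
each run begins with an extrinsic trial; no more than three consecutive
intrinsic trials; each run begins and ends with a positive-valence
stimulus; and all pairwise Pearson correlations among the four
HRF-convolved affect-category regressors stay below 0.25 (sampled at
TR = 2 s). Accepted designs carry a constraint report and are re-verified
by an independent checker. The default attempt budget is 10 000; typical
catalogs accept within ~50–300 attempts, with the accepted maximum
correlation around 0.16–0.20.

The category construction deserves a note. If the four categories are the
*marginal* label groups (positive valence, negative valence, high arousal,
low arousal), every stimulus belongs to one valence **and** one arousal
category. Shared events put a floor of roughly `n_shared/√(n_i·n_j)`
(≈ 0.2–0.6 here) under the between-property correlations for **any**
timing, and trial-density competition holds the within-property pairs
around |r| ≈ 0.3–0.4; no admissible design exists under that reading. The
criterion is therefore implemented on the four **discrete** affect
quadrants of the plane (positive/high, positive/low, negative/high,
negative/low — a partition of the stimuli, still derived purely from the
labels against the midpoint), under which the maximum pairwise correlation
of uniformly sampled candidates is ≈ 0.16–0.23: below, but near, the 0.25
threshold, i.e. a real and occasionally binding rejection criterion. The
marginal ("overlapping") and per-trial regressor variants remain available
via `category_regressors(..., mode=...)` for diagnostics.

## Trial-wise BOLD estimation (least-squares-separate)

The block HRF is a gamma variate `(t/4)^4 e^(4−t)` convolved with the 2-s
stimulation boxcar and peak-normalised; its 2-s event response peaks
~5 s after onset and is negligible beyond 25 s. For each trial, one linear
model is solved: the trial's own regressor, one aggregate regressor per
presentation format collecting all other trials, per-run Legendre drift of
degree `1 + floor(run_seconds/150)`, optional nuisance columns (e.g. a
motion model supplied as a matrix), with censored volumes dropped from the
fit. The trial's coefficient is its beta; the returned series keeps
extrinsic trials only. Rank deficiency after censoring raises rather than
returning garbage.

Least-squares-separate is exactly unbiased only when the truth lies in
each trial model's span: in practice, when trial responses do not overlap,
or when the other trials' amplitudes are homogeneous within format. With
overlapping 2–6-s-ITI designs and heterogeneous amplitudes the aggregate
regressor absorbs the other trials imperfectly and the estimate carries a
deterministic bias even at zero noise (on the order of 10–40% of the
amplitude spread at desk scale). The recovery tests therefore check
exactness on the two nested cases (widely spaced trials without shared
drift columns; overlapping trials with format-constant per-voxel
amplitudes), and the realistic overlapping + noisy path is exercised
end-to-end through the pipeline, where the LSS estimation noise simply
propagates into downstream accuracy.

## Skin conductance

Preprocessing applies, in order: a 10-ms median filter (all samples within
±10 ms of the centre); zeroing against the mean of the first 10 ms
(`ceil(fs·0.01)` samples); a first-order bi-directional Butterworth
band-pass between 0.033 and 5 Hz; downsampling to 10 Hz (polyphase
resampling — the 5-Hz edge already bounds content at the new Nyquist); and
z-scoring within run. Any input rate ≥ 20 Hz is accepted (the synthetic
default is 100 Hz). A trace that is near-constant after band-passing
cannot be z-scored; it is returned flagged degenerate and its run's trials
are excluded downstream, feeding the pipeline's excluded-data QC fraction.
Note that a first-order band-pass attenuates even the band centre by
~1.3% per (bidirectional) application, so "idempotency in the pass band"
holds only approximately.

Trial amplitudes are estimated by ordinary least squares against per-trial
regressors built from the canonical SCR shape — a bi-exponential
`e^(−t/3.0) − e^(−t/0.75)` (peak-normalised, peak latency ≈ 1.39 s; time
constants configurable, since published canonical parameterisations vary)
— convolved with onset impulses, passed through the *identical* filter
chain as the data (this accounts for filter-induced peak shifting), and
z-scored. An ill-conditioned design (onsets dense relative to the
canonical width) triggers a condition-number warning. The synthetic SCR
forward model is the same canonical shape scaled by
`scr_amp_slope · (arousal − 5)` plus slow drift (smoothed random walk) and
white measurement noise; zero-noise recovery correlates with the planted
amplitudes at r > 0.999.

## Gram-Schmidt compression

Each subject's trial patterns span at most n_trials dimensions of voxel
space. Modified Gram-Schmidt with one re-orthogonalisation pass builds an
orthonormal basis of that span in chronological trial order (relative rank
tolerance 1e−10; a dependent pattern names the offending trial in the
error). Projection onto the basis preserves all inner products, hence all
Euclidean geometry and every kernel-SVM decision value; the compression is
exactly lossless for any linear analysis. Classification is therefore run
in the 90-dimensional coordinate system, and the voxel/GS decision-value
equivalence is asserted to 1e−6 in the tests (empirically ~1e−15).

## Balanced leave-one-out classification and SCR regression

Classification is intra-subject leave-one-stimulus-out with a linear SVM
(C = 1, the toolbox-default setting). In each fold the minority class of
the remaining trials is kept whole and the majority class is uniformly
down-sampled to match, so the training set has exactly `2·N_min` trials
and chance is exactly 0.5. The whole cross-validation repeats 30 times
(library default) to average over the down-sampling; per-fold RNG streams
derive from (seed, subject, repetition, fold) so repetitions are
independent yet bit-reproducible, and trials are canonicalised by stimulus
id so results are invariant to input row order. SCR regression uses a
linear SVR (C = 1, default ε = 0.1) without balancing and is
deterministic, hence one repetition. Affective-state (AS) accuracy counts
a trial correct only when valence and arousal are both correct — chance
0.25. Group summaries are means of per-subject accuracies with a 95%
t-interval over subjects, clipped to [0, 1].

## Encodings

Decoder weights are projected to encodings via the feature covariance:
`A = Cov(X)·w / Var(w^T X)`, with covariance and score variance estimated
on the training data of the fit being transformed. Per-subject encodings
are built by fitting a balanced SVM to the full stimulus set once per
repetition, transforming each fit, and averaging the *encodings* (the mean
of the encodings, not the encoding of the mean — the order matters on
heterogeneous subjects and a regression test asserts the two differ).
Group maps take a feature into the group mask when ≥ 50% of subject masks
contain it, then compute the group mean and one-sample t per feature;
zero-variance features get an undefined-t flag and are excluded from the
thresholded map (default |t| > 2.10, clusters ≥ 20 face-adjacent voxels
when a volumetric shape is supplied; the cluster filter is skipped, with
the map untouched, for abstract feature lattices). Two studies' maps are
compared by iteratively reweighted least squares with bisquare weights
over either the joint mask or the jointly significant features.

The Haufe-recovery property holds in the regime it was designed for: when
signal and noise occupy the same spatial band (here: planted patterns
smoothed at the same correlation length as the noise), decoder weights are
pulled away from the generative pattern while the group-mean encoding
recovers it (r > 0.9 at 10 subjects, 90 trials, 150 features,
amplitude/noise = 1, correlation length 5). With white (unsmoothed)
patterns against smooth noise the opposite holds — the decoder whitens
away the noise band and the raw weights are closer to the truth — so the
generator's `spatial_corr` smooths patterns and noise alike.

## Reliable and unreliable stimulus sets

For subject i and stimulus j, the predictions of the other n−1 subjects
form a binomial experiment against chance ½; with stochastic repetitions a
subject's verdict is the strict majority vote (ties count as incorrect;
a per-repetition variant is exposed). Stimuli whose correct count reaches
the exact upper critical — smallest k with P(X ≥ k) < α, i.e. 13 at
n = 18, α = 0.05 — enter RSS_i; those at or below the lower critical (5 at
n = 18) enter USS_i; group-level sets are the intersections across
subjects. The chance simulation flips a coin with P(head) = group mean
accuracy, 19 flips per each of 90 stimuli, flags counts against the
Bin(19, ½) criticals (14/5), and repeats 1000 times to give the null
distribution of apparent subset sizes.

With 12% planted incongruent stimuli the union of the USS_i is enriched
for the planted set (hypergeometric p ≪ 0.01 at default settings) and
accuracy follows the reliable > full > unreliable ordering — the mechanism
the real-data analysis attributes its unreliable set to.

## Spatial multimodality

The dip statistic — the minimum sup-norm distance between the sample's
empirical CDF and any unimodal CDF — is computed by the
greatest-convex-minorant / least-concave-majorant modal-interval
iteration. The implementation handles ties exactly (a unimodal
distribution function may carry an atom, but only at its mode) and was
validated against a brute-force oracle that solves the defining
minimisation directly as a family of linear programs, one per candidate
mode, with the atom modelled explicitly; the oracle ships in the test
suite. Values satisfy 1/(2n) ≤ dip ≤ ¼, with dip({0, 1}) = ¼ exactly, and
are invariant to affine transforms of the projection.

The rotation scan evaluates the dip of the tested property's projection at
every plane rotation from −π/4 to π/4 in 0.01-rad steps (the exact
endpoints are included; π/2 is not a multiple of 0.01, so the closing
increment is shorter), keeping the maximising angle, ties broken toward
zero. The bootstrap draws size-matched subsets of the full stimulus set
without replacement (with-replacement exposed), projects them at the
*observed* maximising angle, and reports p as the fraction of null dips at
least as large as the observed maximum.

Because the observed statistic is angle-maximised and the null draws are
not, this construction is anti-conservative: at desk scale (subsets of
20–40 from a 90-point boomerang) null subsets yield p ≤ 0.05 in ~30% of
runs rather than 5%. The same bootstrap at a fixed projection angle is
well calibrated (~93–95% of null runs above 0.05, median p ≈ 0.5), which
is how the test suite verifies the machinery; `maximize_null=True` re-runs
the full scan on every null draw and restores calibration for the
maximised statistic at ~150× the cost. The default remains the cheaper
maximise-then-test form, with this caveat; small reported p-values from it
should be read accordingly.

Identifiability of the maximising angle requires the planted bimodality to
*decay* off-axis: with isotropic clusters the projected separation varies
as cos Δθ and the dip is nearly flat over the grid, so the recovery tests
plant anisotropic clusters (narrow along the separation axis, wide
orthogonal to it) at n = 1000, where the angle is recovered within
±0.03 rad.

## Mixed-effects effect sizes

Observed measures are regressed on predicted measures with subject-wise
random slope and intercept, estimated by maximum likelihood. Singular
random-slope fits fall back to random-intercept-only and finally to a
zero-random-effect report, always flagged, never silent. The reported
effect size is the Pearson correlation between the fixed-effect fitted
values and the observations; the t-to-r conversion `r = t/√(t² + df)` is
carried alongside. The Wald 95% interval of the fixed slope covers a
planted slope in ≥ 90% of simulations at 19 subjects × 30 observations.
The SCR median split retains observations strictly above the pooled median
(per-subject variant exposed) and recomputes the model — on synthetic data
whose signal-to-noise grows with response amplitude, the upper-half effect
size exceeds the full-set one, the mechanism behind restricting analyses
to strong responders. The set-size experiment classifies uniformly drawn
stimulus subsets at 16 fractions (25%…100% in 5% steps; class-collapsing
draws are redrawn and counted) and fits accuracy on set size with
subject-wise random effects.

## Pipeline, seeds, and problem sizes

`run_pipeline` executes simulate → design → betas/SCR → GS → MVPA →
subsets → chance simulation → dip scan → effects → encodings from one
config dict; per-stage seeds derive from the master seed by hashing
(seed, stage name), so a run is bit-reproducible and every output is
traceable to (config hash, stage seed). QC counters track excluded SCR
runs as a fraction of all runs (three excluded half-subjects of 19 × 2
runs give the reference 7.9%). Any stage failure halts with the stage
named.

Default desk-scale dimensions are 19 subjects, 90 extrinsic + 30 intrinsic
stimuli, 2000 voxels, 2 runs — the emulated study's subject and stimulus
counts at a tractable feature count. The pipeline's default data route
generates trial patterns directly (`bold_forward: false`); setting
`bold_forward: true` simulates full BOLD runs and inverts them through the
LSS stage. The test suite picks its problem sizes per question: the
compression-equivalence checks run at the full 19 × 90 × 2000; null
calibration and the incongruent-mechanism test run in the 90-dimensional
GS space with 5 LOOCV repetitions (odd, so majority votes cannot tie); the
planted-d′ oracle comparison runs at 5 features, the regime where a
~90-trial training set leaves little estimation noise and a linear SVM can
realise the Φ(d′/2) oracle (at 2000 features the same planted d′ yields
≈ 0.58 accuracy — attenuation by estimation noise, not a defect); the
mixed-model coverage check uses 40 simulations.

## What the generator does not emulate

Head motion and physiological artifacts (the pipeline accepts nuisance
matrices and censor vectors but none are simulated); realistic 3-D
anatomy and inter-subject anatomical variability (spatial structure is a
1-D feature lattice; the volumetric cluster filter is exercised on
synthetic grids only); scanner drift beyond low-order polynomials;
inter-subject pattern misalignment (all subjects share the planted
patterns exactly — group t-maps are therefore cleaner than real data
would give); and rating-scale measurement error in the normative scores.
Passing tests consequently show that the *machinery* is correct and
calibrated under the stated generative model, not that real acquisitions
meet that model's assumptions.
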