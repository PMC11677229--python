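# Methods

This note documents the models, estimators and numerical choices in
`tuftpipe`, what the synthetic-data generator does and does not emulate,
and the known limitations.

## Trial-aligned quantification

Per-trial response amplitude is the mean ΔF/F over [onset, onset + 1.5 s)
minus the mean over [onset − 1 s, onset). Windows are half-open in frame
indices — the frame containing the onset belongs to the response window —
and a window of `w` seconds spans `floor(w · fs)` whole frames, so the same
second-based definitions apply at 30 Hz (45/30 frames) and at 10 Hz
volumetric rates (15/10 frames) without interpolation. Trials whose windows
extend past the session edge are dropped and counted. Per-stimulus mean
amplitudes include failure trials; variances use the unbiased (n−1)
estimator. The amplitude baseline is 1 s; the responsiveness test below
uses a symmetric 1.5 s pre-window — both windows are separately
configurable because they serve different definitions.

## Selectivity, discriminability, classification

SI = (F₊ − F₋)/(F₊ + F₋) after clipping each mean amplitude at 0, keeping
SI ∈ [−1, 1]; if both clipped means are 0 the SI is undefined (NaN) and the
tuft is excluded from SI distributions with a logged count.
d′ = |F₊ − F₋| / √((σ²₊ + σ²₋)/2); equal means give 0 even at zero
variance, unequal means at zero pooled variance give +∞.

A tuft is responsive to a stimulus when (1) per-trial window means 1.5 s
before vs 1.5 s after onset differ by a two-sided Mann–Whitney test at
α = 0.05 and (2) its mean amplitude exceeds 0.04 ΔF/F. The amplitude gate
dominates false-positive control: on null simulations the joint criterion's
false-positive rate is far below α because a noise-level mean amplitude
essentially never reaches 0.04. Tufts responsive to exactly one stimulus
are *highly selective* and their SI is set to ±1 (sign of the responsive
stimulus); tufts responsive to both are *selective* iff the CS+/CS−
amplitude distributions differ by rank-sum at α = 0.05. α is exposed and
applied per tuft without multiple-testing correction, matching the
per-tuft screening character of the classification. Rank-sum tests use
scipy's Mann–Whitney implementation (exact for small untied samples,
tie- and continuity-corrected normal approximation otherwise).

Population summaries (median |SI|, fixed-bin histograms on [−1, 1],
Kolmogorov–Smirnov distances to a fitted Normal and to uniform[−1, 1])
default to responsive tufts only: for a tuft with no evoked response the
clipped-ratio SI is noise-dominated and lands at ±1 about half the time,
which would swamp any learning-related median shift. The
`include_unresponsive` flag restores the all-tuft summary. The KS distances
are descriptive — no distributional test is attached to them. Forced
|SI| = 1 records replace the formula SI, so each tuft is counted exactly
once.

## Transient-probability mixture

Single-trial amplitudes are modeled as (1−p)·N(µ₁,σ₁) + p·N(µ₂,σ₂), the
low-mean component for failures and the high-mean component for transients;
p estimates the transient probability. Fitting is EM with 10 quantile-split
restarts, tolerance 1e-8 on the log-likelihood, 500 iteration cap, and a
variance floor of 1e-6 times the sample SD. Two robustness measures matter
in practice:

- Amplitudes are trimmed at the 2% tails before fitting. Spontaneous events
  landing in a trial's baseline or response window create heavy two-sided
  tails; the unrestricted two-Normal maximum likelihood absorbs them into a
  spuriously wide "failure" component that swallows much of the transient
  mass.
- Among converged restarts, solutions whose mean-ordered components satisfy
  σ₁ ≤ 1.5·σ₂ and (µ₂ − µ₁) > 0.5 pooled SDs are preferred (best
  likelihood among them); the unrestricted maximum is the fallback. This
  encodes the model's semantics — the failure component is a narrow
  distribution near zero — and removes the wide/narrow pathological optimum.

A fit is flagged *degenerate* when the data carry no credible second
component: constant input, a two-component likelihood less than 3 nats
above a single-Normal fit, a minor component carrying fewer than ~6 trials,
or component separation under 2.5 pooled SDs. This flag is a heuristic
guard, not a calibrated hypothesis test; on pure-noise inputs a minority of
fits still report an unflagged intermediate p, which is why transient
probabilities are only interpreted for responsive tufts. Under the
generator's default conditions (success probability 0.7, 180 trials) the
estimator recovers p with bias < 0.01 and SD ≈ 0.05.

## Behavior

A trial response is ≥1 lick in (onset, onset + 0.5 s] — open at the onset,
closed at the right edge (the boundary convention is a package choice).
CS+ with/without response → hit/miss; CS− → FA/CR. Performance per
stimulus carries exact Clopper–Pearson 95% intervals; discrimination is
P(lick|CS+) − P(lick|CS−), with CS+ base rate 0.5 as the chance reference.
Choice modulation compares FA vs CR post-stimulus window means by rank-sum
and requires ≥12 FA trials. Extinction curves are CS+ response
probabilities over consecutive 20-trial CS+ blocks (trailing partial blocks
dropped).

## Whisker kinematics

The 125 Hz median angle is filtered 4–30 Hz with a 4th-order Butterworth
applied forward–backward (zero phase); the analytic-signal phase of the
filtered trace defines the whisk cycle. Envelope anchors are the
*unfiltered* angle at phase-0 crossings (most protracted) and ±π crossings
(most retracted, detected as wrap jumps); anchor values use quadratic
3-point interpolation at the fractional crossing index — the angle is
locally parabolic at cycle extremes, and linear interpolation would bias
the envelope low by several percent at 10 Hz whisking. Envelopes are
linearly interpolated between anchors (held at the edges), amplitude is
upper − lower (order enforced pointwise), and normalized amplitude divides
by the 99.9th percentile of the session (logged alongside the true max) to
guard single-sample artifacts, clipped to [0, 1].

Bouts are maximal runs with normalized amplitude above 20% of maximum;
runs ≥ 250 ms are whisking, shorter runs are ambiguous (kept in the output,
excluded from whisking-vs-quiescence contrasts). Because neighboring bouts
merged at a low threshold can separate as the threshold rises out of the
noise floor, bout *counts* are not exactly monotone in the threshold; total
whisking duration is, and both properties are tested in their valid form.
Whisk-triggered averages align calcium (by time stamp, never index ratio)
to bout starts occurring 2–8 s after the preceding stimulus; the frame
whose interval contains the bout start is lag 0.

## Encoding and decoding

Encoding models regress the concatenated per-trial calcium excerpts
(−2 to +6 s around onset) on: binary CS+/CS− vectors with an 800 ms
(24-frame) on-period centered at onset and delayed by the tuft's
response-peak latency (argmax of the mean aligned response in the first
1.5 s); normalized whisking amplitude resampled to the frame grid and
shifted by the calcium–whisking cross-correlation peak lag (searched within
±30 frames); and a binary lick-bout vector (a bout is ≥2 licks with
inter-lick gaps ≤ 200 ms). Fits are ordinary least squares with an
intercept; rank-deficient columns are dropped greedily and reported.
Excerpts are concatenated without overlap trimming. R² is computed on the
concatenated series.

Decoding uses per-trial, per-tuft mean ΔF/F in a pre-stimulus epoch (1 s
before onset; negative control) and a post-stimulus epoch (0.1–1.1 s after
onset), a linear-kernel SVM with C = 1, and 10 iterations of random 75/25
train/test splits stratified by stimulus (stratification avoids degenerate
single-class test sets at modest trial counts); accuracy is the mean over
iterations, all seeded.

## Longitudinal statistics

Tufts are matched across sessions by persistent id (spatial re-registration
is upstream of this package). Transition tables count first→last category
pairs over matched ids; unmatched ids are excluded with a logged count.
The pooled two-proportion z-test, z = (p̂₁ − p̂₂)/√(p̂(1−p̂)(1/n₁+1/n₂)),
uses no continuity correction. Arm contrasts run two-sample t-tests across
animals between arms and paired t-tests within arm, requiring ≥2 animals
per arm. Both pooled-tuft and per-animal reporting modes are available
because cohort studies alternate between them.

## The synthetic-session generator

The generator emulates the study conditions: ~180 trials per ~30 min
session, inter-trial intervals uniform on 8–12 s, 50% CS+ probability;
calcium transients as a unit-peak double-exponential kernel (rise 50 ms,
decay 400 ms, GCaMP6f-like) with success amplitudes N(0.28, 0.05) ΔF/F;
spontaneous events as a 3/min Poisson process; Gaussian trace noise with
SD 0.05 ΔF/F at 30 Hz; evoked responses as per-trial Bernoulli successes.
Event superposition is linear (no indicator saturation), which keeps
closed-form oracles for every downstream estimate. Evoked failures are
true zeros, matching the mixture model's failure component.

Selectivity ground truth: each tuft's preferred-stimulus success
probability is drawn uniform on [0.6, 0.9] and the non-preferred
probability is scaled to p·(1−|SI|)/(1+|SI|), so the SI formula on expected
amplitudes reproduces the true SI exactly, with no clipping. True SI is
drawn from a truncated Normal (SD 0.35) in naive sessions; in the
conditioned arm it drifts linearly to a fresh uniform[−1, 1] draw by the
post session, in the exposure arm it stays fixed. 75% of tufts start
unresponsive; in the conditioned arm 40% of those gain a response at a
random later session, while in the exposure arm gains and losses are
balanced at 15% so the exposure population's stimulus signal stays
stationary — the exposure phenotype is an unchanged selectivity
distribution, flat decoding, and no d′ growth. Lick behavior follows a
saturating (exponential-in-session) CS+ learning curve and a decaying CS−
curve, with reward-consumption bouts on rewarded trials and exponential
within-session extinction (τ = 30 CS+ trials) in the unrewarded post
session. Whisking is a setpoint plus bout-gated 10 Hz carrier (inside the
4–30 Hz band) with Tukey-tapered envelopes; every stimulus evokes a bout
starting within 200 ms (disable with `whisk_evoked=False` to get
stimulus-independent whisking for encoding controls), and spontaneous
bouts arrive at 6/min. One master seed drives deterministic per-session,
per-tuft substreams; identical configs are bit-identical.

What the generator does **not** emulate: indicator saturation and
nonlinearity, branch-specific (NMDA-spike) local events, segmentation
errors (split/merged tufts), slow drift and motion artifacts,
session-to-session SNR changes, correlated noise across tufts, and any
coupling of calcium to whisking or licking unless explicitly configured
(`whisk_coupling`, `lick_coupling`). Passing recovery tests therefore
demonstrates estimator correctness under the stated generative model, not
robustness to those real-data features.

In cohort-level checks, the selectivity-vs-performance correlation is
evaluated over the naive and rewarded sessions: in the post session
licking extinguishes by design while selectivity persists, so including it
only injects a known decoupling (that persistence is itself the phenomenon
of interest).

## Problem sizes and determinism

Validation suites use the sizes at which their contracts are stated:
200 tufts × 180 trials for SI recovery (RMSE < 0.1 at default SNR), 50
seeded single-tuft sessions for mixture-p recovery (±0.08), 2000 trials for
the analytic d′ check, 200 null tufts for classifier calibration, and
150-tuft / 16-tuft three-session cohorts for the two-arm selectivity and
decoding contrasts. All stochastic stages take explicit seeds;
`run_pipeline` embeds the seed and a configuration hash in every output,
and re-runs are byte-identical.

## Known limitations

- The event detector (smoothed-trace peaks over a robust noise threshold)
  is a pragmatic spontaneous-rate estimator; event *rates* depend on its
  parameters and are not comparable across detector settings.
- The mixture degeneracy flag is heuristic (see above).
- Highly-selective forcing (|SI| = 1) makes post-learning SI distributions
  strongly tail-weighted whenever the weaker stimulus's amplitude falls
  under the 0.04 gate; median |SI| can saturate at 1 in small responsive
  populations.
- The two-proportion z-test is the uncorrected pooled approximation; for
  small counts an exact test is preferable (the test suite bounds the
  approximation error against Fisher's exact test).
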