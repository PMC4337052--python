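# Methods

This note records the models, parameter choices and numerical conventions
behind the package, and what the synthetic validation does and does not
establish.

## The index pipeline

The index is a three-stage chain applied to single-channel frontal EEG
sampled at `fs` Hz (default 125, carried explicitly everywhere):

1. **N-A MEMD filtering.** The EEG is decomposed by noise-assisted
   multivariate empirical mode decomposition and reconstructed from IMFs 2
   and 3 (1-based, fast to slow). IMF 1 absorbs broadband noise and
   electrosurgical transients; the slow IMFs and residue carry drift.
2. **Windowed sample entropy.** SampEn(m=2, r=0.1·SD, N=625) per
   non-overlapping 5-s window, stamped at the window end.
3. **Regression to the 0–100 score.** A backpropagation network maps the
   lagged entropy track to the expert consciousness score (EACL), whose
   conventions follow the clinical 0–100 scale: 100 fully awake, 40–60 the
   band adequate for surgery, an awake/anesthetised decision threshold
   of 65.

## Decomposition

**Sifting.** Proto-IMF h is repeatedly replaced by h − m(t), where m(t) is
the mean of per-direction envelopes. A direction's envelope interpolates the
multichannel samples at the local maxima of the signal's projection onto
that direction with not-a-knot cubic splines. Directions come in
near-opposite pairs on the sphere, so maxima-only projections cover upper
and lower envelope structure; on one channel with directions {+1, −1} the
construction reduces exactly to classic EMD's (max-spline + min-spline)/2,
which the test suite asserts at 1e-10.

**Stopping.** The literature's Cauchy-type criterion: accept the proto-IMF
when `SD = Σ|h_prev − h|² / Σ h_prev² < 0.075`, capped at 30 sifts per IMF
and 12 IMFs. Decomposition stops early when no projection retains two local
maxima ("trend only"); a constant input yields zero IMFs and the input as
residue. Completeness (IMFs + residue = input) holds by construction and is
tested at 1e-8 relative.

**Boundary handling.** Up to two extrema are mirrored across each signal
end before spline fitting. Extremum detection uses strict inequalities on
both neighbours; plateau samples are not extrema.

**Direction set.** K = 64 deterministic unit vectors (power of two,
adequate for the ≤ 4 channels used here). In the plane the 1-D Hammersley
sequence gives equispaced angles; in higher dimension a Hammersley point set
is pushed through the normal quantile and normalised. Directions whose
projection power is below 1e-10 of the signal scale are skipped: with
linearly dependent channels such projections are float noise and their
"extrema" are meaningless.

**Noise assist.** Two white-Gaussian channels at 10% of the signal SD,
seeded independently of the session noise. Only the original channel's IMFs
are returned.

**Long signals.** MEMD cost grows superlinearly with length, so signals are
decomposed in contiguous 10,000-sample blocks extended by 625 samples of
context on each side; the context is discarded after reconstruction so
spline end effects never reach a seam. Per-block noise channels derive from
`noise_seed + block_index`.

## Sample entropy

Matching uses the Chebyshev distance with a strict `< r` comparison, and the
tolerance is relative to the *window* standard deviation (config flag for a
session-global SD), making the track invariant to amplitude rescaling — the
EEG's units therefore never matter. Two normalisation conventions are
implemented: the default restricts both template lengths to the shared index
universe i, j ≤ N−m (the standard A/B count ratio, in which any common
normaliser cancels); `template_universe="full"` counts the m-length matches
over all N−m+1 templates. Both agree on every ratio-based property (zero for
constants, exact scale invariance, monotonicity in irregularity) and both
are covered by the brute-force oracle tests. Windows with zero variance, or
with no template matches at either length, yield NaN — never ±infinity —
and the regression stage imputes by the last valid value rather than
fabricating an entropy.

## Network

Architecture [L, 10, 1]: L lagged entropy values (default L = 6, 30 s of
context; L = 1 gives the strictly pointwise mapping), 10 tanh hidden units,
logistic output scaled by 100 so predictions live in [0, 100] by
construction. Inputs are standardised by training-set mean/SD; targets are
scaled to [0, 1]. Training is full-batch gradient descent with momentum 0.9
and learning rate 0.01 (up to 2000 epochs), initial weights uniform(−0.5,
0.5) from a seeded generator, early stopping on validation MSE with
patience 50, returning the validation-best weights. Non-finite loss raises
immediately with advice to lower the learning rate. The analytic gradient is
tested against central finite differences at 1e-6 relative.

Splitting is by session only: epochs within a session are strongly
autocorrelated and an epoch-level split would leak test sessions into
training. The default 30:10:24 proportions are allocated by largest
remainder (12 sessions → 6/2/4).

## Evaluation

Pearson r and MSE are computed on pairs formed by interpolating the
reference track onto the prediction's time grid over the overlap. MSE is the
literal mean of squared differences on the 0–100 scale; because published
"MSE" values for such indices are sometimes root-MSE, a `root_mse` flag is
provided, with the literal form the default. The ROC binarises the reference
at 65 (strictly above = awake = positive class, so AUC near 1 means the
index is high when awake); the AUC is the Mann–Whitney pair-count value with
ties scored 1/2, and the trapezoidal integral of the ROC curve is computed
alongside as a permanent internal cross-check (tested to 1e-10, and against
an independent pair-enumeration oracle and scikit-learn). Cohort summaries
report mean ± sample SD (n−1); undefined per-session metrics (single-class
reference, constant tracks) propagate as missing values excluded from the
summary, never as fabricated numbers.

## Synthetic sessions

The generator emulates exactly the structure the method assumes, nothing
more. Consciousness follows a C1 trajectory: awake level 97 before
induction, logistic descent (time constant 20 s) to a maintenance level of
45 — inside the 40–60 surgical band — with a bounded ±3 slow wander, and
logistic emergence. The EEG is MIX(p(t)): each sample is, with probability
p, uniform noise on [−√3, √3], otherwise a unit-variance 10 Hz sinusoid
(alpha-band-like), scaled to 20 µV. The consciousness→p map is piecewise
linear through (0, 0.05), (45, 0.15), (100, 0.9), so entropy falls
monotonically with depth — SampEn's monotone response to MIX(p) is well
characterised, which is precisely why MIX was chosen: it provides an oracle
clinical data cannot. Electrosurgical interference is mimicked by
Poisson-timed (default 1/min) Hann-windowed broadband bursts of 0.2–1 s at
5× the signal SD. The BIS-like reference is the true trajectory seen
through bounded AR(1) observation noise (φ = 0.8, stationary SD 5, clipped
to [0, 100]) — it is a noisy second reference for the evaluation stack, not
a reimplementation of any proprietary index.

Default sessions are 10 minutes (awake 0–60 s, induction to 180 s,
maintenance to 480 s, emergence thereafter) — a deliberately compressed
surgery that keeps a 12-session study tractable on one CPU; all durations
are configurable. One integer seed drives every draw in a session.

**What passing tests show — and don't.** The synthetic cohort establishes
that the chain recovers a monotone complexity→consciousness relationship
through realistic nuisance (artifacts, observation noise, filtering) and
that every stage honours its numerical contract. It does not establish
clinical performance: real EEG has spectral structure, drug- and
patient-specific dynamics, and artifact families the generator does not
model, and expert scores have inter-rater variability the single EACL track
does not. Numbers obtained here (test r ≈ 0.95, AUC ≈ 0.99 under default
settings) are upper bounds produced by favourable, noise-controlled data.

## Storage

Sessions are directories of plain CSV plus a JSON manifest; EEG can also be
written as single-channel EDF (16-bit format, so round-trips are exact only
to the quantisation step of range/2¹⁶ — CSV is the default where exactness
matters). The EDF writer is part of the package; reading goes through MNE,
which doubles as an independent check of the writer. Reading rejects, with
the offending row named, any non-finite sample, out-of-range score or
non-increasing timestamp — tracks are validated, never silently clipped.

## Reproducibility

A single global seed fans out through `numpy.random.SeedSequence` spawning
with fixed stage ordinals (generate = 0, memd = 1, train = 2), so inserting
a stage never perturbs another stage's randomness and every derived seed
stays below 2³¹. Rerunning a configuration reproduces every artifact —
entropy CSVs, model JSON, evaluation report — byte for byte.
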