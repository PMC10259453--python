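# Methods

`stnvalue` implements a complete analysis chain for studying how
subthalamic-nucleus (STN) neurons encode temporally discounted value while
an animal waits out a delay for food reward, together with a synthetic-data
generator that plants recoverable ground truth so every stage can be
validated without access to recordings.

## Task model and behavioral readout

The emulated task is a 3x2 design: reward size R in {1, 2, 3} drops crossed
with a delay class, short (3.5-5.6 s) or long (5.2-7.3 s), with the six
cues presented in balanced pseudo-random order within each session. The
subject may abort (reject) a trial instead of holding through the delay.

Subjective value is hyperbolic,

    SV = R / (1 + kD),

with discount factor k (1/s) and delay D (s). Rejection behavior is modeled
as inversely proportional to subjective value,

    E = (1 + kD) / (aR),

where E is the rejection rate and a a subject-specific scale.
`HyperbolicDiscounting.fit` minimizes squared error between observed
condition-mean rejection rates and this model by Nelder-Mead simplex search
on (log k, log a) — the log parameterization enforces k >= 0, a > 0 — with
10 restarts from log-spaced k in [0.01, 10] and a closed-form optimal scale
at each start. Goodness of fit is R^2 = 1 - SSres/SStot. D enters the fit
as the per-condition mean realized delay (midpoints 4.55 s / 6.25 s under
the defaults); R enters linearly (no utility exponent, consistent with a
two-delay design that cannot identify one).

**Identifiability caveat.** With delays confined to [3.5, 7.3] s,
k = slope/intercept of E·R as a function of D requires extrapolating the
intercept to D = 0 from far outside the sampled range. At realistic
Bernoulli trial noise (30 sessions x 180 trials) the Cramér-Rao bound for
k already allows median relative errors of ~30-100% depending on the scale
a. The fit is exact on noiseless inputs (verified to 1e-4) and unbiased in
the large-sample limit, but single-experiment k estimates at this design
carry large sampling error; this is a property of the design, not of the
estimator. A boundary flag is raised when k collapses to ~0 (no measurable
discounting).

## Synthetic-data generator

The generator's defaults are the study conditions, not tuning knobs:

- 30 sessions x 180 trials; k_true = 1.62 1/s; a_true = 40 (chosen so
  rejection rates span ~5-30%, "relatively low", and are higher for small
  rewards and long delays); realized delays are truncated Gaussians
  centered on the range midpoint with sd = range/4 (the within-range
  distribution is not otherwise constrained; the two ranges overlap).
- 231 neurons assigned round-robin to sessions. Each neuron has a planted
  category: Discounting- (reward+/delay-), Discounting+, Compounding+,
  Compounding-, a switcher that flips Discounting- -> Compounding+ at 2 s,
  or untuned. Default mix (0.20/0.08/0.10/0.06/0.10/0.46) reproduces the
  reported taxonomy scale: ~54% task-related, Discounting- dominant in
  phase 1, ~22% switchers among task-related cells.
- Spikes are an inhomogeneous Poisson process on [-1.2, 3.7] s around cue
  onset, discretized at 1 ms, with

      log rate = log b + transient(t) + s(t) (w_R z(R) + w_D z(D) + w_RD z(R)z(D)),

  where b ~ U(5, 30) Hz, the transient is a Gaussian log-rate bump
  (amplitude 0.8, peak 150 ms, sd 50 ms) emulating the cue-evoked phasic
  response, s(t) switches the gain signs between phases at 2 s, and
  z-scores are taken over the 6-condition design. The exponential link
  keeps rates positive without rectification; gains are quoted in log-rate
  units (default magnitude 0.3, log-normal spread 0.25 across neurons).
- Eye position is AR(1) noise (phi = 0.95 at 240 Hz, stationary sd
  0.5 deg) plus a post-cue condition offset (0.3 deg per z(R), 0.2 deg per
  z(D), 0.3 s ramp) so the eye channel genuinely confounds reward/delay
  coding; velocity is the first difference over the step.
- Anatomy: positions are sampled uniformly in an ellipsoid (semi-axes
  1.5/4.0/2.0 mm) and then re-assigned to neurons by a Gaussian-copula rank
  match so that the projection onto the gradient direction (default
  (0, -1, +1)/sqrt(2), i.e. dorso-posterior) has Spearman rho ~ 0.35 with
  planted encoding gain. The copula correlation is calibrated by bisection
  against a Monte-Carlo estimate of the realized Spearman, which also
  compensates rank-tie attenuation from the untuned (zero-gain) block.

Each artifact (trials, spikes, eye, anatomy) draws from its own RNG stream
spawned from the master seed, so stages are independently reproducible and
a fixed seed yields byte-identical outputs.

What the generator does **not** emulate: non-Poisson spiking (bursting,
refractoriness), session-to-session drift, saccade main-sequence dynamics,
EMG channels (the eye machinery doubles as the continuous-signal test bed),
and any coupling between rejection behavior and single-neuron state.
Passing recovery tests therefore demonstrates correctness of the analysis
machinery under the stated model, not robustness to those real-data
features.

## Single-unit analyses

Counts are taken in half-open sliding windows [c - w/2, c + w/2), default
200 ms stepped 20 ms: 174 analysis centers at 0.00..3.46 s and 47 control
centers at -0.94..-0.02 s (a fixed convention matching the published bin
counts; edge windows may overhang the epoch slightly). Spike density
functions convolve spikes with a 20 ms-sd Gaussian kernel on a 1 ms grid
over [-1, 3.5] s ("20 ms variance" is read as the conventional sd
parameter; a literal-variance kernel is available via the kernel_sd
argument). The Fano factor is the variance-to-mean ratio (ddof = 1) across
the six condition-mean SDFs, masked where the mean is zero and averaged
across neurons.

Per bin, a type-II two-way ANOVA (reward x delay class, with interaction)
tests single-trial counts; significance is Bonferroni-corrected at
0.05/174 (0.05/173 for continuous signals, both configurable; the source
procedure alternates between the two denominators). A neuron is
task-related if any reward or delay flag is set in at least one bin. The
ANOVA is computed as a vectorized QR model comparison shared across bins —
a calibration run needs ~3.5e5 ANOVAs — and matches statsmodels
`anova_lm(typ=2)` to 1e-8 in tests.

The time-resolved regression per bin is

    SC_i = b0 + bR R_i + bD D_i + bP P_i + bV V_i,

with regressors z-scored across trials within the bin (so the b's are
standardized slopes, invariant to rescaling of the raw regressors), D the
realized delay in seconds (a binary-class option exists), and P/V the
trial's mean tangential eye position/velocity within the window (an
option drops them). The response enters raw; population comparability is
restored by the control-epoch standardization below.

**Coefficient significance** is calibrated against the 1 s pre-cue control
epoch: the same regression on the 47 control bins yields a control
population per coefficient, and a test beta is flagged when
tau = (beta - mean_ctrl)/sd_ctrl falls in the two-sided 5% tail of the
null reference. Because overlapping control windows are correlated
(correlation = fractional window overlap under Poisson counts), a plain
prediction-band t with df = 46 over-rejects (~8% instead of 5%); the
reference distribution is therefore computed once per grid from the
overlap-correlation Gaussian model by fixed-seed Monte Carlo (40k draws,
cached). With independent control bins the analytic df = 46 prediction
band is used. Both paths are verified to flag ~5% per coefficient under
the null.

## Vector taxonomy

Bins where bR or bD is flagged contribute vectors (bR, bD) - control mean
in the reward x delay plane. Component-wise sums over phase 1 (bin centers
in [0, 2) s) and phase 2 ([2, 3.5] s) give per-neuron resultants whose
four-quadrant angle classifies the encoding: Discounting- in [-90, 0),
Compounding+ in [0, 90), Discounting+ in [90, 180], Compounding- in
(-180, -90); exact boundaries are assigned counter-clockwise (a package
convention — the interval endpoints are not otherwise determined).
Per-neuron labels use raw-beta resultants; population figures standardize
components by (beta - control mean)/(2 x control sd). Population-level
statistics: the resultant of standardized vectors, the Rayleigh test
(z = n Rbar^2 with the Zar small-sample p approximation, cross-checked
against pingouin), a chi-square of the four category counts against
uniform (df = 3, unclassified excluded), a one-way ANOVA of magnitudes
across categories, and pooled-variance two-sample t contrasts of category
position/waveform features (df = n1 + n2 - 2).

## Population PCA

Each neuron's regression is refit on 35 non-overlapping 100 ms windows
(independent bins), giving a neurons x 70 matrix (all bR bins, then all
bD bins). Columns are centered, not variance-scaled, and the covariance is
eigendecomposed. Eigenvectors are read per bin as (bR, bD) pairs — an
angle/magnitude trajectory per PC. Sign convention: each eigenvector is
oriented so its summed reward component is >= 0 (falling back to
largest-element-positive); a fixed orientation is needed because the
reward/delay reading of a PC is meaningful only modulo the arbitrary
eigenvector sign, and the reward-positive choice makes Discounting-
patterns land in the fourth quadrant by construction.

Significance uses trial-shuffle surrogates: per shuffle, each neuron's
trials are permuted (whole trials, jointly across bins, independently
across neurons), the regressions refit (via cached per-bin design
pseudoinverses) and the PCA re-run. The 2.5-97.5 percentile envelopes of
explained variance (per PC, rank-matched) and per-bin eigenvector
magnitude are the significance bounds; a PC or bin is flagged when the
real value falls outside its envelope. Defaults: 200 shuffles in the test
profile, 1000 for full fidelity.

## Anatomical gradient

The scan correlates per-neuron scores with position projected on a rotated
axis set: for 45-degree steps, the 13 sign-collapsed integer-lattice
directions (components in {-1, 0, 1}, normalized); for 90 degrees, the 3
cardinal axes. Per direction, Spearman rho with the standard t
approximation p; the best axis maximizes |rho| and is reported oriented so
rho >= 0, optionally with a permutation family-wise p over the whole axis
set (positions shuffled jointly, seeded).

## Numerical and degenerate-input choices

- Zero-variance count bins: ANOVA F undefined, bin skipped and logged.
- Zero-variance regressors: affected coefficients NaN and flagged;
  undefined betas entering the population matrix are set to 0 (logged).
- Zero control sd: significance falls back to strict inequality (logged).
- Discounting fit: soft box penalty outside log k, log a in
  [log 1e-6, log 1e3] blocks the degenerate k, a -> inf ridge along fixed
  k/a; k < 1e-4 sets the boundary flag.
- Neurons with < 20 completed trials are excluded from regression stages.
- Phase membership is by bin center; the final phase closes at 3.5 s.
- Rejected trials contribute to behavior but are excluded from all neural
  computations.

## Problem sizes

Default test-profile sizes were chosen so the whole chain runs comfortably
on one CPU: the full pipeline uses 231 neurons x 180 trials with 200
shuffles (~2-4 min end to end); calibration suites use 200 null neurons
(one seed in the test suite, 10 seeds in the acceptance script); envelope
coverage checks use 20 runs of a 20-neuron population at 200 shuffles.
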