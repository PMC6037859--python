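# Methods

`synctoj` simulates and analyses a study design in which the same audiovisual
stimuli (a point-light drummer with its drum-hit sound) are judged under two
tasks: synchrony judgment (SJ, "were sound and video in synch?") and temporal
order judgment (TOJ, "which came first?").  The package covers four stages:
psychometric modelling of the behavioral session, optimization of a mixed
block/event-related fMRI design, first-level GLM estimation of sustained and
transient BOLD responses, and group-level cluster-corrected ANOVA.  Every
stage runs on synthetic data with known ground truth, so the tests quantify
recovery rather than merely execute code.

## Psychometric models

The signed cue-onset asynchrony (COA, ms; negative = audio leads) is the
stimulus variable.  The SJ response probability is a scaled Gaussian

    p_SJ(coa) = A exp(-(coa - mu)^2 / (2 sigma^2)),   0 < A <= 1,

whose peak `mu` is the point of subjective simultaneity (PSS) and whose SD
`sigma` is the temporal integration window (TIW).  The TOJ "video-first"
probability is a cumulative Gaussian `Phi((coa - mu)/sigma)` with the PSS at
its 50% point.  TOJ ability is classified by the goodness of fit of the
cumulative Gaussian: R^2 >= 0.5 is "able", below is "unable".  The boundary
value 0.5 itself counts as able (the published rule uses strict inequalities
on either side, leaving the boundary — a measure-zero event — undefined; we
resolve it permissively).

**Fitting.**  Parameters minimise the sum of squared errors between the
per-level observed proportions and the model, with L-BFGS-B from 8
deterministic starting points spanning mu in {-150, -50, +50, +150} ms and
sigma in {60, 220} ms; bounds are mu in [-800, 800] ms, sigma in [1, 2000]
ms, A in (0, 1].  R^2 = 1 - SS_res/SS_tot over per-level proportions.
Degenerate data with zero variance across levels (e.g. a fully biased
responder) get R^2 = 0, hence "unable" — the conservative choice, since such
data carry no order information.  SSE-on-proportions was chosen over
binomial maximum likelihood because the estimand is defined by the fitted
curve's shape (peak / 50% point), the per-level trial counts are equal, and
a least-squares criterion keeps the R^2 used by the ability gate internally
consistent with the loss being minimised.

**Frame quantization.**  Stimuli are realisable only on the 60-Hz frame
grid, so a subject's PSS condition is the nearest multiple of 1000/60 ms
(ties toward zero), clipped to +/-20 frames (+/-333.33 ms).  The grid uses
the exact 16.67-ms frame rather than a rounded 16 ms, so the extreme levels
are 333.33 ms; reports round to integer ms.

**Group tests.**  Paired and pooled-variance independent t-tests are
implemented from the classical formulas (and cross-checked against
scipy.stats in the tests); zero-variance inputs raise rather than returning
infinite statistics.

## Synthetic cohorts and behavior

`make_cohort` draws subject parameters uniformly from ranges centred on the
group-level behavioral estimates for these stimuli: SJ PSS in [40, 100] ms
(video-leading, mean ~+70), SJ TIW in [90, 165] ms, SJ amplitude in
[0.75, 1], TOJ PSS in [-150, 40] ms (mean ~-55, audio-leading), TOJ TIW in
[100, 280] ms.  TOJ-unable subjects are split evenly between a "random"
phenotype (p = 0.5 at every level) and a "biased" one (every response
identical); the published account names both phenotypes without proportions,
so the split is configurable and defaults to 50/50.  The phenotype affects
only the TOJ task: unable subjects still answer SJ from their Gaussian
model, which is what makes between-group comparisons of SJ parameters
meaningful.  Responses are binomial draws per (task, level) with 10
trials/level at the 11 behavioral levels (0, +/-4, 8, 12, 16, 20 frames) by
default.

A known limitation of the ability gate follows from its construction: a
chance-level responder's R^2 against the 2-parameter monotone model is
scale-invariant, so ~5% of random responders pass the gate at any trial
count.  Classification accuracy is therefore a rate (>= 95% per subject),
not a certainty, and the tests treat it as such.

## fMRI design

One run: 32 stimulation blocks (16 per task, order randomized), each 25 s
containing 9 events — 5 stimuli of 3 s separated by 4 fixations whose
durations permute {1, 2, 3, 4} s.  A 4-s instruction screen precedes every
block and a 16-s fixation block follows every pair of blocks (run duration
1184 s; 592 scans at TR = 2 s).  Four COA conditions are scanned per task
(-333, 0, subject PSS, +333 ms), each 20 times per run, distributed over
the 16 same-task blocks as 0 presentations in 4 blocks, 1 in 6, 2 in 4 and
3 in 2.  `assign_block_composition` realises this multiset constraint by
randomized depth-first search with backtracking (the system 16x5 = 4x20 is
satisfiable; search failure is practically unreachable and tested as such).

**Design matrix (18 columns per session).**  Two sustained columns (25-s
boxcars per task), eight transient columns (impulses per task x condition),
an instruction boxcar, six motion placeholders (identically zero in
synthetic sessions, kept so column indices match a motion-corrected
session), and the constant.  Neural signals are built at 0.1-s microtime,
convolved with the canonical double-gamma HRF (response gamma shape 6,
undershoot shape 16, both scale 1, ratio 1:6, 32-s support, peak-normalized)
and sampled at the TR.

**Optimization.**  1000 candidate randomizations are scored by
(a) estimation efficiency, the mean over the 10 unit contrasts of interest
of `1 / (c' (X'X)^-1 c)`, and (b) the mean absolute Pearson correlation
between each transient column and its *same-task* sustained column (8
pairs, computed before high-pass filtering; cross-task pairs are near zero
by construction and would only dilute the statistic).  Both metrics are
z-scored across candidates and combined as `z(eff) - z(corr)`; the argmax
wins.  The selected design's mean sustained-transient correlation lands
near 0.40-0.41 under these defaults, in the published neighbourhood (0.47)
— residual differences plausibly reflect unstated choices in the original
scoring (efficiency formula, correlation pairing, filtering).

## First-level GLM

Both data and design are high-pass filtered by residualization against an
orthonormal DCT basis holding every component with period > 128 s
(K = floor(2·N·TR/128); 18 components at N = 592-600, TR = 2 s).
Residualizing rather than adding drift columns gives the same estimands
with simpler bookkeeping; the constant column is orthogonal to the basis
and survives, so baselines remain estimable.  A single AR(1) coefficient is
pooled (mean lag-1 autocorrelation) over mask voxels from the OLS
residuals; data and design are then prewhitened (first sample scaled by
sqrt(1-rho^2), the rest differenced by rho) and refit.  Near-noiseless fits
skip whitening (rho estimation on numerically-zero residuals is undefined).
Degrees of freedom are N - K - rank(X).  Exactly-zero design columns are
excluded with beta = 0; genuine collinearity among nonzero columns raises
an error naming the dependent columns.

Contrast maps carry `t = c'beta / sqrt(c'(X'X)^-1 c · sigma^2)`.  Percent
signal change is `100 · (c'beta) · 0.132 / beta_constant`, where 0.132 is
the supplied peak of the convolved reference trial (its derivation depends
on trial timing conventions outside this package and is not re-estimated).
Two runs are fit as separate sessions and per-condition contrasts averaged
with equal weights.

## Group inference

The split-plot ANOVA engine takes per-subject cell images with one between
factor (group) and up to two within factors (task; COA condition), and
computes each term's F vectorised over voxels.  Error terms follow the
classical partition: group against subjects-within-group, each within term
and its group interaction against the corresponding subject x factor
interaction.  Unequal group sizes (e.g. 9 vs 11) use the weighted-cell-means
sequential decomposition, verified in the tests against R's
`aov(... + Error(subj/(A*B)))` and against pingouin for the one-within
case.  Zero-variance voxels get F = 0 and can never cross the cluster
threshold.  No sphericity correction is applied — a known limitation; with
2-level factors the issue is moot, and the 4-level COA factor is
interpreted under the exchangeability the permutation test provides.

Clusters form at voxel p < 0.0001 of the F null under 18-connectivity
(edge + face, the convention of SPM-family software); peak ties break
toward the lowest linear voxel index.  Cluster p-values come from a
permutation null of the *maximum* cluster extent: group terms permute group
labels across subjects; within-subject main effects permute that factor's
levels independently per subject; the within x within interaction permutes
one factor's levels within each level of the other.  Group x within
interactions also permute group labels — exchangeable only in the absence
of a group main effect, a deliberate simplification.  Benjamini-Hochberg
across the observed clusters then controls FDR over clusters at q = 0.05.
This permutation construction replaces a random-field-theory cluster-FDR
procedure: the error criterion (FDR over cluster extents) is the same; the
null distribution is empirical instead of analytic.

Coordinates are voxel indices under an identity affine; synthetic volumes
default to 12x12x12 voxels.  Equivalent z in the cluster table is the
probit of the peak statistic's upper-tail p.

## The BOLD simulator, and what passing does not show

`simulate_bold_run` generates exactly the model the GLM assumes: design x
region amplitudes + baseline (default 100, giving percent signal change a
well-defined denominator) + a single cosine drift (default period 300 s —
deliberately inside the stopband of the 128-s high-pass) + stationary AR(1)
Gaussian noise (marginal SD `sigma`, default rho 0.3).  Recovery tests on
this generator validate the estimator's correctness, not its robustness:
real data add motion, physiological noise, spatially varying
autocorrelation, HRF variability and registration error, none of which are
simulated.  Noiseless forward-then-inverse is exact to 1e-8 by
construction; calibration claims (false-positive rates, power) hold under
this generative model only.

## Problem sizes used by the default test run

Tests use 100-subject behavioral cohorts at 100 trials/level for recovery,
the full 1000-candidate design optimization, 592-scan runs on 4-6 voxel
cubes for GLM checks, and 12^3-voxel, 20-subject group simulations with
150-200 permutations (50 null replicates for the false-positive rate, 20
for power).  These sizes give Monte-Carlo error comfortably inside each
asserted tolerance while keeping the whole suite fast.
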