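# synctoj

Simulation and analysis pipeline for experiments that contrast audiovisual
**synchrony judgments** (SJ: "were sound and video in synch?") with
**temporal order judgments** (TOJ: "which came first?") behaviorally and
with fMRI.  The package is aimed at researchers who want to prototype or
validate this analysis chain end to end on synthetic data with known ground
truth — no scanner data required.

It implements four stages as importable modules, driven by numbered
scripts under `analysis/`:

1. **Psychometrics** (`synctoj.psychometrics`).  The probability of a
   "synchronous" response as a function of the signed cue-onset asynchrony
   (COA, ms; negative = audio leads) is a scaled Gaussian
   `A·exp(-(coa-μ)²/2σ²)`; the probability of a "video-first" response is a
   cumulative Gaussian `Φ((coa-μ)/σ)`.  The peak / 50% point `μ` is the
   point of subjective simultaneity (PSS), `σ` the temporal integration
   window (TIW).  Subjects whose TOJ fit has R² < 0.5 are classified
   TOJ-unable.  Per-subject PSS values are quantized to the 60-Hz frame grid
   to define scannable stimulus conditions.
2. **Design optimization** (`synctoj.design`).  Mixed block/event-related
   runs: 32 stimulation blocks of 25 s (5 stimuli of 3 s + jittered
   fixations), 16-s rest blocks, 20 presentations per COA condition per task
   per run distributed over blocks as {0×4, 1×6, 2×4, 3×2}.  1000 random
   sequences are scored by GLM estimation efficiency
   `1/(c'(X'X)⁻¹c)` and by the mean |Pearson r| between transient and
   same-task sustained regressors; the best z-score combination is kept.
3. **First-level GLM** (`synctoj.glm`).  18 regressors per session (2
   sustained boxcars, 8 transient impulse responses, instruction, 6 motion
   placeholders, constant), all HRF-convolved; 128-s DCT high-pass; pooled
   AR(1) prewhitening; contrasts, t maps and percent signal change
   (scale factor 0.132).
4. **Group inference** (`synctoj.group`).  Voxelwise split-plot ANOVA
   (group × task × COA condition), clusters at voxel p < 0.0001
   (18-connectivity), cluster p-values from a permutation null of maximum
   extent, Benjamini–Hochberg FDR over clusters at q < 0.05, reported as a
   cluster table (peak, extent, F, equivalent z).

`synctoj.synthetic` generates the matching ground truth: cohorts with
TOJ-able/random/biased responder phenotypes, binomial response tables, and
4D NIfTI BOLD runs containing sustained + transient signal, cosine drift
and AR(1) noise.  See `docs/methods.md` for modelling details and
limitations.

## Worked example

```sh
python analysis/01_behavioral_psychometrics.py --seed 1
python analysis/02_design_optimization.py --seed 1
python analysis/03_firstlevel_glm.py --seed 1
python analysis/04_group_inference.py --seed 1
```

prints (abridged):

```
TOJ-able: 10 subjects; TOJ-unable: 10
mean SJ PSS +73 ms; mean TOJ PSS (able) -40 ms; paired t(9) = 3.60, p = 0.006
selected design: mean sustained-transient correlation 0.403 (candidate mean 0.411), efficiency 7123.6
run 1: AR(1) rho = 0.235, dof = 562
sustained SJ-TOJ contrast in region 1: 1.399 (truth 1.400); mean PSC 0.185%
task: 1 cluster(s), 1 significant (voxel p<0.0001, cluster FDR q<0.05)
  peak (5,5,5) extent 7 F=53.04 z=4.77 q=0.0020
```

Reading this: the cohort was generated as 9 able + 11 unable, and the R²
gate classified 10/10 at this seed — one chance-level responder slipped past
the gate, which happens ~5% of the time per random responder and is a
property of the classification rule itself.  The SJ PSS is video-leading
(+73 ms) while the TOJ PSS of able subjects is audio-leading, and the paired
t-test detects that dissociation.  The selected fMRI design decorrelates
block and event regressors to r ≈ 0.40 while keeping high efficiency.  The
GLM recovers the planted sustained task difference (1.399 vs true 1.400),
and group inference finds exactly the planted task cluster and nothing
elsewhere.  Outputs (fit tables, events TSV, design matrix CSV, NIfTI maps,
cluster tables) land under `results/`.

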