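# stnvalue

Analysis pipeline for **temporally discounted value coding in
subthalamic-nucleus (STN) spiking data** — for electrophysiologists and
computational neuroscientists studying how reward size and delay-to-reward
are integrated by single neurons and neural populations during a waiting
period.

The package covers the full chain used in delayed-reward experiments:

1. **Behavior** — rejection-rate statistics and a hyperbolic discounting
   fit. Subjective value is `SV = R / (1 + kD)` (reward size R in drops,
   delay D in seconds, discount factor k in 1/s), and rejection behavior is
   modeled as `E = (1 + kD) / (aR)` with a subject-specific scale `a`.
2. **Single-unit encoding** — sliding-window two-way ANOVA (reward x delay,
   Bonferroni-corrected across 174 bins of 200 ms stepped 20 ms) and a
   time-resolved standardized regression per bin,
   `SC = b0 + bR·R + bD·D + bP·P + bV·V` (P, V: eye-position/velocity
   nuisance covariates), with coefficient significance calibrated against a
   47-bin pre-cue control epoch.
3. **Vector taxonomy** — significant (bR, bD) pairs form vectors in the
   reward x delay plane; phase-wise resultants (phase 1: 0–2 s, phase 2:
   2–3.5 s) are classified by angle as Discounting− (−90..0°),
   Compounding+ (0..90°), Discounting+ (90..180°) or Compounding−
   (−180..−90°), with Rayleigh, chi-square and magnitude-ANOVA population
   statistics.
4. **Population PCA** — PCA of the neurons x (bR, bD x 35 time bins)
   matrix with 95% trial-shuffle surrogate envelopes for explained variance
   and eigenvector magnitude.
5. **Anatomy** — a rotated-axis (45°) Spearman scan for gradients of PC
   scores across recording coordinates.

A first-class **synthetic-data generator** plants known ground truth
(discounting behavior, cue transients, phase-dependent encoding categories
including Discounting−→Compounding+ switchers, eye confounds, a
dorso-posterior encoding gradient) so every stage is testable end to end.

## Worked example

```python
from stnvalue import SimConfig, PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=1)          # 231 neurons, 30 sessions x 180 trials
report = run_pipeline(cfg, out_dir="out")
```

or, equivalently, from a shell:

```bash
stn-valuecode run-all --seed 1 --out out
stn-valuecode report --report out/report.json
```

which prints (as produced by the run above):

```
behavior: k=1.340 1/s  a=33.08  R^2=0.993
task-related neurons: 123/231
PC variance (%): 52.2, 32.5, 9.5, 0.2  significant PCs: [0, 1, 2, 3, 4, 5, 6, 7, 8, 9]
best anatomical axis (PC1): rho=0.131
```

Reading the numbers: the recovered discount factor k = 1.34 1/s sits near
the generator's planted 1.62 1/s (the two-delay design identifies k only
coarsely; see `docs/methods.md`) with the condition-mean fit at
R² = 0.99. 123 of 231 simulated neurons are flagged task-related by the
Bonferroni-corrected sliding ANOVA. The population matrix concentrates
52% of its variance in PC1; PCs are marked significant whenever their
explained variance falls outside the 200-shuffle surrogate 95% interval
(trailing PCs fall *below* it, which is why they are listed). The best
anatomical axis correlates PC1 scores with position at rho = 0.13 — the
planted gradient couples position to encoding *strength*, so the signed PC
score recovers it only partially.

Per-stage artifacts (`trials.csv`, `spikes.csv`, `betas.csv`,
`vectors.csv`, `pca_variance.csv`, `eigenvectors.csv`, `scores.csv`,
`anatomy.csv`, `report.json`, …) are written to the output directory, and
each stage is also available as a library object — e.g.
`HyperbolicDiscounting(table).fit()` returns a results object with `k`,
`a`, `r_squared` and `summary()`; `NeuronEncodingModel(...).fit()` carries
the ANOVA and beta series; `PopulationPCA.from_neurons(...).fit()` exposes
`explained_variance_pct` and per-PC `eigenvector_series()`.

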