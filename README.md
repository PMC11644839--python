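# neuraxes

Seed-connectivity "neural axes" of explicit and implicit sensorimotor
learning: a tested, reusable implementation of an analysis pipeline that
links individual differences in motor-learning behavior to patterns of
functional connectivity with the hand area of primary motor cortex, and
a synthetic-cohort generator with planted ground truth so that every
stage can be validated end to end.

## Who this is for

Researchers in human sensorimotor neuroscience and functional
connectomics who want to (a) decompose visuomotor-rotation (VMR)
learning into explicit (re-aiming) and implicit (adaptation) components
from report trials, (b) segment reward-based learning curves with a
Bayesian sigmoid model, (c) analyze task-epoch covariance with
Riemannian (tangent-space) centering, (d) build penalized-regression
connectivity maps of behavior and score their expression in new data,
or (e) run spin-permutation spatial null tests — or who want a
simulation harness that exercises this whole class of pipeline against
known truth.

## The model in brief

**Behavior.** In the VMR task the cursor is rotated 45° clockwise
(CCW-positive convention: −45), so explicit + implicit = +45 is full
compensation; explicit learning is the circular mean of reported aim
minus target over the last 8 of 16 report trials, implicit is hand
direction minus reported aim, and performance is the mean signed error
over the first 32 learning trials.  In the reward task, subjects trace
a half-sine path and are secretly rewarded for its mirror image; per-trial
lateral movement scores y_i follow

    y_i ~ Normal(f(x_i), σ²),   f(x) = L + (U − L)/(1 + e^{−k(x−m)})

with x = trial/100 and priors m ~ N(1.7, 0.5), L ~ N(−0.2, 0.25),
U ~ N(0, 0.25), k ~ N(7, 2), σ ~ half-N(0, 0.25), fit by MCMC
(3 chains × 5,000 draws, 1,500 burn-in); the 2.5%/5%/97.5% crossings of
the posterior-mean curve define pre-learning / learning / post-learning
epochs and k is the learning rate.

**Connectivity.** Epoch covariances S_ij (Ledoit–Wolf shrinkage,
100-volume epochs) are centered on the SPD manifold: projected to the
tangent space at the subject mean S̄_i,
T_ij = S̄_i^{1/2} log(S̄_i^{−1/2} S_ij S̄_i^{−1/2}) S̄_i^{1/2}, then
parallel-transported to the grand mean, T^c = G T Gᵀ with
G = S̄^{1/2} S̄_i^{−1/2}.  Seed connectivity is the mean tangent
covariance between the seed (hand-area) rows and each other region.

**Axes.** Ridge regressions of explicit / implicit (residualized on
early error) and sign-inverted early error on seed connectivity, with
per-network penalties tuned by leave-one-out cross-validation, yield
the Explicit, Implicit and Performance neural axes; axis expression in
new data is the Pearson correlation between the axis and an observed
connectivity profile, and rank(β_explicit) − rank(β_implicit) is the
explicit-alignment axis, tested against a reference spatial map with a
spherical-rotation (spin) permutation null.

See `docs/methods.md` for assumptions, parameter defaults and
limitations.

## Worked example

Run the full pipeline on a synthetic cohort (the CLI uses the
full-size defaults — 36 subjects, 120 regions — and takes a few
minutes; a YAML config can override any parameter):

```bash
neuraxes run-all --out-dir demo_run --seed 7
```

or, at reduced size, in Python:

```python
from neuraxes.pipeline import PipelineConfig, run_pipeline

cfg = PipelineConfig(out_dir="demo_run", seed=7, n_subjects=24,
                     n_rois=60, mcmc_samples=2000, mcmc_burnin=600,
                     n_perm=200)
result = run_pipeline(cfg)
for axis, stats in result["cross_task"].items():
    print(axis, {k: round(v, 4) for k, v in stats.items()})
```

A run at these settings printed:

```
explicit {'r': 0.7133, 't': 4.7737, 'p': 0.0001, 'n': 24}
performance {'r': -0.3395, 't': -1.6927, 'p': 0.1046, 'n': 24}
implicit {'r': -0.7269, 't': -4.965, 'p': 0.0001, 'n': 24}
```

The synthetic cohort plants a coupling between reward-task learning
rates and the *explicit* connectivity pattern only, and that is what
comes back: the Explicit axis's expression during the reward-task
learning epoch correlates positively with learning rate (r = 0.71,
t(22) = 4.77, two-sided p = 1e-4), while the control axes show no
positive relationship (their negative correlations reflect
anticorrelated cross-talk between axis maps, which is pronounced at
this small demo size).  The run directory contains the trial tables, connectivity
profiles (`connectivity/*.tsv`), axis maps (`axes.tsv`, with
per-network penalties and cross-validated R² in `axes_meta.json`),
axis-expression scores, the spin-test result, and a manifest listing
every artifact with its content hash.  Identical configuration and
seed reproduce every file byte for byte.

Individual stages are available as subcommands (`simulate`, `behavior`,
`connectivity`, `axes`, `express`, `spin`, `validate`) operating on the
same run directory.

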