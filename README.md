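# twostep

Simulation and estimation toolkit for a gamified two-step
decision-making task with first-stage choices only: probabilistic
common/rare transitions, independently drifting per-colour reward
probabilities, difficulty-graded target hits, and blocks of 100 trials.
The package generates synthetic agent cohorts, estimates model-based and
model-free indices from lagged stay/switch behaviour, and reproduces
task-design analyses (reliability, trial-number curves, design-arm
comparisons) without any human data.

## Layout

| module                 | contents |
|------------------------|----------|
| `twostep.taskmodel`    | task configuration, drift generators (reflected random walk, moment-matched), session simulator, trial-log CSV/YAML I/O |
| `twostep.agents`       | hybrid model-based/model-free learner (weight `w`, shared learning rate, sticky softmax) plus degenerate agents (uniform-random, fixed-side, win-stay/lose-shift) |
| `twostep.stayfit`      | lagged stay-row design builder (±1 coding), per-subject ridge logistic fits, hierarchical (mixed-effects, Laplace) logistic fits, group-comparison and lagged-hit models, per-subject MBI extraction |
| `twostep.psychometrics`| odd–even split-half reliability, Spearman-Brown correction, one-way ICC(1,1), interpretation bands |
| `twostep.cohort`       | exclusion filters (missed > 20%, same choice > 95%), synthetic populations with a latent trait driving `w`, covariate-association models |
| `twostep.harness`      | trial-number cumulative/binned curves, design-arm comparisons, config-driven scenario runner |

## CLI

```bash
twostep simulate --n-subjects 50 --w 0.7 --seed 1 --out runs/sim
twostep exclude  --input runs/sim/trials.csv --out runs/excl
twostep fit      --input runs/excl/trials_kept.csv --model base \
                 --estimator hierarchical --out runs/fit
twostep reliability --input runs/sim/trials.csv --out runs/rel
twostep curve    --input runs/sim/trials.csv --step 25 --max-trials 200 \
                 --mode cumulative --out runs/curve
twostep compare  --factor transition_ratio --input-a a/trials.csv \
                 --input-b b/trials.csv --out runs/cmp
twostep run recovery --seed 1 --out runs/recovery   # bundled scenario
```

`twostep run` also accepts a YAML scenario file with sections `task`,
`population`, `estimation`, `experiments`; see
`twostep.harness.BUILTIN_SCENARIOS` for examples.

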