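# motr

Analysis pipelines for **mouse-tracking-for-reading (MoTR)** experiments —
a web-deployable paradigm in which text is blurred except for a spotlight
at the cursor, so 20 Hz mouse trajectories proxy reading attention. The
package targets factorized reading studies of grammatical-agreement
processing (match vs. mismatch between a head noun and a modifying
adjective, predicative adjective, or verb), but every layer is generic
over the five classic reading measures.

It is written for psycholinguists who want to go from raw trajectories to
Bayesian effect estimates without hand-rolled scripts:

1. **Trajectory processing** — nearest-word assignment, merging of
   consecutive samples into *attentional associations* (the fixation
   analogue), 160–4000 ms duration filtering, and the five measures per
   word or region: gaze duration, go-past time, total duration, first-pass
   regression (FPReg) and incoming regression (RegIn); plus
   comprehension-accuracy participant exclusion at 0.8.
2. **Contrast coding** — named hypothesis weights over the 12 design cells
   (grammaticality × gender × agreeing element), converted to a model
   matrix via the generalized inverse so each coefficient *is* the named
   condition difference in the response space.
3. **Hierarchical inference** — for reading times
   `y ~ Lognormal(eta, sigma)` and for binary regressions
   `y ~ Bernoulli(logit^-1(eta))` with
   `eta = (beta_0 + b_0i + c_0j) + sum_p (beta_p + b_pi + c_pj) x_p`,
   crossed by-participant/by-item random effects with LKJ(2)-prior
   correlations, intercept prior Normal(6, 1) on log-ms and slope priors
   Normal(0, 0.1). Posteriors come from a purpose-built blocked Gibbs
   sampler (Polya-Gamma augmentation for the binary family); effects are
   back-transformed to milliseconds / probability at the draw level.
4. **Evidence and power** — bridge-sampled marginal likelihoods for the
   Gram×AgrType-only vs Gram×LexCat-only model comparison with
   prior-sensitivity sweeps, and counterfactual-simulation power analysis
   over items × participants grids.
5. **Synthetic data** — a generator that emulates the full study design
   (24 targets, 48 fillers, 3 lists, 12 cells) and renders model-drawn
   region times as raw saccadic or smooth cursor trajectories with known
   ground truth, so the entire stack is testable offline.

See `docs/methods.md` for model details, numerical choices and limitations.

## Worked example

```python
from motr import StudyPlan, simulate_study, measures_from_samples, filter_participants
from motr.model import HierarchicalReadingModel

study = simulate_study(StudyPlan(n_participants=24), seed=1)
measures, assocs = measures_from_samples(study["samples"], study["layouts"])
table = measures.merge(
    study["trials"], left_on=["participant", "trial"],
    right_on=["participant_id", "trial_id"],
)
table = table[~table.is_practice & ~table.is_filler].assign(source="motr")
table, report = filter_participants(table, study["comprehension"])

model = HierarchicalReadingModel.from_measures(
    table, "total_duration", chains=2, iterations=1200, warmup=500
)
res = model.fit(seed=3)
print(res.summary().loc[["Gram", "AgrType", "GramxAgrType"]].round(3)
         [["mean", "lower", "upper", "resp_mean", "resp_lower", "resp_upper"]])
print(res.marginal_mismatch_cost().round(1))
```

Output from this exact run:

```
              mean  lower  upper  resp_mean  resp_lower  resp_upper
effect
Gram          0.104  0.020  0.188     56.916       8.582     105.762
AgrType      -0.132 -0.237 -0.012    -74.832    -132.421      -9.151
GramxAgrType  0.063 -0.081  0.199     25.871     -53.193     103.708
```

Read: mismatching agreement costs ~57 ms [9, 106] of total reading time on
the head noun (the generator's true penalty here is ≈52 ms); nouns after
externally agreeing elements are read ~75 ms slower; the extra mismatch
penalty under internal agreement is ~26 ms with an interval spanning zero.
The marginal table splits the mismatch cost by element (modifying
adjective 74 ms vs predicative adjective 51 ms in this run) with tail
probabilities. `res.back_transform("Gram")` gives any single effect in
ms; for `fp_reg` the same code path reports probability differences.

The same models fit externally computed (e.g. eye-tracking) measure
tables read with `motr.io.read_measures(path, source="eyetracking")`.

A CLI mirrors the pipeline: `motr simulate | process | fit | compare |
power`, each taking `--seed`, `--config` (YAML) and `--out`, writing CSVs
plus a `run.log` with the resolved configuration; same seed, same bytes.

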