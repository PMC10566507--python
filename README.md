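# amidebench

Benchmarking machine-learning yield prediction for carbodiimide-mediated
amide couplings — the workhorse reaction of medicinal chemistry — on
literature-style reaction data, with mechanism-aware augmentation,
multimodal descriptors, model stacking, and auditing of the two data
pathologies that sink yield models: **reactivity cliffs** (near-identical
reactions with wildly different yields) and **uncertain records** (the same
reaction reported with several yields).

Real literature reaction corpora are license-encumbered, so the package
ships a first-class synthetic-data generator that emulates their
statistical fingerprints (high-yield-skewed distribution, three amine
classes, categorical context effects, planted cliffs and uncertain groups,
latent electronic energies weakly anti-correlated with yield) with full
ground truth, making every downstream stage testable.

## What it does

* **Data model & I/O** — validated reaction records (`A + B = C + H2O`,
  formula-balanced, EDC/DCC/DIC only), CSV round-tripping, SDF/XYZ
  conformers.
* **Mechanism** — O-acylisourea intermediates via deterministic addition of
  the acid across the carbodiimide N=C=N; reaction-center annotation (atoms
  whose bond incidence changes); amine classification (primary
  aliphatic/aromatic, secondary).
* **Featurization** — Morgan fingerprints; a ~210-descriptor 2D battery;
  Behler–Parrinello-style atomic environment vectors (sum-pooled) from
  seeded ETKDG+MMFF conformers; percent buried volume at the reaction
  centers; reaction-level QM features (ΔE_rxn = E_product + E_water −
  E_acid − E_amine, Fukui difference, center charges, IP/EA) through a
  pluggable provider; leakage-safe context encoding, variance filtering and
  per-block recursive feature elimination.
* **Benchmark** — seeded 90/10 split plans; mean-baseline/linear/kernel/
  ensemble/MLP registry; R²/MAE as mean ± std over splits; stacking whose
  meta-prediction is the exact arithmetic mean of four per-descriptor base
  models; negative-reaction augmentation; per-amine-class subsets.
* **Cliff audit** — exact O(n²) cosine scan for cliff pairs (similarity
  > 0.9, |Δyield| ≥ 30 points), signature-based uncertain-group detection,
  and before/after re-benchmarking when they are removed.

## Worked example

```python
import numpy as np
from amidebench.synthetic import GeneratorConfig, generate_dataset
from amidebench.features import ReactionFeaturizer
from amidebench.benchmark import (ModelSpec, SplitPlan, StackSpec,
                                  run_benchmark, make_splits,
                                  stack_fit_predict, evaluate)
from amidebench.cliffs import find_cliffs, find_uncertain

config = GeneratorConfig(n_reactions=2000, n_planted_cliffs=60,
                         n_planted_uncertain=10, seed=0)
dataset, truth = generate_dataset(config)
print(f"{len(dataset)} reactions, mean yield {np.mean(dataset.yields()):.1f}%")

featurizer = ReactionFeaturizer(dataset, qm_provider=truth.qm_provider())
plan = SplitPlan(n_splits=5)
result = run_benchmark(dataset, featurizer, ["fingerprint", "qm"],
                       [ModelSpec("mean_baseline"), ModelSpec("ridge")], plan)
print(result.to_frame().round(3).to_string(index=False))

pairs = find_cliffs(dataset)
groups = find_uncertain(dataset)
print(f"{len(pairs)} cliff pairs, {len(groups)} uncertain groups detected")
```

prints

```
2000 reactions, mean yield 63.8%
        model    features  r2_mean  r2_std  mae_mean  mae_std
mean_baseline fingerprint   -0.007   0.010    10.172    0.719
        ridge fingerprint    0.325   0.101     7.628    0.340
mean_baseline          qm   -0.007   0.010    10.172    0.719
        ridge          qm    0.369   0.047     7.462    0.165
89 cliff pairs, 10 uncertain groups detected
```

Reading this: the mean-yield baseline scores R² ≈ 0 by construction (it
carries no information beyond the training mean, so it defines the zero
point of the scale); ridge on reactant fingerprints or on the
reaction-level QM vector explains a third of the yield variance, limited by
the additive label noise and the planted corruption. The detector finds all
60 planted cliff pairs (plus incidental near-duplicates the sampler created)
and all 10 planted uncertain groups. Stacking the four descriptor families
(`StackSpec` + `stack_fit_predict`) averages their base predictions exactly
and tightens the error further; removing the detected cliffs and uncertain
records before re-benchmarking (`amidebench.cliffs.remove_and_reevaluate`)
raises R² substantially — the quantitative version of "noisy labels, not
weak models, are the bottleneck".

The same flow is available from the shell:

```bash
amidebench generate --seed 0 --n-reactions 2000 --out run/
amidebench benchmark --reactions run/reactions.csv --block fingerprint \
    --model mean_baseline --model ridge --out run/benchmark.csv
amidebench cliffs --reactions run/reactions.csv --out run/cliffs/
amidebench pipeline --seed 0 --out run/full/     # all stages + manifest
```

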