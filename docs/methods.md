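# Methods

`amidebench` studies how well standard machine-learning models predict the
yield of carbodiimide-mediated amide couplings from literature-style
reaction records, and how *reactivity cliffs* and *uncertain records*
degrade that prediction. Because real literature reaction corpora are
license-encumbered, the package ships a synthetic-data generator with known
ground truth; every claim the test suite makes is a claim about recovering
that ground truth, not about any proprietary dataset.

## Reaction model

Every reaction follows A + B = C + H2O: a mono-carboxylic acid A and an
amine B with exactly one reactive N–H site condense to the amide C. All
couplings are mediated by one of three carbodiimides (EDC, DCC, DIC), whose
structures are fixed constants. Validation checks formula balance
(`formula(product) = formula(acid) + formula(amine) − H2O`), the yield range
[0, 100], and the closed coupling-agent set.

Mechanism-derived augmentation adds two things:

* the **O-acylisourea intermediate** R–C(=O)–O–C(=N–R′)(NH–R″), built by
  bonding the acyl oxygen to the central carbodiimide carbon and moving the
  carboxyl proton to one nitrogen. For the asymmetric EDC the proton goes to
  the nitrogen whose substituent has the smaller heavy-atom count (ties
  broken by canonical rank) — an arbitrary but deterministic tautomer rule;
* **reaction centers**: atoms whose bond incidence differs between the two
  sides — carboxyl carbon and departing hydroxyl oxygen in the acid, the
  nucleophilic nitrogen in the amine, amide C and N in the product. Centers
  are located by substructure matching, so they are invariant to atom
  renumbering. Symmetry-equivalent amine nitrogens (e.g. a symmetric
  diamine) count as a single site.

Amines are classified as primary aliphatic, primary aromatic, or secondary
by the carbon substitution of the reactive nitrogen; amide, sulfonamide and
aromatic-ring nitrogens are never reactive sites.

## Descriptors

* **Morgan fingerprints**: radius 2, 2048 bits, counts folded to binary —
  the conventional default for reaction ML.
* **2D battery**: the full RDKit 2D descriptor list (~210 named
  constitutional/topological/electronic-count descriptors). Non-computable
  entries become NaN and are removed column-wise by the variance filter,
  never imputed.
* **Atomic environment vectors (AEVs)**: Behler–Parrinello-style symmetry
  functions computed directly in NumPy. Radial term per element channel and
  shell center Rs: `G = Σ_j exp(−η (R_ij − Rs)²) · fc(R_ij)`; angular term
  per element pair, shell and angle center:
  `G = 2^(1−ζ) Σ_{j<k} (1 + cos(θ − θ_s))^ζ · exp(−η_a ((R_ij + R_ik)/2 − Rs)²) · fc(R_ij) fc(R_ik)`,
  with `fc(R) = 0.5 cos(πR/Rc) + 0.5` below the cutoff and 0 beyond.
  Defaults: radial Rc = 5.2 Å, 16 shells, η = 16 Å⁻²; angular Rc = 3.5 Å,
  4 shells × 8 angle sections, ζ = 32; element channels
  {H, C, N, O, F, Si, P, S, Cl}. All values are config-overridable. Per-atom
  AEVs are sum-pooled into a molecule vector.
* **Conformers** come from RDKit ETKDG distance-geometry embedding followed
  by MMFF94 minimization, keeping the lowest-energy of 10 seeded embeddings;
  the minimized force-field energy is the conformer's surrogate energy.
  Embedding is deterministic under a fixed seed and cached per canonical
  SMILES.
* **Buried volume** (%V_bur): the fraction of a probe sphere (default
  radius 3.5 Å, grid 0.1 Å, Bondi vdW radii, hydrogens included) occupied by
  the van der Waals spheres of surrounding atoms, evaluated at the acid
  carboxyl carbon and the amine nitrogen (both, concatenated).
* **QM-style reactivity features** come from a pluggable provider contract
  restricted to the elements {H, C, N, O, F, Si, P, S, Cl}; molecules
  outside that coverage raise a coverage error and drop out of QM
  experiments. The reaction-level vector contains the electronic reaction
  energy `ΔE_rxn = E(product) + E(water) − E(acid) − E(amine)`, the Fukui
  difference `Δf_rxn = f⁺(acid C) − f⁻(amine N)` (signed acid-minus-amine),
  the center charges, and IP/EA per reactant — 10 named columns. The default
  provider in the test pipeline is the synthetic-data oracle (exact
  latents); a heuristic additive group-contribution provider serves demos on
  arbitrary SMILES and is plausible in trend only.
* **Context** is encoded as a multi-hot vector over a (field, label)
  vocabulary built from training folds only; unknown test-time labels encode
  to zero. Numeric context (temperature, time) is carried through I/O with
  explicit missing markers but does not enter the encoded features.

Feature hygiene: the variance filter (which also removes NaN columns) is
fitted on training rows per split and applied unchanged to test rows, so a
column constant in training disappears everywhere — no leakage. Recursive
feature elimination reduces each descriptor family independently to a target
width using a seeded random-forest ranking refit each round (10% of
remaining columns dropped per round), then merges the survivors.

## Synthetic data generator

The generator emulates the statistical fingerprints of a literature amide
coupling corpus:

* **Fragment library**: fixed curated pools of 60+ mono-acids and 20 amines
  per class, all within the supported element set, filtered through the
  mechanistic preconditions. Two-ring "drug-like" members anchor the pools
  because literature couplings are mostly late-stage steps on such
  substrates — and because a remote methyl/methoxy edit on a two-ring
  substrate keeps fingerprint cosine similarity above 0.9, which is the
  regime reactivity cliffs live in. The library is identical across seeds so
  per-molecule descriptor caches are shared between replicate datasets.
* **Latent yield**: a deterministic function of interpretable structure
  terms — electron-withdrawing substitution on the acid (+3 points each),
  aromatic acids (−5), acid size (−0.4/heavy atom), steric crowding within
  three bonds of the amine nitrogen (−2.8/atom), amine class offsets
  (aliphatic +5, aromatic −7, secondary −2) — plus mild seeded categorical
  context effects (label coefficients ~N(0, 1–1.5 points)) and small
  temperature/time slopes. The intercept is calibrated per dataset so the
  sampled mean hits the configured target (default 64.1%); the result is
  clipped to [0, 100]. Observed yield = latent + N(0, σ), σ = 8 points by
  default, clipped. These coefficient scales were fixed once as a plausible
  desk-scale picture (structure effects dominate, context is secondary);
  they are conditions of the study, not tuning knobs. The distribution is
  right-skewed toward high yields (P(yield > 50) ≈ 0.87), emulating
  literature reporting bias.
* **Planted cliffs** (default 150 pairs at n = 5000): a base reaction is
  duplicated with a methyl or methoxy added to an aromatic CH at least four
  bonds from the carboxyl carbon; the pair's observed yields are forced at
  least the configured gap (default 45 points) apart while the detection
  feature-space cosine stays ≥ 0.9 (verified at planting time; bounded
  retries, else a generation error).
* **Planted uncertain groups** (default 25 groups of 3): exact duplicate
  records with distinct yields drawn uniformly over 30–90%, matching the
  scale of multiply-reported literature yields.
* **Latent energies**: each fragment gets a per-molecule electronic energy;
  product energies are set so the reaction energy carries a weak negative
  correlation with yield (target −0.12, achieved within sampling error by
  construction), with a constant exothermic shift. Oracle QM records expose
  reactivity quantities (center charges, Fukui indices, IP/EA) that are
  linear in the latent structure terms with small jitter — the synthetic
  analogue of electronic descriptors tracking nucleophilicity and
  electrophilicity.

What the generator does *not* emulate: real reagent chemistry beyond
categorical effects, correlated context–substrate selection, heteroscedastic
measurement error, duplicate-extraction artifacts, or the 41k-record scale
of real corpora. Tests passing on this data show the pipeline recovers known
structure under its stated noise model; they say nothing about accuracy on
proprietary literature data.

## Benchmark harness

Five fixed 90/10 train/test splits by default, seeded and reproducible; R²
(about the test-fold mean) and MAE in yield points are aggregated as mean ±
standard deviation over splits (the ± is std, not SEM). Model registry:
mean baseline, ridge, lasso, RBF-SVM (standardized), random forest (500
trees, √-features), histogram gradient boosting (500 rounds, depth 3, lr
0.05), MLP (256×64, early stopping, seeded); all predictions are clipped to
the physical range [0, 100]. Hyperparameter sweeping is out of scope; the
defaults are fixed and config-overridable.

**Stacking**: four base models, one per descriptor family {fingerprint,
battery2d, aev, qm}; the meta-model is the exact arithmetic mean of the four
base predictions. The package default base model is ridge (α = 10): the
synthetic latent is additive over fragments, and a linear model over
fingerprint bits (or AEV/descriptor signatures) can represent any
fragment-additive function, so ridge is both the fastest and the
best-calibrated base family for this data. RF/MLP bases remain available
through `StackSpec`.

**Parameter recovery**: with additive Gaussian noise σ and latent variance
V, no predictor can beat R² = 1 − σ²/(V + σ²) in expectation. The recovery
experiment (20 seeded replicates, n = 5000, single split per replicate, the
default ridge stack) checks the stacked R² lands within 0.1 of that ceiling.
The replicates are generated *without* planted cliffs/uncertain records,
because the ceiling formula assumes Gaussian noise is the only label
corruption; planting adds structured outliers that belong to the removal
experiment instead.

## Cliff and uncertainty auditing

Similarity space: concatenated acid+amine Morgan fingerprints plus the
context multi-hot, raw binary cosine. A cliff pair has cosine > 0.9 and
|Δyield| ≥ 30 points (read as percentage points) with non-identical
signatures; signature-identical duplicates with differing yields are routed
to the uncertain-group detector instead (tolerance 0 by default: any
difference counts). The scan is an exact blocked O(n²) matrix pass —
exactness is the contract, verified against a brute-force loop in the tests.
Removal takes every member of a flagged pair/group, then re-runs the
identical benchmark configuration on the reduced dataset; at desk scale
(n = 1200, 5–10% planted corruption, ridge on fingerprints, 3 splits) the
mean test R² improves in essentially every replicate, the directional
analogue of cleaning literature data.

## Problem sizes and numerical choices

Defaults were chosen to keep every experiment on a single CPU at interactive
scale: n = 5000 reactions, 60 acids, 60 amines, 10 solvents / 8 reagents /
5 condition labels; the recovery experiment uses 20 replicates at n = 5000;
the removal experiment 10 replicates at n = 1200; detector-exactness checks
run at n = 200. Buried-volume grids use midpoint sampling (grid offset by
half a spacing), which converges to within 0.5 percentage points at 0.1 Å.
Cosine similarity is undefined for zero vectors and raises rather than
returning a default. Ties in the EDC tautomer rule and in amine-site
selection are broken by RDKit canonical ranks. `ΔE_rxn` mixes energies from
a single provider only; provider units are opaque and never converted.

## Known limitations

* The heuristic QM provider is a trend-level stand-in, not a trained
  surrogate; quantitative QM feature values on real molecules are arbitrary.
* The O-acylisourea generator does not model N-acylurea side products or
  transition-state geometry.
* Cliff detection is exact but O(n²) in memory-blocked passes; beyond ~10⁵
  records a locality prefilter would be needed.
* The generator's context effects are independent of substrate; real
  solvent/substrate interactions are not represented.
* Only single low-energy conformers are used; no ensembles or Boltzmann
  weighting.
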