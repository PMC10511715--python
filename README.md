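# medpheno

**Pharmacophenotyping of ICU patients from medication administration
records.**

Critically ill patients are heterogeneous in ways that diagnosis-based
classifiers miss. `medpheno` derives *pharmacophenotypes* — patient
subgroups defined by the medications they actually received — and tests
whether those subgroups differ in clinical outcomes (mortality, length of
stay, delirium, AKI, mechanical ventilation, vasopressor use, fluid
overload, APACHE II, MRC-ICU). It is aimed at clinical-informatics and
pharmacoepidemiology researchers working with EHR medication
administration record (MAR) extracts.

## What it does

1. **Preprocess** raw MAR events: keep each patient's index ICU admission,
   keep only administered actions (*Given, New Bag, Restarted, Rate
   Change*), drop free-text/duplicate/incomplete rows, collapse dose/route
   decorations to generic names (`Cefepime 1gm` → `cefepime`), and
   binarize into a patients × medications matrix **X** ∈ {0,1}.
2. **Learn medication clusters** with a Bernoulli restricted Boltzmann
   machine, energy `E(v,h) = −aᵀv − cᵀh − vᵀWh`, trained by contrastive
   divergence (CD-1). Medication *i* joins cluster *k* iff
   `σ(W_ik + c_k) > τ` (τ = 0.5 ⇔ `W_ik + c_k > 0`); medications that
   activate no hidden unit form a residual cluster. A PCA variance profile
   of **X** is produced as a dimensionality diagnostic.
3. **Featurize patients** by their normalized medication-cluster
   distribution: the fraction of each patient's distinct medications
   falling in each cluster.
4. **Cluster patients** by Ward hierarchical agglomeration, choosing the
   number of phenotypes k by silhouette analysis.
5. **Validate** the phenotypes: pairwise Fisher exact tests (binary
   outcomes) and Wilcoxon rank-sum tests (continuous outcomes) with Holm
   familywise adjustment per outcome, plus a distance-based permutation
   MANOVA (`pseudo-F` on z-scored outcomes) over all outcomes jointly.

Because real MAR extracts are protected data, the package includes a
synthetic cohort generator with planted ground truth (patient archetypes
driving medication co-occurrence blocks and outcome rates), so the whole
pipeline is testable and benchmarkable end to end.

## Worked example

```python
from medpheno import RunConfig, run_pipeline

solution = run_pipeline(RunConfig(seed=1, out_dir="run1"))
print(solution.summary())
```

prints (abridged):

```
Patient phenotype solution
========================================
patients: 1000   clusters: 4   linkage: ward
selection: no qualifying k; global mean-silhouette argmax
cluster sizes: 1: 399, 2: 207, 3: 198, 4: 196
mean silhouette by k: k=2: 0.410, k=3: 0.515, k=4: 0.584, k=5: 0.501, ...

Permutation MANOVA
pseudo-F = 32.2648  (df 3, 996)
p = 0.0001  (9999 permutations, seed 1, standardize=zscore)

Per-cluster outcome summary
========================================
                 cluster 1 (N = 399) cluster 2 (N = 207) cluster 3 (N = 198) cluster 4 (N = 196)
icu_los_days               4.8 ± 4.4           2.5 ± 2.2           4.1 ± 3.3           7.5 ± 7.0
mortality                 40 (10.03)            5 (2.42)            8 (4.04)          48 (24.49)
...
Significant pairwise contrasts (Holm-adjusted p < 0.05): 52 of 66
```

Reading this: the pipeline simulated a 1,000-patient cohort (~30k MAR
events over 440 medications), learned five medication clusters plus a
residual cluster, and found four patient phenotypes. Phenotype 4 is the
high-acuity group — 24.5% mortality and 7.5 ICU days versus 2.4% and 2.5
days in phenotype 2 — and the permutation MANOVA confirms the phenotypes
separate on all outcomes jointly (p = 0.0001, the smallest value 9,999
permutations can resolve). Cells are `mean ± SD` or `count (%)`;
`52 of 66` counts pairwise cluster/outcome contrasts that remain
significant after Holm adjustment within each outcome.

Every stage is also available as a library call
(`preprocess_records`, `MedicationRBM(...).fit()`,
`compute_cluster_distribution`, `PhenotypeModel(...).fit()`,
`pairwise_outcome_tests`, `permutation_manova`) or as a CLI:

```bash
medpheno simulate --n-patients 1000 --out-dir sim
medpheno preprocess --mar sim/mar_records.csv --outcomes sim/outcomes_raw.csv --out-dir pre
medpheno fit-rbm --matrix pre/binary_matrix.tsv --out-dir fit
medpheno run-all --seed 1 --out-dir run1     # everything at once
```

See `docs/methods.md` for the models, defaults and their rationale.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch on the seeded reference
synthetic cohort — generation, preprocessing, PCA profile, RBM training,
medication cluster assignment, patient featurization, hierarchical
phenotyping, pairwise outcome testing and permutation MANOVA — printing
the run summary and writing the result record to the given path.
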