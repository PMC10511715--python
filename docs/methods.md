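# Methods

`medpheno` derives **pharmacophenotypes** — patient subgroups defined by
their medication profiles rather than by diagnosis — from raw ICU
medication administration records (MAR), and tests whether the subgroups
differ in clinical outcomes. This note documents the models, the numerical
choices, and what the synthetic benchmark does and does not establish.

## 1. From MAR events to a binary matrix

A MAR extract has one row per administration event: patient id, admission
index, medication name (often decorated with dose/route), an action label,
and a timestamp. Cleaning proceeds in a fixed order:

1. **Index admission** — only each patient's earliest ICU admission is
   retained (derived from timestamps, with a >30-day gap heuristic, when an
   explicit admission index is absent).
2. **Action filter** — only actions that denote an actual administration
   are kept: *Given, New Bag, Restarted, Rate Change* (case-insensitive,
   whitespace-trimmed). *Missed*, *Held* and free-text communication rows
   are discarded.
3. **Dedup / completeness** — exact duplicates (all fields, timestamp
   included) collapse to the first occurrence; rows missing patient id,
   medication name or action are dropped.
4. **Generic-name collapse** — names are lowercased; dose tokens
   (`number + {gm, g, mg, mcg, unit(s), %}`) and route words
   (IV, PO, IM, SC, SL, PR, inhaled) are stripped, so `Cefepime 1gm` and
   `cefepime 2gm` become the single feature `cefepime`. This is string
   normalization only; brand→generic vocabulary mapping (RxNorm etc.) is
   out of scope.

The result is a patients × medications indicator matrix **X** with
`X[p, m] = 1` iff patient *p* has at least one retained record of
medication *m*. Rows and columns are sorted (patient id, then
lexicographic medication name) so every downstream seeded computation is
reproducible. Outcome tables are recoded so categorical labels become
{0, 1}, with *unknown / missing → 0* ("no").

## 2. Medication clusters from a Bernoulli RBM

A restricted Boltzmann machine with visible units `v` (one per medication)
and hidden units `h` (one per medication cluster, default 5) defines

```
E(v, h) = −aᵀv − cᵀh − vᵀW h
P(h_k = 1 | v) = σ(c_k + Σ_i W_ik v_i),   P(v_i = 1 | h) = σ(a_i + Σ_k W_ik h_k)
```

Training maximises the likelihood of the patient rows by **contrastive
divergence** (CD-1 by default): the model expectation in the gradient is
replaced by a one-step Gibbs reconstruction started at the data. Defaults
follow the common reference implementation: learning rate 0.1, minibatch
10, 10 epochs, CD-1. Training rows are put in canonical (lexicographic)
order first, so the fit is invariant to the order patients arrive in; one
master seed drives initialization, shuffling and Gibbs noise.

**Initialization.** Weights start from N(0, 0.01²); hidden biases from 0;
visible biases from the data log-odds `log(p_i / (1 − p_i))`. The log-odds
start matters: ICU medication matrices are sparse (~16 of 440 medications
per patient), and with zero-initialized visible biases the hidden biases
drift to large positive values to absorb the sparsity — every hidden unit
is then always on and the activation rule below assigns every medication
to every cluster. With the log-odds start the biases model the marginals
from step one and the weights carry the co-occurrence signal.

**Cluster assignment.** Medication *i* joins cluster *k* iff clamping its
one-hot visible vector activates unit *k* above a threshold τ:
`σ(W_ik + c_k) > τ`, which at the default τ = 0.5 is simply
`W_ik + c_k > 0`. Multi-membership is allowed; a medication that activates
no unit falls into the **residual cluster** (index `n_hidden + 1`). On the
reference synthetic world roughly 350 of 440 medications are residual —
the rarely-used tail of the formulary — matching the qualitative shape of
the motivating analysis. The original study never defines "activated";
thresholding the one-hot conditional is this package's documented choice,
and τ is configurable.

**PCA.** A PCA variance profile of the binary matrix is computed as a
dimensionality diagnostic (default target: the smallest component count
reaching 75% cumulative variance). A configuration switch
(`rbm_input: binary | pca`) also allows training the RBM on binarized,
[0, 1]-rescaled PCA scores. On that alternative pathway there are no
per-medication visible units, so medication assignment is undefined (all
medications are reported residual) and patients are featurized by their
hidden-unit activation probabilities instead. The binary pathway is
canonical.

## 3. Patient features and hierarchical phenotypes

Each patient's distinct medications are counted per cluster (residual
included) and normalized by the patient's total distinct medications
(`by_total_meds`). With overlapping memberships those rows can sum to more
than 1; the alternative `simplex` normalization divides counts by their own
sum. Features live on a common [0, 1] scale, so distances are computed on
the raw features without standardization.

Patients are clustered by agglomerative hierarchical clustering (default
Ward linkage on Euclidean distances; complete/average available). The
number of phenotypes k is selected by silhouette analysis over a k range
(default 2–8): prefer the k whose every per-cluster mean silhouette is at
or above the overall mean at that k ("all clusters above average"),
breaking ties toward smaller k; if no k qualifies, fall back to the global
argmax of the mean silhouette. Note that because the overall mean is the
size-weighted average of the per-cluster means, the qualification can only
hold when the per-cluster means are numerically equal — in practice the
fallback argmax performs the selection, and the rule actually applied is
recorded in the results object. Points in singleton clusters get
silhouette 0.

## 4. Outcome validation

For every unordered phenotype pair and every outcome:

* **binary outcomes** (mortality, AKI, delirium, MV presence, fluid
  overload) — two-sided **Fisher exact** test on the 2×2 table, with the
  sum-of-no-more-probable-tables convention. A table with a zero margin
  admits only itself and returns p = 1.
* **continuous outcomes** (hospital/ICU LOS, MV days, vasopressor days,
  APACHE II, MRC-ICU) — two-sided **Wilcoxon rank-sum**, exact by
  enumeration when n + m ≤ 12 without ties, otherwise a tie- and
  continuity-corrected normal approximation. (A signed-rank test is
  provided for paired designs but is not part of the pairwise table, which
  compares independent groups.)

**Holm** step-down adjustment is applied *within each outcome's family* of
C(k, 2) comparisons — the familywise error is controlled per outcome, not
across the whole table. Pairs containing a degenerate cluster (n < 2) are
flagged, not dropped.

A distance-based **permutation MANOVA** tests all outcomes jointly:
outcomes are z-scored per column (configurable to raw), squared Euclidean
distances give `SS_total = (1/N) Σ_{i<j} d²_ij` and
`SS_within = Σ_g (1/n_g) Σ_{i<j∈g} d²_ij`, and
`pseudo-F = (SS_among/(k−1)) / (SS_within/(N−k))` is referenced against
seeded label permutations (default 9,999), with
`p = (1 + #{F* ≥ F}) / (n_perm + 1)`. Constant outcome columns are dropped
before z-scoring.

## 5. The synthetic cohort

Real MAR data are protected, so the package ships a generator whose
defaults emulate the aggregate shape of a ~1,000-patient ICU cohort:

| parameter | default | rationale |
|---|---|---|
| patients / medications | 1,000 / 440 | cohort scale of the motivating study |
| planted blocks | 5 blocks × 20 medications | archetype-linked co-occurrence signal |
| block usage | 0.4 own-block, 0.02 off-block | moderate, realistic contrast |
| background receipt | 0.025 over 340 medications | rare-use formulary tail (residual cluster) |
| events per received med | 1 + Poisson(0.7) | yields ~30k administration events |
| action mix | 62% Given, plus New Bag/Restarted/Rate Change/Missed/Held/free-text | exercises the action filter |
| duplicates / incomplete rows | 2% / 1% | exercises the cleaner |
| repeat admissions | 1% of patients | exercises the index-admission filter |
| per-archetype mortality | 2.6–22% | outcome gradient across latent archetypes |

Lengths of stay are log-normal, support durations exponential, severity
scores truncated normal; every outcome parameter is archetype-specific, so
phenotype recovery implies outcome separation. A small unknown-label rate
(3%) on delirium/AKI/fluid-overload exercises the missing→no recoding.
Ground truth (patient archetype, medication block) is returned for
benchmarking.

What the generator does **not** emulate: real pharmacology (drug classes,
interactions, dosing curves), informative missingness, admission-level
temporal structure, or correlated outcome noise beyond the archetype
effects. A green recovery benchmark therefore establishes that the
pipeline recovers planted co-occurrence structure at realistic scale — not
that it would find clinically meaningful phenotypes in any particular EHR.

## 6. Numerical choices and degenerate inputs

* Exact test enumeration cutoff n ≤ 12; above it, corrected normal
  approximations (the convention of the major statistical ecosystems).
* Fisher two-sided ties use a 1e-7 relative slack on table probabilities.
* Permutation p-values are never 0 by construction (the `+1` convention).
* All-zero medication profiles in the generator are forced to one receipt
  with a warning; a patient with zero medications at featurization is an
  error naming the patient.
* A cohort whose features collapse to a single point yields undefined
  silhouettes; selection then falls back to the smallest k with a logged
  "degenerate" rule.
* Seeds: every stochastic component (generator, RBM, MANOVA) takes an
  explicit seed; the pipeline fans one master seed out and records it in
  the run manifest.

## 7. Known limitations

* The activation rule (and hence cluster content) is sensitive to training
  length: long over-training slowly absorbs rare background medications
  into clusters. The defaults (10 epochs) are calibrated to the reference
  scale; inspect assignment sizes when changing them.
* Silhouette-guided k selection on weak-contrast data tends to merge
  archetypes (the reference world yields k = 4 with two archetypes fused);
  this is a property of the data contrast, not a failure of the search.
* The pairwise table controls FWER within each outcome only, mirroring the
  motivating analysis; no across-outcome correction is applied.
* Nothing here supports causal interpretation of phenotype–outcome
  associations.
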