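# Methods

## The problem

Global predictive models trained on all available EMR records are not
always the best tool for predicting an *individual* patient's status:
records dissimilar to the index patient act as noise. The personalized
alternative measures the similarity between the index patient and every
candidate training patient, trains a model only on the top-K most
similar ("patients like me"), and applies it to the index patient — one
model per query. This package implements the similarity measure, the
per-query modeling procedure and the evaluation design that compares
similarity-based against random training-sample selection, with a
synthetic diabetes case-control cohort standing in for the
(non-deposited) hospital EMR data.

## The patient similarity measure

A patient is a tuple (age, sex, lab vector of m items, ICD-10 diagnosis
set). Similarity between patients i and j is a convex weighted sum of
four feature-level similarities, each in [0, 1]:

    PS(i,j) = w1·FS_D(i,j) + w2·FS_L(i,j) + w3·FS_A(i,j) + w4·FS_S(i,j)

with default weights (0.4, 0.4, 0.1, 0.1) and Σw = 1 (validated to
1e-9).

* **Age** FS_A = min(Age_i, Age_j) / max(Age_i, Age_j); ages must be
  positive.
* **Sex** FS_S = 1 if equal, else 0.
* **Labs** FS_L = 1 − d′, where d′ is the Euclidean distance between
  z-scored lab vectors, min-max normalized. The normalization scope is
  not intrinsic to the formula; this package takes the min and max over
  the query's distances to the *entire training pool*, so FS_L is
  relative: within one profile the closest pool patient scores 1 and
  the farthest 0. FS_L values are therefore comparable within a
  profile, not across queries. If every distance in a batch is equal
  (a degenerate case possible only in toy pools) all FS_L are defined
  as 1 and the event is logged. Z-scoring uses training-pool means and
  SDs only, also for test patients — pooled statistics would leak test
  information into the similarity. A zero-variance lab column is an
  error naming the column.
* **Diagnoses**, two schemes:
  * *Hierarchical ICD-10* (`scheme="icd"`). Codes are canonicalized to
    the chapter letter plus the first three digits (dot stripped), a
    4-level hierarchy: level = 1 + digit count. Pairwise code
    similarity S(x,y) = level(NCA(x,y)) / 4, where the NCA is the
    longest common prefix; codes from different chapters share only a
    virtual root (level 0, S = 0). Two diagnosis *sets* X, Y are
    compared by penalizing the non-shared codes: with d(x,y) = 1 −
    S(x,y),

        FS_D1 = 1 − (1/|X∪Y|) ( Σ_{x∈X\Y} mean_{y∈Y} d(x,y)
                               + Σ_{y∈Y\X} mean_{x∈X} d(y,x) ).

    Identical sets score exactly 1; cross-chapter disjoint sets score
    0. Note that S(x,x) = level(x)/4 < 1 for partial-depth codes, so
    cohorts should carry full-depth (letter + 3 digits) codes; the
    parser and generator produce them.
  * *CCS cosine* (`scheme="ccs"`). Diagnoses are collapsed through a
    longest-prefix ICD-10→CCS crosswalk into a 259-dimensional 0/1
    category vector and FS_D2 is the cosine similarity of the two
    vectors. An all-zero vector (possible when no code is mapped)
    yields similarity 0 with a logged warning. Unmapped codes are
    dropped with a warning by default; a strict mode raises instead.
    A small crosswalk covering the synthetic code universe ships with
    the package; users supply a full crosswalk as
    `icd_prefix<TAB>ccs` text for real data.

Profiles are sorted by PS descending with ties broken by ascending
pool patient id, so top-K selection is deterministic and reproducible.

## Personalized predictive modeling

Model input features, in fixed column order: age, a male indicator,
binary presence indicators for the screened diagnosis features (sorted
lexicographically), and the m z-scored labs — 2 + |screened| + m
columns. The diagnosis screen drops codes below 1% cohort prevalence,
then keeps codes whose 2×2 presence-by-label χ² test gives P < 0.05.

When the prediction target is itself diagnosis-defined (diabetes =
E10–E14), those codes would pass the screen and predict the label
perfectly by construction. The evaluation harness therefore excludes
the target block from the *feature* set by default
(`feature_exclude_prefixes`); the similarity computation keeps the
full diagnosis sets, since "has the same diseases" is exactly what
patient similarity should capture.

Three classifier families:

* **kNN**: probability = proportion of positive labels among the k
  (default 50, clamped to the training-subset size) nearest training
  rows by Euclidean distance; distance ties resolved by ascending
  training order. Implemented in-package because of the deterministic
  tie-break contract; cross-checked against scikit-learn's
  `KNeighborsClassifier` in the tests.
* **LR**: scikit-learn `LogisticRegression` at C = ∞ (plain maximum
  likelihood); an optional `ridge` strength adds an L2 penalty for
  collinear or separable inputs.
* **RF**: scikit-learn `RandomForestClassifier` with 100 trees.

A training subset containing a single class (possible at very small K
under strong similarity) yields that class proportion (0 or 1) as the
probability, logged, instead of failing mid-sweep.

### Seeds and the degenerate-K identity

One master seed drives everything. Sub-seeds are derived by hashing
the context (`derive_seed(master, *tokens)`, SHA-256 → [0, 2³¹)):
per-query seeds for random subset draws, per-replicate-per-algorithm
seeds for model fitting. Two deliberate choices make the K = pool-size
limit an exact identity rather than an approximate one: training rows
are always ordered by ascending patient id before fitting, and the
model seed does not depend on the query or on the selection mode. At
K = pool size both selection modes therefore fit byte-identical
matrices with identical seeds and every query receives the same
prediction — the personalized model degenerates into the traditional
one exactly. Models are cached per (algorithm, training-id-set) within
a sweep cell, which is a pure optimization under these conventions.

## Evaluation design

`holdout_split` makes a class-balanced random split into a training
pool and test set. `sweep_training_size` then, for each (scheme,
replicate, algorithm, K): trains one model per test patient on its
top-K similar pool patients (*similar* arm) and one model on a single
random K-subset shared across algorithms within the replicate
(*random* arm), scoring both by AUC over the whole test set. Each cell
is repeated over replicate seeds (default 5) so curve comparisons have
within-cell samples; replicates vary the RF seed and the random
subsets (the similar-arm kNN/LR cells are deterministic and identical
across replicates by design). Results are tidy rows
`algorithm, scheme, mode, K, replicate, seed, auc`.

Curve trends are summarized by a least-squares cubic polynomial
(requiring ≥ 4 distinct K). Two AUC curves are compared by a two-sided
Mann-Whitney U test over the per-K values — the exact null
distribution when both samples have ≤ 12 values and no ties, the
tie-corrected normal approximation otherwise — with Bonferroni
adjustment capped at 1.

### Problem sizes

The packaged study conditions are a 500-per-class training pool, a
100-per-class test set, 5 replicates, and a K grid at {2, 5, 10, 20,
30}% of the pool plus the full pool, chosen as a desk-scale rendering
of the original 10,000-pool design (whose grid spanned 2–30%).
One-model-per-query sweeps are the dominant cost; at these sizes the
full three-algorithm sweep runs in roughly fifteen minutes on one CPU,
almost all of it random-forest fits.

## The synthetic cohort

`generate_cohort` emulates the study population's descriptive
structure: per-class truncated-normal ages (63.0 ± 11.6 DM,
57.2 ± 17.1 control, truncated at 18 because an untruncated normal
with SD 17 puts mass on implausible ages — this raises the control
mean by ≈ 0.5 y, which the recovery tests allow for), per-class male
fractions (0.626 / 0.735), 77 labs of which 6 glucose-like items are
shifted by 0.8 pooled SDs in the DM class, and per-code Bernoulli
diagnosis draws with class-specific prevalences over a ~25-code
universe (diabetes block E10–E14 exclusive to cases; comorbidity codes
with diabetes-skewed prevalence; balanced respiratory/hepatic codes).
Every DM patient is guaranteed ≥ 1 E10–E14 code (the label is
diagnosis-defined) and set sizes are kept within a configurable range.
Labs are emitted on an arbitrary raw scale and pass through the same
z-scoring path as real data.

What the generator does **not** emulate: lab-lab correlations (items
are conditionally independent Gaussians), diagnosis co-occurrence
structure beyond class-conditional independence, longitudinal
readmissions, missing values, and coding noise. Passing tests
therefore demonstrate the machinery and the direction of the
selection-strategy effects under clean planted structure, not
real-data effect sizes; in particular, AUC levels on this cohort are
not comparable to EMR results. One consequence is worth stating
plainly: because six clean independent Gaussians carry most of the
signal, a logistic regression fitted on even a small *random* subset
is close to the global optimum, while a similarity-selected subset is
adversarial for a discriminative fit (its minority-class members are
precisely the query's look-alikes, so the boundary passes through the
query's neighborhood). Personalized LR consequently trails random LR
at intermediate K on this cohort even though personalized kNN and RF
dominate throughout — on real, noisy EMR data the small-sample random
LR baseline is far weaker, which is the regime where personalized LR
shines.

## Numerical and design choices

* Canonical code form `[A-Z][0-9]{0,3}`; parsing strips one dot,
  truncates after three digits, rejects non-digits among them.
* The set-similarity formula is implemented as printed above even
  though its identity value requires summing over set *differences*;
  an intersection-only reading would not reproduce FS_D1(X, X) = 1.
* Degenerate inputs: empty diagnosis sets are rejected at validation
  (every cohort patient must carry ≥ 1 code); single-patient pools
  skip z-scoring (center-only) since a variance is undefined.
* Profile ties, kNN distance ties and random draws are all
  deterministic under the master seed; whole sweeps are
  bit-reproducible.
* The χ² screen uses `scipy.stats.chi2_contingency` (with its default
  continuity correction for 2×2 tables); margins with an empty row or
  column are untestable and dropped.

## Known limitations

* FS_L is pool-relative; PS values are not comparable across different
  pools.
* The similarity is unsupervised and unlearned (fixed weights);
  learned metrics are out of scope.
* Model objects are not serialized; one-model-per-query sweeps are
  recomputed per run.
* Only single-level CCS (259 categories) is supported, via a
  user-supplied or bundled prefix crosswalk — not the full official
  ICD-10-CM ontology.
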