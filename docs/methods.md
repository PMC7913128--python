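# Methods

## The screening model

`moscreen` ranks a compound library against a panel of proteins split into
*targets* (activity wanted) and *off-targets* (activity to be avoided).
The input is a probability matrix `P` with one row per compound and one
column per protein: `P[i, j]` is the probability, produced by some
per-protein classifier, that compound `i` is active on protein `j`. How
those classifiers are built is outside this package — any probabilistic
classifier can feed the matrix; the package's job starts at the matrix.

A *screening model* is a bit mask over the columns. Under a mask selecting
`N^P` target columns and `N^O` off-target columns, the desirability of
compound `i` is

    D_i = P_i^P · P_i^O,
    P_i^P = (1/N^P) Σ_j P_{i,j}     over selected target columns,
    P_i^O = (1/N^O) Σ_j (1 − P_{i,j}) over selected off-target columns.

Both factors are means of probabilities, so `D_i ∈ [0, 1]`; the product
form means a compound must simultaneously look active on the chosen
targets and inactive on the chosen off-targets. Masks selecting no target
or no off-target column are *invalid*: one of the two objectives would be
undefined, and silently dropping a factor would collapse the
multi-objective intent. They raise an error in the library and receive a
`-inf` fitness sentinel in the optimizer.

## Early-recognition metrics

Ranking the library by descending `D` (ties broken lexicographically by
compound id, so every score vector has a unique total order) gives a
screen evaluated by:

- **AUAC** `= 1 − mean(x_i)` with `x_i = r_i/N` the relative ranks of the
  `n` known desirables. The `r_i/N` convention is used throughout (not the
  `(r_i − 0.5)/N` variant found elsewhere).
- **EF(χ)**: actives in the top `⌈χN⌉` positions divided by the random
  expectation `χ_eff · n`, with `χ_eff = ⌈χN⌉/N` the fraction actually
  cut. Using the realised cutoff keeps the stated maximum `1/χ_eff`
  attainable exactly; at the published screening scale (N = 14 686,
  n = 19, 6 retrieved in the top 147) this convention prints 31.55 where
  the naive `χ = 0.01` denominator would print 31.58 — the ceil convention
  is the one consistent with the published value.
- **RIE / BEDROC**: `RIE = mean_i e^{−αx_i} / E_uniform[e^{−αx}]`,
  min-max normalised to `BEDROC ∈ [0, 1]` using the closed-form
  `RIE_min/RIE_max` for `n` actives among `N`. All exponential ratios are
  computed with `expm1` so that screening-scale weights (α ≈ 161,
  `e^α ≈ 10^{70}`) cannot overflow.

The weight α is calibrated from `(θ, z)` by solving
`θ(1 − e^{−α}) − 1 + e^{−αz} = 0` with bracketed Brent root search
(residual < 1e−10). The conventional screening setting θ = 0.8, z = 0.01
("80 % of the weight in the top 1 %") gives α = 160.9, the package-wide
default.

## Genetic model selection

The space of masks (2^T models) is searched by a bit-string genetic
algorithm whose fitness is the BEDROC(α) of the mask's desirability
ranking. Defaults follow the published search scale: population 4000,
3000 generations, mutation probability 0.4. Operators not fixed by that
description are standard choices, all exposed in `GAConfig`:

- tournament selection, size 3;
- two-point crossover, probability 0.6;
- mutation applied per individual with probability 0.4; inside a mutated
  individual each bit flips independently with probability 1/T (a 0.4
  *per-bit* rate would be near-random search — the per-individual reading
  is the only one compatible with convergence, and the per-bit rate is
  configurable for anyone wanting the other reading);
- one-elite preservation, which makes the per-generation best-fitness
  trace non-decreasing;
- initial individuals are uniform random bits repaired to validity
  (one random bit of a missing role switched on); during evolution
  invalid offspring are not repaired but scored `-inf`, so lineages can
  cross invalid regions;
- fitness values are memoized by mask — fitness is a pure function of
  (matrix, mask, α), so the cache is behaviour-preserving and makes the
  4000 × 3000 budget tractable (later generations revisit genotypes
  heavily);
- multiple restarts use derived seeds `seed + k` and report the best
  restart's final population.

The high-level interface is a model/results pair:
`DesirabilityScreenGA(matrix, config).fit()` returns a `GAResult` carrying
the best mask, the final population with fitnesses, the fitness trace and
a `summary()` report (BEDROC, EF, AUAC, selected columns per role).

## Consensus analysis

Because many masks achieve similar fitness, downstream analysis uses the
population, not the single best model. Models with BEDROC at or above a
threshold (0.15 at published scale; the comparison is inclusive) are kept
*with duplicates* — a mask's multiplicity in the final population reflects
GA convergence and deliberately weights the statistics. The kept masks are
grouped by agglomerative hierarchical clustering on the raw bit vectors
with Euclidean distance. The linkage is not fixed by the published
description; Ward linkage is the default (the natural partner of Euclidean
distance), with `method="average"` available when matching externally
produced partitions. Per cluster:

- **target relevance** `S_i` = fraction of the cluster's models selecting
  column `i` (the column mean of the bit matrix);
- **global desirability** `GD_i` = the compound's desirability averaged
  over the cluster's models — the consensus repurposing score of a drug
  library (invalid masks inside an externally loaded population are
  skipped with a warning);
- cluster agreement is summarised by top-`n` list overlaps (full Venn
  pattern counts, union and intersection sizes; `n = 50` by default) and
  by pairwise correlation of the clusters' GD vectors (Pearson by
  default; Spearman by flag, since rankings are the object of interest).

ATC-style category tabulation is a plain frequency count over a
caller-supplied drug → codes table (external registries are not queried);
unannotated drugs are tallied separately.

## Bioactivity curation and class balancing

The upstream data path mirrors standard ChEMBL practice. Records carry
IC50/Ki/EC50/GI50 values in μM (helpers convert pM–M); a record is
*active* iff its value is strictly below 10 μM, so exactly 10 μM is
inactive. Replicated (compound, target) reports are collapsed to one
consensus label when the modal label reaches 75 % of the reports,
otherwise the pair is discarded; the operation is idempotent and counts
reports (not unique assays — assay identity is not modelled). Proteins
need at least 100 actives and 100 inactives to survive (inclusive bounds);
blocklisted compounds (approved drugs, the seed drugs defining the target
sets) are removed so the screen cannot be trained on its own evaluation
set. Proteins appearing in both seed-derived sets are assigned the target
role (the seed drugs are in clinical use, so those proteins are evidently
tolerable) and flagged `was_common`.

Class balancing reduces the majority class to the minority count while
preserving its chemical diversity: compounds are 1024-bit Morgan circular
fingerprints of radius 4; PCA is fitted on the pooled matrix (both
classes, so the projection is class-independent) keeping the smallest
number of components with cumulative explained variance above 90 %;
k-means clusters the majority class in that space for k in 3…nPCA+1
(silhouette computed in the same PCA space, maximal value wins, ties to
smaller k, 10 seeded restarts per k); each cluster then contributes a
random sample proportional to its size. Proportional quotas use
largest-remainder (Hamilton) apportionment so they sum exactly to the
minority count — the published procedure does not state a rounding rule,
and largest remainder is the one that conserves the total by
construction. When the k range is unusable (nPCA + 1 < 3, or too few
majority samples) the reduction falls back to simple random undersampling
and says so in the run metadata. The external validation split (25 % by
default) is stratified by class — the split is described only as random,
but stratification keeps external metrics meaningful on balanced data —
with per-class hold-out counts again apportioned by largest remainder.
Records with censored values (e.g. "> 10 μM") are not modelled; callers
must resolve them upstream.

## The synthetic benchmark

`gen_probability_matrix` manufactures the screening input with known
ground truth: M = 2000 compounds, T = 20 columns (14 targets, 6
off-targets), a planted informative subset of 12 targets + 4 off-targets,
and 20 planted actives (1 % of the library — the rarity regime
early-recognition metrics are designed for), signal level 0.9. Cell means
are hierarchical: every cell starts at the background level (0.5, a
coin-flip classifier); actives overwrite the informative cells they carry
signal for with 0.9 on targets and 0.1 on off-targets. Cells then draw
Beta noise around their means — tight for signal cells (pseudo-count 30,
sd ≈ 0.05, the spread of a well-calibrated classifier near a confident
score) and deliberately broad for background cells (pseudo-count 0.5, a
U-shaped distribution mimicking the polarised scores hard classifiers
emit on out-of-domain compounds).

Two design features exist specifically so the benchmark can do its job of
validating the optimizer. With homogeneous tight background noise the
benchmark is degenerate: every mask containing the planted columns ranks
all actives first (BEDROC = 1 ties), nothing distinguishes the planted
structure, and recovery is meaningless. Therefore (i) background cells
are broad, so the decoy tail genuinely overlaps the weakest actives and
averaging over more informative columns measurably suppresses it, and
(ii) each active carries signal on an independent 95 % subset of the
informative columns, so each column is load-bearing for a different
subset of actives. Under these defaults the planted mask scores
BEDROC > 0.5 while remaining strictly fitter than the all-columns mask,
and a small GA (population 200, 100 generations) recovers it to
Jaccard ≥ 0.8 in 8 of the 10 experiment seeds (0–9).

Known limitation: with only 20 actives the fitness functional is noisy,
and the realized-noise optimum can legitimately differ from the planted
mask by ~3 bits; on other seed ranges the ≥ 0.8 recovery rate is closer
to one seed in two. This is a property of the 20-active regime, not of
the optimizer — the GA reliably finds masks at least as fit as the
planted one.

What the generator does **not** emulate: correlated classifier errors
across proteins, compound-series structure (rows are exchangeable),
missing predictions, and real chemistry (SMILES appear only in a tiny
fixed fixture list for fingerprint tests). Passing the synthetic tests
therefore demonstrates the correctness and recovery behaviour of the
pipeline machinery, not the accuracy of any particular classifier panel
on real bioactivity data.

`gen_activity_records` emulates the raw curation input: per
(compound, target) truth label, `replicate_count` measurements drawn
log-uniform on the correct side of the 10 μM threshold, each flipping
side independently with probability `disagreement_rate`. With
disagreement 0 the curation pipeline recovers the truth labels exactly;
with 4 fair-coin replicates the 75 % rule discards the expected ~37 % of
pairs (the 2–2 splits).

## Numerical and degenerate-input choices

- Score ties are broken by compound id before ranking (BEDROC needs a
  total order; reproducibility over arbitrary dictionary order).
- `RankedScreen` requires `1 ≤ n < N`; `n = N` collapses the BEDROC
  bounds and is rejected rather than patched.
- α must be positive; the α solver requires θ > z (otherwise no positive
  root exists) and verifies its residual.
- Probability matrices must be complete — loaders reject missing cells
  rather than imputing.
- The balancing PCA keeps `min(nPCA, available components)`; silhouette
  needs 2 ≤ k ≤ m−1 and the k range is clipped accordingly.
- Seeds: every stochastic routine takes an explicit integer seed; the
  pipeline derives per-stage seeds (< 2^31) from one master seed, so a
  rerun of a config is byte-identical.

## Scales used in the shipped experiments

The shipped tests validate the metric formulas exhaustively at
enumerable scale (all active placements for N ≤ 8, n ≤ 3), the
desirability aggregation against a scalar double-loop oracle, and the GA
on the 2000 × 20 benchmark with population 200 for 100 generations —
sizes chosen so the whole suite runs in about a minute on one CPU while
exercising the identical code paths used at the published scale
(14 686 × 55, population 4000, 3000 generations). The full-scale
configuration itself is smoke-checked by evaluating a 4000-individual
population at generation zero. The published-scale numbers (best-model
BEDROC 0.258, EF_1% 31.55, AUAC 0.831, 275 selected models, 71/36 top-50
overlap, mean GD correlation 0.962) are recomputed by
`tests/test_acceptance.py` only when the original supplementary archives
are placed under `data/supplementary/`; they are not redistributable with
the package, so that check reports failure in their absence instead of
passing vacuously.
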