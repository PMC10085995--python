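# Methods

## Model and assumptions

The enrichment sphere model treats a multi-biome metagenome collection as a
single pooled urn of annotated reads. Per-sample relative abundances of GO
terms (and of species) are converted to integer counts by multiplying by
the sample's total read depth and rounding (ties half-away-from-zero, so
the rule is reproducible across languages), then summed within each biome.
For feature *f* and biome *b* this yields the urn quantities
`k = counts[f, b]`, `K = row total`, `n = biome total`, `N = grand total`,
and the one-sided exact over-representation test is the hypergeometric
upper tail `P(X >= k)`. Under-representation is deliberately not tested:
the question is which biome a function or species concentrates in. The
enriched call uses the strict inequality `p < alpha` with `alpha = 0.01` by
default and no multiplicity correction, mirroring standard practice for
this kind of exploratory mining; Benjamini–Hochberg q-values can be
attached (`adjust_bh`, `--bh`) and optionally used for calling.

The urn convention — background = all features pooled over all biomes,
draw = one biome's reads — is a modeling choice; its null holds exactly
when reads are multinomial draws from biome-independent proportions
(conditionally on the margins, each cell is then Fisher-exact
hypergeometric).

### Sphere p-value

Joint enrichment of a term set *S* is evaluated under the central
multivariate hypergeometric urn whose colors are the members of *S* plus a
pooled "other" color, with draw size `n_biome`. The test statistic is the
pooled member count `T = sum_m k_m`. The pooling (lumping) identity of the
multivariate hypergeometric makes `T` univariate hypergeometric with
success count `sum_m K_m`, so the sphere p-value has an exact closed form
and no resampling is needed. A seeded Monte-Carlo sampler of the actual
multivariate urn (`numpy`'s `multivariate_hypergeometric`) is kept in the
test suite as an independent cross-check of this identity; it is never the
implementation.

Among statistics available under the central model, the pooled count is
the one that yields an exact closed form; alternatives (e.g. the minimum of
member-wise p-values, or biased-urn models with odds weights) would require
calibration by simulation and are out of scope.

### Greedy expansion and its stop rule

Expansion starts from every enriched term (seeds processed in ascending
univariate p, ties by term id) and repeatedly evaluates the frontier of the
current sphere: all distance-1 neighbors in the `is_a` DAG (parents and
children — "ontologically adjacent" is read as distance 1 in either
direction), restricted to the seed's namespace and to terms present in the
count table. The candidate minimizing the sphere p-value is added, with
lexicographic tie-breaking, and the failing candidate is never included.

Two gates control the stop:

1. the sphere p-value must stay below alpha, and
2. by default it must also **strictly decrease** with each addition
   (`require_improvement=True`).

The second gate is a deliberate design decision. With deeply sequenced
data a genuinely enriched sphere reaches p-values around 1e-100 or below;
from there the pooled tail stays under any fixed alpha through dozens of
diluting additions, so a threshold-only rule degenerates into absorbing
entire namespaces. Requiring strict improvement keeps spheres tight around
terms that actually share the enrichment signal, reduces to the
threshold-only behavior in the marginal regime, and never ejects a seed
(the final p is at most the seed's p, which already passed alpha). Setting
`require_improvement=False` restores the threshold-only rule for
comparison.

A second greedy pathology is handled at the pipeline level: a marginal
(noise-level) seed adjacent to a strong sphere would always "improve" by
annexing the strong sphere's members, after which merging would fold the
noise term into the real sphere. `build_sphere_model` therefore fences off
terms already claimed by an earlier (lower-p) sphere in the same biome
(`exclude` argument of `expand_sphere`). Residual overlaps are resolved by
`merge_spheres`: same-biome, same-namespace spheres sharing a member are
unioned when the union still passes the gate, to a fixed point;
a union that fails leaves the originals in place.

### Host linkage

Candidate hosts of a sphere are the species owning at least one gene
annotated to a member term (gene -> term -> species map). Each candidate is
tested univariately on the species count table in the sphere's biome and
attached when `p < alpha`. The species urn is the species' full abundance;
gene ownership acts as a linkage filter, not as a conditioning of the urn
(the alternative — restricting the urn to annotation-bearing reads — would
require per-gene read assignments the input tables do not carry).

### Supplementation rule

For a protein family with homolog counts per biome, the biome with the
strictly maximal count is selected and the supplemented alignment size is
`reference + selected count`; a tie yields an explicit no-selection result.
On the published counts for the copper-resistance family PF12597
(Soil 183, Freshwater 125, Gut 39, Engineered 68; reference 182) this
selects Soil and reports 365.

## Biome classifier

Features are the relative abundances of the enriched GO terms (union of
sphere members) and/or the enriched host species from a fitted model;
absent features impute 0. The classifier is a 100-tree random forest
evaluated by stratified 10-fold cross-validation; within each training
fold a grid search over `max_depth in {None, 8, 16}` x
`max_features in {sqrt, log2}` is scored by inner 3-fold accuracy (the
grid is a fixed, recorded choice — small enough to be cheap, wide enough to
matter). Out-of-fold class probabilities are pooled into single per-class
one-vs-rest ROC/AUC values plus micro (all sample x class decisions
pooled) and macro (unweighted class mean) averages; accuracy and F1 come
from pooled out-of-fold hard predictions. Micro-averaged recall equals
accuracy identically in this single-label setting and is asserted as such.
A class whose pooled probability column is exactly constant gets AUC 0.5
by the tie convention. Stability selection uses 50 stratified
half-subsamples, records the top-20 features by impurity importance per
fit, and selects features recorded in >= 60% of subsamples; all three
numbers are exposed as arguments.

## Synthetic data generator

The generator emulates the structure the miner assumes, with planted
ground truth for scoring:

- **Ontology**: per namespace one root; each new term draws
  `1 + Poisson(mean_parents - 1)` parents uniformly from its namespace
  (acyclic by construction). Defaults: 845 terms — matching the number of
  GO annotations retrieved in the four-biome survey the method targets —
  in the three GO namespaces, `mean_parents = 1.5`.
- **Truth**: `n_spheres = 5` connected, pairwise-disjoint member sets of
  size 3–6 assigned round-robin to the four biomes (Engineered,
  Freshwater, Gut, Soil), each with effect multiplier 5; two planted host
  species per sphere share its biome and effect and are linked to its
  member terms through the gene map. Baselines are flat Dirichlet draws
  over 845 terms / 300 species.
- **Counts**: per sample, expected proportions are the baseline with that
  biome's planted features multiplied by the effect and renormalized;
  sample proportions are `Dirichlet(concentration x expected)` and counts
  `Multinomial(depth, proportions)`. Defaults: 30 samples/biome, depth
  5x10^4, concentration 1e5 (per-sample compositional noise of roughly 10%
  on a typical term — profiles treated as batch-corrected replicates of a
  biome-level composition); `concentration=None` gives the exact
  multinomial limit used for null calibration.

Renormalization after the effect multiplication means the realized
between-biome fold of a planted term is below the nominal effect (about
3.5–6.5 for effect 5 at the defaults); tolerance windows in the tests
account for this.

Recovery scoring matches each planted sphere to the same-biome recovered
sphere with maximal member overlap; member precision/recall/F1 are
computed on matched pairs and an unmatched planted sphere scores zero.

### What the generator does and does not emulate

It reproduces the features the method relies on: biome-labeled samples,
DAG-adjacent co-enriched term sets, linked host species, multinomial read
sampling with tunable overdispersion. It does **not** emulate real GO term
frequency spectra, biome sub-structure (samples within a biome are
replicates of one composition), batch effects, or compositional coupling
beyond the closure constraint. Two sensitivities discovered while
validating at scale are worth stating plainly, because passing tests on
synthetic data do not certify them away on real data:

- **Compositional leakage.** Planting a large compositional displacement
  (few features at high baseline abundance and strong effect) depletes all
  other features in that biome, which at millions of pooled reads makes
  *every* feature significant somewhere. At the default scale (845 terms,
  per-term baseline ~0.12%) the displacement is negligible, but on real
  data with dominant features the pooled-urn test inherits this artifact.
- **Overdispersion miscalibration.** The hypergeometric null assumes
  multinomial sampling. Strong Dirichlet-multinomial dispersion (small
  concentration) inflates the false-positive rate of every test in the
  pipeline — visible in the summary as single-term spheres with p just
  below alpha. The null-calibration guarantee (false-positive rate <=
  1.5% at alpha = 0.01) holds in the multinomial limit, which is how it is
  tested.

## Numerical choices

- `hypergeom_tail` validates the urn bounds, returns exactly 1.0 at the
  lower support bound, and is computed as an exact tail sum: a
  closed-form survival function while it has floating-point headroom
  (>= 1e-250), otherwise a truncated log-space sum of log-pmf terms with
  geometrically growing chunks, truncated past the mode once a chunk falls
  40 nats below the running total. A `log=True` variant keeps tails far
  below 1e-308 finite and strictly ordered; sphere expansion compares
  candidates in log space so underflow cannot erase the greedy ordering.
- All iteration orders are fixed (feature order x lexicographic biome
  order; sorted frontiers; lexicographic tie-breaks), making every fit
  bit-reproducible; the only randomness anywhere is in the generator and
  the classifier, both fully seeded.
- Biome columns are ordered lexicographically so aggregation is invariant
  to sample order.
- Features with zero counts in every biome have an undefined test and are
  recorded with p = 1.0 and a `skipped` flag; fold is defined as
  `(k/n)/(K/N)` and 0 when `K = 0`.
- Proportions may sum to less than 1 (unclassified mass); a column sum
  above `1 + 1e-6` is an error.
- JSON writers emit floats via `repr` (bit-exact round trips) and NaN
  metrics as `null`.

## Problem sizes in the validation suite

The acceptance-level tests run the exact-oracle grid at N <= 25
(exhaustive), Monte-Carlo cross-checks at 1e5 draws x 10 urns, null
calibration at 4 biomes x 20 samples x 200 terms x depth 1e4 x 10 seeds,
planted recovery at the full benchmark conditions over 20 replicates, and the
classifier comparison on one full-scale planted dataset with 10 label
permutations; `scripts/acceptance.py` uses 5 recovery replicates and 3
permutations. These sizes were chosen to give stable means at interactive
runtimes.

## Known limitations

- The pooled-urn null ignores within-biome sample variance entirely
  (counts are summed before testing); any real overdispersion appears as
  excess significance. A Dirichlet-multinomial or CAMP-style test would be
  the natural extension.
- Sphere membership is greedy and order-dependent by construction;
  determinism is guaranteed, global optimality is not (an exhaustive
  connected-subset oracle in the tests bounds the gap on toy instances).
- Sphere labels ("detoxification", "ion binding" and the like) are a
  presentation concern left to the user; the model emits member ids and
  names only.
- `part_of` and other non-`is_a` relations are ignored; namespaces are
  hard boundaries.
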