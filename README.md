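# enrichsphere

Mining biome–species–function enrichment patterns from metagenome profiles.

Microbial species and their functional genes are not spread evenly across
habitats: copper-resistance functions concentrate in soil, flagellar
functions in freshwater, fiber degradation in the gut. `enrichsphere`
formalizes this observation as an **enrichment sphere model**: for each
habitat *biome* it finds the Gene Ontology (GO) terms whose pooled read
counts are over-represented there, grows each enriched term into a
*function sphere* — a connected set of GO terms in one namespace that is
jointly enriched — and links the enriched host species that carry genes
with those functions. The fitted model supports two downstream
applications: identifying the biome of a new metagenome sample from its
enriched-feature profile, and choosing which biome's metagenome to mine for
extra homologous sequences of a protein family (e.g. to deepen an alignment
before structure prediction).

It is intended for microbial ecologists and bioinformaticians working with
biome-labeled abundance tables (GO-term and species profiles such as those
derived from MGnify metagenomes), and ships a synthetic benchmark generator
with planted ground truth so every stage is testable end to end.

## The statistics

**Univariate enrichment.** Abundance proportions are converted to integer
read counts (`round(proportion x read_depth)`) and pooled per biome. For a
feature *f* and biome *b* the counts form an urn: *N* pooled reads in
total, *K* of them belonging to *f*, *n* in biome *b*, *k* of those from
*f*. The one-sided exact test is the hypergeometric upper tail

```
p = P(X >= k),   X ~ Hypergeometric(N, K, n)
```

computed in log space so values far below double-precision underflow remain
ordered. A feature is *enriched* in *b* when `p < alpha` (default 0.01).
Benjamini–Hochberg q-values are available behind a flag.

**Sphere expansion.** For a member set *S* of GO terms, joint enrichment is
judged under the central multivariate hypergeometric urn (colors = member
terms + one pooled "other"); the statistic is the pooled member count,
which by the pooling identity is again univariate hypergeometric with
`K = sum K_m` and `k = sum k_m`. Starting from each enriched seed term the
expansion repeatedly adds the neighboring term (distance 1 in the `is_a`
DAG, either direction, same namespace) that minimizes the sphere p-value,
as long as the p-value stays below alpha **and strictly improves**;
overlapping spheres in one biome/namespace are merged when their union
still passes the gate. Host species are attached when they own a gene
annotated to a member term and are themselves enriched in the sphere's
biome.

**Biome identification.** A random forest on the relative abundances of the
enriched GO terms and/or enriched host species, evaluated by stratified
10-fold cross-validation with an inner grid search, reporting per-class
one-vs-rest ROC/AUC plus micro- and macro-averages from pooled out-of-fold
probabilities. Stability selection (repeated stratified half-subsampling)
is available for picking a robust feature subset.

## Worked example

```python
from enrichsphere.synthetic import make_ontology, plant_truth, simulate_dataset, score_recovery
from enrichsphere.model import EnrichmentSphereModel

graph = make_ontology(n_terms=845, seed=7)                 # random is_a DAG
truth = plant_truth(graph, n_spheres=5, seed=7)            # planted ground truth
terms, species, samples, gene_map = simulate_dataset(truth, seed=7)

model = EnrichmentSphereModel(terms, graph, species, gene_map)
results = model.fit(alpha=0.01, seed=7)
print(results.summary())
```

prints (abridged):

```
Enrichment sphere model
=======================
alpha = 0.01, spheres = 92, enriched terms = 429, enriched hosts = 10

biome        namespace              size    p_value  members (seed first)
------------------------------------------------------------------------------------------------
Engineered   biological_process        6          0  T:000259,T:000541,T:000637,T:000544,T...
             host: SP:0084 (p = 0)
             host: SP:0103 (p = 0)
Engineered   molecular_function        3          0  T:000204,T:000582,T:000396
...
```

The large, near-zero-p spheres with linked hosts are the planted signals
(the display shows underflowed p-values as 0); the many single-term spheres
with p just below 0.01 are the expected false positives of an exact test
run over thousands of deeply sequenced cells. Scoring against the truth and
classifying the samples:

```python
rep = score_recovery(results.sphere_model, truth)
# recall 1.00  precision 1.00  host recall 1.00
report = results.classify(variant="both", seed=7)
# accuracy 1.000  micro-AUC 1.000  macro-AUC 1.000
```

The supplementation rule, on the published per-biome homolog counts for the
copper-resistance family PF12597 (183 in Soil vs 125/39/68 elsewhere,
reference alignment 182):

```bash
$ enrichsphere select-biome --counts Soil=183,Freshwater=125,Gut=39,Engineered=68 --reference 182
{
  "biome": "Soil",
  "supplemented_total": 365,
  ...
}
```

The same pipeline is scriptable from the shell: `enrichsphere simulate`,
`enrichsphere enrich`, `enrichsphere mine`, `enrichsphere classify` — see
`--help` for flags (`--alpha`, `--bh`, `--trace`, `--features`, `--trees`,
`--folds`, `--seed`).

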