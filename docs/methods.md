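# Methods

## Model

`symgene` prioritizes genes for a clinical symptom *s* by propagating a
disease-derived prior over a PPI network. The inputs are a record corpus (or
a precomputed symptom-disease similarity table), a disease→gene map *B*, an
undirected PPI *G = (V, E)* with adjacency *W*, and optionally a benchmark
of curated symptom-gene pairs.

**Co-occurrence and similarity.** A record is a set of symptom terms and a
set of disease terms observed in the same bibliographic entry; counting is
presence-based (a term twice in one record counts once) and at whole-record
granularity. The profile of an entity is the vector of its record-level
co-occurrence counts with each vocabulary symptom; the self-coordinate of a
symptom's profile is defined as its document frequency, the natural *j = i*
case of "records containing both *i* and *j*". Similarity is the cosine of
two profiles; a zero-norm profile yields similarity 0 rather than an error
so that rare terms cannot abort a batch run. Zero-similarity pairs are
omitted from the table. Only symptom-disease similarities are computed;
symptom-symptom and disease-disease similarities play no role in the model.

**Prior.** The candidate pool is every pair with similarity strictly above
`min_similarity` (default 0.1). The cutoff is the smallest pool value such
that at least `top_fraction` (default 0.10) of the pool is ≥ it — a closed
upper tail with no interpolation, chosen for exact reproducibility. The pool
and cutoff are global over all pairs by default (matching a single
dataset-wide threshold); a per-symptom mode is available via
`PriorConfig(scope="per-symptom")`. For a query symptom the
`top_k_diseases` (default 10) most similar diseases at or above the cutoff
are kept, ties at the truncation boundary broken toward the
lexicographically smaller disease id. The prior is binary: *Y(g) = 1* iff
*g* is associated with a selected disease and present in *V*. A
similarity-weighted prior (*Y(g)* = the maximum similarity among selected
diseases carrying *g*) is implemented behind `weighted=True` but is off by
default, since the binary prior is the base method.

**Normalization and propagation.** *W′ = D^{-1/2} W D^{-1/2}* with *D* the
weighted-degree diagonal; rows of isolated nodes are zero. This symmetric
normalization bounds the spectral radius of *W′* by 1, so the update
*Fₜ = α W′ Fₜ₋₁ + (1 − α) Y* is a contraction for α < 1 and converges to
*(1 − α)(I − α W′)⁻¹ Y* geometrically with ratio ≤ α. A row-stochastic
alternative is exposed as a config option. Edge weights default to 1;
self-loops are dropped at load time and duplicate/reversed edges collapsed.
Gene identifiers are matched case-insensitively after trimming.

**Outputs.** Ranked genes (score descending, gene id ascending on ties, so
output is bit-reproducible) with 1-based consecutive ranks; *potential
genes* are those scoring strictly above `score_cutoff` (default 0.01).
Output tables label the score column "correlation", the customary heading
for these propagation scores; they are not statistical correlations.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `min_similarity` | 0.1 | floor of the similarity pool (cosine, unitless) |
| `top_fraction` | 0.10 | fraction of the pool above the cutoff |
| `top_k_diseases` | 10 | diseases seeding each symptom's prior |
| `alpha` | 0.9 | weight of network smoothing vs prior |
| `tolerance` | 1e-9 | L1 convergence threshold of the iteration |
| `max_iterations` | 1000 | iteration cap (ample: decay ratio ≤ 0.9 needs ~200 steps for 1e-9) |
| `score_cutoff` | 0.01 | potential-gene threshold (strict >) |

On non-convergence the last iterate is returned with `converged=False` and a
warning — never silently.

## Evaluation

Recall is 100·|list ∩ benchmark|/|benchmark|. AUC is the Mann-Whitney
statistic computed from midranks (ties contribute 1/2); positives are the
benchmark genes present in *V*, negatives all other network genes, and
benchmark genes without a score are excluded but counted in the report. For
multi-symptom runs the default pools every (score, label) pair into one
statistic; a per-symptom mean is available. Fold enrichment uses the
analytic hypergeometric mean (per-gene probability × list size); a seeded
Monte-Carlo mode cross-checks it by simulation. Reports print the per-gene
probability to 7 decimals and the expected overlap to 3.

The headache and hemiplegia worked examples ship with partly reconstructed
benchmarks: only some members of the curated sets are public, and the
unnamed remainder are SYNTH-* placeholder identifiers chosen to match
nothing in the candidate lists, which preserves every overlap count and
recall exactly.

## Synthetic data

The generator plants a known symptom→gene signal: each symptom is linked to
`diseases_per_symptom` (3) diseases; genes are partitioned into contiguous
per-disease modules; the PPI is a stochastic block model (within-module edge
probability 0.30, between 0.01) plus a spanning chain per module so every
module is connected — mirroring the premise, which propagation exploits,
that causal genes of one phenotype interact. Each of the 2,000 corpus
records names one primary disease and, with probability `signal_strength`
(0.9), each symptom linked to it; background mentions (symptom rate 0.02,
disease rate 0.005 per record) emulate incidental co-citation. Defaults —
20 symptoms, 60 diseases, 500 genes — are a desk-scale rendition of the
hundreds-of-symptoms / thousands-of-genes shape of the real data layers. A
`benchmark_dropout` knob removes a fraction of true genes from the benchmark
to emulate the incompleteness of curated symptom-gene resources.

What the generator does **not** emulate: real MeSH-style vocabulary
structure, citation dynamics, scale-free PPI degree distributions,
overlapping disease modules, or identifier noise. Passing the
planted-recovery tests therefore demonstrates that the implementation is
correct and that the method recovers modular signal under its own
assumptions — not that it attains any particular accuracy on real
literature and interaction data.

With `signal_strength=0` planted records never mention their symptom, so
similarities carry no information about the planted modules and the
pipeline scores at chance (mean AUC ≈ 0.5); this null is the bias control
for the evaluation stack.

## Numerical choices and degenerate inputs

- Fixed-point checks compare the iterate against a dense
  `numpy.linalg.solve` of *(I − αW′)F = (1 − α)Y* (tolerance 1e-8).
- A corpus with zero records but explicit vocabularies yields all-zero
  profiles, not an error; an empty similarity pool, an unknown symptom, and
  a prior with no seed genes in *V* raise typed errors so batch drivers can
  skip and log (as `run_pipeline` does).
- Disease-gene rows whose gene is absent from the PPI are retained in the
  association map but flagged; they never enter *Y*.
- Shortest-path classification is unweighted; a node *x* is on a shortest
  path between causal genes *a, b* iff *d(a,x) + d(x,b) = d(a,b)*, computed
  per connected component (cross-component pairs contribute nothing).

## Known limitations

- The global-pool quantile cutoff assumes similarity scales are comparable
  across symptoms; per-symptom scope is provided but untested against any
  reference outcome.
- The binary prior discards similarity magnitude; the weighted variant is
  experimental.
- Pooled AUC mixes score scales across symptoms; with the binary prior the
  scales are comparable, but the per-symptom mean mode is safer when priors
  differ strongly in seed count.
- Runtime of the shortest-path classification is quadratic in the number of
  causal genes times BFS cost; it is intended for symptom-sized disease
  sets, not genome-wide sweeps.
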