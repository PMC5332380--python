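# Methods

## Study design the package assumes

Three conditions — control/sham, disease model, treated — with a handful of
biological replicates each, profiled as gene-level counts (tag-based or
read-based RNA sequencing).  The analysis asks which functional gene groups
the treatment reverts toward the healthy state and ranks those groups by how
strongly their members dominate the co-expression network's hub structure.

## Differential expression and reverse regulation

The DE stage is pluggable: precomputed tables (gene, log2fc, pvalue, fdr)
from any external tool are ingested verbatim.  The built-in test exists so
the pipeline runs end to end on counts alone:

- **Normalization.**  Within the DE test, samples are scaled by
  median-of-ratios size factors (median ratio to the per-gene geometric
  mean over genes expressed everywhere).  Per-million (TPM) scaling, which
  the package exposes as `normalize_tpm` and uses for the co-expression
  stage, is *not* robust here: when hundreds of genes shift strongly in one
  direction, per-million renormalization induces an apparent fold change in
  every unchanged gene.
- **Test.**  Unequal-variance t on log2(normalized + 1), with
  empirical-Bayes variance moderation: each group's variance is shrunk
  toward the median variance of similarly abundant genes (20
  abundance-quantile bins) with `prior_df = 4` prior degrees of freedom,
  added to the Welch–Satterthwaite df.  At triplicate designs a raw
  per-gene variance has 2 df and essentially no power; the trended prior
  restores power while keeping null p-values slightly conservative
  (measured: 0.1% of null genes below p = 0.005).  `prior_df = 0` recovers
  the plain Welch test.
- **Calls.**  FDR < 0.10 (Benjamini–Hochberg) *and* |log2FC| > 0.58, both
  strict, each gene tagged by sign.  Thresholds are parameters.
- **Reverse-regulated set.**  Genes significant in both contrasts with
  opposite signs.  Direction labels anchor on the treatment contrast: a
  gene up in disease and down under treatment is `inversely_down`.  The
  anchoring is a convention (the mirror reading exists); it is configurable
  by swapping the inputs.

A pseudocount of 1 is added before the log transform; genes flat in both
groups get log2fc 0 and p 1.

## Co-expression network

Pearson correlation across all samples of all three conditions pooled
(condition-driven variation is signal here: reverse-regulated genes
correlate through their shared condition profile, which is precisely the
structure the hub analysis consumes).  Two-sided p from
t = r√((n−2)/(1−r²)) on n−2 df, |r| = 1 clipped to p = 0.  BH adjustment is
joint over all tested pairs; edges kept at q < 0.05 strict; negative
correlations are edge-eligible and keep their sign as an edge attribute.
Zero-variance genes cannot be correlated and are dropped from pairing (not
assigned r = 0); they remain isolated nodes.

## Keystone selection

PageRank with damping 0.85 and uniform teleport (canonical defaults;
recorded in the run manifest), isolated nodes handled as dangling.  Ties in
score order break by gene identifier, so rankings are pure functions of the
graph.  The targeted-attack curve removes nodes in ranking order and
records the largest-connected-component fraction **among remaining nodes**
(denominator = remaining count, making the threshold rule scale-free);
the k = N point is 0 by convention.  The curve is computed backwards with a
union-find (re-inserting nodes), costing near O(V+E) rather than N
component scans.  The keystone set is the smallest prefix whose removal
drives the fraction below θ = 0.10; if the curve never crosses θ the
maximum-curvature (largest discrete second difference) point is used
instead, with a logged warning.  θ is a declared operational choice — dense
co-expression networks often stay connected until most nodes are gone, in
which case the rule selects most of the ranking; hub sets covering the
large majority of such networks' nodes are typical.

## Pathway groups

Over-representation is the hypergeometric upper tail (ties at the observed
overlap included) of query ∩ pathway within a declared universe, p < 0.05
strict.  Enriched pathway graphs (from KGML — gene entries become nodes,
relations become edges, compounds/maps dropped — or from edge-list TSV) are
merged into one undirected simple background graph with per-node pathway
provenance; a pathway without topology contributes nothing (a gene set is
not a graph; the clique fallback is deliberately off).  The responsive
genes induce a sub-network, partitioned by the leading-eigenvector method:

- connected components are processed independently; singletons are groups;
- within a component, the generalized modularity matrix
  B^(g) = [A_ij − k_i k_j/2m] − diag(row sums) is built with whole-graph
  degrees, its leading eigenpair taken from a dense symmetric
  eigendecomposition (deterministic and exact at these problem sizes —
  sub-networks here are tens to hundreds of nodes — in place of an
  iterative solver), and the component splits by eigenvector sign, exact
  zeros joining the positive side;
- each split is fine-tuned by Kernighan–Lin sweeps (every vertex flipped
  once greedily, best intermediate state kept, repeated while the
  objective s^T B^(g) s improves);
- recursion stops when the leading eigenvalue ≤ 1e−8 or the fine-tuned
  split no longer increases modularity.

The fine-tuning step matters: on small random graphs the refined partition
attains the exhaustive-search maximum bipartition modularity, and on
planted-partition graphs it recovers partitions at or above the modularity
of igraph's implementation of the same method (both verified in the test
suite).

## Group significance

Scaling is min–max over the full GCN ranking: s = (score − min)/(max − min);
a degenerate all-equal ranking maps to all zeros with a warning.  The
priority list L contains the keystone genes present in the sub-network,
score-descending, identifier-ascending on ties.  For a group C with
N_group = |C| and N_diff = |C \ L|, the running sum over positions
i = 1…N_genelist gains s_i on hits and loses N_diff/(N_genelist·N_group) on
misses; ES is the maximum over i ≥ 1 (no i = 0 term, so a group disjoint
from L scores negative, not zero).  When N_diff = 0 the penalty vanishes
and ES is simply the sum of the members' scaled scores.

N_diff is read as |C \ L| rather than the symmetric difference: the
symmetric reading would add |L \ C|, a group-independent constant that
swamps the per-group signal.

The null samples B = 10,000 groups of size N_group uniformly **without**
replacement from *all* background-network nodes — not just from L — so the
null is sensitive to how much of the background lies outside the keystone
list, and re-scores each against the same L (vectorized: one B × N_genelist
hit matrix per group size; nulls are shared across groups of equal size,
with per-size seeds derived from the run seed).  Nominal
p = #(ES_null ≥ ES)/B with ties in the numerator; a zero count is stored as
0.0 and *rendered* as `<1/B` in text output.  Simes–Hochberg step-up
adjustment (adjusted p_(i) = min_{j≥i}(m−j+1)p_(j), via statsmodels) across
all tested groups; significance at adjusted p < 0.005 strict.

## Synthetic data generator

Emulates the statistical shape of a small tag-sequencing experiment:

- counts are gamma–Poisson (negative binomial, Var = μ + φμ², φ = 0.05)
  around log-normal per-gene baselines (ln-mean 5.0, ln-sd 1.2, ≈ 300
  counts/gene, matching ≈ 3 M tags over ≈ 10.5 k genes), with per-sample
  library sizes uniform within ±20%;
- `n_perturbed` genes (default 800) get a ±`effect_log2fc` (default 3.0)
  shift in the disease condition; a `restored_fraction` (default 0.625,
  i.e. 500 genes) return to baseline under treatment, the rest keep the
  disease mean;
- co-expression modules share a per-sample latent factor on the log scale
  with amplitude `block_factor_sd` = 0.8 nat and weight √ρ; the amplitude
  deliberately dominates count noise so the realized count-level
  correlation stays near the configured `block_correlation`
  (≈ 0.92ρ after Poisson attenuation);
- pathway gene sets (default 15, sizes 10–40) draw half their members from
  a supplied ranking hint so enrichment is non-trivial; each pathway graph
  is a random spanning tree plus chords (always connected); one planted
  group (default size 10 from the top 15 of the hint) is wired densely
  inside its pathway so community detection can isolate it.

What the generator does **not** model: realistic pathway topology, gene
length or GC effects, batch structure beyond library size, dispersion
trends, or correlated perturbation directions.  Passing tests therefore
demonstrate algorithmic correctness and end-to-end recoverability of
planted structure under clean negative-binomial noise — not performance on
any particular real tissue.

## Problem sizes and determinism

Default conditions run the full pipeline (10,515 genes, B = 10,000) in
seconds on one core; the test suite uses 300–2,000-gene configurations for
unit-level checks and the full default for the determinism check.  Every
stochastic step (generator, random attack mode, Monte Carlo null) is driven
by explicit seeds recorded in the run manifest; reruns with the same
configuration are byte-identical in all tables.

## Known limitations

- The built-in DE test is a moderated t on log counts, not a count-model
  GLM; at triplicates its power profile differs from a negative-binomial
  fit, which is why the interface accepts external tables.
- The keystone threshold θ has no inferential interpretation; it is an
  operational cut on a descriptive curve.
- The Monte Carlo p floor is 1/B; groups below it tie at the floor and are
  distinguished only by ES.
- Leading-eigenvector detection is deterministic but, like all modularity
  methods, resolution-limited; very small true groups inside large dense
  components may not separate.
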