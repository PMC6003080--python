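# Methods

## The model

`hfe` treats a microbiome classification task as a feature-engineering
problem over a rank-based hierarchy. The inputs are an OTU abundance table
(n samples × m OTUs), a categorical label per sample (≥ 2 classes), and a
Greengenes-style taxonomy: seven named ranks (kingdom, phylum, class, order,
family, genus, species) with an eighth, OTU, level at the bottom. Lineages
may stop early — an OTU confidently classified only to family attaches
directly under its family node and is a *leaf in an incomplete path*.
Placeholder tokens (`s__` with no name) denote absent ranks, not taxa:
aggregating under an unnamed taxon would create meaningless features. A
virtual super-root above kingdom keeps multi-kingdom tables in one tree; it
is never a candidate feature and is excluded from all feature counts.
Internal nodes are identified by their full rank-prefixed path
(`k__Bacteria;p__Firmicutes;...`), so a genus name recurring under two
families yields two distinct features.

All abundances are per-sample relative (rows sum to 1). Counts are converted
on input; an all-zero sample is rejected because its composition is
undefined.

### Phase 1 — aggregation

Each named taxon becomes a candidate feature whose column is the sum of its
children's columns, computed bottom-up so every parent sums already
aggregated children exactly once. Equivalently, a taxon's column is the sum
of its descendant OTUs; in a single-kingdom table the kingdom aggregate is
identically 1. The space grows from m to m + m′ features.

### Phase 2 — correlation-based child pruning

For every parent–child edge (the child being an internal taxon or an OTU
leaf), Pearson ρ between the two columns is computed over the training
samples. The child is discarded iff ρ > θ, strictly; ρ = θ keeps the child.
θ defaults to 0.7 — values 0.6–0.8 behave equivalently in practice, and the
filter is a redundancy heuristic, not a network-inference step. Only the
*immediate* parent is compared: incomplete-path leaves sit far from their
remote ancestors precisely because intermediate ranks are missing, and
comparing across ranks would conflate redundancy with dilution. Three
deliberate conventions:

- an undefined ρ (zero-variance column, e.g. the kingdom aggregate) counts
  as 0, keeping the child — conservative for constant-vs-variable pairs;
- the comparison is signed, not absolute: an anticorrelated child is
  informative, not redundant;
- discarded nodes leave the candidate *feature* set but remain in the
  *tree*, so phase-3 paths still traverse them; the feature-space arithmetic
  subtracts s₁ from the feature count, not from the hierarchy.

### Supervised discretization and information gain

IG is defined for discrete features, so every continuous column is first
discretized against the training labels by recursive binary splitting:
candidate cuts are midpoints between adjacent distinct sorted values, the
cut minimizing the class-weighted entropy is taken, and it is accepted only
when its gain exceeds the minimum-description-length bound

    gain > ( log2(N−1) + log2(3^k − 2) − [k·H(S) − k1·H(S1) − k2·H(S2)] ) / N

(k, k1, k2 = classes present in the subset and its two halves), recursing
into both halves on acceptance. Ties in entropy break toward the lowest cut
value, making the procedure fully deterministic; constant features yield no
cuts. IG is then `H(L) − Σ_b (n_b/n) H(L|b)` in bits over the induced bins;
a feature with no accepted cut has exactly IG 0. The scheme handles any
number of classes. The test suite validates the implementation exhaustively
against a naive reference over all small inputs (~23 000 cases).

### Phase 3 — IG path filtering

Every OTU's lineage defines a root-to-leaf path (including the OTU itself
when its lineage is complete). On each path, the mean IG of the
phase-2-retained nodes is the threshold; a node survives if on at least one
path through it IG ≥ mean and IG > 0. Zero-IG nodes are always discarded;
ties at the mean are kept. Two open readings existed here: averaging per
path versus one global average, and how to adjudicate a node shared by
several paths. The default is per-path averaging with an any-path keep
rule — the phase-4 wording explicitly invokes a *global* average, and the
contrast motivates reading phase 3 per path — but both strategies are
implemented (`phase3_average="per-path" | "global"`) and exposed on the CLI.
Leaves of incomplete paths are exempt from this phase entirely: they are
neither filtered nor counted in path means, since they are adjudicated by
phase 4 and letting an unfilterable node drag a path mean would couple the
two phases.

### Phase 4 — incomplete-leaf filtering

Incomplete-path leaves that survived phase 2 are kept iff IG > 0 and
IG ≥ the global mean IG of the phase-3 survivors (0 when nothing survived).
There is no cap on the fraction discarded. Leaves already discarded by
phase 2 do not re-enter; the phases are strictly sequential.

The selected set always satisfies `|selected| = m + m′ − s₁ − s₂ − s₃`; the
result object enforces this identity at construction.

## Cross-validation protocol

Folds are stratified by dealing each class's shuffled members round-robin
(class proportions within ±1 sample); `k = n` gives leave-one-out. The
entire feature engineering runs on the training partition of each fold;
train and test samples are then projected onto that fold's selection.
Because taxon aggregates are per-sample sums, test columns involve no
training statistics — selection is leakage-free by construction, and the
suite verifies that flipping test-fold labels leaves training selections
bit-identical.

Classifiers are thin adapters over scikit-learn with library defaults:
decision tree, random forest, Gaussian naive Bayes. These defaults are not
numerically interchangeable with other toolkits' implementations of the same
algorithms, so absolute AUCs are comparable only within one toolkit.
Multi-class AUC is macro-averaged one-vs-rest; precision/recall/F are
weighted averages (the averaging rule is a documented convention — scalar
metrics for ≥ 3 classes are not otherwise well defined). Fold-level
standard deviations use ddof = 1. Classifier seeds derive from the fold-plan
seed; an empty selection (possible under the null) falls back to
class-prior scoring, i.e. chance AUC.

## Synthetic data generator

The generator emulates what a 16S case-control study hands the pipeline;
it is first-class, tested code, not a fixture.

**Taxonomy.** Grown top-down from one kingdom with per-rank mean child
counts (defaults: 3 phyla; 2 classes/phylum; 2 orders/class; 2.5
families/order; 3.5 genera/family, minimum 2; 2.5 species/genus). The width
at the genus level matters: observed 16S families typically contribute
several genera, and a rank chain with single children makes a taxon
numerically identical to its ancestors, which is a degenerate regime for
any parent–child redundancy filter. A configurable fraction of OTUs
(default 0.1) has lineages truncated at family or genus, drawn uniformly.

**Abundances.** Per-OTU base proportions are log-normal (σ = 1.5): a few
taxa dominate, most are rare. Per sample, each species- and genus-level
taxon receives a shared log-normal factor multiplying all its member OTUs,
plus independent per-OTU log-normal noise; the `noise` parameter (default
0.5, in log-units) scales all of these. The factor scale decays sharply
with rank (species 1.5×, genus 0.25×, nothing broader): same-species OTUs
are ecologically near-clonal and bloom together, genus-wide coherent shifts
are weaker, and a whole family rarely moves as a unit. This within-clade
covariation is the property that makes ancestral taxa coherent aggregate
features — and it is exactly what independent per-OTU sampling (e.g. a
plain Dirichlet around the base composition) fails to produce, which is why
that simpler model was rejected. Rows are renormalized to 1 after all
effects, so the data are genuinely compositional.

**Planted effect.** All OTUs descending from one chosen taxon (default: a
genus) are multiplied by `effect_size` (default 3) in case samples *before*
renormalization, so every other feature shifts slightly too — the realistic
compositional confound. The planted taxon must have ≥ 4 member OTUs (the
oligophyletic setting the method targets) and must be a minority
constituent (≤ 40 % of its parent's base abundance): a genus that already
dominates its family is numerically interchangeable with it, and "which of
the two is recovered" is then ill-posed. Balanced classes; all randomness
flows from a single seed; a generator version string is stamped into the
truth record.

**What the generator does not emulate.** Sequencing-depth variation and
rarefaction, zero-inflation beyond what the log-normal tail produces,
phylogenetic (branch-length) signal, batch effects, multi-kingdom
communities, and family-or-broader coherent ecological shifts. Passing the
synthetic suite therefore demonstrates correctness of the machinery and
recoverability of clade-level signals under compositional noise — not
performance on any particular real cohort, which additionally depends on
upstream OTU picking and classifier defaults.

## Numerical and design choices

- Entropies in bits (base-2 logs) throughout.
- Pearson correlations, discretization and IG are always computed on the
  training partition only, once per feature per fold.
- Normalization tolerance 1e-9; aggregation conservation holds to 1e-9.
- Near-tie tolerance 1e-12 when choosing among candidate cuts.
- Deterministic orderings everywhere (selection order follows the extended
  table's column order), so identical inputs give byte-identical outputs.
- Study-condition defaults for experiments: n = 100 samples, m = 200 OTUs,
  θ = 0.7, genus-level effect 3. The runtime-scaling check uses n = 200
  with m up to 4000, where a full run takes a few seconds.

## Known limitations

- Phase 2 can chain-prune an informative clade upward until its signal is
  diluted (child → parent → grandparent each exceeding θ); the per-path IG
  rule cannot rescue a node phase 2 removed. This is inherent to the
  correlation heuristic and visible in the recovery experiments as the
  planted genus occasionally being represented by its family instead.
- The per-path/any-path reading of phase 3 is one defensible resolution of
  an ambiguity; the global strategy is provided for comparison.
- Aggregation assumes abundances are comparable across OTUs within a
  sample (relative abundances guarantee this; raw counts from different
  sequencing depths do not — normalize first).
- BIOM v2 (HDF5) is not read; convert to BIOM v1 JSON or classic TSV.
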