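# Methods

## Problem and model

The package treats isoform-level functional network prediction as binary
pair classification. A pair of mRNA isoforms is *functional* if the two
transcripts participate in the same biological process; the classifier
outputs a probability per pair from 27 features (with 17 tissues): one
Fisher-z-transformed Pearson correlation per tissue expression slice, one
over all samples pooled, and one per sequence descriptor group.

Key modelling assumptions, inherited from the study design the package
implements:

- **Single-isoform genes carry gene-level truth.** Functional annotations
  are recorded per gene; only when a gene produces exactly one isoform can
  the annotation be transferred to a transcript without guessing. Positive
  pairs therefore come only from single-isoform genes. Negative pairs come
  from NOT-qualified annotations and are *not* restricted to single-isoform
  genes, since a gene-level "not involved in T" statement holds for every
  transcript of that gene.
- **Ontology semantics.** Positive annotations obey the true-path rule
  (annotation to a term implies annotation to all ancestors); NOT
  annotations propagate in the opposite direction (to all descendants).
  Both operators are monotone and idempotent. Evidence codes IEA, NAS and
  ND are discarded before propagation; terms annotated to fewer than 10 or
  more than 1000 genes after propagation are discarded, and the same
  retained term set serves positive and negative generation. A pair found
  in both sets is kept positive: one shared process suffices.
- **PPI quality rules** are source-specific: APID requires ≥ 2 experimental
  evidences, IID records with only orthologous evidence are dropped, Mentha
  requires score ≥ 0.2, and every source requires both interactors from the
  target organism.

## The z transform

The implemented transform is `z = ½·log2((1−ρ)/(1+ρ))`, which is strictly
*decreasing* in ρ and uses a base-2 logarithm — deliberately not the
classical Fisher transform `½·ln((1+ρ)/(1−ρ))`. The replacement rules pin
the orientation: ρ = 1 ↦ −100, ρ = −1 ↦ +100, undefined ρ (a constant
vector) ↦ 0. ρ within 1e−12 of ±1 is treated as exactly ±1; any other
finite z is clipped to [−100, 100] (this touches only |ρ| ≳ 0.9999995).
A `classical=True` flag exposes the increasing natural-log variant for
experimentation; all defaults use the decreasing form. Because the
transform is a strictly monotone map applied per feature, a tree ensemble
is insensitive to the choice; the extreme-value and undefined-ρ rules are
what matter.

## Sequence descriptors

- **k-mer composition** (mRNA k = 3..6 over {A,C,G,T}; protein k = 1..2
  over the 20 standard residues): overlapping counts divided by
  l − (k − 1); every vector sums to 1. Keys are lexicographic and frozen.
- **Conjoint triads**: residues map to 7 classes by side-chain volume and
  dipole ({A,G,V}, {I,L,F,P}, {Y,M,T,S}, {H,N,Q,W}, {R,K}, {D,E}, {C}),
  then triad frequencies over the class alphabet — 7³ = 343 dimensions.
- **Pseudo-amino-acid composition** (Chou type): 20 composition entries
  plus λ sequence-order correlation factors from standardized
  hydrophobicity, hydrophilicity and side-chain-mass scales, jointly
  normalized to sum 1. Defaults λ = 25, weight = 0.05. λ must stay below
  the minimum retained protein length (30 residues), which rules out the
  common default of 30.
- **Moran autocorrelation**: I(d) for d = 1..30 per property scale, with
  each scale standardized to zero mean / unit variance over the 20
  residues; I(d) is therefore invariant to affine rescaling of a scale.
  I(d) ≔ 0 when N − d < 1 or the denominator vanishes, so every retained
  protein is featurizable at every lag. Eight default scales are bundled
  (two hydrophobicity scales, hydrophilicity, side-chain mass, polarity,
  side-chain volume, isoelectric point, residue weight); any named set of
  20-value tables can be supplied instead.

## Classifier and controls

The forest uses scikit-learn defaults apart from the tree count (100) and
the seed; 100 trees sits on the performance plateau identified by the
tree-count sweep (10–5000). Splits are class-balanced and train/test
disjoint. Controls: resampling the split (performance spread should be
small), label shuffling with class counts preserved (median AUROC should
be ≈ 0.5), stratified 10-fold CV (per-fold variance should be small).

## Leave-one-tissue-out

All 1 + T models are trained on identical pairs with the same seed, so a
prediction flip reflects the removed feature, not sampling noise. The
pooled all-samples feature is never removed. Confidence bands: a
tissue-functional call needs p_full ≥ 0.6 and p_ablated ≤ 0.4 (mirror for
tissue-non-functional); label flips failing the bands are recorded as
low-confidence and excluded from networks; pairs whose label never changes
under any ablation form the reference set regardless of confidence. A pair
may flip under several ablations; it is emitted to each qualifying tissue
and flagged `multi_tissue` rather than discarded. Tissue edges store the
ablated probability as weight (lower = stronger tissue-specific
functional signal); reference edges store the full-model probability.

## Gene-level networks and statistics

Isoform edges collapse to gene edges by merging isoform nodes per gene:
intra-gene edges become self-loops and are dropped; parallel edges merge,
keeping the minimum weight and a multiplicity count. Graph density is
2E/(N(N−1)); for tissue networks both the all-edge and tissue-specific
edge-count variants are obtainable, and the tissue-specific variant is the
headline number. Central nodes are the intersection of the top 10% by
betweenness and by degree, computed on the largest connected component
only; betweenness is unweighted (probabilities are confidences, not
distances); the top-k size is floor(fraction·n) with a minimum of 1, and
ties within one measure break by the other measure, then by node id.
Enrichment is a one-sided hypergeometric test per term of size 10–1000
with Benjamini–Hochberg adjustment at 0.05.

## Synthetic generator

The generator emulates the statistical structure the pipeline assumes:

- A catalog of `n_genes` (default 200), a configurable fraction
  single-isoform (default 0.5), others drawing 2..3 isoforms. mRNA and
  protein sequences are i.i.d. random; protein sequences are *not*
  translations of the mRNA — the pipeline treats the two as independent
  descriptor sources, and no stage assumes coding consistency.
- `planted_module_count` modules (default 8) of `module_single_genes`
  single-isoform genes (default 10) plus `module_multi_genes`
  multi-isoform genes (default 2). Module membership drives **both**
  co-annotation and co-expression, so features and labels are genuinely
  associated. With fewer genes the generator prefers fewer full-size
  modules over undersized ones, because a module of < 10 genes falls below
  the term-size filter and produces no labels.
- **Expression:** 4 tissues × 10 samples (tissue cohorts below ~10 samples
  make 10-point correlation estimates too noisy to be meaningful, and such
  cohorts would not be used for tissue networks). Each module prefers one
  tissue; members share a latent factor only in that tissue's samples,
  with coupling chosen so the within-module, within-tissue log-scale
  correlation is `module_coexpression_rho` (default 0.9) under noise
  `noise_sd` (default 0.5). Marginal variance is matched across tissues so
  only the correlation structure is tissue-specific. An optional
  `module_tissue_shift` raises preferred-tissue median expression for
  emulating tissue-enriched profiles (used by the tissue-similarity
  analysis together with `tissue_groups`, e.g. a brain-like trio); it
  defaults to 0 because the pair features measure correlation, not level,
  and a strong level shift props up the pooled feature enough to suppress
  ablation flips.
- **Annotations:** each module is annotated at the leaf of its own term
  chain (length `dag_depth`, own root). Chains are separate because after
  true-path propagation a single shared root would hold every annotated
  gene, pass the fixed [10, 1000] filter at this scale, and label all
  cross-module pairs positive — destroying the planted
  feature–label association. Real ontologies are likewise multi-rooted.
  Distractor terms carry IEA/NAS/ND annotations to exercise evidence
  filtering; exactly `not_annotation_count` NOT records (default 8) are
  planted on internal chain terms — so inverse propagation is exercised —
  and name genes outside the module, preferring multi-isoform genes.
  Pathway tables mirror every other module; PPI edges link consecutive
  module genes, plus one record per PPI filter rule that must be dropped.

What the generator does **not** emulate: read-level sequencing noise,
realistic gene structure or homology, correlated sequence composition
between functionally related genes (sequence features are uninformative in
the fixture — only expression features carry planted signal), compositional
FPKM effects, or sex/age covariates. Passing tests therefore demonstrate
that the pipeline machinery recovers planted expression structure under
the stated label logic, not that real tissues would yield the same
accuracy.

## Problem sizes and numerics

Tests and the acceptance script run at the default scale: 200 genes
(~350 isoforms, ~60k possible pairs, ~700 labeled pairs), 100-tree
forests, 20–40 control repetitions, and a balanced 100/40 (script: up to
100/100) pairs-per-class split. Seeds flow from one config value through
`numpy.random.default_rng`; repeat runs are byte-identical. Pearson
correlations reduce to dot products of standardized vectors; constant
vectors are flagged and routed to the undefined-ρ ↦ 0 rule rather than
dividing by zero. Probabilities written to edge lists round to six
decimals.
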