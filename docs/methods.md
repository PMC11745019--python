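# Methods

This note documents the statistical procedures `gvniche` implements, the
assumptions behind the synthetic-data generator, and the numerical and
design choices made where the problem left them open. Nothing here reports
an empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Habitat delineation

Habitats are discrete clusters of sampled depths in physicochemical space.
Each environmental variable is standardized to zero mean and unit variance
across depths before computing Euclidean distances between depth rows;
without standardization, high-magnitude solutes (sulfate at tens of mg/L)
would dominate trace variables (total Mn). Missing measurements (detection
limits are common for PAR and H₂S) are handled with pairwise-complete
distances, rescaling the squared sum by p_total/p_observed (the convention
of R's `dist`), so gappy rows stay comparable to complete ones.

Agglomeration is complete linkage, implemented in-package (the depth count
is tiny, typically 8) so that ties on merge distance can be broken
deterministically toward the lexicographically smallest pair of member
tuples; the merge-height history is exposed for verification, and the test
suite cross-checks it against `scipy.cluster.hierarchy.linkage` on random
data and against exhaustive enumeration on a toy matrix. The cut level *k*
is an explicit user parameter (default 3) rather than an automated
dendrogram inspection; labels are ordered by mean member depth and, at
k = 3, named mixolimnion / chemocline / monimolimnion.

Interpolation of profiles is piecewise linear between adjacent measured
depths, exact at measured depths, with extrapolation refused; a variable is
never interpolated beyond its own observed support.

## Abundance and presence

Genome-level coverage statistics aggregate contigs by length weighting:

- depth = Σ(length × mean depth) / Σ length,
- breadth = Σ covered bases / Σ length,

with contigs absent from a sample's (sparse) coverage table imputed as zero.
A genome is *present* in a sample iff breadth ≥ 0.70, boundary inclusive;
below the threshold its abundance is set to 0. The filter is idempotent and
the filtered matrix is elementwise ≤ the raw matrix. The 70% rule trades
false negatives for robustness against reads cross-mapping between related
genomes — a fragment of shared genes can produce deep but narrow coverage,
which breadth filtering rejects.

Normalized abundance is standard RPKM, mapped reads × 10⁹ / (genome length ×
library size). A depth-coverage basis (the length-weighted mean depth above)
is available as an alternative; downstream stages default to filtered RPKM.
The three viral-fraction replicates per depth are kept as distinct samples;
a depth-mean aggregation is available where a single per-depth value is
needed (the pathway–environment correlation uses it by default).

The size-fraction partition ratio per genome is (S − A)/(S + A), S and A the
summed abundances over cellular-fraction (0.22 μm) and viral-fraction
(0.02 μm) samples. This algebra spans exactly [−1, 1] with +1 ⇔
cellular-exclusive and −1 ⇔ viral-exclusive; a genome with no signal in
either fraction is reported missing, never 0 (0 means an even split).
Presence intersections (UpSet-style) count genomes per exclusive
combination of samples or habitats; counts over nonempty patterns sum to the
number of genomes present anywhere.

## Genome QC

Quality control consumes three marker statistics produced upstream: UNI56
(hits to 56 universal cellular housekeeping genes — a contamination signal),
GVOG9 (how many of nine core giant-virus orthologous groups are present) and
the mean duplication factor of the seven single-copy core groups. The pass
rule is UNI56 < 10 AND GVOG9 ≥ 4 AND GVOG7df ≤ 3, boundaries taken
literally (strict <, ≥, ≤). Records missing a statistic fail with reason
`missing_stat`; every failure carries the violated rules. An optional
minimum-GVOG pre-filter exists but is off by default since inputs are
normally pre-screened. Taxonomy summaries report counts and one-decimal
percentages allocated by largest remainder, so the printed column sums to
exactly 100.0.

## Niche calls

Each genome's abundance row is z-scored with the sample standard deviation
(ddof = 1; switchable). Constant rows (including all-zero) are flagged
degenerate and zeroed — they carry no positional information. The habitat of
the maximum-z sample is the genome's most probable habitat; exact ties break
toward the shallowest habitat, and an option aggregates replicates per depth
before the argmax.

The ecotype is a deterministic decision ladder over the presence pattern
(from the filtered matrix) and the argmax habitat; the first matching rule
wins:

1. absent everywhere → `undetected`;
2–4. present in exactly one habitat → `surface_only` / `chemocline_only` /
   `deep_only`;
5. present in the deepest habitat with argmax in the shallowest →
   `exported` (maximal at the surface yet reaching the bottom — the
   signature of sinking-particle transport);
6. present in the deepest habitat with argmax there → `deep_adapted`;
7. otherwise → `generalist`.

The exported/deep-adapted split is operationalized by the argmax-habitat
criterion; "declines with depth" is not thresholded separately. The ladder
is exhaustive and mutually exclusive by construction.

## Two-block association

Cross-block Pearson screening computes all genome × eukaryote correlations
over shared samples (≥ 3 required) and keeps |r| ≥ 0.5; constant rows yield
undefined r and are dropped. Blocks are converted to per-sample relative
abundance (columns normalized to sum 1) before association, matching how
community tables are usually compared; a raw mode exists.

The sparse PLS is the canonical two-block formulation (Lê Cao-style): per
component, NIPALS alternates weight updates from cross-projections, each
weight vector is soft-thresholded so exactly keepX/keepY variables keep
nonzero weight (threshold = the (k+1)-th largest magnitude, survivors shrunk
by it), normalized to unit length, iterated to a 1e-9 change tolerance
(max 500 iterations; non-convergence raises with the iteration trace).
Initialization uses the dominant singular pair of the current
cross-covariance, so the dense case converges in one step and component-1
weights equal the leading singular vectors of XᵀY on the centered/scaled
blocks — the test suite checks this against an SVD oracle and against the R
mixOmics implementation. Deflation regresses each block on its own variate
in canonical mode (the symmetric choice appropriate for relating two
communities; regression mode deflates Y on the X variate and is available).
Signs are fixed by making the largest-magnitude weight entry positive.
Mode = canonical, 2 components and keep = all are defaults chosen for the
virus–eukaryote use case, not tuned. Samples with missing values in either
block are dropped pairwise with a warning.

The correlation circle reports each variable's Pearson correlation with its
own block's first two variates; variables are retained at max(|c1|,|c2|) ≥
0.5. Coordinates lie in the unit disc by Cauchy–Schwarz.

## Functional profiles

Genes inherit abundance from coverage. Default mode gives every gene its
genome's breadth-filtered normalized abundance (genome-level
normalization — robust to per-contig noise); a per-contig depth mode exists,
masked by the genome's presence filter. A gene listing k pathways
contributes its full abundance to each (annotation pipelines emit multiple
pathways per gene and fractional splitting is not obviously correct); a 1/k
fractional mode is provided but off by default.

The pathway × environment correlation averages samples per depth, pairs
them with measured (or interpolated) environmental values, and orders rows
and columns of the resulting Pearson matrix by complete-linkage clustering —
the tabular equivalent of a clustered image map. The ternary contrast
computes, per pathway, the mean per-genome pathway abundance within each of
three ecotype groups (default surface_only / exported / deep_adapted),
normalized to the 3-simplex; rows with zero signal in all groups are
omitted, and the coordinates are invariant to global rescaling.

Marker prevalence reports, per genome group, the fraction of genomes
carrying ≥ 1 copy and the mean copy number over carriers (missing, not 0,
for empty groups). Viral rhodopsin labels carry a phylogenetic group suffix
(`VirR_group1`/`VirR_group2`); querying the family name `VirR` matches both.
Taxon percentages tally best-hit taxa over annotated genes only
(unannotated genes are counted separately), pooling taxa seen fewer than 50
times into `other`.

## The synthetic generator

The generator emits coverage *tables*, not reads: contig mean depth and
covered bases are the minimal sufficient statistics the pipeline consumes,
and everything read-level (trimming, mapping) is upstream of this package.
What it emulates, and how:

- **Survey design.** Eight depths (2, 6, 14, 22, 34, 40, 55, 65 m), each
  with one cellular-fraction and three viral-fraction replicate metagenomes;
  library sizes vary ±10% around `reads_per_sample`.
- **Water column.** Layer boundaries at 10 and 28 m partition the printed
  depths 2,6 | 14,22 | 34–65. Environmental baselines are step-like across
  layers (stratification concentrates gradients at the interfaces): oxygen
  and PAR positive only above the lower boundary and exactly zero below it,
  salinity rising from near-fresh to marine (~35 g/kg), sulfate/H₂S/Fe/Mn
  increasing with depth, a chlorophyll maximum at the chemocline.
  Measurement noise is relative — sd = noise_sd × the local value — so
  structural zeros stay zero and layer contrasts survive realistic noise.
- **Ecotype depth curves.** surface_only decays from 2 m and vanishes below
  the upper boundary; chemocline_only is a Gaussian bump between the
  boundaries; exported decays slowly from a surface maximum and stays
  detectable at the bottom; deep_adapted is maximal below the lower
  boundary, faintly detectable in the chemocline and effectively absent at
  the surface; generalist spans all layers with a weak mid-column optimum.
  The generalist curve is deliberately *not* flat: a flat profile has no
  defined abundance maximum, so the argmax-based classifier would assign it
  a habitat at the whim of noise — a planted class must exemplify a
  recoverable pattern.
- **Coverage model.** Contig lengths are log-normal (clipped at 1.5 kb);
  per-contig mean depth c is proportional to the genome's relative
  abundance, the sample's library size, and `coverage_scale` (default 30×
  at unit abundance). Realized breadth is drawn around the uniform-coverage
  (Lander–Waterman) expectation 1 − exp(−c) with beta jitter
  (concentration 300); c = 0 gives breadth exactly 0. Mapped read counts
  are c × length / read length, rounded. Zero-coverage rows are omitted,
  exercising the sparse-table imputation path.
- **Size fractions.** Viral-fraction samples multiply each genome's
  abundance by a pass-through factor: 1 for most genomes, 0 for a planted
  20% that are thereby exclusive to the cellular fraction.
- **Community composition.** Ecotype proportions default to 45%
  surface_only, 10% chemocline_only, 10% exported, 15% deep_adapted, 20%
  generalist (deterministic counts by largest remainder), mirroring the
  strongly surface-skewed layer occupancy of stratified polar lakes.
  Per-genome scales are log-normal (σ = 0.4); per-genome-per-sample noise is
  multiplicative log-normal with σ = noise_sd (default 0.2).
- **Eukaryotes.** 64 taxa over the cellular samples; half track a randomly
  chosen genome's true profile (times noise), the rest follow independent
  Gaussian depth niches with random optimum and width — giving linked pairs
  r ≥ 0.5 and a null median |r| < 0.5.
- **Annotations.** ~1 gene per 1.1 kb of contig; each gene draws 0–2 KEGG
  pathway labels from its genome's layer pool (photosynthesis-like labels in
  the surface pool, sugar/pyruvate-like labels in the deep pool, housekeeping
  labels shared) with a 0.6 own-pool bias. Viral-rhodopsin carriage per
  genome is Bernoulli with its layer's rate (defaults 0.507 surface, 0.60
  chemocline, 0.742 deep), with ≥ 1 copy when carried and more copies at
  depth; four auxiliary markers (photolyase, K⁺ channel, sulfite exporter,
  SfsA) have their own layer-biased rates. Best-hit taxa follow a fixed
  frequency table (~60% eukaryote among annotated genes) with a rare tail
  that exercises the <50-count pooling.
- **Determinism.** All stages draw from independent streams spawned from the
  single config seed; identical configs give byte-identical output tables.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: sequence-level artifacts (chimeric bins,
cross-mapping between related genomes, GC/coverage bias), compositionality
of real library-size normalization, eukaryote 18S copy-number variation,
phylogenetic correlation between genomes, and any spatial/temporal structure
beyond the single idealized depth transect. The breadth filter's
false-positive protection is therefore *assumed*, not demonstrated, by the
synthetic runs.

## Problem sizes and runtime choices

Default simulations use 200 genomes × 32 samples (~2 000 contigs, ~35 000
genes); recovery properties are evaluated over seed grids of 10–20 at these
sizes, chosen as the smallest community at which the planted binomial
contrasts (e.g. viral-rhodopsin rates 0.742 vs 0.507) are statistically
resolvable per seed. The full pipeline on that scale runs in roughly a
second.

## Known limitations

- The ecotype ladder is a hard classifier; genomes near the
  exported/deep_adapted boundary flip under noise, which is visible in the
  recovery-vs-noise curve.
- Pairwise-complete distances can violate the triangle inequality in
  principle; with the default profiles this has no practical effect.
- The sPLS keep values are not tuned (no cross-validation); the model is a
  descriptive projection, not an inferential fit, and no uncertainty is
  attached to the weights.
- `deep_only` calls are rare by construction (a genome must clear the 70%
  breadth bar in deep samples only); with few deep samples this class is
  sensitive to the replicate design.
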