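# Methods

This note documents the models and procedures `syntopo` implements, the
parameters that matter, what the synthetic-data generator does and does
not emulate, and the numerical conventions. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Microsynteny detection

A pairwise block between species A and B is a set **F** of at least
`min_genes` (default 3) distinct gene families such that, on one
chromosome of each species, the genes belonging to F form a chain in
which consecutive members are separated by at most `max_intervening`
(default 5) genes of any family status. Member order may differ freely
between the two species (no collinearity constraint), and the
intervening-gene bound applies per gap, per side.

The detector works per chromosome pair by iterative refinement. Starting
from the "anchor" genes whose family occurs on the partner chromosome, it
alternates two moves until a fixed point: restrict each side to the
families currently shared by both sides, and split each side into maximal
runs obeying the gap bound, recursing into every pair of runs. A
fixed point with a single chain per side and ≥ `min_genes` distinct
shared families is a candidate block; candidates contained in another
candidate on both sides are discarded. Every maximal block is reachable
this way (restriction only shrinks family sets, and any valid block lies
inside one run at each refinement level), and the output is exactly the
set of maximal valid blocks — the test suite verifies equality with an
independent exhaustive window-enumeration oracle on thousands of random
instances. Requiring distinct families makes tandem arrays of one family
collapse to a single member, so single-family runs never qualify.

Maximality, not a scoring scheme, resolves overlaps: all maximal blocks
are returned, including multiple pairings of one locus (paralogous
copies), which the cluster-level paralogy flag then records. Output order
is deterministic (sorted by chromosome and member tuple).

Degenerate regime worth knowing about: if two chromosomes share nearly
all families, the entire chromosome pair is one valid block under this
definition. Real comparisons avoid this because orthologs scatter across
chromosomes; the generator reproduces that sparsity.

## Clusters and classification

Pairwise blocks merge into multi-species clusters as connected components
of the graph whose edges join blocks with family-set Jaccard ≥
`min_family_jaccard` (default 0.5). Each species contributes the union of
its member genes, split into separate loci per chromosome and wherever
consecutive members exceed the intervening bound; multiple loci in one
species, or two clusters sharing families above the threshold, set the
paralogy flag. The merge rule is a documented stand-in — reasonable
alternatives (anchor chaining, score-based merging) exist, and the
Jaccard-component rule was chosen for determinism and transparency.

Classification by presence pattern, relative to a focal clade and a
designated reference species: *novel_clade* requires the reference plus
at least one other clade member and absence from every non-clade species;
*ancient* requires presence in at least `ancient_min_species` species
outside the clade (default 7, mirroring a 24-outgroup setting; on the
synthetic fixture with 3 outgroups the pipeline uses
`min(ancient_min_species, n_outgroups)`, i.e. presence in all outgroups);
intermediate labels (e.g. a molluscan clade) come from a configurable
hierarchy of (label, species set, minimum presence) rules; everything
else is *other*. Clusters lacking the reference are counted and labelled
*other* with a warning.

## Randomizations

The genome-shuffle null permutes gene order uniformly within every
chromosome (genes swap coordinate slots wholesale, preserving geometry),
re-runs the full detect → merge → classify chain with identical
parameters, and records the count of clusters in the queried class; the
median over `rounds` (default 3) is the null expectation. Random block
sets for expression/topology comparisons draw, per observed cluster, a
run of consecutive genes of the same gene count uniformly over all
placements that fit on a chromosome — the size distribution of each
random set matches the observed distribution exactly, and the default is
20 iterations.

## Hi-C topology

*Balancing.* Iterative proportional fitting (ICE): rows/columns are
rescaled until every non-masked row sum equals the mean within `tol`
(default 1e-6, max 200 iterations); zero-coverage rows stay masked. The
procedure is idempotent on its own output.

*TAD calling* is deliberately plumbing-grade: the insulation score at the
boundary between bins i−1 and i is the mean of the `window × window`
submatrix crossing it; boundaries are strict local minima below
(mean − 1 SD) of the score track, and domains are the intervals between
boundaries. It recovers planted domains on clean matrices and is not a
substitute for production TAD callers.

*Interaction tree.* Agglomerative clustering constrained to chromosomal
adjacency: at each of n−1 steps the two adjacent clusters with the
highest mean inter-cluster contact merge (average linkage; ties go to the
leftmost pair, making the tree deterministic). Every subtree therefore
spans a contiguous bin interval, and the last common ancestor (LCA) of
any bin interval is the unique deepest node containing it. The
*compactness ratio* of a region is (bins in region)/(leaf bins under its
LCA) ∈ (0,1]; enlarging a region within a fixed LCA can only raise it.
Average linkage is a documented choice — the underlying idea ("merge each
bin with its closest neighbor by interaction strength") does not fix a
linkage, and the choice is recorded in tree metadata (Newick export
carries merge strengths). Group analyses keep only clusters spanning
`min_bins`–`max_bins` bins (defaults 7–25 at the analysis resolution) and
compare groups with the two-sided Wilcoxon rank-sum test.

*TAD-relative localization.* A cluster maps to the TAD containing its
midpoint only (clusters spanning several TADs are not split), at
normalized position (midpoint − TAD start)/TAD length; midpoints in no
TAD are dropped and counted. Density ratios use Gaussian KDEs with
Silverman bandwidth on a uniform grid over [0,1]; positions are not
reflected at the boundaries, so edge estimates are conservative. A sample
against itself gives ratio 1 identically.

*A/B compartments.* Observed/expected by diagonal, Pearson correlation
matrix, leading eigenvector; the sign is oriented by correlation with a
supplied per-bin covariate (e.g. gene density), otherwise reported
unoriented (the vector and its negation are equivalent).

## Expression

Block co-expression is the mean pairwise Pearson correlation of
log2(x+1) tissue profiles over the block's genes (absent or
zero-variance genes are excluded and counted; fewer than 2 usable genes →
undefined). Pearson on log-transformed TPM-like values is the
conventional choice; Spearman and the raw scale are available as options.
Class-level comparisons (novel vs matched random, ancient vs matched
random, novel vs ancient) use the two-sided rank-sum test.

Expression modules: per cluster, the mean log2 profile of its
reference-species member genes, z-scored per cluster, Ward-linkage
hierarchical clustering on Euclidean distance cut at k modules (default
8). Deterministic given input order. Module enrichment crosses in/out of
each module with novel/ancient class in a 2×2 Fisher exact test.

Dominance: a block is dominated when one gene contributes more than half
the block's summed (linear-scale) expression; blocks with zero total are
excluded from the denominator. Relative profiles divide each gene's
tissue vector by its own total before averaging over the block. The
variance–mean relation across genes is summarized as a Spearman
correlation. Tissue specificity uses the tau index on log2(x+1) profiles,
with all-zero genes undefined.

## Regulatory elements

Peak annotation is midpoint-based with precedence promoter > exon >
intron > distal; the promoter is ±`promoter_flank` (default 10 kb) around
the strand-aware TSS, and genes without exon records count as single-exon
(hence never intronic). Midpoint + precedence gives every peak exactly
one deterministic label. Synteny association labels an interval by
overlap with cluster spans extended by `margin` (default 1 kb) on both
sides; when both classes match, the nearer unextended span wins and exact
ties go to novel (recorded). Enrichment of a focus category between
groups is a two-sided Fisher exact test. Repeat content merges repeat
intervals before computing covered fractions (no double counting) and
reports per-family shares of covered bp per group.

The CNE filter chain runs, in order: (1) percent-identity filter;
(2) multimapping removal — a region is dropped when the number of regions
overlapping it reciprocally by ≥ `overlap_frac` of *both* lengths
(counting itself) exceeds `max_copies` (defaults 0.5 and 3, matching the
count-then-threshold idiom of interval toolkits); (3) merging of
remaining overlapping regions; (4) removal of regions overlapping any
exon by ≥1 bp; (5) DUST low-complexity masking — the classic triplet
score S = Σ c_t(c_t−1)/2 / (w−3) over sliding 64-bp windows, windows
scoring above `dust_cutoff` (default 10) masked, masked ends trimmed, and
regions shorter than `min_size` after trimming dropped; (6) removal of
regions with N fraction above `max_n_frac` (default 0.25); (7) a final
length filter (`min_size` ∈ {50, 100} bp are the conventional settings).
Every stage reports survivor and drop counts, the audit sums to the input
count, and the chain is idempotent on its own output. Screening against
an external protein database is out of scope; a hook accepts an exclusion
interval list instead.

## Statistical kernels

The Wilcoxon rank-sum test computes the exact tie-aware permutation
p-value via a subset-sum dynamic program over doubled mid-ranks whenever
the pooled sample has ≤ 40 observations, and otherwise the normal
approximation with continuity and tie correction; two-sided p =
min(1, 2·min(lower tail, upper tail)). Fisher's exact test uses the
standard two-sided rule (sum of table probabilities no larger than the
observed one). Both are validated against literal enumeration oracles in
the test suite.

## The synthetic study system

`SimulationConfig` defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_species_clade / n_species_outgroup | 2 / 3 | focal clade (first member = reference) and outgroups |
| n_chromosomes × genes_per_chromosome | 10 × 500 | 5000 background genes per species |
| n_ancestral_blocks / n_novel_blocks | 20 / 30 | planted blocks |
| block_size_range / intervening_range | 3–8 / 0–3 | genes per block; intervening genes per gap (≤ detector bound 5) |
| orphan_fraction | 0.02 | genes with no family |
| bg_family_presence | 0.75 | probability a background family is retained/detectable per species (lineage-specific loss) |
| gene_length / intergenic gap | lognormal, ~20 kb / ~7 kb | invertebrate-scale gene geometry |
| novel-block gaps | lognormal, ~0.2 kb | tight packing of clade-novel blocks |
| hic_resolution, decay_exponent | 40 kb, 1.0 | contact decay ∝ distance⁻¹ |
| tad_boost / compact_boost | 4 / 5 | fold contact enrichment in TADs / planted compact regions |
| noise_cv | 0.1 | multiplicative (log-normal) noise CV on contacts and expression |
| n_tissues / n_modules | 12 / 8 | expression panel and planted modules |
| within_block_corr | 0.6 | latent-factor correlation in co-expressed blocks |
| module_amplitude / gene_level_sd | 2.0 / 2.0 (natural log) | tissue-template strength; per-gene abundance spread |

Ancestral blocks are inserted as contiguous runs in **every** species;
novel blocks are contiguous only in clade species, and their families are
placed in outgroups as scattered single genes separated by more than the
detector's intervening bound. Placements on a chromosome are separated by
at least that bound plus one, so planted blocks can never chain into each
other, and leftover background positions are spread randomly between
placements.

Recovery is exact *by construction*: after placement, the generator runs
the detector over every species pair and removes the family assignment of
any background gene participating in a non-planted block, iterating to a
fixed point. Removing anchors can never create blocks, so this converges;
it slightly raises the effective orphan rate and is the reason detection
precision and recall are exactly 1 on the fixture. Real genomes retain a
low rate of chance co-occurrence — the shuffle null, run on the fixture,
quantifies exactly that rate after order randomization.

Expression, in natural-log space:
`y = base + gene_level + amplitude · template(module) + sd · (√ρ · z_block + √(1−ρ) · ε)`,
exponentiated to TPM-like values. `template` is one-hot on the module's
home tissue; `z_block` is a per-block latent tissue profile shared by the
genes of co-expressed blocks (by default the ancestral ones, ρ =
`within_block_corr`); `sd` derives from `noise_cv`; `gene_level` is a
per-gene constant that spreads baseline abundance over orders of
magnitude. Because `gene_level` is constant across tissues, it leaves
Pearson correlations and z-scored profiles untouched while making
single-gene dominance of block expression common. Ancestral-block genes
share their block's module; novel-block and background genes draw
independent modules — the generator's expression model of the central
contrast that ancient blocks are co-regulated units while clade-novel
blocks assemble genes with unrelated programs. Fixtures that study pure
co-expression set `module_amplitude = 0` so the latent factor is the only
source of correlation; fixtures that study module recovery keep the
template. With `noise_cv = 0` and ρ = 1 the block's genes have identical
profiles (correlation exactly 1); with ρ = 0 and no template their
correlations are centered on 0.

Peak fixtures draw a feature category per peak from a class-dependent
distribution and place the peak *midpoint* uniformly inside the
category's eligibility zone, computed by interval arithmetic under the
same precedence rules the annotator applies — annotation recovery is
therefore exact by construction. If a category has no eligible interval
near the cluster, the nearest interval on the chromosome is used; if none
exists chromosome-wide, a placement error names the category. Peak widths
are log-normal (median ≈ 300 bp).

What the generator does **not** emulate: sequence content (no motifs,
no repeats in the genome itself), realistic karyotype evolution,
inter-chromosomal Hi-C contacts, mapping/assembly artifacts, replicate
structure, or count noise in expression. Passing tests therefore
demonstrate algorithmic correctness and calibrated statistics on a
faithful structural model — not robustness to every artifact of real
data.

## Numerical conventions and tie-breaks

- Coordinates are 0-based half-open internally; GFF3 is converted on
  read/write. Genes sort by (start, id); duplicate ids are hard errors;
  unknown strands warn and default to "+".
- Contact matrices are symmetric within 1e-9 (relative); COO input is
  symmetrized by the maximum of mirrored entries with a warning. The
  simulated diagonal is each row's maximum off-diagonal expectation and
  is never used in statistics.
- Tree merges break ties leftmost; module clustering and all writers are
  deterministic, so a fixed config + seed reproduces byte-identical
  tabular outputs (timestamps live only in the run manifest).
- All randomness flows through explicitly passed
  `numpy.random.Generator` objects seeded from one configuration seed;
  no global RNG state is touched.
- Problem sizes in the test suite and acceptance script (e.g. 1000 toy
  pairs for the detector-oracle check, 8 × 300-bin matrices for the
  compactness study, 200 blocks per class for co-expression) were chosen
  to give stable statistics at interactive runtimes.

## Known limitations

- The multi-species merge rule and the interaction-tree linkage are
  documented stand-ins for under-specified steps; results depending
  finely on either should be checked against alternatives.
- The insulation-score TAD caller is plumbing, tuned only to recover
  planted domains on clean synthetic matrices.
- The compactness fixture is idealized (planted sub-domains align with
  bin boundaries), so planted ratios concentrate near 1 — real data
  yields intermediate values.
- Exact rank-sum p-values switch to the normal approximation above 40
  pooled observations; extremely discrete data with larger samples rely
  on the tie-corrected approximation.
- The CNE chain consumes alignment hits; it does not run the aligner,
  and its multimapping rule counts overlaps per region (a per-group
  alternative exists in the literature and would differ on rare
  geometries).
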