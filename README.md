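# syntopo

Microsyntenic gene blocks — small sets of genes that stay physically
linked across hundreds of millions of years of evolution — and what
happens to them when a genome is massively reorganized. `syntopo`
implements the full comparative workflow around this question: detecting
microsyntenic blocks across species, classifying them as ancient
(metazoan-wide) or clade-novel, and profiling their chromatin topology
(Hi-C interaction trees and TADs), co-expression, and regulatory-element
associations. The motivating system is the coleoid cephalopod genome,
where large-scale rearrangement created hundreds of lineage-novel
microsyntenies, but every component is organism-agnostic.

Because the real analyses require multi-gigabase genomes, cross-species
orthology inference and external TAD callers, the package ships a
first-class synthetic-data generator that plants ground truth — conserved
and clade-novel blocks, extra-compact Hi-C sub-domains, tissue expression
modules, class-biased chromatin peaks — so the entire pipeline is
testable offline against known answers.

It is intended for comparative genomicists and genome-evolution
researchers who want a tested, reusable implementation of these analyses
(or of any one stage), and for methodologists who need a planted-truth
benchmark for synteny/topology methods.

## The core definitions

- **Microsyntenic block** (pairwise): at least 3 genes from distinct
  orthologous families co-occurring on one chromosome in each of two
  species, with at most 5 intervening genes between consecutive members
  on either side and *no* collinearity requirement. The detector returns
  all maximal such blocks and provably matches exhaustive enumeration.
- **Syntenic cluster**: connected component of pairwise blocks under a
  family-set Jaccard threshold (default 0.5), with per-species loci and a
  paralogy flag.
- **Classification**: *novel* — present in the reference species and ≥1
  other focal-clade member, absent from every outgroup; *ancient* —
  present in ≥ k species outside the clade (k = 7 in the full-scale
  setting); intermediate clade labels are configurable.
- **Null models**: genome shuffling (order permuted within chromosomes,
  full detect→merge→classify rerun; counts and their median over rounds)
  and random blocks sampled to match the observed size distribution.
- **Interaction tree / compactness**: an adjacency-constrained
  average-linkage dendrogram of Hi-C bins. For a region spanning *b* bins
  whose last common ancestor in the tree covers *L* leaf bins, the
  compactness ratio is *b/L* ∈ (0,1] — near 1 when the region forms its
  own tight interaction compartment.
- **Co-expression coefficient** of a block: mean pairwise Pearson
  correlation of log-transformed tissue profiles of its genes.
- **tau**: tissue-specificity index in [0,1]; 0 = uniform, 1 =
  single-tissue.

## Worked example

Run the whole pipeline on a small synthetic study system (2 clade species
+ 3 outgroups, 8 ancestral + 10 clade-novel planted blocks, 800
background genes per species):

```python
from syntopo.pipeline import run_pipeline

run_pipeline({
    "seed": 3,
    "simulation": {"n_chromosomes": 4, "genes_per_chromosome": 200,
                   "n_ancestral_blocks": 8, "n_novel_blocks": 10},
    "detect": {"ancient_min_species": 3},
    "topology": {"hic_chromosomes": 1, "hic_resolution": 10_000,
                 "window_bins": 5, "min_bins": 3, "max_bins": 60},
}, "demo_out")
```

`demo_out/report.json` from this exact run contains (abridged):

```json
"cluster_counts": {"ancient": 8, "novel_clade": 10},
"shuffle_null": {"median": 2.0, "observed_novel": 10, "rounds": [2, 2, 1]},
"expression_stats": {
  "coexpression_medians": {"ancient": 0.990, "novel": -0.020,
                            "random_ancient": 0.062, "random_novel": 0.038},
  "coexpression_pvalues": {"ancient_vs_random_ancient": 1.9e-06,
                            "novel_vs_random_novel": 0.48},
  "dominant_fraction": 0.778},
"regulatory_stats": {"intron_enrichment": {"odds_ratio": 11.79,
                                            "pvalue": 1.15e-05}}
```

Reading this: all 18 planted blocks were recovered and correctly
classified; shuffling gene order leaves a median of only 2 chance blocks
versus 10 observed novel ones; ancient blocks are strongly co-expressed
relative to size-matched random blocks while novel blocks are not
(median −0.02, p = 0.48); 78% of blocks have one gene contributing more
than half the cumulative expression; and chromatin peaks associated with
novel blocks are intron-enriched relative to ancient ones. The directory
also holds the clusters table, TAD calls, the interaction tree in Newick
form, compactness ratios, the TAD-relative density-ratio profile, A/B
compartment signs, and a reproducibility manifest.

The same stages are available from the shell:

```bash
syntopo run --seed 3 --out demo_out
syntopo detect --genes genes_sp1.bed --genes genes_sp2.bed \
    --orthogroups orthogroups.tsv --focal-clade sp1,sp2 \
    --min-genes 3 --max-intervening 5 --rounds 3 --seed 1 --out out/
syntopo topology --matrix hic_chr00.coo.tsv --window-bins 5 --out out/
```

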