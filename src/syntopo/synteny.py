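"""Microsynteny detection, clustering, classification and randomization.

A pairwise microsyntenic block is a set of at least ``min_genes`` distinct
gene families whose members co-occur on one chromosome of each of two
species, with at most ``max_intervening`` genes (of any family status)
between consecutive members on either side, and no constraint on the
relative order of the members (collinearity is not required).

Detection works per chromosome pair by iterative refinement: start from the
genes whose family is present on the partner chromosome, alternately
(a) restrict each side to the families currently shared, and (b) split each
side into maximal runs satisfying the intervening-gene bound, recursing into
every pair of runs until a fixed point. Every maximal block is reached this
way; blocks contained in another block on both sides are discarded.

Multi-species clusters are connected components of the block graph under a
family-set Jaccard threshold; phylogenetic classification follows presence
patterns (clade-novel vs ancient vs configurable intermediate clades).
Two randomizations are provided: a genome-shuffle null (gene order permuted
within chromosomes, full chain re-run) and random block sampling matched to
the observed block-size distribution.
"""

from __future__ import annotations

import statistics
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .genome import Gene, GenomeOrder, OrthologyMap
from .stats import rank_sum_test

# --------------------------------------------------------------------------
# data types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PairwiseBlock:
    species_a: str
    species_b: str
    chrom_a: str
    chrom_b: str
    genes_a: tuple[str, ...]  # gene ids in chromosomal order
    genes_b: tuple[str, ...]
    families: frozenset[str]

    def side(self, species: str) -> tuple[str, tuple[str, ...]]:
        if species == self.species_a:
            return self.chrom_a, self.genes_a
        if species == self.species_b:
            return self.chrom_b, self.genes_b
        raise KeyError(species)


@dataclass
class ClusterInstance:
    chrom: str
    genes: tuple[str, ...]  # chromosomal order
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class SyntenyCluster:
    cluster_id: str
    families: frozenset[str]
    instances: dict[str, list[ClusterInstance]]  # species -> loci
    label: str = "unclassified"
    paralogous: bool = False

    @property
    def species_present(self) -> frozenset[str]:
        return frozenset(self.instances)

    def instance(self, species: str) -> ClusterInstance:
        """Primary (largest) locus of a species."""
        return max(self.instances[species], key=lambda i: len(i.genes))


# --------------------------------------------------------------------------
# pairwise detection
# --------------------------------------------------------------------------


def _split_chains(members: tuple[tuple[int, str], ...],
                  max_intervening: int) -> list[tuple[tuple[int, str], ...]]:
    """Split (rank, family) members into maximal runs obeying the gap rule."""
    if not members:
        return []
    chains: list[list[tuple[int, str]]] = [[members[0]]]
    for prev, cur in zip(members, members[1:]):
        if cur[0] - prev[0] - 1 > max_intervening:
            chains.append([cur])
        else:
            chains[-1].append(cur)
    return [tuple(c) for c in chains]


def _refine(seed_a, seed_b, min_genes: int, max_intervening: int,
            out: set[tuple]) -> None:
    """Drive (sideA, sideB) candidate pairs to fixed points, collecting
    single-chain fixed points with enough distinct shared families."""
    stack = [(seed_a, seed_b)]
    seen: set[tuple] = set()
    while stack:
        a, b = stack.pop()
        key = (a, b)
        if key in seen:
            continue
        seen.add(key)
        fams_a = {f for _, f in a}
        fams_b = {f for _, f in b}
        shared = fams_a & fams_b
        if len(shared) < min_genes:
            continue
        a2 = tuple(m for m in a if m[1] in shared)
        b2 = tuple(m for m in b if m[1] in shared)
        chains_a = _split_chains(a2, max_intervening)
        chains_b = _split_chains(b2, max_intervening)
        if len(chains_a) == 1 and len(chains_b) == 1:
            if a2 == a and b2 == b:
                out.add((a, b, frozenset(shared)))
            else:
                stack.append((a2, b2))
        else:
            for ca in chains_a:
                for cb in chains_b:
                    stack.append((ca, cb))


def _maximal(cands: set[tuple]) -> list[tuple]:
    """Drop candidates contained in another candidate on both sides."""
    items = list(cands)
    sets = [(frozenset(a), frozenset(b)) for a, b, _ in items]
    keep = []
    for i, (sa, sb) in enumerate(sets):
        contained = any(
            j != i and sa <= oa and sb <= ob and (sa, sb) != (oa, ob)
            for j, (oa, ob) in enumerate(sets))
        dup = any(j < i and sets[j] == (sa, sb) for j in range(i))
        if not contained and not dup:
            keep.append(items[i])
    return keep


def detect_pairwise_blocks(a: GenomeOrder, b: GenomeOrder,
                           orth: OrthologyMap, min_genes: int = 3,
                           max_intervening: int = 5) -> list[PairwiseBlock]:
    """All maximal microsyntenic blocks between two genomes.

    Symmetric up to side labelling; empty genomes yield an empty list.
    """
    if min_genes < 2:
        raise ValueError("min_genes must be >= 2")
    if max_intervening < 0:
        raise ValueError("max_intervening must be >= 0")

    # family -> chromosomes carrying it, per species
    fam_chroms_b: dict[str, set[str]] = {}
    for chrom, genes in b.chromosomes.items():
        for g in genes:
            fam = orth.family_of(b.species, g.gene_id)
            if fam is not None:
                fam_chroms_b.setdefault(fam, set()).add(chrom)

    blocks: list[PairwiseBlock] = []
    for ca, genes_a in a.chromosomes.items():
        # anchors on ca, bucketed by the partner chromosome that shares
        # their family
        buckets: dict[str, list[tuple[int, str]]] = {}
        for rank, g in enumerate(genes_a):
            fam = orth.family_of(a.species, g.gene_id)
            if fam is None:
                continue
            for cb in fam_chroms_b.get(fam, ()):
                buckets.setdefault(cb, []).append((rank, fam))
        for cb, anchors_a in buckets.items():
            genes_b = b.chromosomes[cb]
            fams_a_here = {f for _, f in anchors_a}
            anchors_b = [
                (rank, fam) for rank, g in enumerate(genes_b)
                if (fam := orth.family_of(b.species, g.gene_id)) in fams_a_here
            ]
            if len(anchors_b) < min_genes or len(anchors_a) < min_genes:
                continue
            cands: set[tuple] = set()
            for seed_a in _split_chains(tuple(anchors_a), max_intervening):
                for seed_b in _split_chains(tuple(anchors_b), max_intervening):
                    _refine(seed_a, seed_b, min_genes, max_intervening, cands)
            for side_a, side_b, fams in _maximal(cands):
                blocks.append(PairwiseBlock(
                    species_a=a.species, species_b=b.species,
                    chrom_a=ca, chrom_b=cb,
                    genes_a=tuple(genes_a[r].gene_id for r, _ in side_a),
                    genes_b=tuple(genes_b[r].gene_id for r, _ in side_b),
                    families=fams))
    blocks.sort(key=lambda bl: (bl.chrom_a, bl.genes_a, bl.chrom_b, bl.genes_b))
    return blocks


def detect_all_pairs(genomes: Sequence[GenomeOrder], orth: OrthologyMap,
                     min_genes: int = 3,
                     max_intervening: int = 5) -> list[PairwiseBlock]:
    """Pairwise blocks over every unordered species pair."""
    blocks: list[PairwiseBlock] = []
    ordered = sorted(genomes, key=lambda g: g.species)
    for i, ga in enumerate(ordered):
        for gb in ordered[i + 1:]:
            blocks.extend(detect_pairwise_blocks(
                ga, gb, orth, min_genes=min_genes,
                max_intervening=max_intervening))
    return blocks


# --------------------------------------------------------------------------
# multi-species clusters
# --------------------------------------------------------------------------


def _jaccard(a: frozenset, b: frozenset) -> float:
    if not a and not b:
        return 0.0
    return len(a & b) / len(a | b)


def merge_blocks_to_clusters(blocks: Sequence[PairwiseBlock],
                             genomes: Mapping[str, GenomeOrder] | Sequence[GenomeOrder],
                             min_family_jaccard: float = 0.5,
                             max_intervening: int = 5) -> list[SyntenyCluster]:
    """Merge pairwise blocks into multi-species clusters.

    Clusters are connected components of the graph joining blocks whose
    family sets have Jaccard similarity >= ``min_family_jaccard``. Each
    species contributes the union of its member genes, split into separate
    loci per chromosome (and within a chromosome wherever consecutive
    members are further apart than ``max_intervening`` genes); a species
    with several loci, or two clusters sharing families above the
    threshold, marks the paralogy flag.
    """
    if not isinstance(genomes, Mapping):
        genomes = {g.species: g for g in genomes}
    g = nx.Graph()
    g.add_nodes_from(range(len(blocks)))
    fams = [bl.families for bl in blocks]
    for i in range(len(blocks)):
        for j in range(i + 1, len(blocks)):
            if _jaccard(fams[i], fams[j]) >= min_family_jaccard:
                g.add_edge(i, j)

    clusters: list[SyntenyCluster] = []
    comps = sorted(nx.connected_components(g), key=min)
    for cid, comp in enumerate(comps):
        members = [blocks[i] for i in sorted(comp)]
        family_union = frozenset().union(*(bl.families for bl in members))
        per_species: dict[str, set[str]] = {}
        for bl in members:
            per_species.setdefault(bl.species_a, set()).update(bl.genes_a)
            per_species.setdefault(bl.species_b, set()).update(bl.genes_b)
        instances: dict[str, list[ClusterInstance]] = {}
        paralogous = False
        for sp, gene_ids in per_species.items():
            genome = genomes[sp]
            by_chrom: dict[str, list[tuple[int, str]]] = {}
            for gid in gene_ids:
                chrom, rank = genome.locate(gid)
                by_chrom.setdefault(chrom, []).append((rank, gid))
            loci: list[ClusterInstance] = []
            for chrom, ranked in by_chrom.items():
                ranked.sort()
                runs: list[list[tuple[int, str]]] = [[ranked[0]]]
                for prev, cur in zip(ranked, ranked[1:]):
                    if cur[0] - prev[0] - 1 > max_intervening:
                        runs.append([cur])
                    else:
                        runs[-1].append(cur)
                for run in runs:
                    gids = tuple(gid for _, gid in run)
                    gs = [genome.gene(gid) for gid in gids]
                    loci.append(ClusterInstance(
                        chrom=chrom, genes=gids,
                        start=min(x.start for x in gs),
                        end=max(x.end for x in gs)))
            if len(loci) > 1:
                paralogous = True
            instances[sp] = sorted(loci, key=lambda l: (l.chrom, l.start))
        clusters.append(SyntenyCluster(
            cluster_id=f"cl{cid:05d}", families=family_union,
            instances=instances, paralogous=paralogous))

    # cross-cluster paralogy: two clusters at disjoint loci sharing families
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            if _jaccard(clusters[i].families,
                        clusters[j].families) >= min_family_jaccard:
                clusters[i].paralogous = True
                clusters[j].paralogous = True
    return clusters


def classify_clusters(clusters: Iterable[SyntenyCluster],
                      focal_clade: set[str], all_species: set[str],
                      reference: str | None = None,
                      ancient_min_species: int = 7,
                      clade_hierarchy: Sequence[tuple[str, set[str], int]] = (),
                      ) -> tuple[list[SyntenyCluster], int]:
    """Assign phylogenetic class labels in place.

    ``novel_clade``: present in the reference species and at least one other
    clade member, and absent from every non-clade species. ``ancient``:
    present in at least ``ancient_min_species`` species outside the focal
    clade. ``clade_hierarchy`` entries ``(label, species_set, min_present)``
    supply intermediate labels (e.g. a molluscan clade), checked in order
    and requiring absence outside their species set. Everything else is
    ``other``. Returns the clusters and the count of clusters skipped
    because the reference species carries no instance.
    """
    if not focal_clade <= all_species:
        raise ValueError("focal_clade must be a subset of all_species")
    if reference is None:
        reference = sorted(focal_clade)[0]
    if reference not in focal_clade:
        raise ValueError("reference species must belong to the focal clade")
    outgroups = all_species - focal_clade
    skipped = 0
    clusters = list(clusters)
    for cl in clusters:
        present = set(cl.species_present)
        if reference not in present:
            skipped += 1
            cl.label = "other"
            continue
        clade_present = present & focal_clade
        out_present = present & outgroups
        if len(clade_present) >= 2 and not out_present:
            cl.label = "novel_clade"
        elif len(out_present) >= ancient_min_species:
            cl.label = "ancient"
        else:
            cl.label = "other"
            for label, clade_set, min_present in clade_hierarchy:
                if (len(present & clade_set) >= min_present
                        and present <= clade_set):
                    cl.label = label
                    break
    if skipped:
        warnings.warn(f"{skipped} clusters lacked the reference species and "
                      "were classified as 'other'", stacklevel=2)
    return clusters, skipped


def build_clusters(genomes: Sequence[GenomeOrder], orth: OrthologyMap,
                   focal_clade: set[str], reference: str | None = None,
                   min_genes: int = 3, max_intervening: int = 5,
                   min_family_jaccard: float = 0.5,
                   ancient_min_species: int = 7,
                   clade_hierarchy: Sequence[tuple[str, set[str], int]] = (),
                   ) -> list[SyntenyCluster]:
    """Full detect -> merge -> classify chain."""
    blocks = detect_all_pairs(genomes, orth, min_genes=min_genes,
                              max_intervening=max_intervening)
    clusters = merge_blocks_to_clusters(
        blocks, genomes, min_family_jaccard=min_family_jaccard,
        max_intervening=max_intervening)
    all_species = {g.species for g in genomes}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        classify_clusters(clusters, focal_clade, all_species,
                          reference=reference,
                          ancient_min_species=ancient_min_species,
                          clade_hierarchy=clade_hierarchy)
    return clusters


# --------------------------------------------------------------------------
# randomizations
# --------------------------------------------------------------------------


def shuffle_genome(genome: GenomeOrder, rng: np.random.Generator) -> GenomeOrder:
    """Uniformly permute gene order within each chromosome; genes swap
    coordinate slots wholesale so geometry is preserved."""
    new_orders = {}
    for chrom, genes in genome.chromosomes.items():
        ids = [g.gene_id for g in genes]
        new_orders[chrom] = [ids[i] for i in rng.permutation(len(ids))]
    return genome.reordered(new_orders)


def shuffle_null(genomes: Sequence[GenomeOrder], orth: OrthologyMap,
                 focal_clade: set[str], reference: str | None = None,
                 query_class: str = "novel_clade", rounds: int = 3,
                 seed: int | np.random.Generator = 0,
                 **detect_kwargs) -> tuple[list[int], float]:
    """Genome-shuffle null model.

    Each round independently permutes gene order within every chromosome of
    every genome, re-runs the full detect -> merge -> classify chain with
    identical parameters, and counts clusters of ``query_class``. Returns
    the per-round counts and their median.
    """
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    counts: list[int] = []
    for _ in range(rounds):
        shuffled = [shuffle_genome(g, rng) for g in genomes]
        clusters = build_clusters(shuffled, orth, focal_clade,
                                  reference=reference, **detect_kwargs)
        counts.append(sum(1 for c in clusters if c.label == query_class))
    return counts, float(statistics.median(counts))


@dataclass(frozen=True)
class RandomBlock:
    chrom: str
    genes: tuple[str, ...]
    start: int
    end: int

    @property
    def span(self) -> int:
        return self.end - self.start


def sample_random_blocks(genome: GenomeOrder,
                         observed: Sequence[SyntenyCluster],
                         iterations: int = 20,
                         seed: int | np.random.Generator = 0,
                         ) -> list[list[RandomBlock]]:
    """Random blocks matched to the observed size distribution.

    For every iteration and every observed cluster, a run of consecutive
    genes with the cluster's gene count is drawn uniformly over all
    placements that do not cross a chromosome end; the size multiset of
    each random set equals the observed one exactly.
    """
    if not observed:
        raise ValueError("observed clusters must be non-empty")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    sizes = []
    for cl in observed:
        if genome.species in cl.instances:
            sizes.append(len(cl.instance(genome.species).genes))
        else:
            sizes.append(len(cl.families))
    chroms = sorted(genome.chromosomes)
    out: list[list[RandomBlock]] = []
    for _ in range(iterations):
        drawn: list[RandomBlock] = []
        for size in sizes:
            eligible = [(c, len(genome.chromosomes[c]) - size + 1)
                        for c in chroms
                        if len(genome.chromosomes[c]) >= size]
            if not eligible:
                raise ValueError(
                    f"block of {size} genes exceeds every chromosome")
            total = sum(n for _, n in eligible)
            r = int(rng.integers(0, total))
            for chrom, n in eligible:
                if r < n:
                    genes = genome.chromosomes[chrom][r:r + size]
                    drawn.append(RandomBlock(
                        chrom=chrom,
                        genes=tuple(g.gene_id for g in genes),
                        start=genes[0].start, end=genes[-1].end))
                    break
                r -= n
        out.append(drawn)
    return out


# --------------------------------------------------------------------------
# geometry
# --------------------------------------------------------------------------


def measure_block_geometry(clusters: Sequence[SyntenyCluster],
                           genomes: Mapping[str, GenomeOrder] | Sequence[GenomeOrder],
                           ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Per-instance geometry plus class comparisons.

    Columns: span (bp), n_genes, intergenic bp between consecutive members
    (overlapping genes contribute 0), mean intervening-gene count. The
    returned dict holds two-sided Wilcoxon rank-sum p-values comparing
    novel vs ancient distributions of intergenic sums and spans.
    """
    if not isinstance(genomes, Mapping):
        genomes = {g.species: g for g in genomes}
    rows = []
    for cl in clusters:
        for sp, loci in cl.instances.items():
            genome = genomes[sp]
            for locus in loci:
                genes = [genome.gene(gid) for gid in locus.genes]
                inter_bp = sum(max(0, b.start - a.end)
                               for a, b in zip(genes, genes[1:]))
                ranks = sorted(genome.locate(gid)[1] for gid in locus.genes)
                intervening = [b - a - 1 for a, b in zip(ranks, ranks[1:])]
                rows.append({
                    "cluster_id": cl.cluster_id, "label": cl.label,
                    "species": sp, "chrom": locus.chrom,
                    "span_bp": locus.span, "n_genes": len(genes),
                    "intergenic_bp": inter_bp,
                    "mean_intervening": (float(np.mean(intervening))
                                         if intervening else 0.0),
                })
    table = pd.DataFrame(rows)
    pvals: dict[str, float] = {}
    if len(table):
        novel = table[table.label == "novel_clade"]
        ancient = table[table.label == "ancient"]
        for col in ("intergenic_bp", "span_bp"):
            if len(novel) >= 2 and len(ancient) >= 2:
                res = rank_sum_test(novel[col], ancient[col],
                                    method="asymptotic")
                pvals[f"{col}_novel_vs_ancient"] = res.pvalue
            else:
                pvals[f"{col}_novel_vs_ancient"] = float("nan")
    return table, pvals
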