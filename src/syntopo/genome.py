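"""Core containers: gene orders, gene models with exons, orthology maps.

Coordinates are 0-based half-open throughout. A :class:`GenomeOrder` stores
one species' chromosomes as coordinate-sorted gene lists; the per-chromosome
rank of a gene (its index in that list) is the unit in which intervening-gene
counts are expressed by the synteny detector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping


@dataclass(frozen=True)
class Gene:
    gene_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"gene {self.gene_id}: start must be < end "
                             f"({self.start} >= {self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be + or -")

    @property
    def tss(self) -> int:
        """Strand-aware transcription start site."""
        return self.start if self.strand == "+" else self.end


class GenomeOrder:
    """One species' chromosomes as coordinate-sorted gene lists."""

    def __init__(self, species: str, chromosomes: Mapping[str, Iterable[Gene]]):
        self.species = species
        self.chromosomes: dict[str, tuple[Gene, ...]] = {}
        self._index: dict[str, tuple[str, int]] = {}  # gene_id -> (chrom, rank)
        for chrom, genes in chromosomes.items():
            genes = tuple(sorted(genes, key=lambda g: (g.start, g.gene_id)))
            self.chromosomes[chrom] = genes
            for rank, g in enumerate(genes):
                if g.gene_id in self._index:
                    raise ValueError(f"duplicate gene id {g.gene_id!r} "
                                     f"in species {species!r}")
                self._index[g.gene_id] = (chrom, rank)

    # -- lookups -----------------------------------------------------------
    def locate(self, gene_id: str) -> tuple[str, int]:
        """(chromosome, rank) of a gene."""
        return self._index[gene_id]

    def gene(self, gene_id: str) -> Gene:
        chrom, rank = self._index[gene_id]
        return self.chromosomes[chrom][rank]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._index

    @property
    def n_genes(self) -> int:
        return len(self._index)

    def iter_genes(self) -> Iterator[tuple[str, Gene]]:
        for chrom, genes in self.chromosomes.items():
            for g in genes:
                yield chrom, g

    def chrom_length(self, chrom: str) -> int:
        genes = self.chromosomes[chrom]
        return genes[-1].end if genes else 0

    def reordered(self, new_orders: Mapping[str, list[str]]) -> "GenomeOrder":
        """New genome with genes swapped wholesale into each other's
        coordinate slots (order randomization that preserves geometry)."""
        chroms: dict[str, list[Gene]] = {}
        for chrom, genes in self.chromosomes.items():
            order = new_orders.get(chrom)
            if order is None:
                chroms[chrom] = list(genes)
                continue
            if len(order) != len(genes):
                raise ValueError(f"permutation length mismatch on {chrom}")
            slots = [(g.start, g.end) for g in genes]
            originals = {g.gene_id: g for g in genes}
            chroms[chrom] = [
                Gene(gid, s, e, originals[gid].strand)
                for gid, (s, e) in zip(order, slots)
            ]
        return GenomeOrder(self.species, chroms)


@dataclass
class GeneModels:
    """Gene order plus exon structure (for feature annotation)."""

    genome: GenomeOrder
    exons: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def exons_of(self, gene_id: str) -> list[tuple[int, int]]:
        """Exon intervals; a gene without exon records is single-exon."""
        ex = self.exons.get(gene_id)
        if not ex:
            g = self.genome.gene(gene_id)
            return [(g.start, g.end)]
        return sorted(ex)


class OrthologyMap:
    """Gene-family assignments across species.

    A gene belongs to at most one family; genes without a family are orphans
    (no detectable homology outside their own lineage).
    """

    def __init__(self, families: Mapping[str, Iterable[tuple[str, str]]]):
        self.families: dict[str, frozenset[tuple[str, str]]] = {
            fam: frozenset(members) for fam, members in families.items()
        }
        self._rev: dict[tuple[str, str], str] = {}
        for fam, members in self.families.items():
            for sp, gid in members:
                key = (sp, gid)
                if key in self._rev:
                    raise ValueError(
                        f"gene {gid!r} of {sp!r} assigned to families "
                        f"{self._rev[key]!r} and {fam!r}")
                self._rev[key] = fam

    def family_of(self, species: str, gene_id: str) -> str | None:
        return self._rev.get((species, gene_id))

    def is_orphan(self, species: str, gene_id: str) -> bool:
        return (species, gene_id) not in self._rev

    def species_families(self, species: str) -> set[str]:
        return {fam for (sp, _), fam in self._rev.items() if sp == species}

    def members(self, family: str) -> frozenset[tuple[str, str]]:
        return self.families[family]

    def __len__(self) -> int:
        return len(self.families)
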