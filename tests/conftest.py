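from __future__ import annotations

import numpy as np
import pytest

from syntopo.genome import Gene, GenomeOrder, OrthologyMap
from syntopo.synthetic import SimulationConfig, simulate_species_set


def make_genome(species: str, layout: dict[str, list[str]],
                gene_len: int = 100, gap: int = 50) -> GenomeOrder:
    """Genome from per-chromosome token lists.

    A token is a family name (``f1``) or ``x`` for a gene with no family;
    repeated families get distinct gene ids. Coordinates are laid
    end-to-end.
    """
    chroms = {}
    serial = 0
    for chrom, tokens in layout.items():
        genes = []
        pos = 0
        for tok in tokens:
            gid = f"{species}.{chrom}.{serial}.{tok}"
            serial += 1
            genes.append(Gene(gid, pos, pos + gene_len))
            pos += gene_len + gap
        chroms[chrom] = genes
    return GenomeOrder(species, chroms)


def orthology_from_genomes(*genomes: GenomeOrder) -> OrthologyMap:
    """Families from the token encoded in each gene id (`x` = orphan)."""
    fams: dict[str, list[tuple[str, str]]] = {}
    for g in genomes:
        for _, gene in g.iter_genes():
            tok = gene.gene_id.rsplit(".", 1)[1]
            if tok != "x":
                fams.setdefault(tok, []).append((g.species, gene.gene_id))
    return OrthologyMap(fams)


def random_toy_pair(rng: np.random.Generator, max_genes: int = 40):
    """Random two-species toy instance for detector/oracle comparison."""
    n_fams = int(rng.integers(3, 9))
    fams = [f"f{i}" for i in range(n_fams)]

    def tokens():
        n = int(rng.integers(6, max_genes + 1))
        toks = []
        for _ in range(n):
            r = rng.random()
            if r < 0.45:
                toks.append(fams[int(rng.integers(0, n_fams))])
            else:
                toks.append("x")
        return toks

    a = make_genome("A", {"c1": tokens()})
    b = make_genome("B", {"c1": tokens()})
    return a, b, orthology_from_genomes(a, b)


@pytest.fixture(scope="session")
def small_fixture():
    """Small planted-truth species set shared across tests."""
    cfg = SimulationConfig(seed=11, n_chromosomes=4,
                           genes_per_chromosome=150,
                           n_ancestral_blocks=6, n_novel_blocks=8)
    genomes, orth, truth = simulate_species_set(cfg)
    return cfg, genomes, orth, truth


@pytest.fixture(scope="session")
def default_fixture():
    """The full default fixture (5 species, 20+30 planted blocks,
    5000 background genes per species)."""
    cfg = SimulationConfig(seed=7)
    genomes, orth, truth = simulate_species_set(cfg)
    return cfg, genomes, orth, truth
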