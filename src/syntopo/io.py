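"""Readers and writers for the tabular formats the pipeline touches.

Internal convention is 0-based half-open everywhere; GFF3 input/output is
converted from/to its native 1-based inclusive coordinates. Writers are
deterministic (sorted, fixed formatting) so that identical runs produce
byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import Gene, GeneModels, GenomeOrder, OrthologyMap
from .synteny import SyntenyCluster, ClusterInstance
from .topology import ContactMatrix, TADSet

_COORD_COMMENT = "# coordinates: 0-based half-open"


# --------------------------------------------------------------------------
# gene models
# --------------------------------------------------------------------------


def write_genes_bed(genome: GenomeOrder, path: str | Path) -> None:
    """BED6 genes (chrom, start, end, gene_id, score, strand)."""
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT + "\n")
        for chrom in sorted(genome.chromosomes):
            for g in genome.chromosomes[chrom]:
                fh.write(f"{chrom}\t{g.start}\t{g.end}\t{g.gene_id}\t0\t"
                         f"{g.strand}\n")


def read_genes_bed(path: str | Path, species: str) -> GenomeOrder:
    chroms: dict[str, list[Gene]] = {}
    n_warn = 0
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            parts = line.rstrip("\n").split("\t")
            chrom, start, end, gid = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 else "+"
            if strand not in ("+", "-"):
                n_warn += 1
                strand = "+"
            chroms.setdefault(chrom, []).append(Gene(gid, start, end, strand))
    if n_warn:
        warnings.warn(f"{n_warn} records had unknown strand; treated as +",
                      stacklevel=2)
    return GenomeOrder(species, chroms)


def write_gff3_lite(models: GeneModels, path: str | Path) -> None:
    """GFF3 subset with gene and exon lines (1-based inclusive on disk)."""
    genome = models.genome
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(genome.chromosomes):
            for g in genome.chromosomes[chrom]:
                fh.write(f"{chrom}\tsyntopo\tgene\t{g.start + 1}\t{g.end}\t."
                         f"\t{g.strand}\t.\tID={g.gene_id}\n")
                for k, (s, e) in enumerate(models.exons_of(g.gene_id)):
                    fh.write(f"{chrom}\tsyntopo\texon\t{s + 1}\t{e}\t.\t"
                             f"{g.strand}\t.\tID={g.gene_id}.e{k};"
                             f"Parent={g.gene_id}\n")


def read_gff3_lite(path: str | Path, species: str) -> GeneModels:
    chroms: dict[str, list[Gene]] = {}
    exons: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            chrom, ftype = f[0], f[2]
            start, end = int(f[3]) - 1, int(f[4])  # to 0-based half-open
            strand = f[6] if f[6] in ("+", "-") else "+"
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            if ftype == "gene":
                chroms.setdefault(chrom, []).append(
                    Gene(attrs["ID"], start, end, strand))
            elif ftype == "exon":
                exons.setdefault(attrs["Parent"], []).append((start, end))
    return GeneModels(GenomeOrder(species, chroms), exons)


# --------------------------------------------------------------------------
# orthology
# --------------------------------------------------------------------------


def write_orthogroups_tsv(orth: OrthologyMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("family_id\tspecies\tgene_id\n")
        for fam in sorted(orth.families):
            for sp, gid in sorted(orth.families[fam]):
                fh.write(f"{fam}\t{sp}\t{gid}\n")


def read_orthogroups_tsv(path: str | Path) -> OrthologyMap:
    fams: dict[str, list[tuple[str, str]]] = {}
    with open(path) as fh:
        header = fh.readline()
        for line in fh:
            fam, sp, gid = line.rstrip("\n").split("\t")
            fams.setdefault(fam, []).append((sp, gid))
    return OrthologyMap(fams)


# --------------------------------------------------------------------------
# contact matrices
# --------------------------------------------------------------------------


def write_contact_matrix_coo(m: ContactMatrix, path: str | Path) -> None:
    """Upper-triangle COO triplets with a chrom/resolution header."""
    with open(path, "w") as fh:
        fh.write(f"# chrom={m.chrom} resolution={m.resolution} "
                 f"n_bins={m.n_bins}\n")
        fh.write("bin_i\tbin_j\tcount\n")
        n = m.n_bins
        for i in range(n):
            for j in range(i, n):
                v = m.counts[i, j]
                if v != 0:
                    fh.write(f"{i}\t{j}\t{v:.10g}\n")


def read_contact_matrix(path: str | Path) -> ContactMatrix:
    """COO triplets or dense TSV; asymmetric input symmetrized by max."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise ValueError("matrix file must start with a '# chrom=... "
                             "resolution=...' header")
        meta = dict(kv.split("=") for kv in header[1:].split())
        rest = fh.read().splitlines()
    chrom = meta["chrom"]
    res = int(meta["resolution"])
    if rest and rest[0].startswith("bin_i"):
        n = int(meta["n_bins"])
        counts = np.zeros((n, n))
        asym = 0
        seen: dict[tuple[int, int], float] = {}
        for line in rest[1:]:
            i, j, v = line.split("\t")
            i, j, v = int(i), int(j), float(v)
            if v < 0:
                raise ValueError("negative counts are not allowed")
            key = (min(i, j), max(i, j))
            if key in seen and seen[key] != v:
                asym += 1
            seen[key] = max(seen.get(key, 0.0), v)
            counts[i, j] = counts[j, i] = seen[key]
        if asym:
            warnings.warn(f"{asym} asymmetric entries symmetrized by max",
                          stacklevel=2)
    else:
        counts = np.array([[float(x) for x in line.split("\t")]
                           for line in rest if line.strip()])
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise ValueError("dense matrix must be square")
        if (counts < 0).any():
            raise ValueError("negative counts are not allowed")
        counts = np.maximum(counts, counts.T)
    return ContactMatrix(chrom, res, counts)


# --------------------------------------------------------------------------
# TADs / intervals
# --------------------------------------------------------------------------


def write_tads_bed(tads: TADSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT + "\n")
        for s, e in tads.intervals:
            fh.write(f"{tads.chrom}\t{s}\t{e}\n")


def read_tads_bed(path: str | Path) -> dict[str, TADSet]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, s, e = line.rstrip("\n").split("\t")[:3]
            by_chrom.setdefault(chrom, []).append((int(s), int(e)))
    return {c: TADSet(c, sorted(v)) for c, v in by_chrom.items()}


# --------------------------------------------------------------------------
# clusters
# --------------------------------------------------------------------------


def write_clusters_tsv(clusters: Sequence[SyntenyCluster],
                       path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("cluster_id\tlabel\tparalogous\tspecies\tchrom\tstart\tend"
                 "\tgene_ids\n")
        for cl in sorted(clusters, key=lambda c: c.cluster_id):
            for sp in sorted(cl.instances):
                for inst in cl.instances[sp]:
                    fh.write(f"{cl.cluster_id}\t{cl.label}\t"
                             f"{int(cl.paralogous)}\t{sp}\t{inst.chrom}\t"
                             f"{inst.start}\t{inst.end}\t"
                             f"{','.join(inst.genes)}\n")


def write_clusters_json(clusters: Sequence[SyntenyCluster],
                        path: str | Path) -> None:
    payload = [{
        "cluster_id": cl.cluster_id,
        "label": cl.label,
        "paralogous": cl.paralogous,
        "families": sorted(cl.families),
        "instances": {
            sp: [{"chrom": i.chrom, "start": i.start, "end": i.end,
                  "genes": list(i.genes)} for i in insts]
            for sp, insts in sorted(cl.instances.items())},
    } for cl in sorted(clusters, key=lambda c: c.cluster_id)]
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_clusters_json(path: str | Path) -> list[SyntenyCluster]:
    payload = json.loads(Path(path).read_text())
    out = []
    for rec in payload:
        out.append(SyntenyCluster(
            cluster_id=rec["cluster_id"],
            families=frozenset(rec["families"]),
            instances={
                sp: [ClusterInstance(chrom=i["chrom"], genes=tuple(i["genes"]),
                                     start=i["start"], end=i["end"])
                     for i in insts]
                for sp, insts in rec["instances"].items()},
            label=rec["label"], paralogous=rec["paralogous"]))
    return out


# --------------------------------------------------------------------------
# truth / manifest
# --------------------------------------------------------------------------


def write_truth_json(truth, path: str | Path) -> None:
    payload = {
        "planted_blocks": [{
            "label": b.label, "families": list(b.families),
            "module": b.module,
            "genes": {sp: list(g) for sp, g in sorted(b.genes.items())},
        } for b in truth.planted_blocks],
        "planted_compact_regions": [list(r) for r in
                                    truth.planted_compact_regions],
        "planted_tads": [list(t) for t in truth.planted_tads],
        "planted_modules": dict(sorted(truth.planted_modules.items())),
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def read_truth_json(path: str | Path):
    from .synthetic import PlantedBlock, TruthSet

    payload = json.loads(Path(path).read_text())
    return TruthSet(
        planted_blocks=[PlantedBlock(
            label=b["label"], families=tuple(b["families"]),
            genes={sp: tuple(g) for sp, g in b["genes"].items()},
            module=b["module"]) for b in payload["planted_blocks"]],
        planted_compact_regions=[tuple(r) for r in
                                 payload["planted_compact_regions"]],
        planted_tads=[tuple(t) for t in payload["planted_tads"]],
        planted_modules=payload["planted_modules"])


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(path: str | Path, *, version: str, config: dict,
                   seed: int, inputs: Iterable[str | Path] = (),
                   stages: dict | None = None,
                   timestamps: dict | None = None) -> None:
    payload = {
        "tool": "syntopo", "version": version, "seed": seed,
        "config": config,
        "input_digests": {str(p): file_digest(p) for p in inputs},
        "stages": stages or {},
        "timestamps": timestamps or {},
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


# --------------------------------------------------------------------------
# misc tables
# --------------------------------------------------------------------------


def write_expression_tsv(expr: pd.DataFrame, path: str | Path) -> None:
    expr.to_csv(path, sep="\t", index_label="gene_id", float_format="%.6g")


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_peaks_bed(peaks, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(_COORD_COMMENT + "\n")
        for p in peaks:
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t"
                     f"{p.category or '.'}\t{p.score:.4g}\t.\t"
                     f"{p.association or '.'}\n")
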