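"""Stage-based pipeline driver.

Stages run in dependency order (simulate -> detect -> topology -> express
-> regulatory -> report); each stage reads its inputs from the output
directory, so stages can also be re-run individually against existing
files. All tabular outputs are deterministic for a fixed config and seed;
wall-clock timestamps appear only in the run manifest.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import fields, replace
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import yaml

from . import io as sio
from . import __version__
from .expression import (cluster_expression_modules, compare_coexpression,
                         dominance_and_relative, module_enrichment,
                         tissue_specificity_tau)
from .regulatory import (annotate_peak_features, associate_with_synteny,
                         feature_enrichment_test)
from .synteny import build_clusters, sample_random_blocks, shuffle_null
from .synthetic import (SimulationConfig, make_gene_models, plan_tads,
                        simulate_contact_matrix, simulate_expression,
                        simulate_peaks, simulate_species_set)
from .topology import (ab_compartments, analyze_compactness,
                       build_interaction_tree, call_tads_insulation,
                       density_ratio, ice_normalize, tad_relative_positions)

log = logging.getLogger("syntopo")

STAGES = ("simulate", "detect", "topology", "express", "regulatory", "report")

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "stages": list(STAGES),
    "simulation": {},
    "detect": {"min_genes": 3, "max_intervening": 5, "rounds": 3,
               "min_family_jaccard": 0.5, "ancient_min_species": 7},
    "topology": {"hic_chromosomes": 1, "hic_resolution": 10_000,
                 "window_bins": 5, "min_bins": 7, "max_bins": 25,
                 "iterations": 20},
    "express": {"k": 8, "iterations": 20},
    "regulatory": {"promoter_flank": 10_000, "margin": 1000,
                   "peaks_per_cluster": 5},
}


class DependencyError(RuntimeError):
    """A stage's upstream output is missing."""


def load_config(source: str | Path | Mapping) -> dict:
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            user = yaml.safe_load(fh) or {}
    else:
        user = dict(source)
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    for key, val in user.items():
        if isinstance(val, Mapping) and isinstance(cfg.get(key), dict):
            cfg[key].update(val)
        else:
            cfg[key] = val
    unknown = set(cfg["stages"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages {sorted(unknown)}")
    return cfg


def _sim_config(cfg: dict) -> SimulationConfig:
    known = {f.name for f in fields(SimulationConfig)}
    params = {k: v for k, v in cfg["simulation"].items() if k in known}
    unknown = set(cfg["simulation"]) - known
    if unknown:
        raise ValueError(f"unknown simulation parameters {sorted(unknown)}")
    params.setdefault("seed", cfg["seed"])
    if isinstance(params.get("block_size_range"), list):
        params["block_size_range"] = tuple(params["block_size_range"])
    if isinstance(params.get("intervening_range"), list):
        params["intervening_range"] = tuple(params["intervening_range"])
    return SimulationConfig(**params)


def _require(outdir: Path, stage: str, *names: str) -> None:
    for name in names:
        if not (outdir / name).exists():
            raise DependencyError(
                f"stage {stage!r} requires missing upstream output {name!r}")


def run_pipeline(config: str | Path | Mapping, outdir: str | Path) -> Path:
    """Execute the configured stages; returns the output directory."""
    cfg = load_config(config)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    timestamps: dict[str, float] = {}
    for stage in STAGES:
        if stage not in cfg["stages"]:
            continue
        t0 = time.time()
        log.info("stage %s starting (params=%s)", stage, cfg.get(stage, {}))
        _STAGE_FUNCS[stage](cfg, outdir)
        timestamps[stage] = round(time.time() - t0, 3)
        log.info("stage %s done in %.2fs", stage, timestamps[stage])
    sio.write_manifest(
        outdir / "manifest.json", version=__version__, config=cfg,
        seed=cfg["seed"],
        inputs=sorted(p for p in outdir.glob("*.tsv")),
        stages={s: cfg.get(s, {}) for s in cfg["stages"]},
        timestamps=timestamps)
    return outdir


# --------------------------------------------------------------------------
# stages
# --------------------------------------------------------------------------


def _stage_simulate(cfg: dict, outdir: Path) -> None:
    sim = _sim_config(cfg)
    genomes, orth, truth = simulate_species_set(sim)
    ref = genomes[0]
    topo = cfg["topology"]
    rng = np.random.default_rng(sim.seed + 1)

    # topology plans on the reference species' first chromosomes
    res = topo["hic_resolution"]
    hic_chroms = sorted(ref.chromosomes)[: topo["hic_chromosomes"]]
    novel_fams = {frozenset(b.families)
                  for b in truth.blocks_of("novel")}
    for chrom in hic_chroms:
        length = ref.chrom_length(chrom)
        tads = plan_tads(length, res, rng)
        truth.planted_tads.extend((chrom, s, e) for s, e in tads)
        compact = []
        for bl in truth.blocks_of("novel"):
            gids = bl.genes[ref.species]
            if ref.locate(gids[0])[0] != chrom:
                continue
            genes = [ref.gene(g) for g in gids]
            compact.append((min(g.start for g in genes),
                            max(g.end for g in genes)))
        truth.planted_compact_regions.extend(
            (chrom, s, e) for s, e in compact)
        m = simulate_contact_matrix(
            replace(sim, hic_resolution=res), length, tads=tads,
            compact_regions=compact, chrom=chrom, rng=rng)
        sio.write_contact_matrix_coo(m, outdir / f"hic_{chrom}.coo.tsv")

    for g in genomes:
        sio.write_genes_bed(g, outdir / f"genes_{g.species}.bed")
    models = make_gene_models(ref, rng=np.random.default_rng(sim.seed + 2))
    sio.write_gff3_lite(models, outdir / "gene_models_reference.gff3")
    sio.write_orthogroups_tsv(orth, outdir / "orthogroups.tsv")
    sio.write_truth_json(truth, outdir / "truth.json")

    expr = simulate_expression(
        [g.gene_id for _, g in ref.iter_genes()], truth, sim,
        rng=np.random.default_rng(sim.seed + 3),
        coexpressed_labels=("ancestral",))
    sio.write_expression_tsv(expr, outdir / "expression.tsv")
    (outdir / "species.json").write_text(json.dumps({
        "clade": sim.species_clade, "outgroup": sim.species_outgroup,
        "reference": sim.reference}, indent=1))


def _read_genomes(cfg: dict, outdir: Path):
    meta = json.loads((outdir / "species.json").read_text())
    species = meta["clade"] + meta["outgroup"]
    genomes = [sio.read_genes_bed(outdir / f"genes_{sp}.bed", sp)
               for sp in species]
    return genomes, meta


def _stage_detect(cfg: dict, outdir: Path) -> None:
    _require(outdir, "detect", "orthogroups.tsv", "species.json")
    genomes, meta = _read_genomes(cfg, outdir)
    orth = sio.read_orthogroups_tsv(outdir / "orthogroups.tsv")
    d = cfg["detect"]
    focal = set(meta["clade"])
    eff_min = min(d["ancient_min_species"], len(meta["outgroup"]))
    clusters = build_clusters(
        genomes, orth, focal, reference=meta["reference"],
        min_genes=d["min_genes"], max_intervening=d["max_intervening"],
        min_family_jaccard=d["min_family_jaccard"],
        ancient_min_species=eff_min)
    sio.write_clusters_tsv(clusters, outdir / "clusters.tsv")
    sio.write_clusters_json(clusters, outdir / "clusters.json")
    counts, median = shuffle_null(
        genomes, orth, focal, reference=meta["reference"],
        rounds=d["rounds"], seed=cfg["seed"] + 10,
        min_genes=d["min_genes"], max_intervening=d["max_intervening"],
        min_family_jaccard=d["min_family_jaccard"],
        ancient_min_species=eff_min)
    observed = sum(1 for c in clusters if c.label == "novel_clade")
    (outdir / "shuffle_null.json").write_text(json.dumps({
        "rounds": counts, "median": median,
        "observed_novel": observed}, indent=1, sort_keys=True))


def _cluster_spans(clusters, species):
    spans = []
    for cl in clusters:
        if species not in cl.instances:
            continue
        inst = cl.instance(species)
        label = {"novel_clade": "novel", "ancient": "ancient"}.get(cl.label)
        if label:
            spans.append((label, inst.chrom, inst.start, inst.end))
    return spans


def _stage_topology(cfg: dict, outdir: Path) -> None:
    _require(outdir, "topology", "clusters.json", "species.json")
    genomes, meta = _read_genomes(cfg, outdir)
    ref = genomes[0]
    clusters = sio.read_clusters_json(outdir / "clusters.json")
    topo = cfg["topology"]
    matrices = sorted(outdir.glob("hic_*.coo.tsv"))
    if not matrices:
        raise DependencyError("stage 'topology' requires hic_*.coo.tsv "
                              "from the simulate stage")
    trees = {}
    tads_all = {}
    profiles = []
    spans = _cluster_spans(clusters, meta["reference"])
    rng = np.random.default_rng(cfg["seed"] + 20)
    random_sets = sample_random_blocks(
        ref, clusters, iterations=topo["iterations"], seed=rng)
    regions = []
    tad_rows = []
    for path in matrices:
        m = ice_normalize(sio.read_contact_matrix(path))
        chrom = m.chrom
        tads = call_tads_insulation(m, topo["window_bins"])
        tads_all[chrom] = tads
        sio.write_tads_bed(tads, outdir / f"tads_{chrom}.bed")
        tree = build_interaction_tree(m)
        trees[chrom] = tree
        (outdir / f"tree_{chrom}.nwk").write_text(tree.to_newick() + "\n")
        signs, vec, _ = ab_compartments(m)
        np.savetxt(outdir / f"compartments_{chrom}.tsv",
                   np.column_stack([signs, vec]), fmt="%.6g",
                   delimiter="\t", header="sign\teigvec", comments="# ")
        for label, c, s, e in spans:
            if c == chrom:
                regions.append((label, chrom, m.bin_of(s),
                                m.bin_of(e - 1) + 1))
        for it in random_sets:
            for rb, (label, *_rest) in zip(it, clusters_labels(clusters)):
                if rb.chrom == chrom and label in ("novel", "ancient"):
                    regions.append((f"random_{label}", chrom,
                                    m.bin_of(rb.start),
                                    m.bin_of(rb.end - 1) + 1))
        obs_pos, _ = tad_relative_positions(
            tads, [(s, e) for lab, c, s, e in spans if c == chrom])
        rnd_spans = [(rb.start, rb.end) for it in random_sets
                     for rb in it if rb.chrom == chrom]
        rnd_pos, _ = tad_relative_positions(tads, rnd_spans)
        tad_rows.append((chrom, obs_pos, rnd_pos))
    table, pvals = analyze_compactness(
        trees, regions, min_bins=topo["min_bins"], max_bins=topo["max_bins"])
    table.to_csv(outdir / "compactness.tsv", sep="\t", index=False,
                 float_format="%.6g")
    obs = np.concatenate([o for _, o, _ in tad_rows]) if tad_rows else []
    rnd = np.concatenate([r for _, _, r in tad_rows]) if tad_rows else []
    ratio_payload = {"pvalues": pvals}
    if len(obs) >= 5 and len(rnd) >= 5:
        grid, ratio = density_ratio(obs, rnd)
        np.savetxt(outdir / "tad_density_ratio.tsv",
                   np.column_stack([grid, ratio]), fmt="%.6g",
                   delimiter="\t", header="position\tratio", comments="# ")
        ratio_payload["n_observed"] = int(len(obs))
        ratio_payload["n_random"] = int(len(rnd))
    (outdir / "topology_stats.json").write_text(
        json.dumps(ratio_payload, indent=1, sort_keys=True))


def clusters_labels(clusters):
    out = []
    for cl in clusters:
        label = {"novel_clade": "novel", "ancient": "ancient"}.get(
            cl.label, "other")
        out.append((label, cl.cluster_id))
    return out


def _stage_express(cfg: dict, outdir: Path) -> None:
    _require(outdir, "express", "expression.tsv", "clusters.json",
             "species.json")
    genomes, meta = _read_genomes(cfg, outdir)
    ref = genomes[0]
    clusters = sio.read_clusters_json(outdir / "clusters.json")
    expr = sio.read_expression_tsv(outdir / "expression.tsv")
    e = cfg["express"]
    observed = {"novel": [], "ancient": []}
    blocks = {}
    classes = {}
    for cl in clusters:
        if meta["reference"] not in cl.instances:
            continue
        genes = list(cl.instance(meta["reference"]).genes)
        label = {"novel_clade": "novel", "ancient": "ancient"}.get(cl.label)
        blocks[cl.cluster_id] = genes
        classes[cl.cluster_id] = label or "other"
        if label:
            observed[label].append(genes)
    random_sets = sample_random_blocks(ref, clusters,
                                       iterations=e["iterations"],
                                       seed=cfg["seed"] + 30)
    random = {"novel": [], "ancient": []}
    for it in random_sets:
        for rb, (label, _) in zip(it, clusters_labels(clusters)):
            if label in random:
                random[label].append(list(rb.genes))
    dists, pvals = compare_coexpression(observed, random, expr)
    k = min(e["k"], len(blocks))
    assignment, means = cluster_expression_modules(blocks, expr, k=k)
    means.to_csv(outdir / "module_profiles.tsv", sep="\t",
                 float_format="%.6g")
    with open(outdir / "modules.tsv", "w") as fh:
        fh.write("cluster_id\tmodule\tclass\n")
        for cid in sorted(assignment.modules):
            fh.write(f"{cid}\t{assignment.modules[cid]}\t{classes[cid]}\n")
    try:
        enrich = module_enrichment(assignment, classes)
        enrich.to_csv(outdir / "module_enrichment.tsv", sep="\t",
                      index=False, float_format="%.6g")
    except ValueError:
        pass
    dom = dominance_and_relative(blocks, expr)
    tau = tissue_specificity_tau(expr)
    payload = {
        "coexpression_pvalues": pvals,
        "coexpression_medians": {k2: float(np.median(v)) if len(v) else None
                                 for k2, v in dists.items()},
        "dominant_fraction": dom.dominant_fraction,
        "variance_mean_spearman": dom.variance_mean_spearman,
        "tau_median": float(tau.dropna().median()),
    }
    (outdir / "expression_stats.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True))


def _stage_regulatory(cfg: dict, outdir: Path) -> None:
    _require(outdir, "regulatory", "clusters.json",
             "gene_models_reference.gff3", "species.json")
    meta = json.loads((outdir / "species.json").read_text())
    models = sio.read_gff3_lite(outdir / "gene_models_reference.gff3",
                                meta["reference"])
    clusters = sio.read_clusters_json(outdir / "clusters.json")
    r = cfg["regulatory"]
    spans = _cluster_spans(clusters, meta["reference"])
    if not spans:
        (outdir / "regulatory_stats.json").write_text(json.dumps(
            {"note": "no classified clusters"}, indent=1))
        return
    probs = {"novel": {"promoter": 0.1, "exon": 0.05, "intron": 0.8,
                       "distal": 0.05},
             "ancient": {"promoter": 0.3, "exon": 0.2, "intron": 0.3,
                         "distal": 0.2}}
    peaks, _truth = simulate_peaks(
        models, spans, probs, peaks_per_cluster=r["peaks_per_cluster"],
        promoter_flank=r["promoter_flank"],
        rng=np.random.default_rng(cfg["seed"] + 40))
    annotate_peak_features(peaks, models, promoter_flank=r["promoter_flank"])
    associate_with_synteny(peaks, spans, margin=r["margin"])
    sio.write_peaks_bed(peaks, outdir / "peaks_annotated.bed")
    try:
        enr = feature_enrichment_test(peaks, focus="intron")
    except ValueError:
        enr = {"odds_ratio": None, "pvalue": None, "table": None}
    (outdir / "regulatory_stats.json").write_text(json.dumps(
        {"intron_enrichment": enr}, indent=1, sort_keys=True))


def _stage_report(cfg: dict, outdir: Path) -> None:
    summary: dict[str, Any] = {"seed": cfg["seed"]}
    for name in ("shuffle_null.json", "topology_stats.json",
                 "expression_stats.json", "regulatory_stats.json"):
        p = outdir / name
        if p.exists():
            summary[name.replace(".json", "")] = json.loads(p.read_text())
    if (outdir / "clusters.json").exists():
        clusters = sio.read_clusters_json(outdir / "clusters.json")
        counts: dict[str, int] = {}
        for cl in clusters:
            counts[cl.label] = counts.get(cl.label, 0) + 1
        summary["cluster_counts"] = counts
    (outdir / "report.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True))


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "topology": _stage_topology,
    "express": _stage_express,
    "regulatory": _stage_regulatory,
    "report": _stage_report,
}
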