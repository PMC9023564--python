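"""Regulatory-element analyses: peak feature annotation, synteny
association, enrichment tests, repeat content, and the conserved
non-coding element (CNE) filter chain with DUST low-complexity masking.

Feature annotation is midpoint-based with precedence
promoter > exon > intron > distal; the promoter is a symmetric window
around the strand-aware transcription start site.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import intervals as iv
from .genome import GeneModels
from .stats import fisher_exact_test

FEATURE_CATEGORIES = ("promoter", "exon", "intron", "distal")


# --------------------------------------------------------------------------
# peak containers
# --------------------------------------------------------------------------


@dataclass
class Peak:
    chrom: str
    start: int
    end: int
    score: float = 0.0
    category: str | None = None
    association: str | None = None
    # fixture-only ground truth, recorded by the peak simulator
    true_category: str | None = None
    true_class: str | None = None

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError("peak start must be < end")

    @property
    def midpoint(self) -> float:
        return (self.start + self.end) / 2.0


class PeakSet:
    def __init__(self, peaks: Sequence[Peak]):
        self.peaks = sorted(peaks, key=lambda p: (p.chrom, p.start, p.end))

    def __len__(self):
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "chrom": p.chrom, "start": p.start, "end": p.end,
            "score": p.score, "category": p.category,
            "association": p.association} for p in self.peaks])


# --------------------------------------------------------------------------
# feature zones and annotation
# --------------------------------------------------------------------------


def feature_zones(models: GeneModels, chrom: str, promoter_flank: int = 10_000,
                  ) -> dict[str, list[tuple[int, int]]]:
    """Disjoint midpoint-eligibility zones per category on one chromosome.

    The zones encode the precedence rules: promoter windows win over exon,
    exon over intron, gene body over intergenic. ``distal`` is everything
    else (represented only implicitly; a bounded distal zone is returned
    for sampling, clipped to the span of annotation +/- one flank).
    """
    genes = models.genome.chromosomes.get(chrom, ())
    promoters = []
    exons = []
    bodies = []
    for g in genes:
        promoters.append((max(0, g.tss - promoter_flank), g.tss + promoter_flank))
        bodies.append((g.start, g.end))
        exons.extend(models.exons_of(g.gene_id))
    promoter_zone = iv.merge(promoters)
    exon_zone = iv.subtract(exons, promoter_zone)
    intron_zone = iv.subtract(iv.subtract(bodies, exons), promoter_zone)
    if genes:
        lo = 0
        hi = max(g.end for g in genes) + promoter_flank
        everything = [(lo, hi)]
    else:
        everything = []
    distal_zone = iv.subtract(iv.subtract(everything, bodies), promoter_zone)
    return {"promoter": promoter_zone, "exon": exon_zone,
            "intron": intron_zone, "distal": distal_zone}


def annotate_peak_features(peaks: PeakSet, models: GeneModels,
                           promoter_flank: int = 10_000) -> PeakSet:
    """Assign each peak a single feature category by its midpoint.

    Precedence promoter > exon > intron > distal; promoter = within
    ``promoter_flank`` of a strand-aware TSS; a gene without exon records
    counts as single-exon (its body is all exon, so never intron).
    """
    zones_by_chrom: dict[str, dict[str, list[tuple[int, int]]]] = {}
    for p in peaks:
        if p.chrom not in zones_by_chrom:
            zones_by_chrom[p.chrom] = feature_zones(
                models, p.chrom, promoter_flank)
        z = zones_by_chrom[p.chrom]
        mid = p.midpoint
        if iv.contains_point(z["promoter"], mid):
            p.category = "promoter"
        elif iv.contains_point(z["exon"], mid):
            p.category = "exon"
        elif iv.contains_point(z["intron"], mid):
            p.category = "intron"
        else:
            p.category = "distal"
    return peaks


def associate_with_synteny(peaks: PeakSet,
                           spans: Sequence[tuple[str, str, int, int]],
                           margin: int = 1000) -> PeakSet:
    """Label peaks by overlap with synteny-class spans extended by margin.

    ``spans`` holds ``(class, chrom, start, end)`` with class in
    {"novel", "ancient"}. A peak overlapping the extended span of both
    classes takes the nearer unextended span; exact ties go to novel.
    Peaks overlapping neither are labelled "none".
    """
    by_chrom: dict[str, list[tuple[str, int, int]]] = {}
    for cls, chrom, s, e in spans:
        by_chrom.setdefault(chrom, []).append((cls, s, e))
    for p in peaks:
        best: dict[str, float] = {}
        for cls, s, e in by_chrom.get(p.chrom, ()):
            if p.start < e + margin and p.end > s - margin:
                # distance to the unextended span (0 when overlapping)
                d = max(0, s - p.end, p.start - e)
                best[cls] = min(best.get(cls, np.inf), d)
        if not best:
            p.association = "none"
        elif len(best) == 1:
            p.association = next(iter(best))
        else:
            p.association = ("novel" if best["novel"] <= best["ancient"]
                             else "ancient")
    return peaks


def feature_enrichment_test(peaks: PeakSet, group_by: str = "association",
                            focus: str = "intron",
                            groups: tuple[str, str] = ("novel", "ancient"),
                            ) -> dict:
    """Fisher exact test: is the focus category enriched in one group?

    Builds the 2x2 table (group x in/out of focus category) over annotated
    peaks and returns odds ratio, p-value and the table.
    """
    g1, g2 = groups
    if group_by == "association":
        in1 = [p for p in peaks if p.association == g1]
        in2 = [p for p in peaks if p.association == g2]
    else:
        raise ValueError("group_by must be 'association'")
    if not in1 or not in2:
        raise ValueError("both groups need at least one peak")
    a = sum(1 for p in in1 if p.category == focus)
    b = len(in1) - a
    c = sum(1 for p in in2 if p.category == focus)
    d = len(in2) - c
    if a + c == 0:
        return {"odds_ratio": float("nan"), "pvalue": float("nan"),
                "table": [[a, b], [c, d]]}
    res = fisher_exact_test([[a, b], [c, d]])
    return {"odds_ratio": res.statistic, "pvalue": res.pvalue,
            "table": [[a, b], [c, d]]}


# --------------------------------------------------------------------------
# repeat content
# --------------------------------------------------------------------------


def repeat_content(peaks: PeakSet,
                   repeats: Sequence[tuple[str, int, int, str]],
                   ) -> tuple[np.ndarray, pd.DataFrame]:
    """Covered fraction per peak plus per-group repeat composition.

    ``repeats`` holds ``(chrom, start, end, family)``. Coverage merges
    overlapping repeats so no base is double-counted; composition is each
    family's share of covered bp within each synteny-association group.
    """
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for chrom, s, e, fam in repeats:
        by_chrom.setdefault(chrom, []).append((s, e, fam))
    fractions = []
    comp_rows = []
    for p in peaks:
        reps = by_chrom.get(p.chrom, ())
        merged = iv.merge([(s, e) for s, e, _ in reps])
        covered = iv.total_length(iv.intersect(merged, [(p.start, p.end)]))
        fractions.append(covered / (p.end - p.start))
        for s, e, fam in reps:
            bp = iv.total_length(iv.intersect([(s, e)], [(p.start, p.end)]))
            if bp:
                comp_rows.append({"association": p.association or "none",
                                  "family": fam, "bp": bp})
    comp = pd.DataFrame(comp_rows, columns=["association", "family", "bp"])
    if len(comp):
        comp = (comp.groupby(["association", "family"], as_index=False)
                .bp.sum())
        comp["share"] = comp.bp / comp.groupby("association").bp.transform("sum")
    else:
        comp["share"] = []
    return np.array(fractions), comp


# --------------------------------------------------------------------------
# CNE filter chain
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class AlignmentHit:
    chrom: str
    start: int
    end: int
    subject_chrom: str = ""
    subject_start: int = 0
    subject_end: int = 0
    identity: float = 100.0

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError("hit length must be > 0")
        if not 0 <= self.identity <= 100:
            raise ValueError("identity must be in [0, 100]")


DUST_WINDOW = 64


def dust_score_windows(seq: str, window: int = DUST_WINDOW) -> np.ndarray:
    """Classic DUST triplet score per sliding window.

    ``S = sum_t c_t (c_t - 1) / 2 / (w - 3)`` over overlapping triplets in
    each ``window``-bp window (one score per start offset; short sequences
    get a single window covering the whole sequence).
    """
    seq = seq.upper()
    n = len(seq)
    w = min(window, n)
    if w < 4:
        return np.zeros(max(1, n - w + 1))
    scores = []
    for off in range(0, n - w + 1):
        counts: dict[str, int] = {}
        sub = seq[off:off + w]
        for i in range(w - 2):
            t = sub[i:i + 3]
            counts[t] = counts.get(t, 0) + 1
        s = sum(c * (c - 1) / 2 for c in counts.values()) / (w - 3)
        scores.append(s)
    return np.array(scores)


def dust_mask(seq: str, cutoff: float = 10.0,
              window: int = DUST_WINDOW) -> np.ndarray:
    """Boolean mask (True = low-complexity) from window DUST scores."""
    n = len(seq)
    mask = np.zeros(n, dtype=bool)
    scores = dust_score_windows(seq, window)
    w = min(window, n)
    for off, s in enumerate(scores):
        if s > cutoff:
            mask[off:off + w] = True
    return mask


@dataclass
class CNEFilterParams:
    min_identity: float = 95.0
    min_size: int = 100
    max_copies: int = 3
    overlap_frac: float = 0.5
    dust_cutoff: float = 10.0
    max_n_frac: float = 0.25


@dataclass
class CNEFilterResult:
    survivors: list[tuple[str, int, int]]
    stage_counts: dict[str, int] = field(default_factory=dict)
    stage_dropped: dict[str, int] = field(default_factory=dict)


def _reciprocal_overlap(a: tuple[int, int], b: tuple[int, int],
                        frac: float) -> bool:
    ov = min(a[1], b[1]) - max(a[0], b[0])
    if ov <= 0:
        return False
    return ov >= frac * (a[1] - a[0]) and ov >= frac * (b[1] - b[0])


def cne_filter_chain(hits: Sequence[AlignmentHit],
                     exons: Sequence[tuple[str, int, int]],
                     params: CNEFilterParams | None = None,
                     seq_fetch: Callable[[str, int, int], str] | None = None,
                     ) -> CNEFilterResult:
    """Ordered CNE filter chain with a per-stage audit trail.

    Stages: (1) identity filter; (2) multimapping removal — drop regions
    whose reciprocal-overlap count (>= ``overlap_frac`` of both regions,
    counting the region itself) exceeds ``max_copies``; (3) merge remaining
    overlapping regions; (4) drop regions overlapping an exon by >= 1 bp;
    (5) DUST-mask (triplet score over 64-bp windows above ``dust_cutoff``),
    trim masked ends and drop if the remainder is shorter than
    ``min_size``; (6) drop regions with N fraction above ``max_n_frac``;
    (7) final length filter. The audit satisfies
    input = survivors + sum of per-stage drops (merged-away regions count
    as stage-3 drops).

    ``seq_fetch(chrom, start, end)`` supplies query sequence for stages 5
    and 6 and is required whenever regions remain at stage 5.
    """
    params = params or CNEFilterParams()
    counts: dict[str, int] = {"input": len(hits)}
    dropped: dict[str, int] = {}

    # 1. identity
    regions = [(h.chrom, h.start, h.end) for h in hits
               if h.identity >= params.min_identity]
    counts["identity"] = len(regions)
    dropped["identity"] = len(hits) - len(regions)

    # 2. multimapping removal (per-region reciprocal-overlap count)
    keep = []
    for i, (c1, s1, e1) in enumerate(regions):
        n_ov = sum(
            1 for c2, s2, e2 in regions
            if c2 == c1 and _reciprocal_overlap((s1, e1), (s2, e2),
                                                params.overlap_frac))
        if n_ov <= params.max_copies:
            keep.append((c1, s1, e1))
    dropped["multimapping"] = len(regions) - len(keep)
    regions = keep
    counts["multimapping"] = len(regions)

    # 3. merge overlapping regions
    merged: list[tuple[str, int, int]] = []
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in regions:
        by_chrom.setdefault(c, []).append((s, e))
    for c in sorted(by_chrom):
        merged.extend((c, s, e) for s, e in iv.merge(by_chrom[c]))
    dropped["merge"] = len(regions) - len(merged)
    regions = merged
    counts["merge"] = len(regions)

    # 4. exon overlap
    exon_by_chrom: dict[str, list[tuple[int, int]]] = {}
    for c, s, e in exons:
        exon_by_chrom.setdefault(c, []).append((s, e))
    exon_by_chrom = {c: iv.merge(v) for c, v in exon_by_chrom.items()}
    keep = [r for r in regions
            if iv.total_length(iv.intersect(
                exon_by_chrom.get(r[0], []), [(r[1], r[2])])) == 0]
    dropped["exon"] = len(regions) - len(keep)
    regions = keep
    counts["exon"] = len(regions)

    # 5. DUST mask, trim masked ends
    if regions and seq_fetch is None:
        raise ValueError("seq_fetch is required for DUST and N-content "
                         "filtering")
    keep = []
    seqs: dict[tuple[str, int, int], str] = {}
    for c, s, e in regions:
        seq = seq_fetch(c, s, e)
        mask = dust_mask(seq, cutoff=params.dust_cutoff)
        unmasked = np.nonzero(~mask)[0]
        if unmasked.size == 0:
            continue
        lo, hi = int(unmasked[0]), int(unmasked[-1]) + 1
        if hi - lo < params.min_size:
            continue
        trimmed = (c, s + lo, s + hi)
        seqs[trimmed] = seq[lo:hi]
        keep.append(trimmed)
    dropped["dust"] = len(regions) - len(keep)
    regions = keep
    counts["dust"] = len(regions)

    # 6. N-content
    keep = []
    for r in regions:
        seq = seqs[r]
        n_frac = (seq.upper().count("N") / len(seq)) if seq else 1.0
        if n_frac <= params.max_n_frac:
            keep.append(r)
    dropped["n_content"] = len(regions) - len(keep)
    regions = keep
    counts["n_content"] = len(regions)

    # 7. length
    keep = [r for r in regions if r[2] - r[1] >= params.min_size]
    dropped["length"] = len(regions) - len(keep)
    regions = keep
    counts["length"] = len(regions)

    return CNEFilterResult(survivors=regions, stage_counts=counts,
                           stage_dropped=dropped)
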