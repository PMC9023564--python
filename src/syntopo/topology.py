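"""Hi-C contact-matrix topology: balancing, TAD calling, interaction trees,
compactness ratios, TAD-relative localization and A/B compartments.

The interaction tree is an adjacency-constrained agglomerative dendrogram:
at each step the two *chromosomally adjacent* clusters with the highest mean
inter-cluster contact frequency merge (average linkage, leftmost pair on
ties), so every subtree spans a contiguous bin interval. The compactness of
a genomic region is the number of bins it covers divided by the number of
leaf bins under the last common ancestor of those bins — near 1 when the
region forms its own tight interaction compartment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import rank_sum_test

# --------------------------------------------------------------------------
# contact matrices
# --------------------------------------------------------------------------


@dataclass
class ContactMatrix:
    """Binned, symmetric, non-negative contact matrix for one chromosome.

    Bin ``k`` covers ``[k*resolution, (k+1)*resolution)``.
    """

    chrom: str
    resolution: int
    counts: np.ndarray
    normalized: bool = False

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=float)
        n, m = self.counts.shape
        if n != m:
            raise ValueError("contact matrix must be square")
        if (self.counts < 0).any():
            raise ValueError("contact matrix must be non-negative")
        scale = max(np.abs(self.counts).max(), 1.0)
        if not np.allclose(self.counts, self.counts.T,
                           rtol=1e-9, atol=1e-9 * scale):
            raise ValueError("contact matrix must be symmetric")

    @property
    def n_bins(self) -> int:
        return self.counts.shape[0]

    def bin_of(self, pos: float) -> int:
        return int(pos // self.resolution)


def ice_normalize(m: ContactMatrix, max_iter: int = 200,
                  tol: float = 1e-6) -> ContactMatrix:
    """Iterative proportional fitting (ICE balancing).

    After balancing, every non-masked row sum equals the mean row sum
    within ``tol`` (relative); rows with zero coverage stay zero.
    """
    counts = m.counts.copy()
    rowsum = counts.sum(axis=1)
    mask = rowsum == 0
    if mask.all():
        raise ValueError("cannot normalize an all-zero matrix")
    for _ in range(max_iter):
        s = counts.sum(axis=1)
        mean = s[~mask].mean()
        delta = np.where(mask, 1.0, s / mean)
        if np.abs(delta[~mask] - 1.0).max() < tol:
            break
        counts /= np.outer(delta, delta)
    return ContactMatrix(m.chrom, m.resolution, counts, normalized=True)


# --------------------------------------------------------------------------
# TAD calling (plumbing insulation-score caller)
# --------------------------------------------------------------------------


@dataclass
class TADSet:
    chrom: str
    intervals: list[tuple[int, int]]  # bp, sorted, non-overlapping
    boundary_scores: list[float] = field(default_factory=list)

    def __post_init__(self):
        prev_end = None
        for s, e in self.intervals:
            if e <= s:
                raise ValueError("TAD intervals must have start < end")
            if prev_end is not None and s < prev_end:
                raise ValueError("TAD intervals must not overlap")
            prev_end = e


def call_tads_insulation(m: ContactMatrix, window_bins: int) -> TADSet:
    """Insulation-score domain caller.

    The score at the boundary between bins ``i-1`` and ``i`` is the mean of
    the ``window x window`` submatrix crossing it; boundaries are strict
    local minima below (mean - 1 SD) of the score track. Domains are the
    intervals between consecutive boundaries (and the chromosome ends).
    """
    if window_bins < 2:
        raise ValueError("window_bins must be >= 2")
    n = m.n_bins
    if n < 3 * window_bins:
        warnings.warn("chromosome shorter than 3 windows; no TADs called",
                      stacklevel=2)
        return TADSet(m.chrom, [])
    w = window_bins
    positions = list(range(w, n - w + 1))
    scores = np.array([m.counts[i - w:i, i:i + w].mean() for i in positions])
    mu, sd = scores.mean(), scores.std()
    cutoff = mu - sd
    boundaries = []
    bscores = []
    for k, i in enumerate(positions):
        if scores[k] >= cutoff:
            continue
        left = scores[k - 1] if k > 0 else np.inf
        right = scores[k + 1] if k + 1 < len(scores) else np.inf
        if scores[k] <= left and scores[k] <= right:
            # plateau tie: keep only the leftmost bin of a flat minimum
            if boundaries and i - boundaries[-1] == 1 and scores[k] == bscores[-1]:
                continue
            boundaries.append(i)
            bscores.append(float(scores[k]))
    edges = [0] + boundaries + [n]
    res = m.resolution
    intervals = [(a * res, b * res) for a, b in zip(edges, edges[1:]) if b > a]
    return TADSet(m.chrom, intervals, bscores)


# --------------------------------------------------------------------------
# interaction tree
# --------------------------------------------------------------------------


class InteractionTree:
    """Adjacency-constrained binary dendrogram over chromosome bins.

    Nodes ``0..n-1`` are leaves (bins, chromosomal order); internal nodes
    ``n..2n-2`` store their children, merge strength and contiguous leaf
    span ``(lo, hi)`` (half-open bin interval).
    """

    def __init__(self, n_leaves: int):
        if n_leaves < 2:
            raise ValueError("need at least 2 bins")
        self.n_leaves = n_leaves
        self.children: dict[int, tuple[int, int]] = {}
        self.strength: dict[int, float] = {}
        self.span: dict[int, tuple[int, int]] = {
            i: (i, i + 1) for i in range(n_leaves)}

    @property
    def root(self) -> int:
        return 2 * self.n_leaves - 2

    def add_node(self, node: int, left: int, right: int, strength: float):
        self.children[node] = (left, right)
        self.strength[node] = strength
        self.span[node] = (self.span[left][0], self.span[right][1])

    def lca(self, lo: int, hi: int) -> int:
        """Deepest node whose leaf span contains bins ``[lo, hi)``."""
        if not (0 <= lo < hi <= self.n_leaves):
            raise ValueError("interval outside leaf range")
        node = self.root if self.n_leaves > 1 else 0
        while node in self.children:
            l, r = self.children[node]
            if self.span[l][0] <= lo and hi <= self.span[l][1]:
                node = l
            elif self.span[r][0] <= lo and hi <= self.span[r][1]:
                node = r
            else:
                break
        return node

    def to_newick(self) -> str:
        def rec(node: int) -> str:
            if node not in self.children:
                return f"bin{node}"
            l, r = self.children[node]
            return f"({rec(l)},{rec(r)})s={self.strength[node]:.6g}"
        return rec(self.root) + ";"


def build_interaction_tree(m: ContactMatrix) -> InteractionTree:
    """Agglomerative average-linkage clustering constrained to adjacency.

    Each step merges the adjacent cluster pair with the highest mean
    inter-cluster contact (leftmost pair on ties); n-1 merges total.
    """
    n = m.n_bins
    if n < 2:
        raise ValueError("need at least 2 bins")
    # 2D prefix sums for O(1) block means
    c = np.zeros((n + 1, n + 1))
    c[1:, 1:] = m.counts.cumsum(axis=0).cumsum(axis=1)

    def block_sum(i0, i1, j0, j1):
        return c[i1, j1] - c[i0, j1] - c[i1, j0] + c[i0, j0]

    tree = InteractionTree(n)
    active: list[int] = list(range(n))  # node ids, left to right
    spans: list[tuple[int, int]] = [(i, i + 1) for i in range(n)]

    def link(k: int) -> float:
        (a0, a1), (b0, b1) = spans[k], spans[k + 1]
        return block_sum(a0, a1, b0, b1) / ((a1 - a0) * (b1 - b0))

    strengths = [link(k) for k in range(n - 1)]
    next_id = n
    while len(active) > 1:
        k = int(np.argmax(strengths))  # argmax takes the leftmost maximum
        tree.add_node(next_id, active[k], active[k + 1], float(strengths[k]))
        spans[k] = (spans[k][0], spans[k + 1][1])
        active[k] = next_id
        del spans[k + 1], active[k + 1], strengths[k]
        if k > 0:
            strengths[k - 1] = link(k - 1)
        if k < len(active) - 1:
            strengths[k] = link(k)
        next_id += 1
    return tree


def compactness_ratio(tree: InteractionTree, lo: int, hi: int) -> float:
    """Bins in the region divided by leaf bins under the region's LCA."""
    if hi <= lo:
        raise ValueError("empty bin interval")
    node = tree.lca(lo, hi)
    s0, s1 = tree.span[node]
    return (hi - lo) / (s1 - s0)


def analyze_compactness(trees: Mapping[str, InteractionTree],
                        regions: Sequence[tuple[str, str, int, int]],
                        min_bins: int = 7, max_bins: int = 25,
                        ) -> tuple[pd.DataFrame, dict[str, float]]:
    """Group compactness-ratio table plus pairwise Wilcoxon p-values.

    ``regions`` holds ``(group, chrom, lo_bin, hi_bin)``; only regions
    spanning ``[min_bins, max_bins]`` bins enter. The linked comparisons
    are observed-vs-random within each class and novel-vs-ancient.
    """
    rows = []
    for group, chrom, lo, hi in regions:
        width = hi - lo
        if width < min_bins or width > max_bins:
            continue
        tree = trees[chrom]
        if hi > tree.n_leaves:
            continue
        rows.append({"group": group, "chrom": chrom, "lo": lo, "hi": hi,
                     "n_bins": width,
                     "ratio": compactness_ratio(tree, lo, hi)})
    table = pd.DataFrame(rows, columns=["group", "chrom", "lo", "hi",
                                        "n_bins", "ratio"])
    comparisons = [("novel", "random_novel"), ("ancient", "random_ancient"),
                   ("novel", "ancient")]
    pvals: dict[str, float] = {}
    for g1, g2 in comparisons:
        x = table.loc[table.group == g1, "ratio"]
        y = table.loc[table.group == g2, "ratio"]
        if len(x) >= 2 and len(y) >= 2:
            pvals[f"{g1}_vs_{g2}"] = rank_sum_test(
                x, y, method="asymptotic").pvalue
        else:
            pvals[f"{g1}_vs_{g2}"] = float("nan")
    return table, pvals


# --------------------------------------------------------------------------
# TAD-relative localization
# --------------------------------------------------------------------------


def tad_relative_positions(tads: TADSet,
                           spans: Sequence[tuple[int, int]],
                           ) -> tuple[np.ndarray, int]:
    """Normalized position of each region midpoint within its TAD.

    Only the TAD containing the midpoint counts, even when the region spans
    several TADs. Midpoints falling in no TAD (and zero-length TADs) are
    dropped; the drop count is returned alongside.
    """
    starts = np.array([s for s, _ in tads.intervals])
    ends = np.array([e for _, e in tads.intervals])
    out = []
    dropped = 0
    for s, e in spans:
        mid = (s + e) / 2.0
        i = np.searchsorted(starts, mid, side="right") - 1
        if i < 0 or mid >= ends[i]:
            dropped += 1
            continue
        length = ends[i] - starts[i]
        if length <= 0:
            dropped += 1
            continue
        out.append((mid - starts[i]) / length)
    return np.array(out), dropped


def density_ratio(observed, random, n_gridpoints: int = 50,
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Ratio of Gaussian KDEs (Silverman bandwidth) on a uniform grid.

    A ratio above 1 marks enrichment of observed positions relative to the
    random sample at that normalized TAD location.
    """
    observed = np.asarray(observed, dtype=float)
    random = np.asarray(random, dtype=float)
    if len(observed) < 5 or len(random) < 5:
        raise ValueError("need at least 5 positions per sample")
    grid = np.linspace(0.0, 1.0, n_gridpoints)
    kde_obs = sps.gaussian_kde(observed, bw_method="silverman")
    kde_rnd = sps.gaussian_kde(random, bw_method="silverman")
    return grid, kde_obs(grid) / kde_rnd(grid)


# --------------------------------------------------------------------------
# A/B compartments
# --------------------------------------------------------------------------


def ab_compartments(m: ContactMatrix, covariate=None,
                    ) -> tuple[np.ndarray, np.ndarray, bool]:
    """Two-state compartment signs from the leading eigenvector.

    Observed/expected by distance, Pearson correlation matrix, first
    eigenvector; with a per-bin ``covariate`` (e.g. gene density) the sign
    is oriented so positive correlates with the covariate (A). Returns
    ``(signs, eigenvector, oriented)``.
    """
    counts = m.counts
    n = m.n_bins
    if n < 10:
        raise ValueError("need at least 10 bins")
    if np.allclose(counts, counts.flat[0]):
        raise ValueError("constant matrix has no compartment signal")
    expected = np.zeros_like(counts)
    for d in range(n):
        diag = np.diagonal(counts, offset=d)
        mu = diag.mean()
        idx = np.arange(n - d)
        expected[idx, idx + d] = mu
        expected[idx + d, idx] = mu
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = np.where(expected > 0, counts / expected, 0.0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        corr = np.corrcoef(oe)
    corr = np.nan_to_num(corr, nan=0.0)
    vals, vecs = np.linalg.eigh(corr)
    vec = vecs[:, -1]
    oriented = False
    if covariate is not None:
        cov = np.asarray(covariate, dtype=float)
        r = np.corrcoef(vec, cov)[0, 1]
        if np.isfinite(r) and r < 0:
            vec = -vec
        oriented = True
    signs = np.where(vec >= 0, 1, -1)
    return signs, vec, oriented
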