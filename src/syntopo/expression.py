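"""Expression analyses of syntenic blocks.

Block co-expression (mean pairwise Pearson correlation of log-transformed
tissue profiles), comparison against size-matched random blocks, module
clustering of block mean profiles, class enrichment per module, dominance
and relative-expression diagnostics, and the tau tissue-specificity index.

Expression matrices are pandas DataFrames (genes x tissues, TPM-like,
non-negative). All correlation-based statistics use log2(x+1) profiles by
default; the transform is configurable off where noted.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster.hierarchy import fcluster, linkage

from .stats import fisher_exact_test, rank_sum_test


def _validate_expr(expr: pd.DataFrame) -> None:
    if expr.shape[1] < 2:
        raise ValueError("expression matrix needs at least 2 tissues")
    if (expr.values < 0).any():
        raise ValueError("expression values must be non-negative")
    if expr.index.duplicated().any():
        raise ValueError("gene ids must be unique")


def _log(expr: pd.DataFrame) -> pd.DataFrame:
    return np.log2(expr + 1.0)


# --------------------------------------------------------------------------
# co-expression
# --------------------------------------------------------------------------


def coexpression_coefficient(genes: Sequence[str], expr: pd.DataFrame,
                             log: bool = True,
                             ) -> tuple[float | None, int, int]:
    """Mean pairwise Pearson correlation of a block's tissue profiles.

    Genes absent from the matrix or with zero variance (after log) are
    excluded. Returns ``(coefficient or None, n_used, n_excluded)``; the
    coefficient is undefined with fewer than 2 usable genes.
    """
    _validate_expr(expr)
    present = [g for g in genes if g in expr.index]
    mat = expr.loc[present]
    if log:
        mat = _log(mat)
    usable = mat[mat.std(axis=1, ddof=0) > 0]
    n_excluded = len(genes) - len(usable)
    if len(usable) < 2:
        return None, len(usable), n_excluded
    r = np.corrcoef(usable.values)
    iu = np.triu_indices(len(usable), k=1)
    return float(r[iu].mean()), len(usable), n_excluded


def compare_coexpression(observed: Mapping[str, Sequence[Sequence[str]]],
                         random: Mapping[str, Sequence[Sequence[str]]],
                         expr: pd.DataFrame, log: bool = True,
                         ) -> tuple[dict[str, np.ndarray], dict[str, float]]:
    """Per-group co-expression distributions plus Wilcoxon p-values.

    ``observed`` maps class ("novel", "ancient") to lists of gene lists;
    ``random`` holds size-matched random block sets keyed the same way.
    Linked comparisons: novel vs random-novel, ancient vs random-ancient,
    novel vs ancient (two-sided rank-sum). Groups with <2 defined
    coefficients yield NaN p-values.
    """
    dists: dict[str, np.ndarray] = {}
    for name, blocks in list(observed.items()) + [
            (f"random_{k}", v) for k, v in random.items()]:
        coefs = []
        for genes in blocks:
            c, _, _ = coexpression_coefficient(genes, expr, log=log)
            if c is not None:
                coefs.append(c)
        dists[name] = np.array(coefs)
    if all(len(v) == 0 for v in dists.values()):
        warnings.warn("no defined co-expression coefficients", stacklevel=2)
    pvals: dict[str, float] = {}
    for g1, g2 in [("novel", "random_novel"), ("ancient", "random_ancient"),
                   ("novel", "ancient")]:
        x, y = dists.get(g1, ()), dists.get(g2, ())
        if len(x) >= 2 and len(y) >= 2:
            pvals[f"{g1}_vs_{g2}"] = rank_sum_test(
                x, y, method="asymptotic").pvalue
        else:
            pvals[f"{g1}_vs_{g2}"] = float("nan")
    return dists, pvals


# --------------------------------------------------------------------------
# expression modules
# --------------------------------------------------------------------------


@dataclass
class ModuleAssignment:
    modules: dict[str, int]  # cluster id -> 1..k
    k: int


def cluster_expression_modules(blocks: Mapping[str, Sequence[str]],
                               expr: pd.DataFrame, k: int = 8,
                               ) -> tuple[ModuleAssignment, pd.DataFrame]:
    """Hierarchical module clustering of block mean profiles.

    Each block's profile is the mean expression (log2(x+1)) of its member
    genes per tissue, z-scored per block; Ward linkage on Euclidean
    distance cut at ``k`` modules. Deterministic given input order.
    Returns the assignment and per-module mean (z-scored) profiles.
    """
    _validate_expr(expr)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(blocks):
        raise ValueError(f"k={k} exceeds the number of blocks ({len(blocks)})")
    ids = list(blocks)
    logged = _log(expr)
    profiles = []
    for bid in ids:
        genes = [g for g in blocks[bid] if g in expr.index]
        if not genes:
            raise ValueError(f"block {bid!r} has no genes in the matrix")
        profiles.append(logged.loc[genes].mean(axis=0).values)
    prof = np.asarray(profiles)
    mu = prof.mean(axis=1, keepdims=True)
    sd = prof.std(axis=1, keepdims=True, ddof=0)
    z = np.where(sd > 0, (prof - mu) / np.where(sd == 0, 1, sd), 0.0)
    if len(ids) == 1 or k == 1:
        labels = np.ones(len(ids), dtype=int)
    else:
        lk = linkage(z, method="ward")
        labels = fcluster(lk, t=k, criterion="maxclust")
    assignment = ModuleAssignment(
        modules={bid: int(lab) for bid, lab in zip(ids, labels)}, k=k)
    means = pd.DataFrame(
        [z[labels == m].mean(axis=0) for m in range(1, k + 1)],
        index=[f"module_{m}" for m in range(1, k + 1)],
        columns=expr.columns)
    return assignment, means


def module_enrichment(assignment: ModuleAssignment,
                      classes: Mapping[str, str]) -> pd.DataFrame:
    """Per-module Fisher exact enrichment of novel vs ancient blocks.

    The 2x2 table per module crosses in/out of the module with
    novel/ancient class (blocks with other labels are ignored).
    """
    labelled = {bid: classes[bid] for bid in assignment.modules
                if classes.get(bid) in ("novel", "ancient",
                                        "novel_clade")}
    if len({v for v in labelled.values()}) < 2:
        raise ValueError("need both classes represented")
    is_novel = {bid: v != "ancient" for bid, v in labelled.items()}
    rows = []
    for m in range(1, assignment.k + 1):
        in_mod = [bid for bid in labelled
                  if assignment.modules[bid] == m]
        if not in_mod:
            continue
        out_mod = [bid for bid in labelled
                   if assignment.modules[bid] != m]
        a = sum(is_novel[b] for b in in_mod)
        b = len(in_mod) - a
        c = sum(is_novel[x] for x in out_mod)
        d = len(out_mod) - c
        res = fisher_exact_test([[a, b], [c, d]])
        rows.append({"module": m, "n_novel_in": a, "n_ancient_in": b,
                     "odds_ratio": res.statistic, "pvalue": res.pvalue})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# dominance / relative expression / specificity
# --------------------------------------------------------------------------


@dataclass
class DominanceResult:
    dominant_fraction: float
    n_defined: int
    per_block_dominant_share: dict[str, float]
    relative_profiles: pd.DataFrame  # block x tissue, averaged relative expr
    variance_mean_spearman: float


def dominance_and_relative(blocks: Mapping[str, Sequence[str]],
                           expr: pd.DataFrame) -> DominanceResult:
    """Dominance of single genes within blocks plus relative profiles.

    A block is dominated when one gene contributes more than half the
    block's cumulative expression (linear scale, summed over tissues);
    blocks with zero total are excluded from the fraction's denominator.
    Relative profiles normalize each gene's tissue vector by its own total
    before averaging across block members. The variance-vs-mean relation
    across all member genes is summarized as a Spearman correlation.
    """
    _validate_expr(expr)
    shares: dict[str, float] = {}
    rel_rows = {}
    all_genes: set[str] = set()
    for bid, genes in blocks.items():
        present = [g for g in genes if g in expr.index]
        if not present:
            continue
        sub = expr.loc[present]
        totals = sub.sum(axis=1)
        block_total = totals.sum()
        if block_total > 0:
            shares[bid] = float(totals.max() / block_total)
        expressed = sub[totals > 0]
        if len(expressed):
            rel = expressed.div(expressed.sum(axis=1), axis=0)
            rel_rows[bid] = rel.mean(axis=0)
        all_genes.update(present)
    n_defined = len(shares)
    frac = (sum(1 for s in shares.values() if s > 0.5) / n_defined
            if n_defined else float("nan"))
    gene_mat = expr.loc[sorted(all_genes)]
    means = gene_mat.mean(axis=1)
    variances = gene_mat.var(axis=1, ddof=0)
    if len(gene_mat) >= 3 and means.std() > 0 and variances.std() > 0:
        rho = float(sps.spearmanr(means, variances).statistic)
    else:
        rho = float("nan")
    return DominanceResult(
        dominant_fraction=frac, n_defined=n_defined,
        per_block_dominant_share=shares,
        relative_profiles=pd.DataFrame(rel_rows).T,
        variance_mean_spearman=rho)


def tissue_specificity_tau(expr: pd.DataFrame, log: bool = True) -> pd.Series:
    """Tau index per gene: 0 = uniform expression, 1 = single-tissue.

    tau = sum_i (1 - x_i / x_max) / (n - 1) on log2(x+1) profiles (values
    are non-negative by construction). All-zero genes yield NaN.
    """
    _validate_expr(expr)
    mat = _log(expr) if log else expr.clip(lower=0)
    xmax = mat.max(axis=1)
    n = mat.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = (1.0 - mat.div(xmax, axis=0)).sum(axis=1) / (n - 1)
    tau[xmax <= 0] = np.nan
    return tau
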