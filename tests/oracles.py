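"""Independent reference implementations used only by the tests.

These deliberately take different algorithmic routes from the package:
window enumeration instead of recursive refinement for block detection,
literal combination enumeration for the rank-sum distribution, exact
rational hypergeometric sums for Fisher's test, and a plain row/column
scaling loop for matrix balancing.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb

import numpy as np
from scipy.stats import rankdata


# --------------------------------------------------------------------------
# exhaustive window oracle for pairwise block detection
# --------------------------------------------------------------------------


def _window_fixpoint(idx_a, idx_b, fams_a, fams_b):
    """Filter-only fixed point of the shared-family restriction."""
    a, b = list(idx_a), list(idx_b)
    while True:
        fa = {fams_a[i] for i in a}
        fb = {fams_b[j] for j in b}
        shared = fa & fb
        a2 = [i for i in a if fams_a[i] in shared]
        b2 = [j for j in b if fams_b[j] in shared]
        if a2 == a and b2 == b:
            return a, b, shared
        if not a2 or not b2:
            return [], [], set()
        a, b = a2, b2


def _gaps_ok(indices, max_intervening):
    return all(j - i - 1 <= max_intervening
               for i, j in zip(indices, indices[1:]))


def oracle_pairwise_blocks(a, b, orth, min_genes=3, max_intervening=5):
    """All maximal blocks by enumeration over anchor-delimited windows.

    Returns a set of ``(chrom_a, frozenset(genes_a), chrom_b,
    frozenset(genes_b))`` tuples for direct comparison with the detector.
    """
    out = set()
    for ca, genes_a in a.chromosomes.items():
        fams_a = [orth.family_of(a.species, g.gene_id) for g in genes_a]
        for cb, genes_b in b.chromosomes.items():
            fams_b = [orth.family_of(b.species, g.gene_id) for g in genes_b]
            set_a = {f for f in fams_a if f}
            set_b = {f for f in fams_b if f}
            anchors_a = [i for i, f in enumerate(fams_a) if f and f in set_b]
            anchors_b = [j for j, f in enumerate(fams_b) if f and f in set_a]
            cands = set()
            for p in range(len(anchors_a)):
                for q in range(p + min_genes - 1, len(anchors_a)):
                    for r in range(len(anchors_b)):
                        for s in range(r + min_genes - 1, len(anchors_b)):
                            ia, ib, shared = _window_fixpoint(
                                anchors_a[p:q + 1], anchors_b[r:s + 1],
                                fams_a, fams_b)
                            if (len(shared) >= min_genes
                                    and _gaps_ok(ia, max_intervening)
                                    and _gaps_ok(ib, max_intervening)):
                                cands.add((tuple(ia), tuple(ib)))
            # drop candidates contained in another candidate on both sides
            for ia, ib in cands:
                sa, sb = set(ia), set(ib)
                if any((set(oa) >= sa and set(ob) >= sb
                        and (set(oa), set(ob)) != (sa, sb))
                       for oa, ob in cands):
                    continue
                out.add((ca, frozenset(genes_a[i].gene_id for i in ia),
                         cb, frozenset(genes_b[j].gene_id for j in ib)))
    return out


def blocks_as_sets(blocks):
    """Canonicalize detector output for comparison with the oracle."""
    return {(bl.chrom_a, frozenset(bl.genes_a),
             bl.chrom_b, frozenset(bl.genes_b)) for bl in blocks}


# --------------------------------------------------------------------------
# statistics oracles
# --------------------------------------------------------------------------


def oracle_ranksum_p(x, y):
    """Two-sided rank-sum p by literal enumeration of all subsets."""
    x, y = list(x), list(y)
    pooled = np.array(x + y, dtype=float)
    ranks = rankdata(pooled)
    n1, n = len(x), len(pooled)
    t_obs = ranks[:n1].sum()
    le = ge = total = 0
    for idx in combinations(range(n), n1):
        t = ranks[list(idx)].sum()
        total += 1
        if t <= t_obs + 1e-12:
            le += 1
        if t >= t_obs - 1e-12:
            ge += 1
    return min(1.0, 2.0 * min(le / total, ge / total))


def oracle_fisher_p(table):
    """Two-sided Fisher p by exact rational hypergeometric enumeration.

    Uses the standard inclusion rule (tables at least as unlikely as the
    observed one, with the customary 1e-7 relative slack for ties).
    """
    (a, b), (c, d) = table
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    denom = comb(n, col1)

    def pmf(k):
        if k < 0 or k > row1 or col1 - k < 0 or col1 - k > row2:
            return Fraction(0)
        return Fraction(comb(row1, k) * comb(row2, col1 - k), denom)

    p_obs = pmf(a)
    cutoff = p_obs * (Fraction(10 ** 7 + 1, 10 ** 7))
    p = sum((pk for k in range(0, col1 + 1)
             if (pk := pmf(k)) <= cutoff), Fraction(0))
    return float(min(p, Fraction(1)))


def oracle_ipf(matrix, n_iter=2000):
    """Plain alternating row/column scaling to equal row sums."""
    m = np.array(matrix, dtype=float)
    mask = m.sum(axis=1) == 0
    for _ in range(n_iter):
        s = m.sum(axis=1)
        target = s[~mask].mean()
        scale = np.where(mask, 1.0, np.sqrt(s / target))
        m = m / scale[:, None] / scale[None, :]
    return m


def oracle_tau(profile):
    """Direct formula evaluation of the tissue-specificity index."""
    x = np.log2(np.asarray(profile, dtype=float) + 1.0)
    xmax = x.max()
    if xmax <= 0:
        return float("nan")
    return float(np.sum(1 - x / xmax) / (len(x) - 1))
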