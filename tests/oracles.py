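"""Independent brute-force oracles.

These deliberately avoid the package's vectorized code paths: plain Python
loops and exhaustive enumeration only, so they can arbitrate correctness.
"""

from __future__ import annotations

import numpy as np
from sympy.utilities.iterables import multiset_permutations


def brute_ssgsea(expression, genes, gene_set, alpha):
    """Running-sum enrichment computed with an explicit per-rank loop."""
    pairs = list(zip(genes, expression))
    # descending expression, stable in input order
    order = sorted(range(len(pairs)), key=lambda i: -pairs[i][1])
    members = set(gene_set)
    n = len(genes)
    k = sum(1 for g in genes if g in members)
    assert 0 < k < n

    denom_in = 0.0
    for pos, idx in enumerate(order):
        if pairs[idx][0] in members:
            denom_in += float(n - pos) ** alpha

    score = 0.0
    cum_in = 0.0
    cum_out = 0
    for pos, idx in enumerate(order):
        if pairs[idx][0] in members:
            cum_in += float(n - pos) ** alpha
        else:
            cum_out += 1
        score += cum_in / denom_in - cum_out / (n - k)
    return score


def brute_hetero_joins(labels, edges):
    """Count edges whose endpoints are labeled 1 (A) and 2 (B)."""
    count = 0
    for i, j in edges:
        if {labels[i], labels[j]} == {1, 2}:
            count += 1
    return count


def enumerate_join_null(n_a, n_b, n_bg, edges):
    """Exact mean/sd of the A-B join count over all distinguishable labelings."""
    base = [1] * n_a + [2] * n_b + [0] * n_bg
    counts = []
    for labels in multiset_permutations(base):
        counts.append(brute_hetero_joins(labels, edges))
    counts = np.asarray(counts, dtype=float)
    return float(counts.mean()), float(counts.std(ddof=0)), len(counts)


def neighbor_covariance(values, coords):
    """Average product of centered values over rook-adjacent spot pairs."""
    values = np.asarray(values, dtype=float)
    centered = values - values.mean()
    index = {tuple(c): i for i, c in enumerate(map(tuple, coords))}
    total, n_pairs = 0.0, 0
    for (x, y), i in index.items():
        for dx, dy in ((1, 0), (0, 1)):
            j = index.get((x + dx, y + dy))
            if j is not None:
                total += centered[i] * centered[j]
                n_pairs += 1
    return total / n_pairs


def brute_otsu(channel, nbins=256):
    """Between-class-variance scan over all candidate histogram thresholds."""
    flat = np.asarray(channel, dtype=float).ravel()
    hist, bin_edges = np.histogram(flat, bins=nbins)
    centers = (bin_edges[:-1] + bin_edges[1:]) / 2.0
    best_t, best_var = None, -1.0
    total = hist.sum()
    for cut in range(1, nbins):
        w0 = hist[:cut].sum()
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:cut] * centers[:cut]).sum() / w0
        mu1 = (hist[cut:] * centers[cut:]).sum() / w1
        var = w0 * w1 * (mu0 - mu1) ** 2
        if var > best_var:
            best_var = var
            best_t = centers[cut - 1]
    return best_t
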