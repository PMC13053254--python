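"""Shared fixtures-by-function and independent oracles for the test suite.

The oracles here are deliberately written as plain nested loops / exhaustive
enumeration, independent of the package's vectorized implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import scipy.sparse as sp

from lrcomm.expression import NormalizedMatrix


def norm_from_values(values, cell_types, conditions=None, gene_ids=None,
                     sample_ids=None) -> NormalizedMatrix:
    """Build a NormalizedMatrix directly from a dense value array."""
    values = np.asarray(values, dtype=float)
    n, m = values.shape
    cell_ids = [f"c{i:04d}" for i in range(n)]
    genes = list(gene_ids) if gene_ids is not None else [f"g{j}" for j in range(m)]
    ann = pd.DataFrame(
        {
            "cell_type": list(cell_types),
            "condition": list(conditions) if conditions is not None else ["X"] * n,
            "sample_id": list(sample_ids) if sample_ids is not None else ["s1"] * n,
        },
        index=pd.Index(cell_ids, name="barcode"),
    )
    return NormalizedMatrix(
        values=sp.csr_matrix(values),
        cell_ids=pd.Index(cell_ids, name="barcode"),
        gene_ids=pd.Index(genes, name="gene"),
        annotations=ann,
    )


def brute_force_interactome(values, cell_types, pairs, senders, receivers,
                            tau=0.5, min_frac=0.2):
    """Triple-loop oracle: set of (sender, receiver, ligand, receptor).

    values: dense cells x genes array; cell_types: per-cell labels;
    pairs: list of (ligand_index, receptor_index).
    """
    values = np.asarray(values, dtype=float)
    cell_types = list(cell_types)

    def is_high(ct, j):
        rows = [i for i, t in enumerate(cell_types) if t == ct]
        n_above = 0
        for i in rows:
            if values[i, j] > tau:
                n_above += 1
        return n_above / len(rows) > min_frac

    out = set()
    for s in senders:
        for r in receivers:
            if s == r:
                continue
            for lj, rj in pairs:
                if is_high(s, lj) and is_high(r, rj):
                    out.add((s, r, lj, rj))
    return out


def exhaustive_perm_pvalue(lig, rec, n_s):
    """Exhaustive label-permutation p for the co-expression statistic.

    Enumerates every way of choosing which n_s pooled cells are 'sender';
    p = #{assignments with statistic >= observed} / #assignments
    (the identity assignment is included in the count).
    """
    lig = np.asarray(lig, dtype=float)
    rec = np.asarray(rec, dtype=float)
    pool = range(len(lig))
    obs = 0.5 * (lig[:n_s].mean() + rec[n_s:].mean())
    n_ge = 0
    total = 0
    for send in itertools.combinations(pool, n_s):
        recv = [i for i in pool if i not in send]
        stat = 0.5 * (lig[list(send)].mean() + rec[recv].mean())
        if stat >= obs - 1e-12:
            n_ge += 1
        total += 1
    return n_ge / total, total


def brute_force_rank_sum_pvalue(x, y):
    """Exhaustive two-sided rank-sum p with midranks, by direct enumeration."""
    pooled = list(x) + list(y)
    m, n = len(x), len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    i = 0
    while i < n:
        j = i
        while j + 1 < n and pooled[order[j + 1]] == pooled[order[i]]:
            j += 1
        midrank = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = midrank
        i = j + 1
    w_obs = sum(ranks[:m])
    mean = m * (n + 1) / 2
    n_extreme = 0
    total = 0
    for subset in itertools.combinations(range(n), m):
        w = sum(ranks[i] for i in subset)
        if abs(w - mean) >= abs(w_obs - mean) - 1e-9:
            n_extreme += 1
        total += 1
    return n_extreme / total


def kruskal_h_oracle(groups):
    """Direct rank-sum formula for the Kruskal-Wallis H (no tie correction)."""
    pooled = [v for g in groups for v in g]
    n = len(pooled)
    order = sorted(range(n), key=lambda i: pooled[i])
    ranks = [0.0] * n
    for pos, i in enumerate(order):
        ranks[i] = pos + 1
    h = 0.0
    start = 0
    for g in groups:
        r = sum(ranks[start : start + len(g)])
        h += r * r / len(g)
        start += len(g)
    return 12.0 / (n * (n + 1)) * h - 3 * (n + 1)
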