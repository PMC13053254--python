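"""Co-culture adhesion/phagocytosis ratios and nonparametric group tests.

The statistical unit is the microscope field of view: each field contributes
one ratio = (phagocytes with the scored event) / (total phagocytes in the
field). Group differences are tested with the Kruskal-Wallis test (tie
corrected, chi-square reference) followed by Dunn's (1964) post-hoc z tests
on pooled mean ranks over exactly the requested comparison family
(e.g. treated vs control), with Holm adjustment by default.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from ._stats import adjust_pvalues, significance_tier

__all__ = [
    "load_field_counts",
    "validate_field_counts",
    "compute_ratios",
    "kruskal_wallis",
    "dunn_posthoc",
    "groups_from_frame",
]

REQUIRED_COLUMNS = ("field_id", "group", "donor", "n_total", "n_event")


def load_field_counts(path: str | Path) -> pd.DataFrame:
    """Read a per-field event-count TSV and validate it."""
    df = pd.read_csv(path, sep="\t")
    return validate_field_counts(df)


def validate_field_counts(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"field-count table missing column(s): {missing}")
    df = df.copy()
    df["n_total"] = df["n_total"].astype(int)
    df["n_event"] = df["n_event"].astype(int)
    if (df["n_total"] < 1).any():
        raise ValueError("n_total must be >= 1 in every field")
    bad = df[(df["n_event"] < 0) | (df["n_event"] > df["n_total"])]
    if len(bad):
        raise ValueError(
            f"n_event outside [0, n_total] in field(s): {bad['field_id'].tolist()[:10]}"
        )
    return df


def compute_ratios(counts: pd.DataFrame) -> pd.DataFrame:
    """One ratio per field: n_event / n_total. No pooling across fields."""
    counts = validate_field_counts(counts)
    out = counts.copy()
    out["ratio"] = out["n_event"] / out["n_total"]
    return out


def groups_from_frame(
    ratios: pd.DataFrame, value_col: str = "ratio"
) -> dict[str, np.ndarray]:
    """Group label -> ratio vector, in first-appearance order."""
    return {
        g: sub[value_col].to_numpy()
        for g, sub in ratios.groupby("group", sort=False)
    }


def kruskal_wallis(groups: Sequence[np.ndarray] | Mapping[str, np.ndarray]):
    """Tie-corrected Kruskal-Wallis H and its chi-square p-value.

    Identical values across all groups give (H, p) = (0, 1) by convention
    (the test statistic degenerates when every observation ties).
    """
    if isinstance(groups, Mapping):
        groups = list(groups.values())
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for i, g in enumerate(groups):
        if g.size < 2:
            raise ValueError(f"group {i} has {g.size} observation(s), need >= 2")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    res = sps.kruskal(*groups)
    return float(res.statistic), float(res.pvalue)


def dunn_posthoc(
    groups: Mapping[str, np.ndarray],
    comparisons: Sequence[tuple[str, str]],
    adjust: str = "holm",
) -> pd.DataFrame:
    """Dunn's post-hoc z tests over the requested comparison family.

    z = (mean rank a - mean rank b) / sqrt(Var), with the pooled ranking's
    tie-corrected variance Var = [N(N+1)/12 - T/(12(N-1))] (1/n_a + 1/n_b),
    T = sum(t^3 - t) over tie groups. Adjustment (holm | bonferroni |
    fdr_bh) is applied over exactly the requested comparisons. The returned
    frame's attrs carry the global Kruskal-Wallis H/p and the tie factor.
    """
    groups = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    unknown = [g for pair in comparisons for g in pair if g not in groups]
    if unknown:
        raise ValueError(f"unknown group(s) in comparisons: {sorted(set(unknown))}")
    labels = list(groups)
    pooled = np.concatenate([groups[g] for g in labels])
    n = pooled.size
    ranks = sps.rankdata(pooled)
    mean_rank: dict[str, float] = {}
    sizes: dict[str, int] = {}
    start = 0
    for g in labels:
        k = groups[g].size
        mean_rank[g] = float(ranks[start : start + k].mean())
        sizes[g] = k
        start += k
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_sum = float(np.sum(tie_counts**3 - tie_counts))
    tie_factor = 1.0 - tie_sum / (n**3 - n) if n > 1 else 1.0
    base_var = n * (n + 1) / 12.0 - tie_sum / (12.0 * (n - 1))
    rows = []
    for a, b in comparisons:
        var = base_var * (1.0 / sizes[a] + 1.0 / sizes[b])
        if var <= 0:  # every observation identical
            z, p = 0.0, 1.0
        else:
            z = (mean_rank[a] - mean_rank[b]) / np.sqrt(var)
            p = float(2.0 * sps.norm.sf(abs(z)))
        rows.append({"group_a": a, "group_b": b, "z": float(z), "p": p})
    out = pd.DataFrame(rows)
    out["p_adj"] = adjust_pvalues(out["p"], method=adjust)
    out["significance"] = [significance_tier(p) for p in out["p_adj"]]
    h, p_global = kruskal_wallis(groups)
    out.attrs.update(
        {"kw_h": h, "kw_p": p_global, "tie_factor": tie_factor, "adjust": adjust}
    )
    return out
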