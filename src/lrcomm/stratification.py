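"""Quantile-based marker+/marker- stratification and differential enrichment.

Cells of one annotated type are split on a marker gene's normalized
expression: cells at or below the q_lo empirical quantile (default 0.25) form
the negative stratum, cells at or above the q_hi quantile (default 0.75) the
positive stratum; cells strictly between are excluded from the contrast.
Quantiles use linear interpolation on the sorted sample. Enrichment between
strata reuses the Wilcoxon + BH machinery; a gene is flagged significant at
p_adjusted < 0.05 and |log2FC| >= 0.5 by default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .differential import _de_between_groups
from .expression import NormalizedMatrix

__all__ = [
    "StratifiedCells",
    "DegenerateStratificationError",
    "stratify_by_quantile",
    "differential_enrichment",
    "gene_set_dot_table",
]


class DegenerateStratificationError(ValueError):
    """Quantile thresholds collapse (e.g. marker mostly zero)."""


@dataclass(frozen=True)
class StratifiedCells:
    marker: str
    cell_type: str
    q_lo: float
    q_hi: float
    threshold_lo: float
    threshold_hi: float
    negative_cells: pd.Index
    positive_cells: pd.Index


def stratify_by_quantile(
    norm: NormalizedMatrix,
    marker: str,
    cell_type: str,
    q_lo: float = 0.25,
    q_hi: float = 0.75,
    min_cells: int = 8,
) -> StratifiedCells:
    """Split one cell type into marker-negative / marker-positive tails."""
    if not 0 <= q_lo < q_hi <= 1:
        raise ValueError("require 0 <= q_lo < q_hi <= 1")
    rows = norm.cells_of(cell_type)
    if rows.size < min_cells:
        raise ValueError(
            f"cell type {cell_type!r} has {rows.size} cells, need >= {min_cells}"
        )
    values = norm.gene_column(marker)[rows]
    thr_lo = float(np.quantile(values, q_lo))  # linear interpolation
    thr_hi = float(np.quantile(values, q_hi))
    if thr_hi <= thr_lo:
        zero_frac = float(np.mean(values == 0))
        raise DegenerateStratificationError(
            f"marker {marker!r} in {cell_type!r}: quantile thresholds collapse "
            f"(lo={thr_lo:g}, hi={thr_hi:g}; {zero_frac:.0%} of cells at zero)"
        )
    cells = norm.cell_ids[rows]
    return StratifiedCells(
        marker=marker,
        cell_type=cell_type,
        q_lo=q_lo,
        q_hi=q_hi,
        threshold_lo=thr_lo,
        threshold_hi=thr_hi,
        negative_cells=cells[values <= thr_lo],
        positive_cells=cells[values >= thr_hi],
    )


def differential_enrichment(
    norm: NormalizedMatrix,
    strata: StratifiedCells,
    p_adj_cutoff: float = 0.05,
    lfc_cutoff: float = 0.5,
    min_pct: float = 0.0,
    exact_max: int = 25,
) -> pd.DataFrame:
    """Positive vs negative stratum Wilcoxon + BH table with significance flag."""
    idx = pd.Index(norm.cell_ids)
    rows_pos = idx.get_indexer(strata.positive_cells)
    rows_neg = idx.get_indexer(strata.negative_cells)
    out = _de_between_groups(
        norm, np.asarray(rows_pos), np.asarray(rows_neg), min_pct=min_pct,
        exact_max=exact_max,
    )
    out = out.rename(columns={"pct_a": "pct_pos", "pct_b": "pct_neg"})
    out["significant"] = (out["p_adj"] < p_adj_cutoff) & (
        out["log2FC"].abs() >= lfc_cutoff
    )
    out.attrs.update(
        {
            "marker": strata.marker,
            "cell_type": strata.cell_type,
            "p_adj_cutoff": p_adj_cutoff,
            "lfc_cutoff": lfc_cutoff,
        }
    )
    return out


def gene_set_dot_table(
    norm: NormalizedMatrix,
    strata_by_celltype: Mapping[str, StratifiedCells],
    enrichment_by_celltype: Mapping[str, pd.DataFrame],
    marker_list: Sequence[str],
    p_adj_cutoff: float = 0.05,
) -> pd.DataFrame:
    """Dot-plot table for a supplied gene set across strata and cell types.

    Rows are the union, over cell types, of gene-set members with
    p_adjusted < cutoff in that cell type's enrichment table; every selected
    gene is reported for all (cell_type, stratum) groups (union semantics).
    Mean expression is standardized per gene across the displayed groups
    (constant genes map to 0); the expressing fraction is unscaled.
    """
    if len(marker_list) == 0:
        raise ValueError("marker_list must be nonempty")
    marker_set = set(marker_list)
    selected: set[str] = set()
    for ct, table in enrichment_by_celltype.items():
        hits = table.loc[
            (table["p_adj"] < p_adj_cutoff) & table["gene"].isin(marker_set), "gene"
        ]
        selected.update(hits)
    genes = [g for g in marker_list if g in selected]
    if not genes:
        import warnings

        warnings.warn("no gene-set member significant in any cell type")
        return pd.DataFrame(
            columns=["gene", "cell_type", "stratum", "mean_scaled", "pct_expressing"]
        )
    idx = pd.Index(norm.cell_ids)
    cols = [norm.gene_index(g) for g in genes]
    records = []
    for ct, strata in strata_by_celltype.items():
        for stratum, cells in (
            ("negative", strata.negative_cells),
            ("positive", strata.positive_cells),
        ):
            rows = np.asarray(idx.get_indexer(cells))
            vals = norm.values[rows][:, cols].toarray()
            records.append(
                pd.DataFrame(
                    {
                        "gene": genes,
                        "cell_type": ct,
                        "stratum": stratum,
                        "mean_raw": vals.mean(axis=0),
                        "pct_expressing": (vals > 0).mean(axis=0),
                    }
                )
            )
    out = pd.concat(records, ignore_index=True)
    # per-gene standardization across the displayed groups; constant rows -> 0
    def _scale(g: pd.Series) -> pd.Series:
        sd = g.std(ddof=0)
        return (g - g.mean()) / sd if sd > 0 else g * 0.0

    out["mean_scaled"] = out.groupby("gene")["mean_raw"].transform(_scale)
    return out[["gene", "cell_type", "stratum", "mean_scaled", "pct_expressing"]]
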