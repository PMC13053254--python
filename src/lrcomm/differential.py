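"""Differential expression between conditions and the increased-interaction rule.

Per cell type, genes passing the min.pct gate (expressed, i.e. normalized
value > 0, in at least ``min_pct`` of cells of either group) are tested with
a two-sided Wilcoxon rank-sum test on normalized values and BH-adjusted.
The fold change is computed on linearized means with a pseudocount:

    log2FC = log2((mean(b^v - 1 in A) + 1) / (mean(b^v - 1 in B) + 1))

A gene is "up in A" when p_adjusted < alpha and log2FC > lfc_floor, "down in
A" when p_adjusted < alpha and log2FC < -lfc_floor, otherwise unchanged
(genes never tested are unchanged). An interaction is gained in a condition
when at least one of {ligand in sender, receptor in receiver} is up there
and neither is down.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._stats import adjust_pvalues, exact_rank_sum_pvalue, rank_sum_test_matrix
from .expression import NormalizedMatrix
from .interactome import Interaction

__all__ = [
    "DifferentialInteraction",
    "differential_expression",
    "classify_regulation",
    "increased_interactions",
    "UP", "DOWN", "UNCHANGED",
]

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"


@dataclass(frozen=True, order=True)
class DifferentialInteraction:
    sender: str
    receiver: str
    ligand: str
    receptor: str
    gained_in: str
    ligand_status: str
    receptor_status: str

    @property
    def key(self) -> tuple[str, str, str, str]:
        return (self.sender, self.receiver, self.ligand, self.receptor)


def _linearized_mean(values: np.ndarray, log_base: float) -> float:
    return float(np.mean(np.power(log_base, values) - 1.0))


def _de_between_groups(
    norm: NormalizedMatrix,
    rows_a: np.ndarray,
    rows_b: np.ndarray,
    min_pct: float = 0.2,
    exact_max: int = 25,
    use_continuity: bool = True,
) -> pd.DataFrame:
    """Shared DE machinery: Wilcoxon + BH on genes passing the min.pct gate."""
    if rows_a.size < 3 or rows_b.size < 3:
        raise ValueError(
            f"need >= 3 cells per group, got {rows_a.size} vs {rows_b.size}"
        )
    va = norm.values[rows_a].toarray()
    vb = norm.values[rows_b].toarray()
    pct_a = (va > 0).mean(axis=0)
    pct_b = (vb > 0).mean(axis=0)
    keep = np.flatnonzero(np.maximum(pct_a, pct_b) >= min_pct)
    if keep.size == 0:
        return pd.DataFrame(
            columns=["gene", "log2FC", "p", "p_adj", "pct_a", "pct_b"]
        )
    a, b = va[:, keep], vb[:, keep]
    base = norm.log_base
    mean_a = (np.power(base, a) - 1.0).mean(axis=0)
    mean_b = (np.power(base, b) - 1.0).mean(axis=0)
    lfc = np.log2((mean_a + 1.0) / (mean_b + 1.0))
    if max(rows_a.size, rows_b.size) <= exact_max:
        p = np.array([
            exact_rank_sum_pvalue(a[:, j], b[:, j]) for j in range(keep.size)
        ])
    else:
        p = rank_sum_test_matrix(a, b, use_continuity=use_continuity)
    return pd.DataFrame(
        {
            "gene": norm.gene_ids[keep],
            "log2FC": lfc,
            "p": p,
            "p_adj": adjust_pvalues(p, "fdr_bh"),
            "pct_a": pct_a[keep],
            "pct_b": pct_b[keep],
        }
    ).reset_index(drop=True)


def differential_expression(
    norm: NormalizedMatrix,
    cell_type: str,
    cond_a: str,
    cond_b: str,
    min_pct: float = 0.2,
    exact_max: int = 25,
    use_continuity: bool = True,
) -> pd.DataFrame:
    """DEG table for one cell type, contrast cond_a over cond_b."""
    rows_a = norm.cells_of(cell_type, cond_a)
    rows_b = norm.cells_of(cell_type, cond_b)
    out = _de_between_groups(norm, rows_a, rows_b, min_pct, exact_max, use_continuity)
    out.insert(1, "cell_type", cell_type)
    out.attrs.update({"cond_a": cond_a, "cond_b": cond_b, "min_pct": min_pct})
    return out


def classify_regulation(
    degs: pd.DataFrame,
    alpha: float = 0.05,
    lfc_floor: float = 0.0,
    genes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per (gene, cell_type) status: up / down / unchanged relative to cond_a.

    When ``genes`` is given, genes absent from the DEG table (e.g. failed the
    min.pct gate) are emitted as unchanged so downstream lookups are total.
    """
    sig = degs["p_adj"] < alpha
    status = np.where(
        sig & (degs["log2FC"] > lfc_floor), UP,
        np.where(sig & (degs["log2FC"] < -lfc_floor), DOWN, UNCHANGED),
    )
    out = pd.DataFrame(
        {"gene": degs["gene"], "cell_type": degs["cell_type"], "status": status}
    )
    if genes is not None:
        for ct in out["cell_type"].unique().tolist() or []:
            tested = set(out.loc[out["cell_type"] == ct, "gene"])
            extra = [g for g in genes if g not in tested]
            if extra:
                out = pd.concat(
                    [out, pd.DataFrame({"gene": extra, "cell_type": ct,
                                        "status": UNCHANGED})],
                    ignore_index=True,
                )
    return out


def increased_interactions(
    interactions: Iterable[Interaction],
    calls: pd.DataFrame,
    cond_a: str = "A",
    cond_b: str = "B",
) -> set[DifferentialInteraction]:
    """The increased-interaction rule over the union interactome.

    For each interaction 4-tuple, look up the ligand's regulation in the
    sender and the receptor's in the receiver. Gained in cond_a iff at least
    one member is up (in A) and neither is down; gained in cond_b under the
    mirrored rule. A missing (gene, cell_type) call is an error — build the
    call table with the full gene universe first.
    """
    lookup = {
        (ct, g): s
        for g, ct, s in zip(calls["gene"], calls["cell_type"], calls["status"])
    }
    out: set[DifferentialInteraction] = set()
    for key in {i.key for i in interactions}:
        s, r, lig, rec = key
        try:
            ls = lookup[(s, lig)]
            rs = lookup[(r, rec)]
        except KeyError as e:
            raise KeyError(
                f"no regulation call for (cell_type, gene) {e.args[0]}"
            ) from None
        statuses = (ls, rs)
        if UP in statuses and DOWN not in statuses:
            gained = cond_a
        elif DOWN in statuses and UP not in statuses:
            gained = cond_b
        else:
            continue
        out.add(
            DifferentialInteraction(
                sender=s, receiver=r, ligand=lig, receptor=rec,
                gained_in=gained, ligand_status=ls, receptor_status=rs,
            )
        )
    return out
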