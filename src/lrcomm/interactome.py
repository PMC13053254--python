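"""Directional ligand-receptor interactome inference and condition comparison.

A gene is "highly expressed" in a cell type when strictly more than
``min_frac`` (default 20%) of that type's cells have normalized expression
strictly above ``tau`` (default 0.5). A directed interaction sender ->
receiver exists for a database pair (L, R) when the sender highly expresses
L and the receiver highly expresses R. Interactions are identified by the
4-tuple (sender, receiver, ligand, receptor) within a condition; two
conditions are compared by set algebra on those 4-tuples.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .expression import NormalizedMatrix
from .lr_database import LRDatabase

__all__ = [
    "Interaction",
    "VennSummary",
    "call_highly_expressed",
    "infer_interactions",
    "count_interactions",
    "compare_conditions",
    "interactions_to_frame",
]


@dataclass(frozen=True, order=True)
class Interaction:
    """One directed sender -> receiver ligand-receptor edge."""

    sender: str
    receiver: str
    ligand: str
    receptor: str
    condition: str | None = None

    @property
    def key(self) -> tuple[str, str, str, str]:
        """Identity 4-tuple, condition-free."""
        return (self.sender, self.receiver, self.ligand, self.receptor)


@dataclass(frozen=True)
class VennSummary:
    """Shared / unique interaction partition of two conditions (by 4-tuple)."""

    shared: frozenset
    unique_a: frozenset
    unique_b: frozenset
    gained: pd.DataFrame  # senders x receivers counts of A-unique edges


def call_highly_expressed(
    norm: NormalizedMatrix,
    cell_types: Sequence[str] | None = None,
    condition: str | None = None,
    tau: float = 0.5,
    min_frac: float = 0.2,
) -> pd.DataFrame:
    """Per (cell_type, gene) expressing fraction above tau and the high call.

    Both comparisons are strict: fraction of cells with value > tau, and
    is_high iff that fraction > min_frac. When ``condition`` is given only
    that condition's cells enter the fractions.
    """
    if norm.annotations is None:
        raise ValueError("normalized matrix carries no annotations")
    ann = norm.annotations
    present = ann["cell_type"].unique().tolist()
    if cell_types is None:
        cell_types = sorted(present)
    unknown = [ct for ct in cell_types if ct not in present]
    if unknown:
        raise ValueError(f"unknown cell type(s): {unknown}")
    above = norm.values > tau  # sparse boolean
    frames = []
    for ct in cell_types:
        rows = norm.cells_of(ct, condition)
        if rows.size == 0:
            raise ValueError(
                f"cell type {ct!r} has no cells"
                + (f" in condition {condition!r}" if condition else "")
            )
        frac = np.asarray(above[rows].sum(axis=0)).ravel() / rows.size
        frames.append(
            pd.DataFrame(
                {
                    "cell_type": ct,
                    "gene": norm.gene_ids,
                    "expressing_fraction": frac,
                    "is_high": frac > min_frac,
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out.attrs.update({"tau": tau, "min_frac": min_frac, "condition": condition})
    return out


def infer_interactions(
    calls: pd.DataFrame,
    db: LRDatabase,
    senders: Sequence[str],
    receivers: Sequence[str],
    condition: str | None = None,
    include_autocrine: bool = False,
) -> set[Interaction]:
    """Emit Interaction(s, r, L, R) iff L is high in s and R is high in r.

    Autocrine edges (sender == receiver) are skipped unless requested; the
    default report is directional sender -> receiver only.
    """
    known = set(calls["cell_type"].unique())
    unknown = [ct for ct in list(senders) + list(receivers) if ct not in known]
    if unknown:
        raise ValueError(f"cell type(s) without high-expression calls: {unknown}")
    high = set(
        map(tuple, calls.loc[calls["is_high"], ["cell_type", "gene"]].to_numpy())
    )
    out: set[Interaction] = set()
    for s in senders:
        for r in receivers:
            if s == r and not include_autocrine:
                continue
            for pair in db:
                if (s, pair.ligand) in high and (r, pair.receptor) in high:
                    out.add(
                        Interaction(
                            sender=s,
                            receiver=r,
                            ligand=pair.ligand,
                            receptor=pair.receptor,
                            condition=condition,
                        )
                    )
    return out


def count_interactions(
    interactions: Iterable[Interaction],
    senders: Sequence[str] | None = None,
    receivers: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Senders x receivers matrix of distinct interaction counts.

    Missing (sender, receiver) combinations are reported as 0. All
    interactions must share one condition.
    """
    interactions = list(interactions)
    conditions = {i.condition for i in interactions}
    if len(conditions) > 1:
        raise ValueError(f"mixed conditions in interaction set: {sorted(map(str, conditions))}")
    if senders is None:
        senders = sorted({i.sender for i in interactions})
    if receivers is None:
        receivers = sorted({i.receiver for i in interactions})
    mat = pd.DataFrame(0, index=pd.Index(senders, name="sender"),
                       columns=pd.Index(receivers, name="receiver"), dtype=int)
    for i in interactions:
        mat.loc[i.sender, i.receiver] += 1
    mat.attrs["condition"] = next(iter(conditions)) if conditions else None
    return mat


def compare_conditions(
    set_a: Iterable[Interaction], set_b: Iterable[Interaction]
) -> VennSummary:
    """Venn partition of two interactomes and the gained-count matrix of A over B.

    Identity is the condition-free 4-tuple; gained[s, r] counts the (L, R)
    pairs interacting in A but not in B for that sender/receiver.
    """
    keys_a = {i.key for i in set_a}
    keys_b = {i.key for i in set_b}
    shared = keys_a & keys_b
    unique_a = keys_a - keys_b
    unique_b = keys_b - keys_a
    senders = sorted({k[0] for k in keys_a | keys_b})
    receivers = sorted({k[1] for k in keys_a | keys_b})
    gained = pd.DataFrame(0, index=pd.Index(senders, name="sender"),
                          columns=pd.Index(receivers, name="receiver"), dtype=int)
    for s, r, _, _ in unique_a:
        gained.loc[s, r] += 1
    return VennSummary(
        shared=frozenset(shared),
        unique_a=frozenset(unique_a),
        unique_b=frozenset(unique_b),
        gained=gained,
    )


def interactions_to_frame(interactions: Iterable[Interaction]) -> pd.DataFrame:
    """Long-format table: condition, sender, receiver, ligand, receptor."""
    rows = sorted(interactions)
    return pd.DataFrame(
        {
            "condition": [i.condition for i in rows],
            "sender": [i.sender for i in rows],
            "receiver": [i.receiver for i in rows],
            "ligand": [i.ligand for i in rows],
            "receptor": [i.receptor for i in rows],
        }
    )
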