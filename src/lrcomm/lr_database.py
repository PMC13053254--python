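"""Ligand-receptor pair resource: loading, validation, deduplication.

Pairs are directed (ligand -> receptor); the reverse pair is a distinct
record. Gene symbols are matched by exact, case-sensitive string equality —
alias resolution is an input-preparation concern, not handled here.
Heteromeric complexes are out of scope: every pair is single gene to single
gene.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

__all__ = [
    "LRPair",
    "LRDatabase",
    "LRFormatError",
    "EmptyDatabaseError",
    "load_lr_pairs",
    "validate_against_universe",
    "write_lr_pairs",
    "write_validation_report",
]


class LRFormatError(ValueError):
    """Raised when an L-R table is malformed (missing/invalid columns)."""


class EmptyDatabaseError(ValueError):
    """Raised when an L-R table contains no pairs."""


@dataclass(frozen=True)
class LRPair:
    """One directed ligand -> receptor gene pair."""

    ligand: str
    receptor: str
    source: str = ""

    def __post_init__(self):
        if not self.ligand or not self.receptor:
            raise ValueError("ligand and receptor symbols must be nonempty")

    @property
    def key(self) -> tuple[str, str]:
        return (self.ligand, self.receptor)


@dataclass(frozen=True)
class LRDatabase:
    """Ordered, duplicate-free collection of directed L-R pairs."""

    pairs: tuple[LRPair, ...]
    gene_universe_checked: bool = False
    _keys: frozenset = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        keys = [p.key for p in self.pairs]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (ligand, receptor) pairs in database")
        object.__setattr__(self, "_keys", frozenset(keys))

    def __len__(self) -> int:
        return len(self.pairs)

    def __iter__(self) -> Iterator[LRPair]:
        return iter(self.pairs)

    def __contains__(self, key) -> bool:
        if isinstance(key, LRPair):
            key = key.key
        return tuple(key) in self._keys

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for p in self.pairs:
            out.add(p.ligand)
            out.add(p.receptor)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "ligand": [p.ligand for p in self.pairs],
                "receptor": [p.receptor for p in self.pairs],
                "source": [p.source for p in self.pairs],
            }
        )


def _dedup(pairs: Iterable[LRPair]) -> tuple[LRPair, ...]:
    seen: set[tuple[str, str]] = set()
    out: list[LRPair] = []
    for p in pairs:
        if p.key not in seen:
            seen.add(p.key)
            out.append(p)
    return tuple(out)


def from_pairs(pairs: Iterable[LRPair | tuple]) -> LRDatabase:
    """Build a database from pairs/tuples, dropping exact duplicate keys."""
    norm = [p if isinstance(p, LRPair) else LRPair(*p) for p in pairs]
    return LRDatabase(pairs=_dedup(norm))


def load_lr_pairs(path: str | Path) -> LRDatabase:
    """Load a delimited L-R table with header columns ligand, receptor[, source].

    Exact duplicate (ligand, receptor) rows are dropped, keeping the first
    occurrence; input order is otherwise preserved.
    """
    import csv as _csv

    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    except pd.errors.EmptyDataError:
        raise EmptyDatabaseError(f"{path}: empty L-R table") from None
    except _csv.Error:
        # the dialect sniffer chokes on blank / single-token files
        if not path.read_text().strip():
            raise EmptyDatabaseError(f"{path}: empty L-R table") from None
        raise LRFormatError(
            f"{path}: could not parse as a delimited table with columns "
            "'ligand' and 'receptor'"
        ) from None
    missing = [c for c in ("ligand", "receptor") if c not in df.columns]
    if missing:
        raise LRFormatError(
            f"{path}: missing required column(s) {missing}; expected header "
            "with columns 'ligand' and 'receptor' (optional 'source')"
        )
    if len(df) == 0:
        raise EmptyDatabaseError(f"{path}: L-R table has a header but no pairs")
    if df["ligand"].isna().any() or df["receptor"].isna().any():
        raise LRFormatError(f"{path}: empty ligand/receptor symbols present")
    sources = df["source"].fillna("") if "source" in df.columns else [""] * len(df)
    pairs = [
        LRPair(ligand=l, receptor=r, source=s)
        for l, r, s in zip(df["ligand"], df["receptor"], sources)
    ]
    return LRDatabase(pairs=_dedup(pairs))


def validate_against_universe(
    db: LRDatabase, universe: set[str]
) -> tuple[LRDatabase, list[dict]]:
    """Drop pairs whose ligand or receptor is absent from the gene universe.

    Matching is exact and case-sensitive. Returns the filtered database
    (flagged as universe-checked) and a report listing each dropped pair
    with its missing member(s). An empty result is legal.
    """
    if not universe:
        raise ValueError("gene universe must be nonempty")
    universe = set(universe)
    kept: list[LRPair] = []
    report: list[dict] = []
    for p in db.pairs:
        missing = [g for g in (p.ligand, p.receptor) if g not in universe]
        if missing:
            report.append(
                {"ligand": p.ligand, "receptor": p.receptor, "missing": missing}
            )
        else:
            kept.append(p)
    return replace(db, pairs=tuple(kept), gene_universe_checked=True), report


def write_lr_pairs(db: LRDatabase, path: str | Path) -> None:
    db.to_frame().to_csv(path, sep="\t", index=False)


def write_validation_report(report: list[dict], path: str | Path) -> None:
    with open(path, "w") as fh:
        if not report:
            fh.write("all pairs present in gene universe\n")
            return
        for entry in report:
            fh.write(
                f"dropped ({entry['ligand']}, {entry['receptor']}): "
                f"missing {', '.join(entry['missing'])}\n"
            )
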