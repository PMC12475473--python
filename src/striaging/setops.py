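"""Venn region counts and UpSet-style exclusive intersections of gene lists.

Every element of the union is assigned to exactly one region — its exact
membership pattern across the input sets — so region counts partition the
union. Gene symbols are upper-cased by default so mouse and human lists
(Cd44 vs CD44) compare directly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("striaging")


@dataclass
class GeneListCollection:
    """Named gene sets with a case-normalization policy."""

    sets: dict[str, set[str]]
    normalize_case: bool = True

    @classmethod
    def from_lists(cls, named_lists: dict[str, list[str]],
                   normalize_case: bool = True) -> "GeneListCollection":
        sets = {}
        for name, genes in named_lists.items():
            norm = [g.upper() if normalize_case else g for g in genes]
            dupes = len(norm) - len(set(norm))
            if dupes:
                logger.warning("%d duplicate genes dropped from list %r", dupes, name)
            sets[name] = set(norm)
        return cls(sets=sets, normalize_case=normalize_case)

    @classmethod
    def from_long_csv(cls, path: str | Path, normalize_case: bool = True) -> "GeneListCollection":
        """Two-column (set, gene) long CSV."""
        df = pd.read_csv(path)
        if df.shape[1] < 2:
            raise ValueError(f"{path}: expected columns (set, gene)")
        set_col, gene_col = df.columns[:2]
        named = {str(name): grp[gene_col].astype(str).tolist()
                 for name, grp in df.groupby(set_col, sort=True)}
        return cls.from_lists(named, normalize_case=normalize_case)

    @property
    def names(self) -> list[str]:
        return list(self.sets)


def _check_k(collection: GeneListCollection) -> None:
    k = len(collection.sets)
    if not 2 <= k <= 6:
        raise ValueError(f"need between 2 and 6 sets, got {k}")


def membership_partition(collection: GeneListCollection) -> dict[tuple[bool, ...], set[str]]:
    """Partition the union by exact membership pattern (one pattern per element)."""
    _check_k(collection)
    names = collection.names
    out: dict[tuple[bool, ...], set[str]] = {}
    union = set().union(*collection.sets.values())
    for g in union:
        pattern = tuple(g in collection.sets[n] for n in names)
        out.setdefault(pattern, set()).add(g)
    return out


def venn_counts(collection: GeneListCollection) -> dict[tuple[bool, ...], int]:
    """Counts for every nonempty membership region (of the 2^k - 1 possible)."""
    return {pat: len(members) for pat, members in membership_partition(collection).items()}


def upset_exclusive(collection: GeneListCollection) -> pd.DataFrame:
    """Exclusive intersection count per membership pattern, descending.

    Returns a DataFrame with one row per nonempty pattern: boolean columns
    per set name, plus ``count`` and sorted ``members``.
    """
    part = membership_partition(collection)
    names = collection.names
    rows = []
    for pat, members in part.items():
        row = {name: flag for name, flag in zip(names, pat)}
        row["count"] = len(members)
        row["members"] = ",".join(sorted(members))
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values("count", ascending=False, ignore_index=True)


def exclusive_count(collection: GeneListCollection, *, pattern: tuple[bool, ...]) -> int:
    """Count of elements whose membership matches exactly this pattern."""
    return len(membership_partition(collection).get(pattern, set()))


def synthetic_cross_dataset_lists(seed: int = 20240) -> GeneListCollection:
    """SYNTHETIC stand-in for a four-way cross-condition DEG comparison.

    Builds four gene lists (murine aging, human aging, Huntington's,
    Parkinson's) from a synthetic symbol universe, constructed so that the
    only genes shared by all four are CD44 and EGFR and the pairwise and
    triple overlaps are modest and variable. These are not the real
    published lists — they exist to exercise the exclusive-intersection
    machinery at a realistic shape (a couple of hundred genes per list,
    sparse high-order overlap).
    """
    rng = np.random.default_rng(seed)
    universe = [f"SYN{i:04d}" for i in range(2000)]
    names = ["murine_aging", "human_aging", "human_hd", "human_pd"]
    lists: dict[str, list[str]] = {}
    for name in names:
        size = int(rng.integers(150, 300))
        lists[name] = list(rng.choice(universe, size=size, replace=False))
    # exactly two genes shared across all four conditions
    for g in ("CD44", "EGFR"):
        for name in names:
            lists[name].append(g)
    shared_all = set(lists[names[0]])
    for name in names[1:]:
        shared_all &= set(lists[name])
    for g in shared_all - {"CD44", "EGFR"}:
        lists[names[0]].remove(g)
    return GeneListCollection.from_lists(lists)
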