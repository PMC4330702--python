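"""k-of-n overlap analysis across named gene lists.

Independent transcriptomic analyses of the same treatment (different
platforms, different dataset selections) yield overlapping but distinct
regulated-gene lists. This module partitions their union into Venn regions,
extracts the "core set" of genes supported by at least (or exactly) k of the
n lists, and reports per-list unique fractions and cross-platform coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from ._ids import normalize_gene_id

__all__ = [
    "GeneListCollection",
    "OverlapPartition",
    "venn_partition",
    "core_set",
    "core_fraction",
    "unique_fraction",
    "platform_coverage",
]

MAX_LISTS = 8


def _normset(genes: Iterable[str]) -> frozenset[str]:
    return frozenset(normalize_gene_id(g) for g in genes)


@dataclass
class GeneListCollection:
    """Named gene sets from independent analyses, plus optional platform universes."""

    lists: dict[str, frozenset[str]]
    universes: dict[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.lists) > MAX_LISTS:
            raise ValueError(f"at most {MAX_LISTS} lists supported, got {len(self.lists)}")
        self.lists = {name: _normset(genes) for name, genes in self.lists.items()}
        self.universes = {name: _normset(g) for name, g in self.universes.items()}

    @property
    def names(self) -> list[str]:
        return list(self.lists)

    def union(self) -> frozenset[str]:
        return frozenset().union(*self.lists.values()) if self.lists else frozenset()

    def membership_counts(self) -> dict[str, int]:
        """Per gene, the number of lists containing it."""
        counts: dict[str, int] = {}
        for genes in self.lists.values():
            for g in genes:
                counts[g] = counts.get(g, 0) + 1
        return counts


@dataclass
class OverlapPartition:
    """Disjoint Venn regions: exact subset of list names → member set."""

    regions: dict[frozenset[str], frozenset[str]]

    @property
    def counts(self) -> dict[frozenset[str], int]:
        return {region: len(members) for region, members in self.regions.items()}

    def total(self) -> int:
        return sum(len(m) for m in self.regions.values())

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "region": "&".join(sorted(region)),
                "n_lists": len(region),
                "count": len(members),
                "members": ",".join(sorted(members)),
            }
            for region, members in sorted(
                self.regions.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["region", "n_lists", "count", "members"])


def venn_partition(coll: GeneListCollection) -> OverlapPartition:
    """Assign each union member to the region of exactly the lists containing it."""
    if len(coll.lists) < 2:
        raise ValueError("venn_partition needs at least 2 lists")
    regions: dict[frozenset[str], set[str]] = {}
    for gene in coll.union():
        key = frozenset(name for name, genes in coll.lists.items() if gene in genes)
        regions.setdefault(key, set()).add(gene)
    return OverlapPartition({k: frozenset(v) for k, v in regions.items()})


def core_set(coll: GeneListCollection, k: int, *, exact: bool = False) -> frozenset[str]:
    """Genes present in at least k lists (or exactly k with ``exact=True``).

    The at-least-k rule extracts the induced core set (e.g. k=3 of 4
    analyses); the exact-k mode implements the repressed rule of collecting
    genes found in exactly two independent analyses.
    """
    n = len(coll.lists)
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    counts = coll.membership_counts()
    if exact:
        return frozenset(g for g, c in counts.items() if c == k)
    return frozenset(g for g, c in counts.items() if c >= k)


def core_fraction(
    coll: GeneListCollection, k: int, *, exact: bool = False, denominator: str = "union"
) -> float:
    """Core-set size relative to all transcripts listed in the source datasets.

    ``denominator="union"`` divides by |union of all lists|;
    ``denominator="sum"`` divides by the summed list sizes (a transcript in
    several lists counted once per list). Both are reported because either
    reading of "all transcripts listed" is defensible.
    """
    core = core_set(coll, k, exact=exact)
    if denominator == "union":
        denom = len(coll.union())
    elif denominator == "sum":
        denom = sum(len(g) for g in coll.lists.values())
    else:
        raise ValueError("denominator must be 'union' or 'sum'")
    return len(core) / denom if denom else float("nan")


def unique_fraction(coll: GeneListCollection, name: str) -> float:
    """Fraction of a list's genes found in no other list; NaN for an empty list."""
    if name not in coll.lists:
        raise KeyError(name)
    target = coll.lists[name]
    if not target:
        return float("nan")
    others: set[str] = set()
    for other, genes in coll.lists.items():
        if other != name:
            others |= genes
    return len(target - others) / len(target)


def platform_coverage(genes: Iterable[str], universe: Iterable[str]) -> float:
    """Fraction of ``genes`` that are represented in a platform's universe."""
    gset = _normset(genes)
    uset = _normset(universe)
    if not uset:
        raise ValueError("universe must be non-empty")
    if not gset:
        return float("nan")
    return len(gset & uset) / len(gset)


def collection_from_mapping(mapping: Mapping[str, Iterable[str]]) -> GeneListCollection:
    return GeneListCollection({name: frozenset(genes) for name, genes in mapping.items()})
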