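"""Iterative reciprocal-top-hit orthology over precomputed similarity hits.

Cross-species comparison needs an Arabidopsis → rice ortholog map. Given a
forward hit table (rice database queried with Arabidopsis proteins) and a
reverse table (Arabidopsis database queried with rice proteins), the rule
walks the ranked forward hits of a gene and accepts each rice subject whose
own top reverse hit is the original gene, stopping at the first subject for
which it is not. A second ortholog source (a plain pair list) can be merged
in, with the overlap fraction between sources reported.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

from ._ids import normalize_gene_id

logger = logging.getLogger(__name__)

__all__ = [
    "Hit",
    "HitTable",
    "OrthologMap",
    "rank_hits",
    "reciprocal_orthologs",
    "build_ortholog_map",
    "merge_sources",
]


@dataclass(frozen=True)
class Hit:
    """One similarity hit: subject with bit score and E-value."""

    subject: str
    bitscore: float
    evalue: float


def rank_hits(hits: Iterable[Hit]) -> tuple[Hit, ...]:
    """Total order: descending bit score, then ascending E-value, then subject ID."""
    return tuple(
        sorted(hits, key=lambda h: (-h.bitscore, h.evalue, h.subject))
    )


@dataclass
class HitTable:
    """Ranked similarity hits per query."""

    hits: dict[str, tuple[Hit, ...]]

    def __post_init__(self) -> None:
        self.hits = {
            normalize_gene_id(q): rank_hits(
                Hit(normalize_gene_id(h.subject), float(h.bitscore), float(h.evalue))
                for h in hs
            )
            for q, hs in self.hits.items()
        }

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, str, float, float]]
    ) -> "HitTable":
        """Build from (query, subject, bitscore, evalue) tuples."""
        grouped: dict[str, list[Hit]] = {}
        for query, subject, bitscore, evalue in records:
            grouped.setdefault(query, []).append(Hit(subject, bitscore, evalue))
        return cls({q: tuple(hs) for q, hs in grouped.items()})

    def queries(self) -> list[str]:
        return list(self.hits)

    def __getitem__(self, query: str) -> tuple[Hit, ...]:
        return self.hits.get(normalize_gene_id(query), ())

    def top_hit(self, query: str) -> str | None:
        """Top-ranked subject of a query, with self-hits removed before ranking."""
        query = normalize_gene_id(query)
        for hit in self.hits.get(query, ()):
            if hit.subject != query:
                return hit.subject
        return None


def reciprocal_orthologs(
    forward: HitTable,
    reverse: HitTable,
    gene: str,
    *,
    mode: str = "stop",
) -> list[str]:
    """Iterative reciprocal-top-hit walk for one gene.

    Walk the ranked forward hits of ``gene`` in order; accept each subject
    whose top reverse hit is ``gene``; in the default ``mode="stop"`` the
    walk ends at the first subject failing the reciprocity check (a subject
    absent from the reverse table also fails it). ``mode="filter"`` instead
    keeps every reciprocal subject regardless of failures in between, for
    sensitivity analysis.

    Returns accepted rice subjects in forward-rank order (a prefix of the
    forward ranking in stop mode). A gene absent from the forward table
    yields an empty list.
    """
    if mode not in ("stop", "filter"):
        raise ValueError("mode must be 'stop' or 'filter'")
    gene = normalize_gene_id(gene)
    accepted: list[str] = []
    for hit in forward[gene]:
        if hit.subject == gene:
            continue
        top = reverse.top_hit(hit.subject)
        if top is None:
            logger.warning(
                "subject %s missing from reverse table; fails reciprocity for %s",
                hit.subject,
                gene,
            )
        if top == gene:
            if hit.subject not in accepted:
                accepted.append(hit.subject)
        elif mode == "stop":
            break
    return accepted


@dataclass
class OrthologMap:
    """Arabidopsis gene → rice orthologs, with a source tag per pair.

    Tags: ``"reciprocal"`` (from the reciprocal-top-hit walk),
    ``"external_list"`` (a provided pair list), ``"both"``.
    """

    pairs: dict[tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pairs = {
            (normalize_gene_id(a), normalize_gene_id(b)): tag
            for (a, b), tag in self.pairs.items()
        }

    @classmethod
    def from_mapping(
        cls, mapping: Mapping[str, Iterable[str]], *, source: str = "reciprocal"
    ) -> "OrthologMap":
        pairs = {
            (gene, rice): source
            for gene, rices in mapping.items()
            for rice in rices
        }
        return cls(pairs)

    def as_mapping(self) -> dict[str, frozenset[str]]:
        out: dict[str, set[str]] = {}
        for gene, rice in self.pairs:
            out.setdefault(gene, set()).add(rice)
        return {g: frozenset(r) for g, r in out.items()}

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: tuple[str, str]) -> bool:
        a, b = pair
        return (normalize_gene_id(a), normalize_gene_id(b)) in self.pairs


def build_ortholog_map(
    forward: HitTable,
    reverse: HitTable,
    genes: Iterable[str] | None = None,
    *,
    mode: str = "stop",
) -> OrthologMap:
    """Run the reciprocal walk for many genes; empty results are not stored."""
    if genes is None:
        genes = forward.queries()
    pairs: dict[tuple[str, str], str] = {}
    for gene in genes:
        gene = normalize_gene_id(gene)
        for rice in reciprocal_orthologs(forward, reverse, gene, mode=mode):
            pairs[(gene, rice)] = "reciprocal"
    return OrthologMap(pairs)


def merge_sources(a: OrthologMap, b: OrthologMap) -> tuple[OrthologMap, float]:
    """Union of two ortholog sources with per-pair provenance tags.

    The overlap fraction is |pairs present in both| / |pairs in the union|
    (NaN when both maps are empty).
    """
    union = set(a.pairs) | set(b.pairs)
    both = set(a.pairs) & set(b.pairs)
    merged = {
        pair: "both" if pair in both else (a.pairs.get(pair) or b.pairs[pair])
        for pair in union
    }
    overlap = len(both) / len(union) if union else float("nan")
    return OrthologMap(merged), overlap
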