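"""Readers and writers for every external format the pipeline touches.

Formats: ratio tables and gene lists as TSV/CSV (decimal commas accepted on
input, since printed expression tables in the plant literature often use
them; all output uses dot decimals), promoters as FASTA, similarity hits in
the standard 12-column tabular format (query, subject, %identity, length,
mismatches, gapopen, qstart, qend, sstart, send, evalue, bitscore),
expression matrices as genes × samples TSV plus a two-column sample sheet,
and ortholog pair lists as two-column TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._ids import normalize_gene_id
from .de import ExpressionMatrix
from .meta import RatioTable
from .motifs import PromoterSet
from .orthology import HitTable, OrthologMap
from .overlap import GeneListCollection

logger = logging.getLogger(__name__)

__all__ = [
    "read_ratio_table",
    "write_ratio_table",
    "read_fasta_promoters",
    "write_fasta_promoters",
    "read_hit_table",
    "write_hit_table",
    "read_gene_list",
    "write_gene_list",
    "read_gene_lists",
    "read_expression_matrix",
    "read_ortholog_pairs",
]

_SEPS = {"tsv": "\t", "csv": ","}

HIT_COLUMNS = [
    "query", "subject", "pident", "length", "mismatches", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def _parse_ratio(cell: str, row: int, column: str):
    """Parse one ratio cell; decimal separator may be '.' or ','."""
    text = str(cell).strip()
    if text in ("", "NA", "NAN", "nan", "NaN", "None"):
        return float("nan")
    try:
        return float(text.replace(",", "."))
    except ValueError:
        raise ValueError(
            f"non-numeric ratio {cell!r} at data row {row}, column {column!r}"
        ) from None


def read_ratio_table(
    path: str | Path,
    dialect: str = "tsv",
    *,
    experiment: str | None = None,
) -> RatioTable:
    """Read a per-experiment ratio table (gene ID column + ratio columns).

    The first column carries gene IDs; every other column is one time
    point's treated/control ratio. One file is one experiment; its name
    defaults to the file stem. Decimal commas are parsed ("11,72" → 11.72);
    empty cells stay missing. Duplicate gene IDs and non-numeric cells are
    errors naming the offender.
    """
    if dialect not in _SEPS:
        raise ValueError(f"dialect must be one of {sorted(_SEPS)}")
    path = Path(path)
    raw = pd.read_csv(path, sep=_SEPS[dialect], dtype=str)
    if raw.shape[1] < 2:
        raise ValueError(f"{path}: need a gene-ID column plus >=1 ratio column")
    gene_col = raw.columns[0]
    genes = [normalize_gene_id(g) for g in raw[gene_col]]
    seen: set[str] = set()
    for g in genes:
        if g in seen:
            raise ValueError(f"{path}: duplicate gene ID: {g}")
        seen.add(g)
    experiment = experiment or path.stem
    columns = {}
    for col in raw.columns[1:]:
        columns[(experiment, col)] = [
            _parse_ratio(cell, row + 1, col) for row, cell in enumerate(raw[col])
        ]
    if not genes:
        empty = pd.DataFrame(
            columns=pd.MultiIndex.from_tuples(columns.keys()), dtype=float
        )
        return RatioTable(empty)
    return RatioTable.from_columns(genes, columns)


def write_ratio_table(table: RatioTable, path: str | Path, dialect: str = "tsv") -> None:
    """Write a ratio table with dot decimals; one column per time point."""
    flat = table.data.copy()
    flat.columns = [
        tp if len(table.experiments) == 1 else f"{exp}:{tp}"
        for exp, tp in flat.columns
    ]
    flat.to_csv(Path(path), sep=_SEPS[dialect], index_label="gene")


def read_fasta_promoters(path: str | Path) -> PromoterSet:
    """Read promoter sequences from FASTA.

    The record ID (first whitespace-separated token) is the gene identifier;
    sequences are upper-cased and validated against {A,C,G,T,N}. Duplicate
    IDs and non-DNA characters are errors naming the record.
    """
    sequences: dict[str, str] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        gid = normalize_gene_id(record.id)
        if gid in sequences:
            raise ValueError(f"{path}: duplicate promoter ID: {gid}")
        sequences[gid] = str(record.seq)
    return PromoterSet(sequences)


def write_fasta_promoters(promoters: PromoterSet, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=gene, description="") for gene, seq in promoters.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_hit_table(path: str | Path) -> HitTable:
    """Read similarity hits in the 12-column tabular format.

    Hits are grouped per query and ranked by descending bit score, ties
    broken by ascending E-value then lexicographic subject ID. Lines with
    fewer than 12 columns are errors with the line number.
    """
    records = []
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected 12 columns, got {len(parts)}"
                )
            records.append(
                (parts[0], parts[1], float(parts[11]), float(parts[10]))
            )
    return HitTable.from_records(records)


def write_hit_table(table: HitTable, path: str | Path) -> None:
    """Write hits back out in the 12-column format (alignment fields zeroed)."""
    with open(path, "w") as handle:
        for query in table.queries():
            for hit in table[query]:
                fields = [query, hit.subject, "0", "0", "0", "0", "0", "0", "0", "0",
                          f"{hit.evalue:g}", f"{hit.bitscore:g}"]
                handle.write("\t".join(fields) + "\n")


def read_gene_list(path: str | Path) -> frozenset[str]:
    """Read a one-column gene list (optional header line 'gene')."""
    genes = []
    with open(path) as handle:
        for line in handle:
            token = line.strip()
            if not token or token.startswith("#"):
                continue
            if token.lower() in ("gene", "gene_id", "geneid", "agi"):
                continue
            genes.append(normalize_gene_id(token))
    return frozenset(genes)


def write_gene_list(genes: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("gene\n")
        for gene in sorted({normalize_gene_id(g) for g in genes}):
            handle.write(gene + "\n")


def read_gene_lists(
    paths: Mapping[str, str | Path] | Iterable[str | Path],
) -> GeneListCollection:
    """Build a collection from several one-column lists (name → path or paths)."""
    if not isinstance(paths, Mapping):
        paths = {Path(p).stem: p for p in paths}
    return GeneListCollection({name: read_gene_list(p) for name, p in paths.items()})


def read_expression_matrix(
    matrix_path: str | Path, groups_path: str | Path
) -> ExpressionMatrix:
    """Read a genes × samples log2 matrix and its sample sheet (sample, group)."""
    values = pd.read_csv(matrix_path, sep="\t", index_col=0)
    sheet = pd.read_csv(groups_path, sep="\t")
    if sheet.shape[1] < 2:
        raise ValueError(f"{groups_path}: need columns (sample, group)")
    groups = dict(zip(sheet.iloc[:, 0].astype(str), sheet.iloc[:, 1].astype(str)))
    return ExpressionMatrix(values, groups)


def read_ortholog_pairs(path: str | Path, *, source: str = "external_list") -> OrthologMap:
    """Read an ortholog pair list TSV (arabidopsis_id, rice_id; optional header)."""
    pairs: dict[tuple[str, str], str] = {}
    with open(path) as handle:
        for lineno, line in enumerate(handle, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"{path}: line {lineno}: expected 2 columns")
            if lineno == 1 and parts[0].lower() in ("arabidopsis_id", "gene", "query"):
                continue
            pairs[(normalize_gene_id(parts[0]), normalize_gene_id(parts[1]))] = source
    return OrthologMap(pairs)
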