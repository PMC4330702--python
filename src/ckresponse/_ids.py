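"""Gene identifier normalization shared by every pipeline stage."""

from __future__ import annotations


def normalize_gene_id(gene_id: str) -> str:
    """Normalize a gene identifier for case-insensitive comparison.

    Locus codes such as AGI codes (``At5g62920``) or rice locus codes are
    compared case-insensitively throughout the pipeline; the canonical form
    is upper case with surrounding whitespace removed.

    Raises
    ------
    ValueError
        If the identifier is empty after stripping.
    """
    gid = str(gene_id).strip().upper()
    if not gid:
        raise ValueError("gene identifier must be non-empty")
    return gid
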