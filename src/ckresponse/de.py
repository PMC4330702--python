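"""Differential-expression calling on normalized expression matrices.

The cross-species stage of the pipeline: treated-vs-control calling on
already-normalized log2 expression matrices (e.g. RMA output from rice
cytokinin-treatment experiments), with Benjamini–Hochberg FDR control, a
quality gate for unusable datasets, and the conserved-regulation join that
asks which induced core-set genes have an ortholog that is also induced.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._ids import normalize_gene_id
from .config import PipelineConfig
from .orthology import OrthologMap

logger = logging.getLogger(__name__)

__all__ = [
    "ExpressionMatrix",
    "differential_expression",
    "bh_qvalues",
    "qc_expression_matrix",
    "conserved_regulation",
]

GROUPS = ("control", "treated")


@dataclass
class ExpressionMatrix:
    """Normalized log2 intensities, genes × samples, with a two-group design.

    ``values``: DataFrame indexed by gene, one column per sample.
    ``groups``: sample → "control" | "treated".
    """

    values: pd.DataFrame
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.values = self.values.copy()
        self.values.index = pd.Index(
            [normalize_gene_id(g) for g in self.values.index], name="gene"
        )
        if self.values.index.duplicated().any():
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene ID: {dup}")
        missing = set(self.values.columns) - set(self.groups)
        if missing:
            raise ValueError(f"samples without group label: {sorted(missing)}")
        bad = set(self.groups.values()) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group labels: {sorted(bad)}; expected {GROUPS}")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValueError("expression values must be finite")

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.values.columns if self.groups[s] == group]


def bh_qvalues(p: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (q-values).

    Sort p ascending; q at rank i (1-based) is ``min_{j>=i} p_(j) * m / j``,
    clipped to 1, then mapped back to the input order.
    """
    pvals = np.asarray(p, dtype=float)
    if pvals.ndim != 1:
        raise ValueError("p must be one-dimensional")
    if pvals.size == 0:
        return pvals.copy()
    if np.any((pvals < 0) | (pvals > 1) | ~np.isfinite(pvals)):
        raise ValueError("p-values must lie in [0, 1]")
    m = pvals.size
    order = np.argsort(pvals, kind="stable")
    ranked = pvals[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty(m, dtype=float)
    q[order] = q_sorted
    return q


def differential_expression(
    mat: ExpressionMatrix,
    cfg: PipelineConfig | None = None,
    *,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Two-group t-test differential expression with BH q-values.

    Per gene: ``log2fc`` is the mean treated log2 value minus the mean
    control log2 value, ``fold_change = 2**log2fc``, ``p`` from a two-sided
    two-sample t-test (equal-variance Student by default; ``equal_var=False``
    for Welch), ``q`` by Benjamini–Hochberg over all tested genes.
    A gene is ``significant`` when its fold change is >= the induced cutoff
    or <= the repressed cutoff AND q <= the q cutoff.

    Genes with zero variance in both groups and equal means get p = 1 by
    convention (no evidence either way from constant data).
    """
    cfg = cfg or PipelineConfig()
    control = mat.samples_in("control")
    treated = mat.samples_in("treated")
    if len(control) < 2 or len(treated) < 2:
        raise ValueError(
            f"need >=2 replicates per group, got {len(control)} control / {len(treated)} treated"
        )
    ctl = mat.values[control].to_numpy()
    trt = mat.values[treated].to_numpy()
    log2fc = trt.mean(axis=1) - ctl.mean(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(trt, ctl, axis=1, equal_var=equal_var)
        p = np.asarray(res.pvalue, dtype=float)
    degenerate = ~np.isfinite(p)
    if degenerate.any():
        # zero within-group variance in both groups: p=1 if means equal, else
        # the difference is exact relative to zero noise
        p[degenerate] = np.where(np.isclose(log2fc[degenerate], 0.0), 1.0, 0.0)
    q = bh_qvalues(p)
    fold = np.exp2(log2fc)
    significant = (
        (fold >= cfg.induced_fold_cutoff) | (fold <= cfg.repressed_fold_cutoff)
    ) & (q <= cfg.q_cutoff)
    return pd.DataFrame(
        {
            "log2fc": log2fc,
            "fold_change": fold,
            "p": p,
            "q": q,
            "significant": significant,
        },
        index=mat.values.index,
    )


def qc_expression_matrix(
    mat: ExpressionMatrix, *, min_within_group_correlation: float = 0.5
) -> tuple[bool, str]:
    """Sanity gate for unusable datasets.

    A dataset whose replicates do not agree carries no usable signal (as in
    a treatment series whose cytokinin arm yields no meaningful data). The
    gate computes the mean pairwise Pearson correlation of log2 profiles
    within each group and fails the dataset when either group falls below
    the threshold. Returns (passed, reason).
    """
    for group in GROUPS:
        samples = mat.samples_in(group)
        if len(samples) < 2:
            return False, f"group {group!r} has fewer than 2 replicates"
        corrs = [
            float(np.corrcoef(mat.values[a], mat.values[b])[0, 1])
            for a, b in combinations(samples, 2)
        ]
        mean_corr = float(np.mean(corrs))
        if not np.isfinite(mean_corr) or mean_corr < min_within_group_correlation:
            return False, (
                f"mean within-group correlation {mean_corr:.3f} in group {group!r} "
                f"below threshold {min_within_group_correlation}"
            )
    return True, "ok"


@dataclass
class ConservedRegulationReport:
    """Join of an induced core set with rice differential-expression calls."""

    per_gene: pd.DataFrame
    n_core: int
    n_with_ortholog: int
    n_conserved: int
    fraction_with_ortholog: float = field(init=False)
    fraction_conserved: float = field(init=False)

    def __post_init__(self) -> None:
        self.fraction_with_ortholog = (
            self.n_with_ortholog / self.n_core if self.n_core else float("nan")
        )
        self.fraction_conserved = (
            self.n_conserved / self.n_with_ortholog if self.n_with_ortholog else float("nan")
        )


def conserved_regulation(
    core: Sequence[str],
    orthomap: OrthologMap,
    de_results: Mapping[str, pd.DataFrame],
    cfg: PipelineConfig | None = None,
) -> ConservedRegulationReport:
    """Which core-set genes have an ortholog that is also cytokinin-induced?

    For each core gene: ``has_ortholog`` if the ortholog map lists at least
    one rice gene for it; ``conserved`` if any of those orthologs is called
    significant AND induced (fold change >= induced cutoff) in at least one
    of the rice DE result tables. Summary fractions are |with ortholog| /
    |core| and |conserved| / |with ortholog|.
    """
    cfg = cfg or PipelineConfig()
    core_ids = sorted({normalize_gene_id(g) for g in core})
    induced_by_dataset: dict[str, set[str]] = {}
    for name, de in de_results.items():
        mask = de["significant"] & (de["fold_change"] >= cfg.induced_fold_cutoff)
        induced_by_dataset[name] = set(de.index[mask])
    rows = []
    mapping = orthomap.as_mapping()
    for gene in core_ids:
        orthologs = mapping.get(gene, frozenset())
        conserved_in = sorted(
            name
            for name, induced in induced_by_dataset.items()
            if orthologs & induced
        )
        rows.append(
            {
                "gene": gene,
                "n_orthologs": len(orthologs),
                "has_ortholog": bool(orthologs),
                "conserved": bool(conserved_in),
                "conserved_in": ",".join(conserved_in),
            }
        )
    per_gene = pd.DataFrame(rows).set_index("gene") if rows else pd.DataFrame(
        columns=["n_orthologs", "has_ortholog", "conserved", "conserved_in"]
    )
    n_with = int(per_gene["has_ortholog"].sum()) if len(per_gene) else 0
    n_cons = int(per_gene["conserved"].sum()) if len(per_gene) else 0
    return ConservedRegulationReport(
        per_gene=per_gene,
        n_core=len(core_ids),
        n_with_ortholog=n_with,
        n_conserved=n_cons,
    )
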