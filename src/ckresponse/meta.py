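"""Multi-experiment ratio averaging and induced/repressed calling.

The meta-analysis stage consumes per-experiment tables of treated-vs-control
expression ratios (linear scale, one column per experiment × time point),
averages them per time point across experiments and then across time points,
and calls genes induced or repressed by inclusive fold-change cutoffs.

Averaging is done on the linear ratio scale: for a two-time-point cytokinin
induction course this reproduces the derived average-ratio column of the
published top-induced-gene tables exactly (e.g. ratios 11.72 and 8.94 at 15
and 120 min average to 10.33).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from ._ids import normalize_gene_id
from .config import PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "RatioTable",
    "RegulationCall",
    "average_ratios",
    "call_regulation",
    "meta_score",
    "round_half_away",
]


class RatioTable:
    """Per-gene treated/control expression ratios.

    Wraps a genes × columns DataFrame whose columns are a two-level
    MultiIndex ``(experiment, timepoint)``. Ratios are linear-scale and
    strictly positive; missing values are NaN.
    """

    def __init__(self, data: pd.DataFrame):
        if not isinstance(data.columns, pd.MultiIndex) or data.columns.nlevels != 2:
            raise ValueError("RatioTable columns must be (experiment, timepoint) pairs")
        index = pd.Index([normalize_gene_id(g) for g in data.index], name="gene")
        dup = index[index.duplicated()]
        if len(dup):
            raise ValueError(f"duplicate gene ID: {dup[0]}")
        values = data.astype(float)
        values.index = index
        present = values.to_numpy()
        if np.any(present[np.isfinite(present)] <= 0):
            bad = values.index[(values <= 0).any(axis=1)][0]
        else:
            bad = None
        if bad is not None:
            raise ValueError(f"non-positive ratio for gene {bad}; ratios must be > 0")
        self.data = values
        self.data.columns = self.data.columns.set_names(["experiment", "timepoint"])

    @classmethod
    def from_columns(
        cls,
        genes: Sequence[str],
        columns: Mapping[tuple[str, str], Sequence[float]],
    ) -> "RatioTable":
        frame = pd.DataFrame(dict(columns), index=list(genes))
        frame.columns = pd.MultiIndex.from_tuples(frame.columns)
        return cls(frame)

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def experiments(self) -> list[str]:
        return list(self.data.columns.get_level_values("experiment").unique())

    @property
    def timepoints(self) -> list[str]:
        return list(self.data.columns.get_level_values("timepoint").unique())

    def __len__(self) -> int:
        return len(self.data)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RatioTable):
            return NotImplemented
        try:
            pd.testing.assert_frame_equal(self.data, other.data, check_like=True)
        except AssertionError:
            return False
        return True

    @staticmethod
    def concat(tables: Iterable["RatioTable"]) -> "RatioTable":
        """Join several single-experiment tables on the gene index (outer join)."""
        frames = [t.data for t in tables]
        joined = pd.concat(frames, axis=1, join="outer")
        if joined.columns.duplicated().any():
            dup = joined.columns[joined.columns.duplicated()][0]
            raise ValueError(f"duplicate (experiment, timepoint) column: {dup}")
        out = RatioTable.__new__(RatioTable)
        out.data = joined
        return out


@dataclass
class RegulationCall:
    """Regulation call for one gene from its averaged ratio."""

    gene: str
    mean_ratio: float
    direction: str  # "induced" | "repressed" | "none"
    meta_score: float = float("nan")


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (6.945 → 6.95, −6.945 → −6.95).

    Display-rounding convention for reported average ratios; Python's
    built-in ``round`` is banker's rounding and differs on half-digits.
    """
    x = float(x)
    if not math.isfinite(x):
        return x
    quantum = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(quantum, rounding=ROUND_HALF_UP))


def average_ratios(table: RatioTable) -> pd.DataFrame:
    """Average ratios per time point across experiments, then overall.

    For each gene the per-timepoint mean is the arithmetic mean, over
    experiments, of that time point's ratios (missing values excluded); the
    overall mean is the arithmetic mean of the per-timepoint means. Genes
    with no non-missing ratio at all are excluded and logged.

    Returns
    -------
    DataFrame indexed by gene with one column per time point plus a
    ``"mean"`` column holding the overall mean.
    """
    data = table.data
    all_missing = data.isna().all(axis=1)
    if all_missing.any():
        for gene in data.index[all_missing]:
            logger.warning("gene %s has no ratio values; excluded from averaging", gene)
        data = data.loc[~all_missing]
    per_tp = data.T.groupby(level="timepoint", sort=False).mean().T
    out = per_tp.copy()
    out["mean"] = per_tp.mean(axis=1)
    return out


def meta_score(
    ratios: Sequence[float], *, log2_threshold: float = 1.0
) -> float:
    """Default pluggable meta statistic over per-experiment ratios.

    Stand-in score: the sum over experiments of |log2 ratio|, multiplied by
    the number of experiments in which |log2 ratio| >= ``log2_threshold``.
    It rewards both strong and consistent regulation. This default does NOT
    reproduce the meta-statistic column of the published tables, whose
    formula is defined elsewhere; pass any alternative scorer to
    :func:`call_regulation` via ``scorer``.

    Returns NaN when fewer than two experiments have a value.
    """
    vals = np.asarray([r for r in ratios if r is not None and np.isfinite(r)], dtype=float)
    if vals.size < 2:
        return float("nan")
    logs = np.abs(np.log2(vals))
    return float(logs.sum() * int((logs >= log2_threshold).sum()))


def _per_experiment_ratios(table: RatioTable) -> pd.DataFrame:
    """Per-gene mean ratio within each experiment (over its time points)."""
    return table.data.T.groupby(level="experiment", sort=False).mean().T


def call_regulation(
    means: pd.Series | pd.DataFrame,
    cfg: PipelineConfig | None = None,
    *,
    table: RatioTable | None = None,
    scorer: Callable[[Sequence[float]], float] = meta_score,
) -> pd.DataFrame:
    """Call induced/repressed genes from overall mean ratios.

    Thresholds are applied inclusively: mean >= ``induced_fold_cutoff``
    (default 2.0) → induced; mean <= ``repressed_fold_cutoff`` (default 0.5)
    → repressed; otherwise none. When the originating :class:`RatioTable`
    is supplied, a pluggable meta score is computed per gene from its
    per-experiment mean ratios.

    Returns a DataFrame with columns ``mean_ratio``, ``direction`` and
    ``meta_score``, sorted by descending mean ratio.
    """
    cfg = cfg or PipelineConfig()
    if isinstance(means, pd.DataFrame):
        means = means["mean"]
    direction = pd.Series("none", index=means.index, dtype=object)
    direction[means >= cfg.induced_fold_cutoff] = "induced"
    direction[means <= cfg.repressed_fold_cutoff] = "repressed"
    scores = pd.Series(float("nan"), index=means.index)
    if table is not None:
        per_exp = _per_experiment_ratios(table)
        for gene in means.index:
            if gene in per_exp.index:
                scores[gene] = scorer(per_exp.loc[gene].dropna().to_list())
    result = pd.DataFrame(
        {"mean_ratio": means, "direction": direction, "meta_score": scores}
    )
    return result.sort_values("mean_ratio", ascending=False)
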