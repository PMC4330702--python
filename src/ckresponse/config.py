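"""Pipeline-wide configuration.

One :class:`PipelineConfig` object carries every threshold used across the
stages: fold-change cutoffs for calling induction/repression, the FDR cutoff
for differential expression, the k-of-n rules for core-set extraction, the
promoter window length and the selection rule of the enrichment screens.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path
from typing import Any, Mapping

import yaml

_STRAND_MODES = ("forward", "both")


@dataclass
class PipelineConfig:
    """Thresholds and conventions shared by all pipeline stages.

    Parameters
    ----------
    induced_fold_cutoff : float
        Minimum average treated/control ratio (linear scale) for a gene to
        be called induced. Applied inclusively (``>=``).
    repressed_fold_cutoff : float
        Maximum average ratio for a gene to be called repressed
        (inclusive ``<=``).
    q_cutoff : float
        Benjamini–Hochberg q-value cutoff for differential expression.
    core_k_induced : int
        A gene belongs to the induced core set when it appears in at least
        this many of the input gene lists.
    core_k_repressed : int
        The repressed core rule is exact-k with this k (genes found in
        exactly this many lists).
    promoter_window : int
        Nominal upstream window length in bp (−window..−1 relative to the
        transcription start, strand-oriented 5'→3' toward the gene).
    enrichment_alpha : float
        Raw p-value cutoff of the motif-screen selection rule.
    enrichment_fold_min : float
        Minimum occurrence-rate fold enrichment of the selection rule.
    strand_mode : str
        ``"forward"`` scans promoters as written; ``"both"`` additionally
        scans the reverse complement and merges counts.
    rng_seed : int
        Single seed from which all randomness in the pipeline flows.
    """

    induced_fold_cutoff: float = 2.0
    repressed_fold_cutoff: float = 0.5
    q_cutoff: float = 0.05
    core_k_induced: int = 3
    core_k_repressed: int = 2
    promoter_window: int = 1000
    enrichment_alpha: float = 0.05
    enrichment_fold_min: float = 2.0
    strand_mode: str = "forward"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.repressed_fold_cutoff < 1 < self.induced_fold_cutoff):
            raise ValueError(
                "need 0 < repressed_fold_cutoff < 1 < induced_fold_cutoff, got "
                f"{self.repressed_fold_cutoff} / {self.induced_fold_cutoff}"
            )
        if not 0 < self.q_cutoff < 1:
            raise ValueError(f"q_cutoff must be in (0, 1), got {self.q_cutoff}")
        for name in ("core_k_induced", "core_k_repressed"):
            k = getattr(self, name)
            if k < 1:
                raise ValueError(f"{name} must be >= 1, got {k}")
        if self.promoter_window < 1:
            raise ValueError("promoter_window must be positive")
        if not 0 < self.enrichment_alpha <= 1:
            raise ValueError("enrichment_alpha must be in (0, 1]")
        if self.enrichment_fold_min < 0:
            raise ValueError("enrichment_fold_min must be >= 0")
        if self.strand_mode not in _STRAND_MODES:
            raise ValueError(f"strand_mode must be one of {_STRAND_MODES}")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, Any]) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(mapping))

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load from a YAML file or a flat ``key=value`` per-line file."""
        text = Path(path).read_text()
        if "=" in text.splitlines()[0] if text.strip() else False:
            mapping: dict[str, Any] = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, value = line.partition("=")
                mapping[key.strip()] = yaml.safe_load(value.strip())
            return cls.from_mapping(mapping)
        data = yaml.safe_load(text) or {}
        if not isinstance(data, Mapping):
            raise ValueError(f"config file {path} does not contain a mapping")
        return cls.from_mapping(data)

    def with_updates(self, **kwargs: Any) -> "PipelineConfig":
        return replace(self, **kwargs)
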