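"""Seeded generators for every input the pipeline consumes.

Each generator emulates one class of real input with the statistical
structure the corresponding analysis stage assumes, together with a truth
table from which exact expected outputs can be computed — so every stage is
testable end to end without downloads:

- promoter FASTA sets (i.i.d. background composition, motifs planted at
  controlled per-promoter rates),
- per-experiment ratio tables (planted induced genes, multiplicative
  log-normal noise),
- normalized log2 expression matrices (planted fold changes, Gaussian
  noise on the log scale),
- forward/reverse similarity hit tables with known reciprocal structure.

All randomness flows from one seed: each generator draws from its own
substream derived from (seed, stable label), so adding a generator never
shifts another generator's stream.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .de import ExpressionMatrix
from .meta import RatioTable
from .motifs import IupacMotif, PromoterSet
from .orthology import Hit, HitTable, OrthologMap

__all__ = [
    "SimulationSpec",
    "gen_promoters",
    "gen_ratio_tables",
    "gen_expression_matrix",
    "gen_hit_tables",
]

_BASES = np.array(list("ACGT"))


@dataclass
class SimulationSpec:
    """Parameters of all synthetic inputs.

    Defaults mirror the study conditions the pipeline targets: four ratio
    experiments, 3-vs-3 expression designs with planted log2 fold change 2
    and noise SD 0.25, and promoter sets of 65 targets vs 103 controls of
    1000 bp at 60% A+T, the composition regime of plant promoter regions.
    """

    seed: int = 0
    n_genes: int = 200
    n_datasets: int = 4
    de_fraction: float = 0.1
    effect_log2fc: float = 2.0
    noise_sd_log2: float = 0.25
    n_replicates: int = 3
    n_target_promoters: int = 65
    n_control_promoters: int = 103
    promoter_length: int = 1000
    base_composition: tuple[float, float, float, float] = (0.3, 0.2, 0.2, 0.3)
    planted_motifs: list[tuple[str, float, float]] = field(default_factory=list)
    ortholog_topology: dict = field(
        default_factory=lambda: {"n_genes": 20, "n_reciprocal": 2, "n_decoys": 1}
    )

    def __post_init__(self) -> None:
        if not 0 <= self.de_fraction <= 1:
            raise ValueError("de_fraction must be in [0, 1]")
        comp = np.asarray(self.base_composition, dtype=float)
        if comp.shape != (4,) or abs(comp.sum() - 1.0) > 1e-9 or (comp < 0).any():
            raise ValueError("base_composition must be 4 non-negative values summing to 1")
        for _, t_rate, c_rate in self.planted_motifs:
            if not (0 <= t_rate <= 1 and 0 <= c_rate <= 1):
                raise ValueError("planted motif rates must be in [0, 1]")

    def rng(self, label: str) -> np.random.Generator:
        """Substream for one generator, stable under addition of others."""
        return np.random.default_rng([self.seed, zlib.crc32(label.encode())])


def _random_sequences(
    rng: np.random.Generator, n: int, length: int, composition: Sequence[float]
) -> list[str]:
    draws = rng.choice(4, size=(n, length), p=np.asarray(composition, float))
    return ["".join(_BASES[row]) for row in draws]


def _plant(
    rng: np.random.Generator,
    sequences: dict[str, str],
    motif: IupacMotif,
    rate: float,
    set_name: str,
    truth: list[dict],
) -> None:
    variants = motif.expand()
    for gene in sequences:
        if rng.random() >= rate:
            continue
        seq = sequences[gene]
        if len(motif) > len(seq):
            raise ValueError(
                f"motif {motif} longer than promoter ({len(motif)} > {len(seq)})"
            )
        instance = variants[rng.integers(len(variants))]
        pos = int(rng.integers(len(seq) - len(motif) + 1))  # 0-based
        sequences[gene] = seq[:pos] + instance + seq[pos + len(motif):]
        truth.append(
            {
                "set": set_name,
                "promoter": gene,
                "motif": str(motif),
                "instance": instance,
                "position": pos + 1,
            }
        )


def gen_promoters(
    spec: SimulationSpec,
) -> tuple[PromoterSet, PromoterSet, pd.DataFrame]:
    """Target and control promoter sets with planted motifs and a truth table.

    Background bases are i.i.d. from ``base_composition``; each planted
    motif is inserted (overwriting background, length preserved) at one
    uniform random position in a Bernoulli(rate) subset of each set's
    promoters. Truth rows record set, promoter, motif, concrete instance and
    1-based position.
    """
    rng = spec.rng("promoters")
    target = {
        f"TGT{i + 1:04d}": s
        for i, s in enumerate(
            _random_sequences(
                rng, spec.n_target_promoters, spec.promoter_length, spec.base_composition
            )
        )
    }
    control = {
        f"CTL{i + 1:04d}": s
        for i, s in enumerate(
            _random_sequences(
                rng, spec.n_control_promoters, spec.promoter_length, spec.base_composition
            )
        )
    }
    truth: list[dict] = []
    for pattern, t_rate, c_rate in spec.planted_motifs:
        motif = IupacMotif(pattern)
        _plant(rng, target, motif, t_rate, "target", truth)
        _plant(rng, control, motif, c_rate, "control", truth)
    truth_frame = pd.DataFrame(
        truth, columns=["set", "promoter", "motif", "instance", "position"]
    )
    return PromoterSet(target), PromoterSet(control), truth_frame


def _gene_ids(n: int) -> list[str]:
    return [f"GENE{i + 1:05d}" for i in range(n)]


def gen_ratio_tables(
    spec: SimulationSpec, timepoints: Sequence[str] = ("t15", "t120")
) -> tuple[list[RatioTable], pd.DataFrame]:
    """Per-experiment ratio tables with planted induced genes.

    True induced genes (a ``de_fraction`` subset) have underlying ratio
    2**effect_log2fc, all others 1.0; every observed value is multiplied by
    independent log-normal noise exp(N(0, noise_sd_log2·ln 2)), i.e. the
    noise SD is ``noise_sd_log2`` on the log2 scale.
    """
    rng = spec.rng("ratio_tables")
    genes = _gene_ids(spec.n_genes)
    n_induced = int(round(spec.de_fraction * spec.n_genes))
    induced = np.zeros(spec.n_genes, dtype=bool)
    induced[rng.choice(spec.n_genes, size=n_induced, replace=False)] = True
    base = np.where(induced, 2.0 ** spec.effect_log2fc, 1.0)
    sd_ln = spec.noise_sd_log2 * np.log(2.0)
    tables = []
    for d in range(spec.n_datasets):
        columns = {}
        for tp in timepoints:
            noise = np.exp(rng.normal(0.0, sd_ln, size=spec.n_genes))
            columns[(f"exp{d + 1}", tp)] = base * noise
        tables.append(RatioTable.from_columns(genes, columns))
    truth = pd.DataFrame(
        {"gene": genes, "induced": induced, "true_ratio": base}
    ).set_index("gene")
    return tables, truth


def gen_expression_matrix(
    spec: SimulationSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Normalized log2 expression matrix for a treated-vs-control design.

    Per gene: log2 value = baseline + group effect (planted genes only, in
    the treated group) + N(0, noise_sd_log2). Baselines are uniform in
    [6, 12] log2 units, the usual intensity range of RMA-normalized arrays.
    """
    if spec.n_replicates < 2:
        raise ValueError("need >=2 replicates per group")
    rng = spec.rng("expression_matrix")
    genes = _gene_ids(spec.n_genes)
    n_planted = int(round(spec.de_fraction * spec.n_genes))
    planted = np.zeros(spec.n_genes, dtype=bool)
    planted[rng.choice(spec.n_genes, size=n_planted, replace=False)] = True
    baseline = rng.uniform(6.0, 12.0, size=spec.n_genes)
    samples = [f"ctl_{i + 1}" for i in range(spec.n_replicates)] + [
        f"trt_{i + 1}" for i in range(spec.n_replicates)
    ]
    groups = {s: ("control" if s.startswith("ctl") else "treated") for s in samples}
    effect = np.where(planted, spec.effect_log2fc, 0.0)
    data = {}
    for s in samples:
        noise = rng.normal(0.0, spec.noise_sd_log2, size=spec.n_genes)
        shift = effect if groups[s] == "treated" else 0.0
        data[s] = baseline + shift + noise
    values = pd.DataFrame(data, index=genes)
    truth = pd.DataFrame(
        {"gene": genes, "planted": planted, "true_log2fc": effect}
    ).set_index("gene")
    return ExpressionMatrix(values, groups), truth


def gen_hit_tables(
    spec: SimulationSpec,
) -> tuple[HitTable, HitTable, OrthologMap]:
    """Forward/reverse similarity hit tables with known reciprocal structure.

    For each of ``n_genes`` query genes the forward ranking starts with
    ``n_reciprocal`` rice genes whose top reverse hit is the query (the true
    orthologs), followed by ``n_decoys`` rice genes whose top reverse hit is
    a different gene — so the iterative reciprocal walk provably returns
    exactly the planted prefix. Bit scores decrease with rank; E-values
    increase.
    """
    topo = spec.ortholog_topology
    n_genes = int(topo.get("n_genes", 20))
    n_rec = int(topo.get("n_reciprocal", 2))
    n_dec = int(topo.get("n_decoys", 1))
    rng = spec.rng("hit_tables")
    forward: list[tuple[str, str, float, float]] = []
    reverse: list[tuple[str, str, float, float]] = []
    pairs: dict[tuple[str, str], str] = {}
    for g in range(n_genes):
        gene = f"AT{g + 1:05d}"
        other = f"AT{(g + 1) % n_genes + 1:05d}"
        score = float(rng.uniform(400, 600))
        for r in range(n_rec + n_dec):
            rice = f"OS{g + 1:05d}R{r + 1}"
            bitscore = score - 25.0 * r
            evalue = 10.0 ** (-bitscore / 10.0)
            forward.append((gene, rice, bitscore, evalue))
            top_back = gene if r < n_rec else other
            reverse.append((rice, top_back, bitscore, evalue))
            # a weaker second reverse hit so "top" is a real ranking decision
            reverse.append((rice, f"AT{rng.integers(n_genes) + 1:05d}X", bitscore / 2, evalue * 1e3))
            if r < n_rec:
                pairs[(gene, rice)] = "reciprocal"
    return (
        HitTable.from_records(forward),
        HitTable.from_records(reverse),
        OrthologMap(pairs),
    )
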