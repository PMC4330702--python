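"""Promoter cis-element engine: degenerate motif scanning and enrichment.

Type-B response regulators, the transcription factors that realize the
immediate-early transcriptional output of cytokinin signalling, bind short
AT-rich elements: the pentameric cytokinin response motif AGAT[TC] (CRM) and
the octameric extended CRM AAGAT[TC]TT. This module provides everything
needed to look for such elements and propose new ones:

- IUPAC/bracket degenerate motifs with expansion semantics,
- exact sliding-window scanning of promoter sets (forward or both strands,
  overlapping occurrences counted by default),
- occurrence- and presence-based enrichment of a motif in a target promoter
  set versus a control set, with a one-sided exact (hypergeometric) test on
  promoter presence and a per-occurrence binomial test,
- the exhaustive screen of all 4^6 = 4096 octamers with a fixed central
  dinucleotide (central AT by default),
- screening of every concrete motif derivable from a degenerate consensus,
- combined coverage of a motif list over a promoter set, and
- position-frequency matrices with per-column information content for
  sequence logos.

Promoter sequences are upper-case DNA over {A,C,G,T,N}; N never matches any
motif symbol (including N, which stands for any *unambiguous* base).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._ids import normalize_gene_id
from .config import PipelineConfig
from .de import bh_qvalues

__all__ = [
    "IupacMotif",
    "PromoterSet",
    "EnrichmentRecord",
    "ScreenResult",
    "CombinedCoverage",
    "PositionFrequencyMatrix",
    "CRM",
    "ECRM",
    "ARR_CONSENSUS",
    "expand_iupac",
    "count_occurrences",
    "enrichment",
    "octamer_screen",
    "consensus_screen",
    "combined_coverage",
    "build_logo",
    "reverse_complement",
]

IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT",
    "K": "GT", "M": "AC", "B": "CGT", "D": "AGT",
    "H": "ACT", "V": "ACG", "N": "ACGT",
}

_BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
# byte code per base: A,C,G,T -> 0..3; anything else (N) -> 4
_ENCODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate(_BASES):
    _ENCODE[ord(_b)] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class IupacMotif:
    """Degenerate DNA motif over IUPAC codes and explicit bracket classes.

    ``"AAGAT[TC]TT"`` and ``"AAGATYTT"`` denote the same motif. Each
    position matches a fixed set of unambiguous bases; the expansion of the
    motif is the Cartesian product of those sets.
    """

    def __init__(self, pattern: str):
        self.pattern = pattern.strip().upper()
        self.classes: tuple[frozenset[str], ...] = self._parse(self.pattern)

    @staticmethod
    def _parse(pattern: str) -> tuple[frozenset[str], ...]:
        classes: list[frozenset[str]] = []
        i = 0
        while i < len(pattern):
            ch = pattern[i]
            if ch == "[":
                end = pattern.find("]", i)
                if end == -1:
                    raise ValueError(f"unclosed '[' at position {len(classes) + 1}")
                inner = pattern[i + 1 : end].replace(",", "").replace("/", "")
                if not inner or any(c not in _BASES for c in inner):
                    raise ValueError(
                        f"invalid bracket class {pattern[i:end + 1]!r} at position {len(classes) + 1}"
                    )
                classes.append(frozenset(inner))
                i = end + 1
            elif ch in IUPAC_CODES:
                classes.append(frozenset(IUPAC_CODES[ch]))
                i += 1
            else:
                raise ValueError(
                    f"invalid symbol {ch!r} at position {len(classes) + 1}"
                )
        if not classes:
            raise ValueError("empty motif")
        return tuple(classes)

    def __len__(self) -> int:
        return len(self.classes)

    def __str__(self) -> str:
        return self.pattern

    def __repr__(self) -> str:
        return f"IupacMotif({self.pattern!r})"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, IupacMotif) and self.classes == other.classes

    def __hash__(self) -> int:
        return hash(self.classes)

    @property
    def expansion_size(self) -> int:
        return math.prod(len(c) for c in self.classes)

    def expand(self) -> list[str]:
        """All concrete sequences matching the motif, lexicographically sorted."""
        return [
            "".join(combo)
            for combo in itertools.product(*(sorted(c) for c in self.classes))
        ]

    def match_table(self) -> np.ndarray:
        """(L, 5) boolean table: does motif position i accept base code j?

        Code 4 (N or any non-ACGT character in the sequence) matches nothing.
        """
        table = np.zeros((len(self.classes), 5), dtype=bool)
        for i, cls in enumerate(self.classes):
            for base in cls:
                table[i, _BASES.index(base)] = True
        return table


CRM = IupacMotif("AGAT[TC]")
ECRM = IupacMotif("AAGAT[TC]TT")
ARR_CONSENSUS = IupacMotif("[ACT][AG][GT]AT[ACT][CT][ACGT]")


def expand_iupac(motif: IupacMotif | str) -> list[str]:
    """Expand a degenerate motif into its concrete DNA strings."""
    if isinstance(motif, str):
        motif = IupacMotif(motif)
    return motif.expand()


class PromoterSet(dict):
    """Gene ID → upper-case promoter sequence (−window..−1, 5'→3' toward the gene).

    A thin mapping with normalization and validation; sequences are over
    {A,C,G,T,N} and non-empty.
    """

    def __init__(self, sequences: Mapping[str, str]):
        normalized: dict[str, str] = {}
        for gene, seq in sequences.items():
            gid = normalize_gene_id(gene)
            if gid in normalized:
                raise ValueError(f"duplicate promoter ID: {gid}")
            s = str(seq).strip().upper()
            if not s:
                raise ValueError(f"empty sequence for {gid}")
            bad = set(s) - set("ACGTN")
            if bad:
                raise ValueError(
                    f"record {gid} contains non-DNA characters: {sorted(bad)}"
                )
            normalized[gid] = s
        super().__init__(normalized)

    @property
    def lengths(self) -> dict[str, int]:
        return {g: len(s) for g, s in self.items()}

    def total_length(self) -> int:
        return sum(len(s) for s in self.values())


def _scan_positions(seq: str, motif: IupacMotif, count_overlaps: bool) -> list[int]:
    """1-based start positions of motif matches on the given strand."""
    m = len(motif)
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    n = codes.size
    if n < m:
        return []
    windows = np.lib.stride_tricks.sliding_window_view(codes, m)
    table = motif.match_table()
    hits = table[np.arange(m), windows].all(axis=1)
    positions = (np.flatnonzero(hits) + 1).tolist()
    if count_overlaps or not positions:
        return positions
    kept: list[int] = []
    next_free = 0
    for pos in positions:
        if pos >= next_free:
            kept.append(pos)
            next_free = pos + m
    return kept


@dataclass
class ScanResult:
    """Occurrences of one motif in one sequence."""

    count: int
    positions: list[int]
    positions_rc: list[int]


def count_occurrences(
    seq: str,
    motif: IupacMotif | str,
    *,
    strand_mode: str = "forward",
    count_overlaps: bool = True,
) -> ScanResult:
    """Count motif occurrences in a sequence by exact sliding-window match.

    Overlapping matches are counted by default. With ``strand_mode="both"``
    the reverse complement is additionally scanned and the merged count
    returned; reverse-strand matches are reported as 1-based start positions
    of the matched site on the forward sequence.
    """
    if isinstance(motif, str):
        motif = IupacMotif(motif)
    if strand_mode not in ("forward", "both"):
        raise ValueError("strand_mode must be 'forward' or 'both'")
    seq = seq.upper()
    fwd = _scan_positions(seq, motif, count_overlaps)
    rc_positions: list[int] = []
    if strand_mode == "both":
        n, m = len(seq), len(motif)
        rc_hits = _scan_positions(reverse_complement(seq), motif, count_overlaps)
        rc_positions = sorted(n - (p - 1) - m + 1 for p in rc_hits)
    return ScanResult(len(fwd) + len(rc_positions), fwd, rc_positions)


def scan_set(
    promoters: PromoterSet,
    motif: IupacMotif | str,
    *,
    strand_mode: str = "forward",
    count_overlaps: bool = True,
) -> pd.DataFrame:
    """Per-promoter occurrence counts and presence flags for one motif."""
    if isinstance(motif, str):
        motif = IupacMotif(motif)
    rows = {}
    for gene, seq in promoters.items():
        res = count_occurrences(
            seq, motif, strand_mode=strand_mode, count_overlaps=count_overlaps
        )
        rows[gene] = {"count": res.count, "present": res.count > 0, "length": len(seq)}
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "gene"
    return frame


@dataclass
class EnrichmentRecord:
    """Occurrence/presence statistics of one motif, target vs control set.

    ``fold_enrichment`` is the occurrence-rate fold (occurrences per bp of
    target promoter over occurrences per bp of control promoter; for sets
    with a fixed window length this equals occurrences-per-promoter fold).
    ``fold_presence`` is the analogous ratio of presence fractions. ``p`` is
    the one-sided exact hypergeometric tail on the presence 2×2 table;
    ``p_occurrence`` a per-occurrence binomial test. ``q`` is filled by the
    screens (BH over all motifs screened).
    """

    motif: str
    target_occurrences: int
    control_occurrences: int
    target_promoters_with_hit: int
    control_promoters_with_hit: int
    n_target: int
    n_control: int
    fold_enrichment: float
    fold_presence: float
    p: float
    p_occurrence: float
    q: float = float("nan")
    selected: bool = False


def presence_pvalue(k_target: int, n_target: int, k_control: int, n_control: int) -> float:
    """One-sided exact test for overrepresentation of presence in the target set.

    Hypergeometric upper tail: probability of >= ``k_target`` target
    promoters with a hit, conditioning on the total number of promoters
    with a hit across both sets.
    """
    population = n_target + n_control
    successes = k_target + k_control
    return float(stats.hypergeom.sf(k_target - 1, population, successes, n_target))


def _fold(rate_target: float, rate_control: float) -> float:
    if rate_target == 0:
        return 0.0
    if rate_control == 0:
        return float("inf")
    return rate_target / rate_control


def enrichment(
    target: PromoterSet,
    control: PromoterSet,
    motif: IupacMotif | str,
    cfg: PipelineConfig | None = None,
) -> EnrichmentRecord:
    """Enrichment of one motif in a target promoter set versus a control set."""
    cfg = cfg or PipelineConfig()
    if not target or not control:
        raise ValueError("both promoter sets must be non-empty")
    if isinstance(motif, str):
        motif = IupacMotif(motif)
    tgt = scan_set(target, motif, strand_mode=cfg.strand_mode)
    ctl = scan_set(control, motif, strand_mode=cfg.strand_mode)
    occ_t, occ_c = int(tgt["count"].sum()), int(ctl["count"].sum())
    k_t, k_c = int(tgt["present"].sum()), int(ctl["present"].sum())
    n_t, n_c = len(target), len(control)
    len_t, len_c = target.total_length(), control.total_length()
    rec = EnrichmentRecord(
        motif=str(motif),
        target_occurrences=occ_t,
        control_occurrences=occ_c,
        target_promoters_with_hit=k_t,
        control_promoters_with_hit=k_c,
        n_target=n_t,
        n_control=n_c,
        fold_enrichment=_fold(occ_t / len_t, occ_c / len_c),
        fold_presence=_fold(k_t / n_t, k_c / n_c),
        p=presence_pvalue(k_t, n_t, k_c, n_c),
        p_occurrence=float(
            stats.binom.sf(occ_t - 1, occ_t + occ_c, len_t / (len_t + len_c))
        )
        if occ_t + occ_c
        else 1.0,
    )
    rec.selected = (
        rec.target_occurrences > 0
        and rec.fold_enrichment >= cfg.enrichment_fold_min
        and rec.p <= cfg.enrichment_alpha
    )
    return rec


@dataclass
class ScreenResult:
    """Full table of an enrichment screen plus the selected subset."""

    records: list[EnrichmentRecord]
    table: pd.DataFrame = field(init=False)

    def __post_init__(self) -> None:
        self.table = pd.DataFrame([vars(r) for r in self.records]).set_index("motif")

    @property
    def selected(self) -> list[EnrichmentRecord]:
        return [r for r in self.records if r.selected]

    @property
    def selected_motifs(self) -> list[str]:
        return [r.motif for r in self.selected]


def _records_from_arrays(
    motifs: Sequence[str],
    occ_t: np.ndarray,
    occ_c: np.ndarray,
    k_t: np.ndarray,
    k_c: np.ndarray,
    n_t: int,
    n_c: int,
    len_t: int,
    len_c: int,
    cfg: PipelineConfig,
) -> list[EnrichmentRecord]:
    """Vectorized statistics for a family of motifs screened together."""
    p = stats.hypergeom.sf(k_t - 1, n_t + n_c, k_t + k_c, n_t)
    q = bh_qvalues(p)
    total = occ_t + occ_c
    frac_len = len_t / (len_t + len_c)
    p_occ = np.where(total > 0, stats.binom.sf(occ_t - 1, total, frac_len), 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(
            occ_t == 0, 0.0, (occ_t / len_t) / np.where(occ_c == 0, np.nan, occ_c / len_c)
        )
    fold = np.where((occ_t > 0) & (occ_c == 0), np.inf, fold)
    with np.errstate(divide="ignore", invalid="ignore"):
        foldp = np.where(
            k_t == 0, 0.0, (k_t / n_t) / np.where(k_c == 0, np.nan, k_c / n_c)
        )
    foldp = np.where((k_t > 0) & (k_c == 0), np.inf, foldp)
    selected = (occ_t > 0) & (fold >= cfg.enrichment_fold_min) & (p <= cfg.enrichment_alpha)
    return [
        EnrichmentRecord(
            motif=motifs[i],
            target_occurrences=int(occ_t[i]),
            control_occurrences=int(occ_c[i]),
            target_promoters_with_hit=int(k_t[i]),
            control_promoters_with_hit=int(k_c[i]),
            n_target=n_t,
            n_control=n_c,
            fold_enrichment=float(fold[i]),
            fold_presence=float(foldp[i]),
            p=float(p[i]),
            p_occurrence=float(p_occ[i]),
            q=float(q[i]),
            selected=bool(selected[i]),
        )
        for i in range(len(motifs))
    ]


def _center_window_codes(seq: str, center: str, k_flank: int = 3) -> np.ndarray:
    """Codes (base-4 over the 6 variable positions) of every valid
    center-anchored octamer window in ``seq``.

    A window of length 8 starting at i is valid when its central two bases
    (positions 4–5, 1-based within the window) equal ``center`` and all 8
    bases are unambiguous. Windows containing N are skipped (N matches no
    motif symbol).
    """
    codes = _ENCODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    length = 2 * k_flank + len(center)
    if codes.size < length:
        return np.empty(0, dtype=np.int64)
    windows = np.lib.stride_tricks.sliding_window_view(codes, length)
    center_codes = _ENCODE[np.frombuffer(center.encode("ascii"), dtype=np.uint8)]
    valid = (windows < 4).all(axis=1)
    for j, cc in enumerate(center_codes):
        valid &= windows[:, k_flank + j] == cc
    windows = windows[valid].astype(np.int64)
    variable = np.concatenate(
        [np.arange(k_flank), np.arange(k_flank + len(center), length)]
    )
    weights = 4 ** np.arange(len(variable) - 1, -1, -1)
    return windows[:, variable] @ weights


def _octamer_set_counts(
    promoters: PromoterSet, center: str, strand_mode: str
) -> tuple[np.ndarray, np.ndarray]:
    """(occurrence counts, presence counts) over all 4^6 octamers for one set."""
    n_oct = 4 ** 6
    occ = np.zeros(n_oct, dtype=np.int64)
    pres = np.zeros(n_oct, dtype=np.int64)
    for seq in promoters.values():
        per_seq = _center_window_codes(seq, center)
        if strand_mode == "both":
            per_seq = np.concatenate(
                [per_seq, _center_window_codes(reverse_complement(seq), center)]
            )
        if per_seq.size:
            occ += np.bincount(per_seq, minlength=n_oct)
            pres[np.unique(per_seq)] += 1
    return occ, pres


def _octamer_strings(center: str) -> list[str]:
    out = []
    for code in range(4 ** 6):
        chars = []
        for pos in range(6):
            shift = 2 * (5 - pos)
            chars.append(_BASES[(code >> shift) & 3])
        out.append("".join(chars[:3]) + center + "".join(chars[3:]))
    return out


def octamer_screen(
    target: PromoterSet,
    control: PromoterSet,
    center: str = "AT",
    cfg: PipelineConfig | None = None,
) -> ScreenResult:
    """Exhaustive enrichment screen over every octamer with a fixed center.

    Screens all 4^6 = 4096 octamers whose central dinucleotide (positions
    4–5) equals ``center``, asking whether any is overrepresented in the
    target promoters. The full table always carries BH q-values; selection
    mirrors the raw-p rule (occurrence fold >= ``enrichment_fold_min`` and
    presence p <= ``enrichment_alpha``).
    """
    cfg = cfg or PipelineConfig()
    center = center.strip().upper()
    if len(center) != 2 or set(center) - set(_BASES):
        raise ValueError("center must be an unambiguous dinucleotide")
    if not target or not control:
        raise ValueError("both promoter sets must be non-empty")
    occ_t, pres_t = _octamer_set_counts(target, center, cfg.strand_mode)
    occ_c, pres_c = _octamer_set_counts(control, center, cfg.strand_mode)
    motifs = _octamer_strings(center)
    records = _records_from_arrays(
        motifs,
        occ_t,
        occ_c,
        pres_t,
        pres_c,
        len(target),
        len(control),
        target.total_length(),
        control.total_length(),
        cfg,
    )
    return ScreenResult(records)


def consensus_screen(
    consensus: IupacMotif | str,
    target: PromoterSet,
    control: PromoterSet,
    cfg: PipelineConfig | None = None,
) -> ScreenResult:
    """Screen every concrete motif derivable from a degenerate consensus.

    Each expansion of the consensus (e.g. the 288 octamers of the type-B
    response regulator consensus [ACT][AG][GT]AT[ACT][CT][ACGT]) is tested
    for enrichment; selection uses the raw-p rule and BH q-values are
    reported over the family. A ``p_relaxed_band`` column flags motifs whose
    presence p lies in (0.05, 0.06], a band worth reporting as borderline.
    """
    cfg = cfg or PipelineConfig()
    if isinstance(consensus, str):
        consensus = IupacMotif(consensus)
    variants = consensus.expand()
    occ_t = np.zeros(len(variants), dtype=np.int64)
    occ_c = np.zeros(len(variants), dtype=np.int64)
    k_t = np.zeros(len(variants), dtype=np.int64)
    k_c = np.zeros(len(variants), dtype=np.int64)
    for i, variant in enumerate(variants):
        motif = IupacMotif(variant)
        t = scan_set(target, motif, strand_mode=cfg.strand_mode)
        c = scan_set(control, motif, strand_mode=cfg.strand_mode)
        occ_t[i], occ_c[i] = t["count"].sum(), c["count"].sum()
        k_t[i], k_c[i] = t["present"].sum(), c["present"].sum()
    records = _records_from_arrays(
        variants,
        occ_t,
        occ_c,
        k_t,
        k_c,
        len(target),
        len(control),
        target.total_length(),
        control.total_length(),
        cfg,
    )
    result = ScreenResult(records)
    result.table["p_relaxed_band"] = (result.table["p"] > 0.05) & (
        result.table["p"] <= 0.06
    )
    return result


@dataclass
class CombinedCoverage:
    """Coverage and pooled enrichment of a motif list over a promoter set."""

    n_target_covered: int
    n_target: int
    coverage: float
    pooled_target_occurrences: int
    pooled_control_occurrences: int
    combined_fold: float


def combined_coverage(
    motifs: Sequence[IupacMotif | str],
    target: PromoterSet,
    control: PromoterSet,
    cfg: PipelineConfig | None = None,
) -> CombinedCoverage:
    """Fraction of target promoters hit by at least one motif, pooled fold.

    A promoter is counted once however many motifs hit it; the combined fold
    enrichment pools occurrences of all motifs in each set and compares
    per-bp occurrence rates.
    """
    cfg = cfg or PipelineConfig()
    if not motifs:
        raise ValueError("need at least one motif")
    parsed = [IupacMotif(m) if isinstance(m, str) else m for m in motifs]
    covered: set[str] = set()
    occ_t = occ_c = 0
    for motif in parsed:
        tgt = scan_set(target, motif, strand_mode=cfg.strand_mode)
        ctl = scan_set(control, motif, strand_mode=cfg.strand_mode)
        covered |= set(tgt.index[tgt["present"]])
        occ_t += int(tgt["count"].sum())
        occ_c += int(ctl["count"].sum())
    fold = _fold(occ_t / target.total_length(), occ_c / control.total_length())
    return CombinedCoverage(
        n_target_covered=len(covered),
        n_target=len(target),
        coverage=len(covered) / len(target),
        pooled_target_occurrences=occ_t,
        pooled_control_occurrences=occ_c,
        combined_fold=fold,
    )


@dataclass
class PositionFrequencyMatrix:
    """Per-position base frequencies with information content in bits.

    ``counts`` and ``frequencies`` are 4 × L DataFrames (rows A, C, G, T);
    ``information`` is 2 − H(column) in bits, in [0, 2], computed without
    small-sample correction.
    """

    counts: pd.DataFrame
    frequencies: pd.DataFrame = field(init=False)
    information: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        totals = self.counts.sum(axis=0)
        if (totals <= 0).any():
            raise ValueError("every column needs at least one observation")
        self.frequencies = self.counts / totals
        freq = self.frequencies.to_numpy()
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(freq > 0, freq * np.log2(freq), 0.0)
        self.information = 2.0 + plogp.sum(axis=0)

    @classmethod
    def from_sequences(cls, sequences: Iterable[str]) -> "PositionFrequencyMatrix":
        seqs = [s.upper() for s in sequences]
        if not seqs:
            raise ValueError("no sequences given")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError(f"sequences have mixed lengths: {sorted(lengths)}")
        length = lengths.pop()
        counts = np.zeros((4, length), dtype=np.int64)
        for s in seqs:
            for j, base in enumerate(s):
                if base not in _BASES:
                    raise ValueError(f"ambiguous base {base!r} in occurrence {s!r}")
                counts[_BASES.index(base), j] += 1
        frame = pd.DataFrame(counts, index=list(_BASES), columns=range(1, length + 1))
        return cls(frame)

    def __len__(self) -> int:
        return self.counts.shape[1]

    def to_frame(self) -> pd.DataFrame:
        out = self.frequencies.T
        out.index.name = "position"
        out["information_bits"] = self.information
        return out


def build_logo(
    motifs_or_hits: Sequence[IupacMotif | str],
    target: PromoterSet | None = None,
    cfg: PipelineConfig | None = None,
) -> PositionFrequencyMatrix:
    """Occurrence-weighted position-frequency matrix for a sequence logo.

    With a promoter set: every occurrence of every motif in the target
    promoters contributes its matched substring, so a motif occurring twice
    in one promoter is counted twice. Without a promoter set the first
    argument is taken as a list of pre-extracted occurrence strings. All
    contributing sequences must share one length.
    """
    cfg = cfg or PipelineConfig()
    if target is None:
        return PositionFrequencyMatrix.from_sequences([str(s) for s in motifs_or_hits])
    occurrences: list[str] = []
    for motif in motifs_or_hits:
        if isinstance(motif, str):
            motif = IupacMotif(motif)
        m = len(motif)
        for seq in target.values():
            res = count_occurrences(seq, motif, strand_mode=cfg.strand_mode)
            occurrences.extend(seq[p - 1 : p - 1 + m] for p in res.positions)
            occurrences.extend(
                reverse_complement(seq[p - 1 : p - 1 + m]) for p in res.positions_rc
            )
    if not occurrences:
        raise ValueError("motifs have no occurrences in the target set")
    return PositionFrequencyMatrix.from_sequences(occurrences)


def plot_logo(pfm: PositionFrequencyMatrix, ax=None, path: str | None = None):
    """Render a sequence logo (letter heights = frequency × column information).

    Requires matplotlib; returns the axes. When ``path`` is given the figure
    is also written to that file.
    """
    import matplotlib

    if path is not None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, len(pfm) * 0.6), 2.5))
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for col in range(len(pfm)):
        info = pfm.information[col]
        heights = [
            (base, pfm.frequencies.iloc[_BASES.index(base), col] * info)
            for base in _BASES
        ]
        y = 0.0
        for base, h in sorted(heights, key=lambda bh: bh[1]):
            if h <= 0:
                continue
            tp = TextPath((0, 0), base, size=1, prop=font)
            bbox = tp.get_extents()
            transform = (
                Affine2D()
                .translate(-bbox.x0, -bbox.y0)
                .scale(0.9 / bbox.width, h / bbox.height)
                .translate(col + 0.05, y)
            )
            ax.add_patch(PathPatch(tp, transform=transform + ax.transData,
                                   facecolor=colors[base], edgecolor="none"))
            y += h
    ax.set_xlim(0, len(pfm))
    ax.set_ylim(0, 2)
    ax.set_xticks(np.arange(len(pfm)) + 0.5, labels=range(1, len(pfm) + 1))
    ax.set_ylabel("bits")
    ax.set_xlabel("position")
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
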