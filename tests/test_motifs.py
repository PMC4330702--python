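import math
from math import comb

import numpy as np
import pytest

from ckresponse.config import PipelineConfig
from ckresponse.motifs import (
    ARR_CONSENSUS,
    CRM,
    ECRM,
    IupacMotif,
    PositionFrequencyMatrix,
    PromoterSet,
    build_logo,
    combined_coverage,
    consensus_screen,
    count_occurrences,
    enrichment,
    expand_iupac,
    octamer_screen,
    presence_pvalue,
    reverse_complement,
)

BASES = "ACGT"


def naive_scan(seq, motif: IupacMotif) -> list[int]:
    """Regex-free character-comparison oracle; 1-based positions."""
    out = []
    m = len(motif)
    for i in range(len(seq) - m + 1):
        if all(seq[i + j] in motif.classes[j] for j in range(m)):
            out.append(i + 1)
    return out


def random_promoters(rng, n, length, p=(0.25, 0.25, 0.25, 0.25)):
    return PromoterSet(
        {
            f"P{i}": "".join(rng.choice(list(BASES), size=length, p=list(p)))
            for i in range(n)
        }
    )


class TestIupacExpansion:
    def test_ecrm_two_variants(self):
        assert set(expand_iupac("AAGAT[TC]TT")) == {"AAGATTTT", "AAGATCTT"}

    def test_consensus_has_288_members(self):
        expanded = expand_iupac(ARR_CONSENSUS)
        assert len(expanded) == 288
        assert len(set(expanded)) == 288

    def test_concrete_motif_is_identity(self):
        assert expand_iupac("ACGT") == ["ACGT"]

    def test_iupac_letters_equal_bracket_classes(self):
        assert IupacMotif("AAGATYTT") == IupacMotif("AAGAT[TC]TT")

    def test_invalid_symbol_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            IupacMotif("AC!T")

    def test_unclosed_bracket_rejected(self):
        with pytest.raises(ValueError, match="unclosed"):
            IupacMotif("A[CT")

    def test_expansion_size_is_product_of_class_sizes(self):
        assert IupacMotif("NRY").expansion_size == 4 * 2 * 2


class TestCounting:
    def test_ecrm_single_occurrence_at_position_one(self):
        res = count_occurrences("AAGATTTT", ECRM)
        assert res.count == 1 and res.positions == [1]

    def test_overlapping_occurrences_counted(self):
        res = count_occurrences("TATATATATA", "TATATATA")
        assert res.count == 2 and res.positions == [1, 3]

    def test_overlap_disabled(self):
        res = count_occurrences("TATATATATA", "TATATATA", count_overlaps=False)
        assert res.count == 1 and res.positions == [1]

    def test_no_match_in_gc_sequence(self):
        for motif in octamer_sample():
            assert count_occurrences("GGGGGGGG", motif).count == 0

    def test_sequence_n_matches_no_motif_symbol(self):
        assert count_occurrences("AANATTTT", ECRM).count == 0
        # motif code N matches unambiguous bases, never the character N
        assert count_occurrences("ACGT", "NNNN").count == 1
        assert count_occurrences("ACNT", "NNNN").count == 0

    def test_both_strands_counts_reverse_complement_site(self):
        motif = IupacMotif("AAGATTTT")
        seq = "GGGG" + reverse_complement("AAGATTTT") + "GGGG"
        assert count_occurrences(seq, motif).count == 0
        res = count_occurrences(seq, motif, strand_mode="both")
        assert res.count == 1 and res.positions_rc == [5]

    def test_palindromic_site_counted_on_both_strands(self):
        # AAGATCTT is its own reverse complement: one site, two strand matches
        res = count_occurrences("GGGGAAGATCTTGGGG", "AAGATCTT", strand_mode="both")
        assert res.count == 2 and res.positions == [5] and res.positions_rc == [5]

    def test_matches_naive_oracle_on_random_pairs(self):
        rng = np.random.default_rng(42)
        symbols = list("ACGTRYSWKMBDHVN")
        for _ in range(300):
            seq = "".join(rng.choice(list(BASES + "N"), size=rng.integers(5, 60)))
            motif = IupacMotif(
                "".join(rng.choice(symbols, size=rng.integers(1, 9)))
            )
            assert count_occurrences(seq, motif).positions == naive_scan(seq, motif)

    def test_ecrm_never_exceeds_crm(self):
        # every extended-motif occurrence embeds a core-motif occurrence
        rng = np.random.default_rng(1)
        at_rich = (0.3, 0.2, 0.2, 0.3)
        for _ in range(1000):
            seq = "".join(rng.choice(list(BASES), size=60, p=at_rich))
            assert count_occurrences(seq, ECRM).count <= count_occurrences(seq, CRM).count


def octamer_sample():
    return ["AAAATAAA", "GCGATCGC", "TTTATTTT"]


def hypergeom_tail_oracle(k_t, n_t, k_c, n_c):
    """Exact summation of the upper hypergeometric tail via binomials."""
    population, successes = n_t + n_c, k_t + k_c
    total = comb(population, n_t)
    acc = 0
    for k in range(k_t, min(successes, n_t) + 1):
        if successes - k <= n_c:
            acc += comb(successes, k) * comb(population - successes, n_t - k)
    return acc / total


class TestEnrichment:
    def test_complete_separation_closed_form(self):
        rng = np.random.default_rng(0)
        target = PromoterSet({f"T{i}": "GGGG" + "AAGATTTT" + "GGGG" for i in range(10)})
        control = PromoterSet({f"C{i}": "G" * 16 for i in range(10)})
        rec = enrichment(target, control, ECRM)
        assert rec.target_promoters_with_hit == 10
        assert rec.control_promoters_with_hit == 0
        assert rec.p == pytest.approx(1 / comb(20, 10))

    def test_identical_sets_presence_fold_unity(self, small_promoters):
        target, _ = small_promoters
        rec = enrichment(target, target, ECRM)
        assert rec.fold_presence == 1.0
        assert rec.fold_enrichment == 1.0

    def test_zero_target_occurrences(self, small_promoters):
        _, control = small_promoters
        target = PromoterSet({"T1": "GGGGGGGGGGGG"})
        rec = enrichment(target, control, ECRM)
        assert rec.fold_enrichment == 0.0
        assert rec.p == 1.0
        assert not rec.selected

    def test_zero_control_occurrences_infinite_fold(self):
        target = PromoterSet({"T1": "AAGATTTTGG"})
        control = PromoterSet({"C1": "GGGGGGGGGG"})
        rec = enrichment(target, control, ECRM)
        assert math.isinf(rec.fold_enrichment)
        assert 0 < rec.p <= 1

    def test_presence_p_matches_summation_oracle_small_tables(self):
        for n_t in range(1, 12):
            for n_c in range(1, 12):
                for k_t in range(n_t + 1):
                    for k_c in range(n_c + 1):
                        assert presence_pvalue(k_t, n_t, k_c, n_c) == pytest.approx(
                            hypergeom_tail_oracle(k_t, n_t, k_c, n_c), abs=1e-12
                        )


class TestOctamerScreen:
    def test_counts_conserve_centered_windows(self):
        rng = np.random.default_rng(5)
        for comp in [(0.25,) * 4, (0.4, 0.1, 0.1, 0.4)]:
            pset = random_promoters(rng, 4, 200, comp)
            res = octamer_screen(pset, random_promoters(rng, 2, 200))
            total = res.table["target_occurrences"].sum()
            windows = sum(
                1
                for s in pset.values()
                for i in range(len(s) - 7)
                if s[i + 3 : i + 5] == "AT"
            )
            assert total == windows

    def test_target_equal_control_selects_nothing(self):
        rng = np.random.default_rng(6)
        pset = random_promoters(rng, 5, 300)
        res = octamer_screen(pset, pset)
        assert res.selected == []
        occ = res.table[res.table["target_occurrences"] > 0]
        assert (occ["fold_enrichment"] == 1.0).all()

    def test_planted_octamer_recovered(self):
        from ckresponse.simulate import SimulationSpec, gen_promoters

        spec = SimulationSpec(seed=3, planted_motifs=[("AAGATCTT", 0.4, 0.05)])
        target, control, _ = gen_promoters(spec)
        res = octamer_screen(target, control)
        assert "AAGATCTT" in res.selected_motifs

    def test_invalid_center_rejected(self, small_promoters):
        target, control = small_promoters
        with pytest.raises(ValueError):
            octamer_screen(target, control, center="ATT")
        with pytest.raises(ValueError):
            octamer_screen(target, control, center="NN")

    def test_full_table_always_emitted_with_qvalues(self, small_promoters):
        target, control = small_promoters
        res = octamer_screen(target, control)
        assert len(res.table) == 4096
        assert res.table["q"].between(0, 1).all()


class TestConsensusScreen:
    def test_only_planted_variant_selected(self):
        from ckresponse.simulate import SimulationSpec, gen_promoters

        spec = SimulationSpec(seed=8, planted_motifs=[("AAGATCTT", 0.5, 0.02)])
        target, control, _ = gen_promoters(spec)
        res = consensus_screen("AAGAT[TC]TT", target, control)
        assert "AAGATCTT" in res.selected_motifs
        assert "AAGATTTT" not in res.selected_motifs

    def test_zero_target_hits_empty_selection(self):
        target = PromoterSet({"T1": "G" * 50})
        control = PromoterSet({"C1": "G" * 50})
        res = consensus_screen("AAGAT[TC]TT", target, control)
        assert res.selected == []

    def test_boundary_rule_lists_all_motifs_with_target_hits(self):
        rng = np.random.default_rng(9)
        target = random_promoters(rng, 5, 400, (0.3, 0.2, 0.2, 0.3))
        control = random_promoters(rng, 5, 400, (0.3, 0.2, 0.2, 0.3))
        cfg = PipelineConfig(enrichment_alpha=1.0, enrichment_fold_min=0.0)
        res = consensus_screen(ARR_CONSENSUS, target, control, cfg)
        hit = res.table["target_occurrences"] > 0
        assert (res.table["selected"] == hit).all()

    def test_relaxed_band_column_present(self, small_promoters):
        target, control = small_promoters
        res = consensus_screen("AAGAT[TC]TT", target, control)
        assert "p_relaxed_band" in res.table.columns


class TestCombinedCoverage:
    def test_single_motif_consistent_with_enrichment(self, small_promoters):
        target, control = small_promoters
        rec = enrichment(target, control, ECRM)
        cc = combined_coverage([ECRM], target, control)
        assert cc.n_target_covered == rec.target_promoters_with_hit
        assert cc.coverage == rec.target_promoters_with_hit / rec.n_target

    def test_promoter_counted_once_across_motifs(self):
        target = PromoterSet({"T1": "AAGATTTTAAGATCTT", "T2": "G" * 16})
        control = PromoterSet({"C1": "G" * 16})
        cc = combined_coverage(["AAGATTTT", "AAGATCTT"], target, control)
        assert cc.n_target_covered == 1
        assert cc.coverage == 0.5

    def test_near_complete_coverage(self):
        # 64 of 65 promoters carry one of the motifs
        seqs = {f"T{i}": "CCCC" + "AAGATTTT" + "CCCC" for i in range(64)}
        seqs["T64"] = "C" * 16
        target = PromoterSet(seqs)
        control = PromoterSet({f"C{i}": "C" * 16 for i in range(10)})
        cc = combined_coverage([ECRM], target, control)
        assert cc.n_target_covered == 64
        assert cc.coverage == pytest.approx(64 / 65)

    def test_empty_motif_list_rejected(self, small_promoters):
        target, control = small_promoters
        with pytest.raises(ValueError):
            combined_coverage([], target, control)


class TestLogo:
    def test_identical_occurrences_full_information(self):
        target = PromoterSet({"T1": "GGAAGATTTTGG", "T2": "AAGATTTTCCCC"})
        pfm = build_logo([IupacMotif("AAGATTTT")], target)
        assert pfm.frequencies.loc["A", 1] == 1.0
        np.testing.assert_allclose(pfm.information, 2.0)

    def test_uniform_column_zero_bits(self):
        pfm = PositionFrequencyMatrix.from_sequences(["A", "C", "G", "T"])
        assert pfm.information[0] == pytest.approx(0.0)

    def test_two_occurrence_entropy_hand_computed(self):
        pfm = build_logo(["AT", "AA"])
        assert pfm.frequencies.loc["A", 1] == 1.0
        assert pfm.information[0] == pytest.approx(2.0)
        assert pfm.frequencies.loc["A", 2] == 0.5
        assert pfm.frequencies.loc["T", 2] == 0.5
        assert pfm.information[1] == pytest.approx(1.0)

    def test_mixed_lengths_rejected(self):
        with pytest.raises(ValueError, match="length"):
            build_logo(["AAGATTTT", "AGATT"])

    def test_no_occurrences_rejected(self):
        target = PromoterSet({"T1": "GGGGGGGG"})
        with pytest.raises(ValueError, match="occurrence"):
            build_logo([ECRM], target)

    def test_columns_sum_to_one(self):
        rng = np.random.default_rng(2)
        seqs = ["".join(rng.choice(list(BASES), size=8)) for _ in range(30)]
        pfm = PositionFrequencyMatrix.from_sequences(seqs)
        np.testing.assert_allclose(pfm.frequencies.sum(axis=0), 1.0)
        assert ((pfm.information >= 0) & (pfm.information <= 2)).all()

    def test_occurrence_weighted(self):
        # one promoter with two occurrences contributes twice
        target = PromoterSet({"T1": "AAGATTTTAAGATCTT"})
        pfm = build_logo([ECRM], target)
        assert pfm.counts.loc["T", 6] == 1
        assert pfm.counts.loc["C", 6] == 1
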