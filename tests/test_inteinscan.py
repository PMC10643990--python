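import math

import numpy as np
import pytest
from conftest import brute_force_scan

from halointein.inteinscan import (
    InteinCall,
    build_pssm,
    call_inteins,
    classify_hen,
    group_summary,
    scan_proteome,
    scan_sequence,
)
from halointein.synthetic import (
    SimConfig,
    make_motif_set,
    synth_block_alignment,
    synth_proteome,
)


class TestBuildPssm:
    def test_identical_block_scores_consensus_positive(self):
        p = build_pssm(["ACDEF"] * 4)
        assert p.consensus == "ACDEF"
        for i, aa in enumerate("ACDEF"):
            col = p.matrix[i, :20]
            assert col[list("ACDEFGHIKLMNPQRSTVWY").index(aa)] > 0
            assert sum(c < 0 for c in col) == 19

    def test_single_column_hand_arithmetic(self):
        # counts A:2 C:2, alpha=0.8, uniform background 0.05:
        # s(A) = log2((2 + 0.8*0.05) / ((4+0.8)*0.05))
        p = build_pssm(["A", "A", "C", "C"], alpha=0.8)
        sA = math.log2((2 + 0.8 * 0.05) / ((4 + 0.8) * 0.05))
        sG = math.log2((0 + 0.8 * 0.05) / ((4 + 0.8) * 0.05))
        aa = "ACDEFGHIKLMNPQRSTVWY"
        assert p.matrix[0, aa.index("A")] == pytest.approx(sA, abs=1e-12)
        assert p.matrix[0, aa.index("G")] == pytest.approx(sG, abs=1e-12)

    def test_gapped_columns_use_ungapped_counts(self):
        p1 = build_pssm(["AC", "A-", "AC"])
        p2 = build_pssm(["AC", "AC"])  # column 2 counts only ungapped rows
        aa = "ACDEFGHIKLMNPQRSTVWY"
        # column 1: both have 'A' only, but n differs (3 vs 2)
        assert p1.matrix[1, aa.index("C")] == pytest.approx(p2.matrix[1, aa.index("C")])

    def test_consensus_window_is_max_attainable(self, rng):
        block = synth_block_alignment("MKVLDERTAY", n_seqs=6, seed=0)
        p = build_pssm(block)
        scores = brute_force_scan(p, p.consensus)
        assert p.consensus_score == pytest.approx(scores.max(), abs=1e-9)

    def test_bad_inputs(self):
        with pytest.raises(ValueError):
            build_pssm(["ACDEF"])
        with pytest.raises(ValueError):
            build_pssm(["AC", "AC"], alpha=0.0)


class TestScanSequence:
    def test_planted_consensus_found_at_offset(self, rng):
        motif = make_motif_set(1, 15, seed=9)["motif1"]
        p = build_pssm(synth_block_alignment(motif, seed=1), name="m")
        from halointein.synthetic import _draw_seq

        seq = _draw_seq(rng, 37) + motif + _draw_seq(rng, 60)
        hits = scan_sequence(p, seq, "s1")
        assert len(hits) >= 1
        assert hits[0].offset == 37

    def test_matches_brute_force_on_random_sequences(self, rng):
        from halointein.synthetic import _draw_seq

        motif = make_motif_set(1, 8, seed=3)["motif1"]
        p = build_pssm(synth_block_alignment(motif, seed=2))
        threshold = -5.0  # low: many hits, exercises merging-free comparison
        for _ in range(10):
            seq = _draw_seq(rng, 80)
            oracle = brute_force_scan(p, seq)
            hits = scan_sequence(p, seq, threshold=threshold)
            # every reported hit has the oracle's score at its offset
            for h in hits:
                assert h.score == pytest.approx(oracle[h.offset], abs=1e-9)
            # the best oracle window above threshold is always reported
            if oracle.max() >= threshold:
                assert any(
                    h.score == pytest.approx(oracle.max(), abs=1e-9) for h in hits
                )

    def test_threshold_above_consensus_no_hits(self):
        p = build_pssm(["MKVLD"] * 3)
        assert scan_sequence(p, "MKVLD" * 4, threshold=p.consensus_score + 1) == []

    def test_self_scan_recovers_source_rows(self):
        block = synth_block_alignment("MKVLDERTAYWQ", n_seqs=5, sub_rate=0.15, seed=4)
        p = build_pssm(block)
        min_self = min(brute_force_scan(p, row)[0] for row in block)
        for row in block:
            hits = scan_sequence(p, "GGGGG" + row + "GGGGG", threshold=min_self)
            assert any(h.offset == 5 for h in hits)

    def test_short_sequence_empty(self):
        p = build_pssm(["MKVLDERT"] * 2)
        assert scan_sequence(p, "MK") == []

    def test_ambiguity_codes_score_zero(self):
        p = build_pssm(["MK", "MK"])
        sX = brute_force_scan(p, "XX")
        assert sX[0] == 0.0


class TestCallInteins:
    def _hit(self, off, pssm="m", score=10.0, L=10, sid="s"):
        from halointein.inteinscan import ScanHit

        return ScanHit(seq_id=sid, offset=off, score=score, pssm=pssm, length=L)

    def test_distant_hits_two_calls(self):
        calls = call_inteins([self._hit(0), self._hit(500)], merge_gap=150)
        assert len(calls) == 2

    def test_overlapping_pssm_hits_one_call(self):
        hits = [self._hit(100, "m1"), self._hit(130, "m2"), self._hit(160, "m3")]
        calls = call_inteins(hits, merge_gap=150)
        assert len(calls) == 1
        assert calls[0].start == 100 and calls[0].end == 170
        assert calls[0].n_hits == 3

    def test_zero_hits_zero_calls(self):
        assert call_inteins([]) == []


class TestClassifyHen:
    def test_full_and_mini(self):
        cfg = SimConfig(seed=42, n_proteins=4)
        sp = synth_proteome(cfg, n_full=1, n_mini=1)
        calls = scan_proteome(sp.proteome, sp.intein_pssms, sp.hen_pssms)
        cats = {c.seq_id: c.category for c in calls}
        truth = dict(zip(sp.truth.seq_id, sp.truth.category))
        assert cats == truth

    def test_threshold_sweep_monotone(self):
        cfg = SimConfig(seed=43, n_proteins=2)
        sp = synth_proteome(cfg, n_full=1, n_mini=0)
        calls = scan_proteome(sp.proteome, sp.intein_pssms)
        call = calls[0]
        seq = sp.proteome[call.seq_id]
        prev_full = True
        transitions = 0
        for th in np.linspace(0, 30, 40):
            c = classify_hen(
                InteinCall(call.seq_id, 0, call.start, call.end, call.n_hits),
                seq, sp.hen_pssms, threshold=float(th),
            )
            now_full = c.category == "full"
            if prev_full != now_full:
                transitions += 1
            assert not (now_full and not prev_full)  # never re-enters "full"
            prev_full = now_full
        assert transitions <= 1


class TestGroupSummary:
    def test_percentage_arithmetic(self):
        # one group: 2 multi-intein genes carrying 4 inteins, 3 full -> 75%
        calls = [
            InteinCall("g1", 0, 0, 100, 1, "full"),
            InteinCall("g1", 1, 500, 600, 1, "full"),
            InteinCall("g2", 0, 0, 100, 1, "full"),
            InteinCall("g2", 1, 500, 600, 1, "mini"),
            InteinCall("g3", 0, 0, 100, 1, "mini"),
        ]
        groups = {"g1": "G", "g2": "G", "g3": "G"}
        out = group_summary(calls, groups)
        assert out.loc["G", "multi_intein_genes"] == 2
        assert out.loc["G", "pct_multi_with_hen"] == pytest.approx(75.0)
        assert out.loc["G", "single_intein_genes"] == 1
        assert out.loc["G", "pct_single_with_hen"] == pytest.approx(0.0)

    def test_group_with_no_multi_genes_is_nan(self):
        calls = [InteinCall("g1", 0, 0, 100, 1, "full")]
        out = group_summary(calls, {"g1": "G"})
        assert np.isnan(out.loc["G", "pct_multi_with_hen"])

    def test_permutation_invariance(self, rng):
        calls = [
            InteinCall(f"g{i}", j, 0, 100, 1, "full" if (i + j) % 2 else "mini")
            for i in range(6)
            for j in range(1 + i % 3)
        ]
        groups = {f"g{i}": "AB"[i % 2] for i in range(6)}
        out1 = group_summary(calls, groups)
        perm = [calls[i] for i in rng.permutation(len(calls))]
        out2 = group_summary(perm, groups)
        assert out1.sort_index().equals(out2.sort_index())

    def test_unlabeled_gene_rejected(self):
        calls = [InteinCall("gX", 0, 0, 100, 1, "mini")]
        with pytest.raises(ValueError, match="gX"):
            group_summary(calls, {"gY": "G"})


class TestEndToEnd:
    def test_planted_recovery_with_categories(self):
        sp = synth_proteome(SimConfig(seed=7), n_full=8, n_mini=5)
        calls = scan_proteome(sp.proteome, sp.intein_pssms, sp.hen_pssms)
        truth = sp.truth.set_index("seq_id")
        assert len(calls) == 13
        for c in calls:
            row = truth.loc[c.seq_id]
            assert c.category == row["category"]
            assert abs(c.start - row["offset"]) <= 5

    def test_no_planted_no_calls(self):
        # ~1e5 random residues, zero planted inteins: no false positives at
        # the default threshold
        sp = synth_proteome(
            SimConfig(seed=8, n_proteins=200, protein_length=(450, 550)),
            n_full=0, n_mini=0,
        )
        calls = scan_proteome(sp.proteome, sp.intein_pssms, sp.hen_pssms)
        assert calls == []

    def test_intein_at_offset_zero(self):
        sp = synth_proteome(SimConfig(seed=11, n_proteins=3), n_full=1, n_mini=0)
        # force a plant at the very start of a protein
        sid = sp.truth.seq_id.iloc[0]
        seq = sp.proteome[sid]
        off, length = int(sp.truth.offset.iloc[0]), int(sp.truth.length.iloc[0])
        moved = seq[off : off + length] + seq[:off] + seq[off + length :]
        calls = scan_proteome({sid: moved}, sp.intein_pssms, sp.hen_pssms)
        assert len(calls) == 1
        assert calls[0].start <= 5
        assert calls[0].category == "full"
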