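"""PWM scoring, normalisation anchors, and exhaustive-scan equivalence."""

import math
import random

import pytest

from promine.promoter_scan import (
    MINUS10_CONSENSUS,
    MINUS35_CONSENSUS,
    PromoterHit,
    PromoterModel,
    build_default_model,
    read_model,
    scan_upstream,
    score_placement,
    write_model,
)

MATCH_BITS = math.log2(0.7 / 0.25)      # per-position consensus log-odds
MISMATCH_BITS = math.log2(0.1 / 0.25)


def _naive_hexamer_score(hexamer: str, consensus: str) -> float:
    """Independent oracle: log-odds of a 6-mer against the consensus model."""
    total = 0.0
    for a, b in zip(hexamer, consensus):
        if a not in "ACGT":
            total += MISMATCH_BITS  # column minimum for N
        else:
            total += MATCH_BITS if a == b else MISMATCH_BITS
    return total


def _naive_scan(seq: str, threshold: float) -> dict[int, tuple[int, float]]:
    """Brute-force double loop over all offsets and spacers; returns the
    best (i35, raw) per -10 offset among placements above threshold."""
    s_max = 12 * MATCH_BITS
    s_min = 12 * MISMATCH_BITS
    kept: dict[int, tuple[int, float]] = {}
    for i35 in range(len(seq)):
        for spacer in range(15, 22):
            i10 = i35 + 6 + spacer
            if i10 + 6 > len(seq):
                continue
            raw = (
                _naive_hexamer_score(seq[i35 : i35 + 6], MINUS35_CONSENSUS)
                + _naive_hexamer_score(seq[i10 : i10 + 6], MINUS10_CONSENSUS)
                - 0.5 * abs(spacer - 17)
            )
            norm = min(1.0, max(0.0, (raw - s_min) / (s_max - s_min)))
            if norm < threshold:
                continue
            if i10 not in kept or raw > kept[i10][1] + 1e-9:
                kept[i10] = (i35, raw)
    return kept


class TestDefaultModel:
    def test_consensus_column_log_odds(self, default_model):
        # -35 consensus starts with T: column 0 must be (A,C,G: mismatch, T: match)
        col = default_model.pwm_minus35[0]
        assert col[3] == pytest.approx(MATCH_BITS)   # ~1.485 bits
        assert col[0] == col[1] == col[2] == pytest.approx(MISMATCH_BITS)

    def test_score_extremes_by_construction(self, default_model):
        assert default_model.max_raw_score == pytest.approx(12 * MATCH_BITS)  # ~17.82
        assert default_model.min_raw_score == pytest.approx(12 * MISMATCH_BITS)

    def test_model_file_round_trip(self, default_model, tmp_path):
        path = tmp_path / "model.tsv"
        write_model(default_model, path)
        back = read_model(path)
        assert back.spacer_optimum == default_model.spacer_optimum
        for a, b in zip(back.pwm_minus35, default_model.pwm_minus35):
            assert a == pytest.approx(b, abs=1e-5)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            build_default_model(spacer_min=18, spacer_optimum=17)


class TestScorePlacement:
    def _window(self, spacer: int, left: str = "", right: str = "") -> str:
        return left + MINUS35_CONSENSUS + "C" * spacer + MINUS10_CONSENSUS + right

    def test_consensus_at_optimal_spacer_scores_one(self, default_model):
        seq = self._window(17)
        raw, norm = score_placement(seq, 0, 17, default_model)
        assert norm == 1.0
        assert raw == pytest.approx(default_model.max_raw_score)

    def test_all_mismatch_scores_zero(self, default_model):
        # per-position non-consensus hexamers vs TTGACA and TATAAT
        seq = "CCCGGC" + "A" * 17 + "CCCCCA"
        raw, norm = score_placement(seq, 0, 17, default_model)
        assert raw == pytest.approx(12 * MISMATCH_BITS)
        assert norm == 0.0

    def test_suboptimal_spacer_penalised_by_hand_arithmetic(self, default_model):
        seq = self._window(15)
        raw, norm = score_placement(seq, 0, 15, default_model)
        assert raw == pytest.approx(default_model.max_raw_score - 2 * 0.5)
        expected_norm = (raw - default_model.min_raw_score) / (
            default_model.max_raw_score - default_model.min_raw_score
        )
        assert norm == pytest.approx(expected_norm)  # ~0.970

    def test_out_of_range_spacer_is_hard_error(self, default_model):
        seq = self._window(14)
        with pytest.raises(ValueError, match="spacer"):
            score_placement(seq, 0, 14, default_model)

    def test_n_bases_score_worst_case(self, default_model):
        clean = self._window(17)
        dirty = "NNGACA" + "C" * 17 + MINUS10_CONSENSUS
        raw_clean, _ = score_placement(clean, 0, 17, default_model)
        raw_dirty, _ = score_placement(dirty, 0, 17, default_model)
        assert raw_dirty == pytest.approx(raw_clean - 2 * (MATCH_BITS - MISMATCH_BITS))

    def test_monotone_in_consensus_matches(self, default_model):
        """More consensus-matching positions never lowers the score."""
        base = list("GGGGGG")
        prev = None
        for k in range(7):
            hexamer = MINUS35_CONSENSUS[:k] + "".join(base[k:])
            seq = hexamer + "C" * 17 + MINUS10_CONSENSUS
            raw, norm = score_placement(seq, 0, 17, default_model)
            if prev is not None:
                assert norm >= prev
            prev = norm


class TestScan:
    def test_planted_consensus_recovered_exactly(self, default_model):
        # poly-C context and spacer: no flanking placement reaches 0.7
        seq = "C" * 80 + MINUS35_CONSENSUS + "C" * 17 + MINUS10_CONSENSUS + "C" * 60
        hits = scan_upstream(seq, default_model, 0.7, gene_id="g")
        assert len(hits) == 1
        assert hits[0].offset_minus35 == 80
        assert hits[0].spacer == 17
        assert hits[0].norm_score == 1.0

    def test_sub_threshold_placement_excluded(self, default_model):
        # 8 of 12 consensus matches -> norm ~0.667 < 0.7
        weak = "TTGAGG" + "C" * 17 + "TATAGG"
        seq = "C" * 40 + weak + "C" * 40
        raw, norm = score_placement(seq, 40, 17, default_model)
        assert 0.6 < norm < 0.7
        assert scan_upstream(seq, default_model, 0.7) == []
        assert len(scan_upstream(seq, default_model, 0.6)) >= 1

    def test_matches_brute_force_on_random_windows(self, default_model):
        """Exhaustive-enumeration equivalence on 60 seeded random 300-mers."""
        rng = random.Random(20260927)
        threshold = 0.55  # low enough that random windows yield hits to compare
        for _ in range(60):
            seq = "".join(rng.choice("ACGT") for _ in range(300))
            expected = _naive_scan(seq, threshold)
            hits = scan_upstream(seq, default_model, threshold)
            got = {h.offset_minus10: (h.offset_minus35, h.raw_score) for h in hits}
            assert set(got) == set(expected)
            for i10, (i35, raw) in expected.items():
                assert got[i10][0] == i35
                assert got[i10][1] == pytest.approx(raw)

    def test_short_window_yields_empty(self, default_model):
        assert scan_upstream("ACGT" * 6, default_model, 0.0) == []

    def test_threshold_zero_keeps_every_minus10_and_above_one_none(self, default_model):
        rng = random.Random(5)
        seq = "".join(rng.choice("ACGT") for _ in range(80))
        hits = scan_upstream(seq, default_model, 0.0)
        # every achievable -10 offset is represented after merging
        achievable = {
            i35 + 6 + sp
            for i35 in range(len(seq))
            for sp in range(15, 22)
            if i35 + 6 + sp + 6 <= len(seq)
        }
        assert {h.offset_minus10 for h in hits} == achievable
        assert scan_upstream(seq, default_model, 1.01) == []

    def test_reverse_complement_does_not_inherit_hits(self, default_model):
        from promine.genome_io import reverse_complement

        seq = "C" * 80 + MINUS35_CONSENSUS + "A" * 17 + MINUS10_CONSENSUS + "C" * 60
        assert len(scan_upstream(seq, default_model, 0.9)) == 1
        assert scan_upstream(reverse_complement(seq), default_model, 0.9) == []

    def test_hits_sorted_distal_first(self, default_model):
        unit = MINUS35_CONSENSUS + "A" * 17 + MINUS10_CONSENSUS
        seq = "C" * 30 + unit + "C" * 40 + unit + "C" * 30
        hits = scan_upstream(seq, default_model, 0.9)
        offsets = [h.offset_minus35 for h in hits]
        assert offsets == sorted(offsets)
        assert offsets[0] == 30


def test_promoter_hit_invariants():
    with pytest.raises(ValueError):
        PromoterHit("g", 0, 10, 17, 1.0, 0.5)  # inconsistent offsets
    with pytest.raises(ValueError):
        PromoterHit("g", 0, 23, 17, 1.0, 1.5)  # norm outside [0,1]
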