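"""Word counting, Fisher enrichment, RNA maps and the background envelope."""

import numpy as np
import pytest

from sepmap.motifmap import (
    ExonSequenceRecord,
    all_words,
    attach_envelope,
    background_envelope,
    build_rna_map,
    count_word_occurrences,
    detect_enriched_windows,
    fisher_containment_p,
    word_enrichment,
)
from sepmap.synthdata import SimulationConfig, gen_exon_sequences


def rec(exon_id, downstream, label="test"):
    return ExonSequenceRecord(
        exon_id=exon_id,
        exon_seq="A" * 10,
        upstream_intron="C" * 10,
        downstream_intron=downstream,
        class_label=label,
    )


class TestWordCounting:
    @pytest.mark.parametrize(
        "seq, word, n",
        [
            ("AAAAAA", "TGCATG", 0),
            ("TGCATGCATG", "TGCATG", 2),  # overlapping occurrences count
            ("TGCATG", "TGCATG", 1),
            ("TGCAT", "TGCATG", 0),       # word longer than sequence
            ("TGCNTG", "TGCATG", 0),      # N never matches
            ("atgcatga", "TGCATG", 1),    # case-insensitive
        ],
    )
    def test_examples(self, seq, word, n):
        assert count_word_occurrences(seq, word) == n

    def test_every_position_carries_exactly_one_word(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 80))
        total = sum(count_word_occurrences(seq, w) for w in all_words(6))
        assert total == len(seq) - 5

    def test_invalid_word_rejected(self):
        with pytest.raises(ValueError):
            count_word_occurrences("ACGT", "TGCNTG")


class TestWordEnrichment:
    def test_three_vs_zero_containment_p(self):
        # margins (3,3): P(X=3) + P(X=0) = 1/20 + 1/20 = 0.1
        test = [rec(f"t{i}", "TGCATG" + "A" * 20) for i in range(3)]
        bg = [rec(f"b{i}", "C" * 26, "background") for i in range(3)]
        df = word_enrichment(test, bg, window=(0, 26), words=["TGCATG"])
        assert df.iloc[0]["p"] == pytest.approx(0.1, abs=1e-12)
        assert df.iloc[0]["n_test_with"] == 3
        assert df.iloc[0]["n_bg_with"] == 0

    def test_identical_proportions_give_p_one(self):
        assert fisher_containment_p(5, 5, 50, 50) == pytest.approx(1.0)

    def test_default_window_is_150nt_downstream(self):
        # motif placed beyond 150 nt must not count under the default window
        test = [rec("t0", "A" * 150 + "TGCATG")]
        bg = [rec("b0", "A" * 156, "background")]
        df = word_enrichment(test, bg, words=["TGCATG"])
        assert df.iloc[0]["n_test_with"] == 0

    def test_results_sorted_by_p_then_word(self):
        test = [rec(f"t{i}", "TGCATGAAAAAACCCCCC") for i in range(8)]
        bg = [rec(f"b{i}", "GGGGGGGGGGGGGGGGGG", "background") for i in range(8)]
        df = word_enrichment(test, bg, window=(0, 18))
        p = df["p"].to_numpy()
        assert (np.diff(p) >= 0).all()
        ties = df[df["p"] == df["p"].iloc[0]]["word"]
        assert list(ties) == sorted(ties)

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            word_enrichment([], [rec("b", "ACGTAC")])

    def test_odds_ratio_haldane_correction_on_zero_cell(self):
        df = word_enrichment(
            [rec("t", "TGCATGAAA")], [rec("b", "AAAAAAAAA", "background")],
            window=(0, 9), words=["TGCATG"],
        )
        orr = df.iloc[0]["odds_ratio"]
        assert orr == pytest.approx((1.5 * 1.5) / (0.5 * 0.5))


class TestRnaMap:
    def test_absent_motif_gives_all_zero(self):
        m = build_rna_map([rec("t", "A" * 150)], "TGCATG")
        assert (m.freq_test == 0).all()

    def test_default_geometry_gives_21_windows(self):
        m = build_rna_map([rec("t", "A" * 150)], "TGCATG")
        assert m.window_starts.size == 21
        assert m.window_starts[0] == 0 and m.window_starts[-1] == 100

    def test_single_occurrence_at_75_fills_exactly_covering_windows(self):
        seq = "A" * 75 + "TGCATG" + "A" * 69
        m = build_rna_map([rec("t", seq)], "TGCATG")
        for w, f in zip(m.window_starts, m.freq_test):
            fully_contains = (w <= 75) and (75 + 6 <= w + 50)
            assert f == (1.0 if fully_contains else 0.0)

    def test_multiple_occurrences_counted_not_presence(self):
        seq = "TGCATGCATGCATG" + "A" * 136
        m = build_rna_map([rec("t", seq)], "TGCATG")
        assert m.freq_test[0] == pytest.approx(3.0)


class TestBackgroundEnvelope:
    def test_zero_occurrence_background_gives_zero_band(self):
        bg = [rec(f"b{i}", "A" * 150, "background") for i in range(10)]
        mean, lo, hi = background_envelope(bg, "TGCATG", 5, rng=0)
        assert (mean == 0).all() and (lo == 0).all() and (hi == 0).all()

    def test_band_is_ordered(self):
        cfg = SimulationConfig(plant_prob=0, seed=2, n_genes=5, n_events=5)
        bg, _ = gen_exon_sequences(cfg, {"background": 200})
        mean, lo, hi = background_envelope(bg, "TGCATG", 50, rng=1)
        assert (lo <= mean).all() and (mean <= hi).all()

    def test_oversized_sample_rejected(self):
        bg = [rec("b", "A" * 150, "background")]
        with pytest.raises(ValueError, match="sample_size"):
            background_envelope(bg, "TGCATG", 2)

    def test_seeded_envelope_reproducible(self):
        cfg = SimulationConfig(plant_prob=0, seed=3, n_genes=5, n_events=5)
        bg, _ = gen_exon_sequences(cfg, {"background": 100})
        a = background_envelope(bg, "TGCATG", 40, rng=7)
        b = background_envelope(bg, "TGCATG", 40, rng=7)
        for x, y in zip(a, b):
            assert np.array_equal(x, y)


class TestEnrichedWindowDetection:
    def test_no_excess_gives_empty_list(self):
        bg = [rec(f"b{i}", "A" * 150, "background") for i in range(10)]
        m = build_rna_map(bg, "TGCATG")
        m = attach_envelope(m, bg, 5, rng=0)
        # test frequencies are all zero, never above the (zero) band
        assert detect_enriched_windows(m) == []

    def test_planted_peak_detected_and_localized(self):
        cfg = SimulationConfig(plant_prob=0.8, plant_window=(70, 90), seed=5)
        recs, _ = gen_exon_sequences(cfg, {"test": 150, "background": 400})
        test = [r for r in recs if r.class_label == "test"]
        bg = [r for r in recs if r.class_label == "background"]
        m = attach_envelope(build_rna_map(test, "TGCATG"), bg, 150, rng=5)
        runs = detect_enriched_windows(m)
        assert runs
        best = max(runs, key=lambda r: r.peak_freq)
        lo, hi = best.peak_interval
        assert lo < 96 and hi > 70  # peak window overlaps the planted region

    def test_envelope_required(self):
        m = build_rna_map([rec("t", "A" * 150)], "TGCATG")
        with pytest.raises(ValueError, match="envelope"):
            detect_enriched_windows(m)


class TestRecordValidation:
    def test_invalid_characters_rejected(self):
        with pytest.raises(ValueError, match="invalid"):
            ExonSequenceRecord("x", "ACGU", "ACGT", "ACGT")
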