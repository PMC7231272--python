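"""PWM parsing, log-odds scoring, scanning and threshold calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as hst

import oracles
from promotif import (PWM, TransfacParseError, calibrate_threshold,
                      collapse_hits, parse_transfac, scan, write_transfac)
from promotif.simulate import gen_background_promoters, random_pwm


class TestTransfacParsing:
    def test_two_matrix_file(self, transfac_text):
        pwms = parse_transfac(transfac_text)
        assert [p.matrix_id for p in pwms] == ["I$TEST_01", "I$TEST_02"]
        assert [len(p) for p in pwms] == [6, 5]
        assert [p.tf_name for p in pwms] == ["testA", "testB"]

    def test_count_row_layout(self, transfac_text):
        # row "01 0 0 9 1 G" means counts (A,C,G,T) = (0,0,9,1) at position 0
        pwm = parse_transfac(transfac_text)[0]
        assert pwm.counts[0].tolist() == [0.0, 0.0, 9.0, 1.0]
        assert pwm.counts[1].tolist() == [9.0, 1.0, 0.0, 0.0]

    def test_po_header_dialect(self, transfac_text):
        # the second block uses the "PO" spelling of the header row
        assert "PO " in transfac_text
        assert len(parse_transfac(transfac_text)) == 2

    def test_round_trip(self):
        rng = np.random.default_rng(0)
        pwms = [random_pwm(f"m{i}", int(rng.integers(4, 15)), seed=i) for i in range(5)]
        back = parse_transfac(write_transfac(pwms))
        for orig, rt in zip(pwms, back):
            assert rt.matrix_id == orig.matrix_id
            np.testing.assert_allclose(rt.counts, orig.counts, atol=1e-9)

    def test_malformed_input_raises(self):
        with pytest.raises(TransfacParseError):
            parse_transfac("not a transfac file\n")


class TestPwmScoring:
    def test_hand_computed_log_odds(self):
        # column (9,0,0,0), uniform background, pseudocount 1:
        # p_A = 9.25/10, score_A = log2(0.925/0.25) = log2(3.7)
        pwm = PWM("m", np.array([[9.0, 0, 0, 0], [1, 1, 1, 1]]))
        lo = pwm.log_odds()
        assert lo[0, 0] == pytest.approx(np.log2(3.7), abs=1e-12)
        assert lo[0, 1] == pytest.approx(np.log2((0.25 / 10) / 0.25), abs=1e-12)
        # uniform column scores 0 for every base
        np.testing.assert_allclose(lo[1], 0.0, atol=1e-12)

    def test_normalization_identity(self):
        # sum_b 2^score[b] * bg[b] = 1 at every position, for any matrix
        for i in range(5):
            pwm = random_pwm(f"m{i}", 8, seed=i, concentration=0.5)
            bg = np.asarray(pwm.background)
            np.testing.assert_allclose((2.0 ** pwm.log_odds() * bg).sum(axis=1),
                                       1.0, atol=1e-9)

    def test_score_bounds(self):
        pwm = random_pwm("m", 9, seed=3)
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), 400))
        hits = scan(seq, pwm, pwm.min_score)
        assert hits, "min-score threshold must report every window"
        for h in hits:
            assert pwm.min_score - 1e-9 <= h.score <= pwm.max_score + 1e-9


class TestScan:
    def test_consensus_found_at_planted_offset(self, consensus_pwm):
        seq = "T" * 7 + consensus_pwm.consensus() + "T" * 10
        hits = scan(seq, consensus_pwm, consensus_pwm.max_score - 1e-9)
        assert [(h.offset, h.strand) for h in hits] == [(7, "+")]
        assert hits[0].score == pytest.approx(consensus_pwm.max_score)

    def test_palindrome_pairs_hits_on_both_strands(self, palindrome_pwm):
        seq = "T" * 5 + palindrome_pwm.consensus() + "A" * 5
        hits = scan(seq, palindrome_pwm, palindrome_pwm.max_score - 1e-9)
        assert [(h.offset, h.strand) for h in hits] == [(5, "+"), (5, "-")]

    def test_short_promoter_yields_empty(self, consensus_pwm):
        assert scan("ACG", consensus_pwm, 0.0) == []

    def test_n_windows_never_hit(self, consensus_pwm):
        seq = "T" * 4 + consensus_pwm.consensus() + "T" * 4
        seq = seq[:6] + "N" + seq[7:]  # N lands inside the planted site
        assert scan(seq, consensus_pwm, consensus_pwm.max_score - 1e-9) == []
        # even at the loosest threshold, no reported window overlaps the N
        for h in scan(seq, consensus_pwm, consensus_pwm.min_score):
            assert not (h.offset <= 6 < h.offset + len(consensus_pwm))

    def test_matches_bruteforce_on_random_inputs(self):
        rng = np.random.default_rng(11)
        for i in range(20):
            pwm = random_pwm(f"m{i}", int(rng.integers(4, 13)), seed=100 + i)
            seq = "".join(rng.choice(list("ACGTN"), 150, p=[0.24] * 4 + [0.04]))
            thr = pwm.min_score + 0.6 * (pwm.max_score - pwm.min_score)
            got = [(h.offset, h.strand, h.score) for h in scan(seq, pwm, thr)]
            exp = oracles.brute_force_scan(seq, pwm.log_odds(), thr)
            assert [(o, s) for o, s, _ in got] == [(o, s) for o, s, _ in exp]
            np.testing.assert_allclose([s for *_, s in got], [s for *_, s in exp],
                                       atol=1e-9)

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(hst.integers(0, 2**31 - 1))
    def test_reverse_complement_equivariance(self, seed):
        """Scanning the reverse complement mirrors offsets and swaps strands."""
        rng = np.random.default_rng(seed)
        pwm = random_pwm("m", 7, seed=seed % 997)
        seq = "".join(rng.choice(list("ACGT"), 80))
        thr = pwm.min_score + 0.5 * (pwm.max_score - pwm.min_score)
        fwd = scan(seq, pwm, thr)
        rev = scan(oracles.revcomp(seq), pwm, thr)
        mirrored = sorted((len(seq) - len(pwm) - h.offset,
                           "-" if h.strand == "+" else "+",
                           round(h.score, 9)) for h in fwd)
        assert mirrored == sorted((h.offset, h.strand, round(h.score, 9))
                                  for h in rev)


class TestCollapse:
    def test_overlapping_hits_keep_best_score(self, consensus_pwm):
        hits = scan("AA" + consensus_pwm.consensus() + "AA", consensus_pwm,
                    consensus_pwm.min_score)
        plus = [h for h in hits if h.strand == "+"]
        kept = collapse_hits(plus, len(consensus_pwm))
        best = max(plus, key=lambda h: h.score)
        assert best in kept
        for i, a in enumerate(kept):
            for b in kept[i + 1:]:
                if a.strand == b.strand:
                    assert (a.offset + len(consensus_pwm) <= b.offset
                            or b.offset + len(consensus_pwm) <= a.offset)


@pytest.fixture(scope="module")
def calibration_set():
    return gen_background_promoters(200, 400, seed=5).sequences


class TestCalibration:
    def test_infinite_cap_returns_min_observed(self, calibration_set):
        pwm = random_pwm("m", 8, seed=1)
        cal = calibrate_threshold(pwm, calibration_set, np.inf)
        assert cal.threshold >= pwm.min_score - 1e-9
        # every window passes at that threshold
        n_hits = sum(len(scan(s, pwm, cal.threshold)) for s in calibration_set[:20])
        assert n_hits == 20 * 2 * (400 - 8 + 1)

    def test_cap_respected_and_tight(self, calibration_set):
        pwm = random_pwm("m", 8, seed=2)
        cap = 1.0 / 2000.0
        cal = calibrate_threshold(pwm, calibration_set, cap)
        total_bp = sum(len(s) for s in calibration_set)
        n_hits = sum(len(scan(s, pwm, cal.threshold)) for s in calibration_set)
        assert n_hits <= int(cap * total_bp)
        assert cal.achieved_frequency == pytest.approx(n_hits / total_bp)
        assert cal.achieved_frequency <= cap

    def test_halving_cap_never_lowers_threshold(self, calibration_set):
        for i in range(6):
            pwm = random_pwm(f"m{i}", 8, seed=40 + i)
            cap = 1.0 / 1000.0
            t1 = calibrate_threshold(pwm, calibration_set, cap).threshold
            t2 = calibrate_threshold(pwm, calibration_set, cap / 2).threshold
            assert t2 >= t1

    def test_tiny_calibration_set_rejected(self):
        pwm = random_pwm("m", 8, seed=1)
        with pytest.raises(ValueError, match="too small"):
            calibrate_threshold(pwm, ["ACGT" * 100], 1.0 / 2000.0)
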