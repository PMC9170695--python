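import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from chromdyn.intervals import SignalTrack
from chromdyn.motif import (
    FootprintProfile,
    PWM,
    candidate_regulators,
    footprint_depth,
    footprint_profile,
    lift_occurrences,
    motif_enrichment,
    pwm_from_counts,
    read_jaspar,
    reverse_complement,
    scan_pwm,
    write_jaspar,
)


class TestPwmConstruction:
    def test_pseudocount_formula(self):
        counts = np.array([[8.0], [0.0], [0.0], [0.0]])
        pwm = pwm_from_counts("X", counts)
        assert pwm.probs[0, 0] == pytest.approx(9 / 12)
        assert pwm.log_odds[0, 0] == pytest.approx(math.log2(3))
        np.testing.assert_allclose(pwm.probs.sum(axis=0), 1.0, atol=1e-12)

    def test_uniform_counts_zero_log_odds(self):
        pwm = pwm_from_counts("X", np.full((4, 5), 10.0))
        np.testing.assert_allclose(pwm.log_odds, 0.0, atol=1e-12)

    def test_jaspar_roundtrip(self, tmp_path):
        counts = {"TF1": np.arange(40).reshape(4, 10), "TF2": np.full((4, 6), 3)}
        p = tmp_path / "m.jaspar"
        write_jaspar(counts, p)
        pwms = read_jaspar(p)
        assert [m.name for m in pwms] == ["TF1", "TF2"]
        expected = pwm_from_counts("TF1", counts["TF1"])
        np.testing.assert_allclose(pwms[0].probs, expected.probs)


def _brute_force_scan(seq, pwm, threshold_fraction=0.8):
    """Independent window-by-window scoring oracle."""
    hits = set()
    thr = threshold_fraction * pwm.max_score
    for strand in "+-":
        s = seq if strand == "+" else reverse_complement(seq)
        for off in range(len(s) - pwm.width + 1):
            score = 0.0
            for j, base in enumerate(s[off : off + pwm.width]):
                if base in "ACGT":
                    score += pwm.log_odds["ACGT".index(base), j]
            if score >= thr:
                fwd_off = off if strand == "+" else len(seq) - off - pwm.width
                hits.add((fwd_off, strand, round(score, 9)))
    return hits


class TestScan:
    pwm = pwm_from_counts(
        "T", np.array([[9, 0, 0, 0], [0, 9, 0, 0], [0, 0, 9, 0], [0, 0, 0, 9]]).T * 1.0
    )  # consensus derived from the count layout

    def test_consensus_reports_max_score(self):
        pwm = pwm_from_counts("T", np.array([[90, 0, 0, 0]] * 6).T * 1.0)
        hits = scan_pwm({"p": pwm.consensus}, pwm)
        row = hits[(hits["strand"] == "+")].iloc[0]
        assert row["offset"] == 0 and row["score"] == pytest.approx(pwm.max_score)

    def test_reverse_complement_of_consensus_on_minus(self):
        counts = np.zeros((4, 5))
        counts[[0, 1, 2, 3, 0], range(5)] = 50  # consensus ACGTA
        pwm = pwm_from_counts("T", counts)
        seq = "TT" + reverse_complement(pwm.consensus) + "GG"
        hits = scan_pwm({"p": seq}, pwm)
        minus = hits[hits["strand"] == "-"]
        assert minus["offset"].tolist() == [2]
        assert minus["score"].iloc[0] == pytest.approx(pwm.max_score)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 20, size=(4, 6)).astype(float) + 1
        pwm = pwm_from_counts("T", counts)
        seq = "".join(rng.choice(list("ACGTN"), 30))
        hits = scan_pwm({"p": seq}, pwm, threshold_fraction=0.3)
        got = {
            (o, s, round(sc, 9))
            for o, s, sc in zip(hits["offset"], hits["strand"], hits["score"])
        }
        assert got == _brute_force_scan(seq, pwm, 0.3)

    def test_invariant_under_global_reverse_complement(self):
        rng = np.random.default_rng(7)
        counts = rng.integers(0, 30, size=(4, 8)).astype(float)
        pwm = pwm_from_counts("T", counts + 1)
        seqs = {"a": "".join(rng.choice(list("ACGT"), 60))}
        fwd = scan_pwm(seqs, pwm, 0.4)
        rc = scan_pwm({"a": reverse_complement(seqs["a"])}, pwm, 0.4)
        flip = {"+": "-", "-": "+"}
        expect = {
            (60 - o - pwm.width, flip[s], round(sc, 9))
            for o, s, sc in zip(fwd["offset"], fwd["strand"], fwd["score"])
        }
        got = {
            (o, s, round(sc, 9))
            for o, s, sc in zip(rc["offset"], rc["strand"], rc["score"])
        }
        assert got == expect

    def test_short_sequence_skipped_with_warning(self):
        pwm = pwm_from_counts("T", np.full((4, 8), 5.0))
        with pytest.warns(UserWarning, match="shorter"):
            hits = scan_pwm({"tiny": "ACG"}, pwm)
        assert len(hits) == 0


def _occurrences(tf_hits):
    rows = [(tf, pid, 0, "+", 1.0) for tf, ids in tf_hits.items() for pid in ids]
    return pd.DataFrame(rows, columns=["tf", "peak_id", "offset", "strand", "score"])


class TestEnrichment:
    def test_p_matches_fisher_exact(self):
        fg = [f"f{i}" for i in range(100)]
        bg = [f"b{i}" for i in range(900)]
        occ = _occurrences({"T": fg[:10] + bg[:5]})
        res = motif_enrichment(occ, fg, bg)
        table = [[10, 90], [5, 895]]
        _, p_ref = stats.fisher_exact(table, alternative="greater")
        assert res.loc[0, "p"] == pytest.approx(p_ref, abs=1e-12)
        assert res.loc[0, "fg_prop"] == pytest.approx(0.10)

    def test_null_case(self):
        fg = [f"f{i}" for i in range(100)]
        bg = [f"b{i}" for i in range(900)]
        occ = _occurrences({"T": fg[:10] + bg[:90]})
        res = motif_enrichment(occ, fg, bg)
        assert res.loc[0, "odds_ratio"] == pytest.approx(1.0)
        assert res.loc[0, "p"] >= 0.5

    def test_input_validation(self):
        occ = _occurrences({"T": ["a"]})
        with pytest.raises(ValueError, match="foreground"):
            motif_enrichment(occ, [], ["b"])
        with pytest.raises(ValueError, match="overlap"):
            motif_enrichment(occ, ["a"], ["a", "b"])


class TestCandidates:
    def test_intersection(self):
        enr = {
            "II": pd.DataFrame({"tf": ["RUNX1", "SOX17"], "q": [0.01, 0.2]}),
            "III": pd.DataFrame({"tf": ["GATA2", "JUNB"], "q": [0.001, 0.04]}),
        }
        out = candidate_regulators(enr, {"JUNB", "GATA2", "MYB", "RUNX1"})
        assert out["tf"].tolist() == ["GATA2", "RUNX1", "JUNB"]  # by best q

    def test_empty_enrichment(self):
        out = candidate_regulators({}, {"JUNB"})
        assert len(out) == 0


class TestFootprint:
    def _track(self, values):
        return SignalTrack({"chr1": np.asarray(values, dtype=float)}, 1)

    def _occ(self, start, strand="+"):
        return pd.DataFrame({"chrom": ["chr1"], "start": [start], "strand": [strand]})

    def test_flat_signal_depth_zero(self):
        track = self._track(np.full(400, 2.0))
        prof = footprint_profile(track, self._occ(150), width=10, radius=50)
        np.testing.assert_allclose(prof.values, 2.0)
        assert footprint_depth(prof) == 0.0

    def test_single_occurrence_is_window_verbatim(self):
        vec = np.arange(400, dtype=float)
        prof = footprint_profile(self._track(vec), self._occ(150), width=10, radius=50)
        np.testing.assert_allclose(prof.values, vec[100:210])

    def test_minus_strand_reverses_window(self):
        vec = np.arange(400, dtype=float)
        plus = footprint_profile(self._track(vec), self._occ(150, "+"), width=10, radius=50)
        minus = footprint_profile(self._track(vec), self._occ(150, "-"), width=10, radius=50)
        np.testing.assert_allclose(minus.values, plus.values[::-1])

    def test_half_core_gives_half_depth(self):
        vec = np.full(400, 4.0)
        vec[150:160] = 2.0  # core at half the flank level
        prof = footprint_profile(self._track(vec), self._occ(150), width=10, radius=100)
        assert footprint_depth(prof) == pytest.approx(0.5)

    def test_out_of_bounds_site_skipped(self):
        track = self._track(np.ones(100))
        prof = footprint_profile(track, self._occ(5), width=10, radius=50)
        assert prof.n_sites == 0 and prof.n_skipped == 1
        assert np.isnan(prof.values).all()

    def test_lift_occurrences(self):
        occ = pd.DataFrame(
            {"tf": ["T"], "peak_id": ["chr2:1000-1500"], "offset": [120], "strand": ["+"]}
        )
        lifted = lift_occurrences(occ, width=8)
        assert lifted.loc[0, "chrom"] == "chr2"
        assert (lifted.loc[0, "start"], lifted.loc[0, "end"]) == (1120, 1128)
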