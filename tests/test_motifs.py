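import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from coregscan.motifs import (
    IUPACMotif,
    PositionWeightMatrix,
    build_pwm,
    iupac_reverse_complement,
    read_pwm_library,
    scan_iupac,
    scan_pwm,
    score_window,
    write_pwm_library,
)
from coregscan.seqio import SequenceRecord, reverse_complement


class TestConservation:
    @pytest.mark.parametrize("freqs, expected", [
        ((0.25, 0.25, 0.25, 0.25), 0.0),       # uniform position
        ((1.0, 0.0, 0.0, 0.0), 100.0),          # single base
        ((0.5, 0.5, 0.0, 0.0), 50.0),           # (100/ln4)(ln4 - ln2)
    ])
    def test_ci_values(self, freqs, expected):
        pwm = PositionWeightMatrix("X", np.array([freqs]))
        assert pwm.ci[0] == pytest.approx(expected, abs=1e-9)

    def test_core_is_most_conserved_window_leftmost_on_ties(self):
        sites = ["AACGTA", "ATCGTA", "AACGTT", "AGCGTA"]
        pwm = build_pwm(sites=sites, pseudocount=0.0, core_length=4)
        # positions 2-5 (CGTA-ish) carry the most information? compute directly
        k = 4
        sums = [pwm.ci[s:s + k].sum() for s in range(len(pwm) - k + 1)]
        assert pwm.core[0] == int(np.argmax(sums))

    def test_pseudocount_frequencies(self):
        pwm = build_pwm(sites=["A", "A"], pseudocount=1.0)
        assert pwm.f[0] == pytest.approx([3 / 6, 1 / 6, 1 / 6, 1 / 6])

    def test_ragged_sites_error(self):
        with pytest.raises(ValueError):
            build_pwm(sites=["ACG", "AC"])

    def test_all_zero_column_needs_pseudocount(self):
        counts = np.array([[0, 0, 0, 0], [1, 0, 0, 0]])
        with pytest.raises(ValueError):
            build_pwm(counts=counts)
        pwm = build_pwm(counts=counts, pseudocount=0.5)
        assert pwm.f[0] == pytest.approx([0.25] * 4)


class TestScoreWindow:
    def test_consensus_scores_one_both_parts(self, simple_pwm):
        for part in ("matrix", "core"):
            assert score_window(simple_pwm, simple_pwm.consensus, part) == pytest.approx(1.0)

    def test_zero_information_position_cannot_penalize(self):
        f = np.array([[0.25] * 4, [0.9, 0.04, 0.03, 0.03], [0.9, 0.04, 0.03, 0.03],
                      [0.9, 0.04, 0.03, 0.03], [0.9, 0.04, 0.03, 0.03]])
        pwm = PositionWeightMatrix("X", f)
        # differ from consensus only at position 0, where Ci = 0
        assert score_window(pwm, "GAAAA") == pytest.approx(score_window(pwm, "AAAAA"))
        assert score_window(pwm, "GAAAA") == pytest.approx(1.0)

    def test_hand_evaluated_two_position_example(self):
        """Ci = (100, 50), consensus frequencies (0.9, 0.8); a window hitting
        the consensus at position 1 and an f = 0.2 base at position 2 scores
        (100*0.9 + 50*0.2) / (100*0.9 + 50*0.8) = 0.769."""
        pwm = PositionWeightMatrix(
            "X",
            np.array([[0.9, 0.05, 0.03, 0.02], [0.8, 0.2, 0.0, 0.0]]),
            ci=[100.0, 50.0],
            core_length=2,
        )
        got = score_window(pwm, "AC")  # consensus A, then the f=0.2 base C
        expected = (100 * 0.9 + 50 * 0.2) / (100 * 0.9 + 50 * 0.8)
        assert got == pytest.approx(expected)
        assert got == pytest.approx(0.769, abs=5e-4)

    def test_length_mismatch_error(self, simple_pwm):
        with pytest.raises(ValueError):
            score_window(simple_pwm, "ACG")

    def test_n_scores_zero_at_position(self, simple_pwm):
        full = score_window(simple_pwm, simple_pwm.consensus)
        with_n = score_window(simple_pwm, "N" + simple_pwm.consensus[1:])
        assert with_n < full


class TestScanPWM:
    def test_planted_consensus_found_once(self, simple_pwm, rng):
        bg = "ATATATAGAGAGATTATA"
        seq = SequenceRecord("s", bg + simple_pwm.consensus + bg)
        hits = scan_pwm(seq, simple_pwm)
        assert len(hits) == 1
        h = hits[0]
        assert (h.start, h.strand) == (len(bg), "+")
        assert h.core_similarity == pytest.approx(1.0)
        assert h.matrix_similarity == pytest.approx(1.0)

    def test_strand_involution(self, simple_pwm):
        bg = "ATATATAGAGAGATTATA"
        seq = SequenceRecord("s", bg + simple_pwm.consensus + bg)
        rc = SequenceRecord("s", reverse_complement(seq.residues))
        fwd = scan_pwm(seq, simple_pwm)
        rev = scan_pwm(rc, simple_pwm)
        L = len(seq.residues)
        mapped = sorted(
            (L - h.end, L - h.start, {"+": "-", "-": "+"}[h.strand],
             round(h.core_similarity, 9), round(h.matrix_similarity, 9))
            for h in rev
        )
        orig = sorted(
            (h.start, h.end, h.strand,
             round(h.core_similarity, 9), round(h.matrix_similarity, 9))
            for h in fwd
        )
        assert mapped == orig

    def test_equals_brute_force_oracle(self, simple_pwm, rng):
        for _ in range(10):
            seq = SequenceRecord("s", "".join(rng.choice(list("ACGT"), size=120)))
            got = scan_pwm(seq, simple_pwm, 0.6, 0.7)
            expected = _brute_force_scan(seq, simple_pwm, 0.6, 0.7)
            assert [(h.start, h.strand) for h in got] == expected

    def test_threshold_monotonicity(self, simple_pwm, rng):
        seq = SequenceRecord("s", "".join(rng.choice(list("ACGT"), size=300)))
        loose = {(h.start, h.strand) for h in scan_pwm(seq, simple_pwm, 0.5, 0.5)}
        tight = {(h.start, h.strand) for h in scan_pwm(seq, simple_pwm, 0.8, 0.9)}
        assert tight <= loose


class TestIUPAC:
    def test_grbox_planted(self):
        seq = SequenceRecord("s", "GGGGGGG" + "CATTGTT" + "AAAA")
        hits = scan_iupac(seq, IUPACMotif("GRBOX", "CATTGTT", 0))
        plus = [h for h in hits if h.strand == "+"]
        assert [(h.start, h.motif) for h in plus] == [(7, "GRBOX")]

    def test_degenerate_symbols(self):
        assert scan_iupac(SequenceRecord("s", "GAT"), IUPACMotif("m", "RAT"))
        assert scan_iupac(SequenceRecord("s", "AAT"), IUPACMotif("m", "RAT"))
        assert not [h for h in scan_iupac(SequenceRecord("s", "CAT"),
                                          IUPACMotif("m", "RAT")) if h.strand == "+"]

    def test_minus_strand_hit(self):
        # TTATA is the reverse complement of TATAA
        hits = scan_iupac(SequenceRecord("s", "CCGTTATACCG"), IUPACMotif("m", "TATAA"))
        assert [(h.start, h.strand) for h in hits] == [(3, "-")]

    def test_mismatch_allowance(self):
        m = IUPACMotif("m", "AAAAA", 1)
        hits = [h for h in scan_iupac(SequenceRecord("s", "AATAA"), m) if h.strand == "+"]
        assert len(hits) == 1
        assert hits[0].matrix_similarity == pytest.approx(4 / 5)

    def test_n_in_sequence_never_matches_non_n_symbol(self):
        assert not [h for h in scan_iupac(SequenceRecord("s", "ANT"), IUPACMotif("m", "AAT"))
                    if h.strand == "+"]
        assert [h for h in scan_iupac(SequenceRecord("s", "ANT"), IUPACMotif("m", "ANT"))
                if h.strand == "+"]

    def test_illegal_symbol_rejected_at_construction(self):
        with pytest.raises(ValueError):
            IUPACMotif("m", "ACGU")

    @given(st.text(alphabet="ACGTRYSWKMBDHVN", min_size=1, max_size=12))
    @settings(max_examples=50, deadline=None)
    def test_reverse_complement_involution(self, pattern):
        assert iupac_reverse_complement(iupac_reverse_complement(pattern)) == pattern


def test_family_from_name():
    assert PositionWeightMatrix("V$MZF1.01", np.array([[1, 0, 0, 0.0]])).family == "V$MZF1"
    assert PositionWeightMatrix("OXBOX", np.array([[1, 0, 0, 0.0]])).family == "OXBOX"


def test_pwm_library_round_trip(tmp_path, simple_pwm):
    path = str(tmp_path / "lib.tsv")
    write_pwm_library([simple_pwm], path)
    lib = read_pwm_library(path)
    assert set(lib) == {"V$MZF1.01"}
    assert np.allclose(lib["V$MZF1.01"].f, simple_pwm.f, atol=1e-6)
    assert lib["V$MZF1.01"].family == "V$MZF1"


def _brute_force_scan(seq, pwm, core_th, mat_th):
    """Independent oracle: score every window on both strands separately."""
    out = []
    L = len(pwm)
    for off in range(len(seq.residues) - L + 1):
        window = seq.residues[off:off + L]
        for strand in "+-":
            w = window if strand == "+" else reverse_complement(window)
            if score_window(pwm, w, "core") >= core_th and \
               score_window(pwm, w, "matrix") >= mat_th:
                out.append((off, strand))
    return out
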