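import io
import itertools

import pytest

from coregscan.fixtures import example_model, make_promoter_set
from coregscan.models import (
    ModelElement,
    RegulatoryModel,
    conserved_across_species,
    read_models,
    scan_model,
    screen_promoter_set,
    write_models,
)
from coregscan.motifs import IUPACMotif, scan_iupac, scan_pwm
from coregscan.seqio import SequenceRecord, reverse_complement

BG = "ATATAGAGATATAGAGATAT"


def _planted_sequence(model, gaps):
    """Background + element sites in order with inert spacers (no spurious
    motif matches) + background."""
    filler = "ACTGA" * 100
    parts = []
    for i, el in enumerate(model.elements):
        site = el.motif.consensus if el.kind == "pwm" else el.motif.pattern
        parts.append(site)
        if i < len(gaps):
            parts.append(filler[:gaps[i]])
    insert = "".join(parts)
    return BG + insert + BG, len(BG), len(insert)


class TestScanModel:
    def test_planted_four_element_chain_found(self, grbox_model):
        seq_str, off, span = _planted_sequence(grbox_model, [10, 5, 20])
        hits = scan_model(SequenceRecord("s", seq_str), grbox_model)
        full = [h for h in hits if h.orientation == "+"]
        assert len(full) == 1
        h = full[0]
        assert (h.start, h.end, h.matched_count) == (off, off + span, 4)
        assert [e.motif for e in h.element_hits] == \
               [el.name for el in grbox_model.elements]

    def test_missing_element_kills_hit_at_full_quorum(self, grbox_model):
        seq_str, _, _ = _planted_sequence(grbox_model, [10, 5, 20])
        # remove the MZF1 site (TCCCC realization) by mutating it away
        broken = seq_str.replace("TCCCC", "TAAGC", 1)
        assert not scan_model(SequenceRecord("s", broken), grbox_model)

    def test_permuted_order_gives_no_hit(self, grbox_model):
        permuted = RegulatoryModel(
            "perm",
            [grbox_model.elements[i] for i in (1, 0, 2, 3)],
            grbox_model.gaps,
        )
        seq_str, _, _ = _planted_sequence(grbox_model, [10, 5, 20])
        assert not scan_model(SequenceRecord("s", seq_str), permuted)

    def test_minus_orientation_reported_in_forward_coordinates(self, grbox_model):
        seq_str, off, span = _planted_sequence(grbox_model, [10, 5, 20])
        rc = reverse_complement(seq_str)
        hits = scan_model(SequenceRecord("s", rc), grbox_model)
        assert len(hits) == 1
        h = hits[0]
        assert h.orientation == "-"
        assert (h.start, h.end) == (len(rc) - off - span, len(rc) - off)
        assert h.check(grbox_model)

    def test_single_element_degenerates_to_motif_scan(self, simple_pwm, rng):
        model = RegulatoryModel("one", [ModelElement(simple_pwm.name, simple_pwm)], [])
        seq = SequenceRecord("s", "".join(rng.choice(list("ACGT"), size=200)))
        got = {(h.start, h.end, h.orientation) for h in scan_model(seq, model)}
        expected = {(h.start, h.end, h.strand)
                    for h in scan_pwm(seq, simple_pwm, 0.75, 0.80)}
        assert got == expected

    def test_gap_ranges_inclusive_at_both_ends(self):
        m = RegulatoryModel(
            "m",
            [ModelElement("a", IUPACMotif("a", "CATTA")),
             ModelElement("b", IUPACMotif("b", "GGCCG"))],
            [(3, 3)],
        )
        hit = scan_model(SequenceRecord("s", "CATTA" + "TTT" + "GGCCG"), m)
        assert [h.matched_count for h in hit if h.orientation == "+"] == [2]
        miss = scan_model(SequenceRecord("s", "CATTA" + "TTTT" + "GGCCG"), m)
        assert not [h for h in miss if h.orientation == "+"]

    def test_every_hit_passes_independent_recheck(self, grbox_model, rng):
        recs, _ = make_promoter_set(5, grbox_model, gap_jitter=2, seed=21)
        for rec in recs:
            for h in scan_model(rec, grbox_model):
                assert h.check(grbox_model)

    def test_equals_brute_force_oracle(self, rng):
        """Chaining equals exhaustive combination enumeration on short
        sequences with a 3-element model."""
        model = RegulatoryModel(
            "m3",
            [ModelElement("a", IUPACMotif("a", "CAT", 0)),
             ModelElement("b", IUPACMotif("b", "GGA", 0)),
             ModelElement("c", IUPACMotif("c", "TTC", 0))],
            [(0, 30), (0, 30)],
        )
        for _ in range(20):
            seq = SequenceRecord("s", "".join(rng.choice(list("ACGT"), size=150)))
            got = {
                (h.orientation, tuple((e.start, e.end) for e in h.element_hits))
                for h in scan_model(seq, model)
            }
            assert got == _brute_force_model_scan(seq, model)

    def test_monotonicity_in_gap_width_and_quorum(self, grbox_model):
        seq_str, _, _ = _planted_sequence(grbox_model, [10, 5, 20])
        seq = SequenceRecord("s", seq_str)
        base = len(scan_model(seq, grbox_model))
        wider = RegulatoryModel(
            grbox_model.name, grbox_model.elements,
            [(max(a - 5, 0), b + 5) for a, b in grbox_model.gaps],
        )
        assert len(scan_model(seq, wider)) >= base
        relaxed = RegulatoryModel(
            grbox_model.name, grbox_model.elements, grbox_model.gaps, quorum_k=3)
        assert len(scan_model(seq, relaxed)) >= base

    def test_relaxed_quorum_matches_with_one_element_absent(self, grbox_model):
        seq_str, _, _ = _planted_sequence(grbox_model, [10, 5, 20])
        broken = seq_str.replace("TCCCC", "TAAGC", 1)
        relaxed = RegulatoryModel(
            grbox_model.name, grbox_model.elements, grbox_model.gaps, quorum_k=3)
        hits = [h for h in scan_model(SequenceRecord("s", broken), relaxed)
                if h.orientation == "+"]
        assert hits and max(h.matched_count for h in hits) == 3

    def test_unresolved_element_error_names_it(self, grbox_model):
        model = RegulatoryModel("m", [ModelElement("V$GHOST.01"),
                                      ModelElement("TATA", IUPACMotif("TATA", "TATAA"))],
                                [(0, 10)])
        with pytest.raises(KeyError, match="GHOST"):
            scan_model(SequenceRecord("s", "ACGTACGTACGT"), model)


class TestScreening:
    def test_planted_subset_summary(self, grbox_model):
        planted, _ = make_promoter_set(3, grbox_model, gap_jitter=1, length=500, seed=4)
        empty, _ = make_promoter_set(7, grbox_model, plant_fraction=0.0,
                                     length=500, seed=5)
        empty = [SequenceRecord(f"bg_{r.id}", r.residues) for r in empty]
        summary = screen_promoter_set(planted + empty, grbox_model)
        with_hits = {sid for sid, hits in summary.per_sequence.items() if hits}
        assert with_hits == {r.id for r in planted}
        assert (summary.n_with_hit, summary.n_total) == (3, 10)

    def test_empty_set(self, grbox_model):
        summary = screen_promoter_set([], grbox_model)
        assert (summary.n_with_hit, summary.n_total) == (0, 0)

    def test_model_planted_twice_gives_two_hits(self, grbox_model):
        seq_str, _, span = _planted_sequence(grbox_model, [10, 5, 20])
        double = seq_str + seq_str
        summary = screen_promoter_set([SequenceRecord("s", double)], grbox_model)
        plus = [h for h in summary.per_sequence["s"] if h.orientation == "+"]
        assert len(plus) == 2


class TestConservation:
    def _sets(self, grbox_model, present, absent):
        sets = {}
        for i in range(present):
            recs, _ = make_promoter_set(1, grbox_model, gap_jitter=1,
                                        length=400, seed=100 + i)
            sets[f"species_{i}"] = recs
        for i in range(absent):
            recs, _ = make_promoter_set(1, grbox_model, plant_fraction=0.0,
                                        length=400, seed=200 + i)
            sets[f"species_absent_{i}"] = recs
        return sets

    def test_pass_at_threshold(self, grbox_model):
        sets = self._sets(grbox_model, present=5, absent=1)
        rep = conserved_across_species(grbox_model, sets, min_species=5)
        assert rep.passed
        assert len(rep.present_species) >= 5

    def test_single_species_suffices_at_min_one(self, grbox_model):
        sets = self._sets(grbox_model, present=1, absent=0)
        assert conserved_across_species(grbox_model, sets, 1).passed

    def test_unsatisfiable_threshold_warns(self, grbox_model):
        sets = self._sets(grbox_model, present=1, absent=0)
        rep = conserved_across_species(grbox_model, sets, 5)
        assert not rep.passed
        assert any("never pass" in w for w in rep.warnings)

    def test_empty_species_counts_absent_with_warning(self, grbox_model):
        sets = self._sets(grbox_model, present=1, absent=0)
        sets["empty_species"] = []
        rep = conserved_across_species(grbox_model, sets, 1)
        assert rep.per_species["empty_species"] is False
        assert any("empty" in w for w in rep.warnings)


def test_model_file_round_trip(tmp_path, grbox_model, simple_pwm):
    path = str(tmp_path / "models.txt")
    write_models([grbox_model], path)
    [back] = read_models(path, {"V$MZF1.01": simple_pwm,
                                "V$EGR1.02": grbox_model.elements[2].motif})
    assert back.name == grbox_model.name
    assert [el.name for el in back.elements] == [el.name for el in grbox_model.elements]
    assert back.gaps == grbox_model.gaps
    assert back.elements[0].motif.pattern == "CATTGTT"


def _brute_force_model_scan(seq, model):
    """Oracle: enumerate every combination of independent element hits and
    keep those in order with legal gaps, per orientation."""
    out = set()
    for orientation in "+-":
        view = seq if orientation == "+" else SequenceRecord(
            seq.id, reverse_complement(seq.residues))
        per_el = [scan_iupac(view, el.motif, strands="forward")
                  for el in model.elements]
        for combo in itertools.product(*per_el):
            ok = True
            for (h1, h2), (dmin, dmax) in zip(zip(combo, combo[1:]), model.gaps):
                gap = h2.start - h1.end
                if not dmin <= gap <= dmax:
                    ok = False
                    break
            if not ok:
                continue
            if orientation == "+":
                coords = tuple((h.start, h.end) for h in combo)
            else:
                L = len(seq.residues)
                coords = tuple((L - h.end, L - h.start) for h in combo)
            out.add((orientation, coords))
    return out
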