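"""Triplet codes: parsing, extraction, reconstruction, decomposition, slides."""

import numpy as np
import pytest

from iminoshift.triplet import (
    CENTRAL_PAIRS,
    AFormRCProvider,
    DecomposedTable,
    IminoShift,
    TableRCProvider,
    TripletCode,
    decompose_lookup,
    enumerate_register_slides,
    enumerate_triplet_codes,
    extract_triplets,
    parse_secondary_structure,
    predict_hybrid,
    predict_imino_shifts,
    read_lookup_tsv,
    reconstruct_lookup,
    register_shift_delta,
    write_lookup_tsv,
)
from iminoshift.structure import WC_PAIRS


class TestParse:
    def test_simple_hairpin(self):
        pairs = parse_secondary_structure("GGGAAACCC", "(((...)))")
        assert [(p.i, p.j, p.kind) for p in pairs] == \
            [(1, 9, "WC"), (2, 8, "WC"), (3, 7, "WC")]

    def test_wobble_classification(self):
        pairs = parse_secondary_structure("GUGAAACGC", "(((...)))")
        assert pairs[1].kind == "wobble"
        assert pairs[1].i == 2 and pairs[1].j == 8

    def test_noncanonical_flagged(self):
        pairs = parse_secondary_structure("AGGAAACCA", "(((...)))")
        assert pairs[0].kind == "noncanonical"  # A.A

    def test_pseudoknot_layers(self):
        pairs = parse_secondary_structure("GCAGAGCAUC", "((.[..)).]")
        idx = {(p.i, p.j) for p in pairs}
        assert idx == {(1, 8), (2, 7), (4, 10)}

    def test_errors(self):
        with pytest.raises(ValueError, match="length"):
            parse_secondary_structure("GGC", "((..")
        with pytest.raises(ValueError, match="unbalanced"):
            parse_secondary_structure("GGCC", "(())" .replace("(", ")", 1))
        with pytest.raises(ValueError, match="unbalanced"):
            parse_secondary_structure("GGCC", "((.)")


class TestExtract:
    def test_stem_interior_only(self):
        """Interior paired G/U yield codes; terminal pairs never do."""
        seq = "GGUGGAAAACUACC"
        ss = "(((((....)))))"
        pairs = parse_secondary_structure(seq, ss)
        triplets, report = extract_triplets(pairs, seq)
        positions = [i for i, _ in triplets]
        # 1 and 5 are boundary-excluded; 11 is the U of the G4.U11 wobble
        assert positions == [2, 3, 4, 11]
        codes = dict(triplets)
        assert codes[3] == TripletCode("GC", "UA", "GU")
        assert codes[11] == TripletCode("CG", "UG", "AU")

    def test_reference_strand_orientation(self):
        """5' U.A neighbor and 3' G.U neighbor of a central G-C."""
        seq = "UGGAAAAUCA"
        ss = "(((....)))"
        pairs = parse_secondary_structure(seq, ss)
        triplets, _ = extract_triplets(pairs, seq)
        assert (2, TripletCode("UA", "GC", "GU")) in triplets

    def test_bulge_breaks_contiguity(self):
        seq = "GGAGGAAAACCCC"
        ss = "((.((....))))"
        pairs = parse_secondary_structure(seq, ss)
        triplets, report = extract_triplets(pairs, seq)
        assert triplets == []  # every candidate spans the bulge or a boundary
        assert {i for i, _ in report} >= {2, 4}

    def test_emitted_codes_are_enumerable(self):
        seq = "GGUGGAAAACCACC"
        ss = "(((((....)))))"
        triplets, _ = extract_triplets(parse_secondary_structure(seq, ss), seq)
        universe = set(enumerate_triplet_codes())
        assert all(code in universe for _, code in triplets)


class TestEnumeration:
    def test_count_and_uniqueness(self):
        codes = enumerate_triplet_codes()
        assert len(codes) == 144
        assert len(set(codes)) == 144

    def test_central_restriction(self):
        assert {c.central for c in enumerate_triplet_codes()} == set(CENTRAL_PAIRS)
        with pytest.raises(ValueError):
            TripletCode.make("GC", "CG", "AU")


class TestReconstruction:
    @pytest.mark.parametrize("code,n15,h1", [
        (("GC", "GC", "AU"), 147.49, 12.60),
        (("UA", "UG", "GU"), 159.09, 11.99),
    ])
    def test_printed_component_sums(self, decomposed, code, n15, h1):
        s = reconstruct_lookup(decomposed)[TripletCode(*code)]
        assert s.n15 == pytest.approx(n15, abs=1e-9)
        assert s.h1 == pytest.approx(h1, abs=1e-9)

    def test_zero_contributions_reduce_to_intrinsic(self, decomposed):
        zeros = {k: IminoShift(0.0, 0.0) for k in decomposed.five_prime}
        flat = DecomposedTable(decomposed.intrinsic, zeros, dict(zeros))
        lookup = reconstruct_lookup(flat)
        for code, s in lookup.items():
            assert s == decomposed.intrinsic[code.central]

    def test_linearity_in_table_entries(self, decomposed):
        """Doubling every component doubles every reconstructed shift."""
        doubled = DecomposedTable(
            {k: IminoShift(2 * v.n15, 2 * v.h1) for k, v in decomposed.intrinsic.items()},
            {k: IminoShift(2 * v.n15, 2 * v.h1) for k, v in decomposed.five_prime.items()},
            {k: IminoShift(2 * v.n15, 2 * v.h1) for k, v in decomposed.three_prime.items()})
        base = reconstruct_lookup(decomposed)
        twice = reconstruct_lookup(doubled)
        for code in base:
            assert twice[code].n15 == pytest.approx(2 * base[code].n15)

    def test_helical_sanity_bounds(self, lookup):
        for s in lookup.values():
            assert 140 <= s.n15 <= 170
            assert 9 <= s.h1 <= 16

    def test_dispersion_pattern(self, lookup):
        """G-central 1H shifts spread much more than UG-central ones."""
        h_gc = [s.h1 for c, s in lookup.items() if c.central == "GC"]
        h_ug = [s.h1 for c, s in lookup.items() if c.central == "UG"]
        assert np.var(h_gc) > np.var(h_ug)

    def test_tsv_round_trip(self, lookup, tmp_path):
        path = tmp_path / "table.tsv"
        write_lookup_tsv(lookup, path)
        back = read_lookup_tsv(path)
        assert set(back) == set(lookup)
        for code in lookup:
            assert back[code].n15 == pytest.approx(lookup[code].n15, abs=5e-3)


class TestPrediction:
    def test_stem_prediction_matches_table_sum(self):
        # central G with 5'GC and 3'AU context inside a hairpin stem
        seq = "CGGAGAAACUCCG"
        ss = "(((((...)))))"
        preds = predict_imino_shifts(seq, ss)
        by_index = {p.index: p for p in preds}
        p3 = by_index[3]
        assert str(p3.code) == "GC-GC-AU"
        assert p3.shift == IminoShift(147.49, 12.60)

    def test_noncanonical_context_reported(self):
        preds = predict_imino_shifts("GGGAAACCC", "(((...)))")
        notes = {p.index: p.note for p in preds if p.shift is None}
        assert 1 in notes and 3 in notes
        assert "not predictable" in notes[1]

    def test_strand_consistency_palindrome(self):
        """The same physical triplet read from either strand predicts equally."""
        stem = "GGCGCC"  # self-complementary
        seq = stem + "AAAA" + stem
        ss = "(" * 6 + "." * 4 + ")" * 6
        preds = {p.index: p for p in predict_imino_shifts(seq, ss)}
        # the duplex dyad maps residue i of the first strand onto residue
        # i+10 of the second; both read the same physical triplet
        for i in (2, 4):
            j = i + 10
            assert preds[i].shift is not None and preds[j].shift is not None
            assert preds[i].code == preds[j].code
            assert preds[i].shift == preds[j].shift

    def test_hybrid_degenerate_reduces_to_table_terms(self, decomposed):
        got = predict_hybrid("GC", "AU", "3p", IminoShift(0.0, 0.0), decomposed)
        expect = decomposed.intrinsic["GC"] + decomposed.three_prime[("AU", "GC")]
        assert got == IminoShift(*expect)


class TestDecomposition:
    def test_round_trip_with_identical_rc(self, decomposed, lookup):
        """decompose(reconstruct(T)) == T when the same RC values anchor both."""
        rt = decompose_lookup(lookup, TableRCProvider(decomposed))
        for c in CENTRAL_PAIRS:
            assert rt.intrinsic[c].n15 == pytest.approx(decomposed.intrinsic[c].n15,
                                                        abs=0.02)
            assert rt.intrinsic[c].h1 == pytest.approx(decomposed.intrinsic[c].h1,
                                                       abs=0.02)
        for store, ref in ((rt.five_prime, decomposed.five_prime),
                           (rt.three_prime, decomposed.three_prime)):
            for k, v in ref.items():
                assert store[k].n15 == pytest.approx(v.n15, abs=0.02)
                assert store[k].h1 == pytest.approx(v.h1, abs=0.02)

    def test_flat_lookup_gives_zero_contributions(self):
        const = {"GC": IminoShift(150.0, 14.0), "UA": IminoShift(164.0, 14.8),
                 "GU": IminoShift(146.0, 12.2), "UG": IminoShift(159.7, 12.3)}
        lookup = {c: const[c.central] for c in enumerate_triplet_codes()}
        zero_rc = lambda central, neighbor, direction: IminoShift(0.0, 0.0)
        dec = decompose_lookup(lookup, zero_rc)
        for store in (dec.five_prime, dec.three_prime):
            for v in store.values():
                assert v.n15 == pytest.approx(0.0, abs=1e-12)
        for c, v in dec.intrinsic.items():
            assert v == pytest.approx(const[c], abs=1e-12)

    def test_incomplete_lookup_rejected(self, lookup):
        partial = dict(lookup)
        partial.pop(next(iter(partial)))
        with pytest.raises(ValueError, match="incomplete"):
            decompose_lookup(partial, lambda *a: IminoShift(0, 0))

    def test_aform_provider_contributions_are_upfield(self):
        """Stacked neighbor pairs shield the central imino proton."""
        prov = AFormRCProvider()
        for n in WC_PAIRS:
            for d in ("5p", "3p"):
                assert prov("GC", n, d).h1 < 0.05


class TestRegisterShift:
    def test_identity_is_zero(self, lookup):
        p = register_shift_delta("GC-GC-AU", "GC-GC-AU", lookup)
        assert p.delta_n15_ppm == 0 and p.delta_h1_hz == 0

    def test_hz_conversion_constants(self, lookup):
        p = register_shift_delta("GC-GC-AU", "AU-GC-GC", lookup)
        assert p.delta_h1_hz == pytest.approx(p.delta_h1_ppm * 800.0)
        assert p.delta_n15_hz == pytest.approx(p.delta_n15_ppm * 81.08)

    def test_unknown_code_rejected(self, lookup):
        partial = dict(lookup)
        partial.pop(TripletCode("AU", "GU", "CG"))
        with pytest.raises(KeyError):
            register_shift_delta("GC-GC-AU", "AU-GU-CG", partial)
        with pytest.raises(ValueError):
            register_shift_delta("GC-GC-AU", "GC-GC-XX", lookup)

    def test_sliding_clusters(self, lookup):
        """Central-pair switches (GC<->GU, UA<->UG) dominate the shift map."""
        slides = enumerate_register_slides(lookup)
        assert len(slides) > 20
        combined = lambda p: np.hypot(p.delta_n15_hz, p.delta_h1_hz)
        switching = [combined(p) for p, sw in slides if sw]
        preserving = [combined(p) for p, sw in slides if not sw]
        assert switching and preserving
        assert np.mean(switching) > 3 * np.mean(preserving)
        # switches only flip the wobble partner of the central residue
        for p, sw in slides:
            if sw:
                assert {p.gs_code.central, p.es_code.central} in \
                    ({"GC", "GU"}, {"UA", "UG"})
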