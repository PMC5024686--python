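"""Association: digestion, circularization, junction/long parsing, table rules."""
from collections import Counter

import numpy as np
import pytest

from bcstarprom._dna import reverse_complement
from bcstarprom.association import (
    Fragment,
    build_association_table,
    circularize_fragment,
    insilico_digest,
    junction_window,
    linearize_circle,
    nhe_xba_fragment,
    parse_junction_read,
    parse_long_read,
    validate_association,
)
from bcstarprom.library_design import RESTRICTION_SITES


class TestDigest:
    def test_construct_fragment_contains_promoter_and_barcode(self, small_library):
        for c in small_library[:5]:
            frags = insilico_digest(
                c.sequence,
                [("NheI", "GCTAGC"), ("XbaI", "TCTAGA")],
            )
            assert len(frags) == 3  # upstream | NheI..XbaI | downstream
            mid = frags[1]
            # substring-position oracle
            assert c.promoter.seq in mid.seq and c.barcode in mid.seq
            assert mid.seq.startswith("GCTAGC")

    def test_no_site_returns_input(self):
        frags = insilico_digest("ACGT" * 10, [("NheI", "GCTAGC")])
        assert len(frags) == 1 and frags[0].seq == "ACGT" * 10

    def test_palindromic_site_strand_agnostic(self):
        # the palindrome's reverse complement is itself, so a site written on
        # the reverse strand is the same forward 6-mer
        site = "GCTAGC"
        assert reverse_complement(site) == site
        seq = "AAAA" + site + "TTTT"
        assert len(insilico_digest(seq, [("NheI", site)])) == 2

    def test_empty_sequence(self):
        with pytest.raises(ValueError):
            insilico_digest("", [("NheI", "GCTAGC")])

    def test_base_conservation(self, small_library):
        c = small_library[0]
        frags = insilico_digest(c.sequence, [("NheI", "GCTAGC"), ("XbaI", "TCTAGA")])
        assert Counter("".join(f.seq for f in frags)) == Counter(c.sequence)


class TestCircularization:
    def test_length_conserved_and_junction(self):
        f = Fragment(seq="AAACCCGGGTTT", source_id="x")
        circ = circularize_fragment(f)
        assert circ.kind == "circular" and len(circ) == len(f)
        # junction window = suffix + prefix of the linear input (rotation oracle)
        assert junction_window(f.seq, up=3, down=4) == "TTT" + "AAAC"

    def test_double_circularization_fails(self):
        circ = circularize_fragment(Fragment(seq="ACGTACGT"))
        with pytest.raises(ValueError):
            circularize_fragment(circ)

    def test_linearize_opens_at_site(self):
        seq = "AAAA" + "GGGCCC" + "TTTT"
        circ = circularize_fragment(Fragment(seq=seq))
        out = linearize_circle(circ, [("ApaI", "GGGCCC")])
        assert len(out) == 1
        assert len(out[0].seq) == len(seq)
        assert out[0].seq.startswith("GGGCCC")
        assert sorted(out[0].seq) == sorted(seq)

    def test_linearize_empty_enzyme_list(self):
        circ = circularize_fragment(Fragment(seq="ACGT"))
        with pytest.raises(ValueError):
            linearize_circle(circ, [])

    def test_no_cut_warns_and_returns_empty(self):
        circ = circularize_fragment(Fragment(seq="ACGTACGT"))
        with pytest.warns(UserWarning):
            out = linearize_circle(circ, [("ApaI", "GGGCCC")])
        assert out == []

    def test_three_enzyme_redundancy(self, small_library):
        # when one enzyme's cut destroys the junction, the pooled aliquots
        # still contain a template with the junction intact
        frag = nhe_xba_fragment(small_library[0])
        window = junction_window(frag.seq)
        # plant an ApaI site inside the first repeat (within the window)
        seq = frag.seq[:60] + "GGGCCC" + frag.seq[66:]
        circ = circularize_fragment(Fragment(seq=seq, source_id="t"))
        pool = linearize_circle(circ)
        window2 = junction_window(seq)
        intact = [lin for lin in pool if window2 in lin.seq]
        broken = [lin for lin in pool if window2 not in lin.seq]
        assert intact and broken  # ApaI aliquot broken, FspI/HincII rescue

    def test_circle_requires_circular_input(self):
        with pytest.raises(ValueError):
            linearize_circle(Fragment(seq="ACGT"), [("ApaI", "GGGCCC")])


class TestJunctionParsing:
    def test_error_free_read_recovers_truth(self, small_library):
        for c in small_library[:10]:
            frag = nhe_xba_fragment(c)
            read = junction_window(frag.seq)
            assert len(read) == 150
            hit = parse_junction_read(read)
            assert hit is not None
            bc, prefix = hit
            assert bc == c.barcode
            assert prefix == c.promoter.units[0].random_core

    def test_random_dna_unparsed(self, rng):
        read = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 150)])
        assert parse_junction_read(read) is None

    def test_one_anchor_substitution_tolerated(self, small_library):
        frag = nhe_xba_fragment(small_library[0])
        read = junction_window(frag.seq)
        # corrupt one base of the constant spacer (read starts inside it)
        corrupted = ("T" if read[0] != "T" else "A") + read[1:]
        assert parse_junction_read(corrupted) is not None

    def test_whitelist_is_exact(self, small_library):
        c = small_library[0]
        read = junction_window(nhe_xba_fragment(c).seq)
        i = read.index(c.barcode)
        bad = read[:i] + ("A" if c.barcode[0] != "A" else "C") + read[i + 1 :]
        whitelist = {c.barcode}
        assert parse_junction_read(read, whitelist=whitelist) is not None
        # one substitution inside the barcode: off-whitelist, no correction
        assert parse_junction_read(bad, whitelist=whitelist) is None


class TestLongReadParsing:
    def test_error_free_long_read(self, small_library):
        for c in small_library[:5]:
            frag = nhe_xba_fragment(c)
            hit = parse_long_read(frag.seq)
            assert hit is not None
            cores, bc = hit
            assert bc == c.barcode
            assert tuple(cores) == c.promoter.cores

    def test_strand_retry(self, small_library):
        frag = nhe_xba_fragment(small_library[0])
        fwd = parse_long_read(frag.seq)
        rev = parse_long_read(reverse_complement(frag.seq))
        assert fwd == rev
        # retry symmetry on garbage too
        assert parse_long_read("ACGT" * 500) is None

    def test_read_missing_barcode_unparsed(self, small_library):
        frag = nhe_xba_fragment(small_library[0])
        assert parse_long_read(frag.seq[:-60]) is None


class TestAssociationTable:
    def test_threshold_strictly_greater(self):
        pairs = [("B" * 20, "P1")] * 60 + [("A" * 20, "P2")] * 10
        t = build_association_table(pairs, min_reads=50)
        assert len(t) == 1
        assert t.table.iloc[0]["read_support"] == 60
        # exactly 50 reads does not pass a '>50' filter
        t2 = build_association_table([("C" * 20, "P3")] * 50, min_reads=50)
        assert len(t2) == 0

    def test_empty_input(self):
        t = build_association_table([])
        assert len(t) == 0 and len(t.conflicts) == 0

    def test_conflicting_barcode_dropped_and_reported(self):
        pairs = [("Z" * 20, "P1")] * 60 + [("Z" * 20, "P2")] * 55
        t = build_association_table(pairs)
        assert len(t) == 0
        assert set(t.conflicts["barcode"]) == {"Z" * 20}
        report = validate_association(t)
        assert report.collisions == ["Z" * 20]

    def test_multi_barcode_promoters_reported(self):
        pairs = (
            [("A" * 20, "P1")] * 60
            + [("C" * 20, "P1")] * 60
            + [("G" * 20, "P1")] * 60
            + [("T" * 20, "P2")] * 60
        )
        t = build_association_table(pairs)
        report = validate_association(t)
        assert report.collisions == []
        assert report.multi_barcode_promoters == ["P1"]

    def test_empty_table_report(self):
        report = validate_association(build_association_table([]))
        assert report.collisions == [] and report.multi_barcode_promoters == []
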