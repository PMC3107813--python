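"""ePST extension rules: prokaryotic, eukaryotic signal-bounded, fixed."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pgmap.automaton import Keyword
from pgmap.epst import (
    GeneSplicerError,
    SpliceSiteSet,
    canonical_splice_sites,
    extend_eukaryotic_signal,
    extend_fixed,
    extend_prokaryotic,
    mirror_sites,
    parse_genesplicer,
)
from pgmap.sixframe import NucleotideRecord, map_peptides, reverse_complement

NO_SITES = SpliceSiteSet(frozenset(), frozenset(), source="none")


def rec(seq, rid="r"):
    return NucleotideRecord(rid, rid, seq)


def match_kp(seq, std, rid="r"):
    (m,) = map_peptides([Keyword("kp", "KP")], [rec(seq, rid)], std)
    return m


class TestProkaryotic:
    def test_start_and_stop_recovered(self, std):
        m = match_kp("TAAATGAAACCCTGA", std)
        e = extend_prokaryotic(m, rec("TAAATGAAACCCTGA"), std)
        assert (e.epst_start, e.epst_end) == (4, 15)
        assert e.nt_seq == "ATGAAACCCTGA"
        assert e.protein_seq == "MKP*"
        assert (e.boundary_5, e.boundary_3) == ("start_codon", "stop_codon")

    def test_no_start_falls_back_to_peptide_start(self, std):
        seq = "TAAAAACCCTGA"
        e = extend_prokaryotic(match_kp(seq, std), rec(seq), std)
        assert (e.epst_start, e.epst_end) == (4, 12)
        assert e.boundary_5 == "peptide_start"

    def test_no_downstream_stop_truncates(self, std):
        seq = "ATGAAACCC"
        e = extend_prokaryotic(match_kp(seq, std), rec(seq), std)
        assert (e.epst_start, e.epst_end) == (1, 9)
        assert (e.boundary_5, e.boundary_3) == ("start_codon", "sequence_end")

    def test_no_stop_between_start_and_peptide(self, std):
        # TGA stop, then CTG (a standard-code start), then peptide, stop
        seq = "TGACTGAAACCCTAA"
        e = extend_prokaryotic(match_kp(seq, std), rec(seq), std)
        assert e.boundary_5 == "start_codon"
        assert e.nt_seq.startswith("CTG")
        codons = [e.nt_seq[i : i + 3] for i in range(0, len(e.nt_seq) - 3, 3)]
        assert not any(c in std.stop_codons for c in codons)

    def test_strand_invariance(self, std):
        seq = "TAAATGAAACCCTGA"
        mirror = reverse_complement(seq)
        e_fwd = extend_prokaryotic(match_kp(seq, std), rec(seq), std)
        e_rev = extend_prokaryotic(match_kp(mirror, std), rec(mirror), std)
        L = len(seq)
        assert e_rev.nt_seq == e_fwd.nt_seq
        assert e_rev.protein_seq == e_fwd.protein_seq
        assert (e_rev.epst_start, e_rev.epst_end) == (
            L - e_fwd.epst_end + 1,
            L - e_fwd.epst_start + 1,
        )

    def test_stop_to_stop_context_spans_both_stops(self, std):
        seq = "TAAATGAAACCCTGA"
        e = extend_prokaryotic(match_kp(seq, std), rec(seq), std)
        assert e.stop_to_stop_nt == seq


class TestCanonicalSpliceSites:
    def test_spec_dinucleotides(self):
        sites = canonical_splice_sites(rec("AAGTAA"), "+")
        assert sites.donors == {3}
        assert sites.acceptors == {3}
        empty = canonical_splice_sites(rec("CCCCCC"), "+")
        assert empty.donors == empty.acceptors == frozenset()

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.text("ACGT", min_size=2, max_size=200))
    def test_donor_count_matches_naive_scan(self, seq):
        sites = canonical_splice_sites(rec(seq), "+")
        naive = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "GT")
        assert len(sites.donors) == naive

    def test_minus_strand_scans_reverse_complement(self):
        seq = "AAGTAA"  # revcomp TTACTT: no GT, no AG
        sites = canonical_splice_sites(rec(seq), "-")
        assert sites.donors == sites.acceptors == frozenset()


class TestGeneSplicer:
    def test_column_mapping(self):
        sites = parse_genesplicer(
            "202 203 11.3 High donor\n115 114 7.1 Medium acceptor\n"
        )
        assert sites.donors == {202}
        assert sites.acceptors == {115}

    def test_junk_line_skipped(self, caplog):
        sites = parse_genesplicer(
            "202 203 11.3 High donor\nthis is not a row\n"
        )
        assert sites.donors == {202}
        assert "malformed" in caplog.text

    def test_all_junk_is_error(self):
        with pytest.raises(GeneSplicerError):
            parse_genesplicer("nothing\nparseable\n")

    def test_mirror_sites(self):
        sites = SpliceSiteSet(frozenset({3}), frozenset({5}), "genesplicer")
        m = mirror_sites(sites, 10)
        assert m.donors == {8}
        assert m.acceptors == {6}


class TestEukaryoticSignal:
    def test_without_sites_behaves_like_start_stop_bounded(self, std):
        seq = "TAAATGAAACCCTGA"
        e = extend_eukaryotic_signal(match_kp(seq, std), rec(seq), std, NO_SITES)
        assert (e.epst_start, e.epst_end) == (4, 15)
        assert e.boundary_5 == "start_codon"
        assert e.boundary_3 == "stop_codon"

    def test_upstream_stop_not_included(self, std):
        seq = "TAAAAACCCTGA"  # stop, no start, peptide, stop
        e = extend_eukaryotic_signal(match_kp(seq, std), rec(seq), std, NO_SITES)
        assert e.epst_start == 4
        assert e.boundary_5 == "stop_codon"

    def test_donor_bounds_3prime(self, std):
        # peptide KP at 4-9, donor GT planted 5 nt after the peptide end
        seq = "CCCAAACCCACCAGTCCCCCC"
        m = match_kp(seq, std)
        assert (m.nt_start, m.nt_end) == (4, 9)
        e = extend_eukaryotic_signal(m, rec(seq), std, canonical_splice_sites(rec(seq), "+"))
        assert e.boundary_3 == "splice_donor"
        assert e.epst_end == 12  # last complete codon before the GT at 14
        assert len(e.nt_seq) % 3 == 0

    def test_acceptor_bounds_5prime(self, std):
        # acceptor AG inside the 5' scan range before any start/stop codon
        seq = "CCAGCCCAAACCCTGA"
        m = match_kp(seq, std)
        assert (m.nt_start, m.nt_end) == (8, 13)
        sites = canonical_splice_sites(rec(seq), "+")
        e = extend_eukaryotic_signal(m, rec(seq), std, sites)
        assert e.boundary_5 == "splice_acceptor"
        # the codon crossing the acceptor at 4 is excluded; tag starts at 5
        assert e.epst_start == 5

    def test_sequence_end_truncation(self, std):
        seq = "AAACCC"
        e = extend_eukaryotic_signal(match_kp(seq, std), rec(seq), std, NO_SITES)
        assert (e.boundary_5, e.boundary_3) == ("sequence_end", "sequence_end")
        assert (e.epst_start, e.epst_end) == (1, 6)


class TestFixed:
    def test_zero_is_identity(self, std):
        seq = "TAAATGAAACCCTGA"
        m = match_kp(seq, std)
        e = extend_fixed(m, rec(seq), std, 0)
        assert (e.epst_start, e.epst_end) == (m.nt_start, m.nt_end)
        assert e.nt_seq == m.coding_nt
        assert e.protein_seq == "KP"
        assert e.boundary_5 == e.boundary_3 == "fixed_length"

    def test_symmetric_growth(self, std):
        seq = "CCCCCCAAACCCCCCCCC"
        m = match_kp(seq, std)
        e = extend_fixed(m, rec(seq), std, 6)
        assert (e.epst_start, e.epst_end) == (m.nt_start - 6, m.nt_end + 6)

    def test_clamped_at_ends(self, std):
        seq = "AAACCC"
        m = match_kp(seq, std)
        e = extend_fixed(m, rec(seq), std, 100)
        assert (e.epst_start, e.epst_end) == (1, 6)
        assert e.boundary_5 == e.boundary_3 == "sequence_end"

    def test_negative_rejected(self, std):
        seq = "AAACCC"
        with pytest.raises(ValueError):
            extend_fixed(match_kp(seq, std), rec(seq), std, -1)


class TestEpstInvariants:
    @pytest.mark.parametrize(
        "seq",
        [
            "TAAATGAAACCCTGA",
            "TAAAAACCCTGA",
            "ATGAAACCC",
            "CCCCCCAAACCCTGACCC",
        ],
    )
    def test_codon_mode_invariants(self, std, seq):
        m = match_kp(seq, std)
        e = extend_prokaryotic(m, rec(seq), std)
        assert e.epst_start <= m.nt_start <= m.nt_end <= e.epst_end
        assert len(e.nt_seq) % 3 == 0
        assert "KP" in e.protein_seq
        if e.boundary_3 == "stop_codon":
            assert e.protein_seq.count("*") == 1
            assert e.protein_seq.endswith("*")
        else:
            assert "*" not in e.protein_seq
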