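"""Guide parsing, gapped alignment, genome scanning and site IO."""

import random

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from casrisk.sequence_search import (
    GuideRNA,
    InvalidGuideError,
    MalformedRecordError,
    OffTargetSite,
    SearchParams,
    align_gapped,
    dedupe_sites,
    find_offtargets,
    parse_guide,
    read_guides,
    read_sites_bed,
    revcomp,
    write_sites_bed,
)

from conftest import oracle_align, oracle_scan, rc

CCR5_GUIDE = "CACCCGATCCACTGGGGAGC"


def random_seq(rng, n):
    return "".join(rng.choice("ACGT") for _ in range(n))


class TestParseGuide:
    def test_ccr5_guide_parses_to_20mer(self):
        g = parse_guide(CCR5_GUIDE, "NGG")
        assert len(g) == 20
        assert g.protospacer == CCR5_GUIDE
        assert g.pam_side == "three_prime"

    def test_lowercase_normalized(self):
        g = parse_guide("acgt" * 5)
        assert g.protospacer == "ACGT" * 5

    @pytest.mark.parametrize("bad", ["ACGUACGUACGU", "", "   ", "ACGT-ACGT"])
    def test_invalid_guides_rejected(self, bad):
        with pytest.raises(InvalidGuideError):
            parse_guide(bad)

    def test_bad_pam_rejected(self):
        with pytest.raises(InvalidGuideError):
            GuideRNA("ACGTACGT", pam_pattern="NQQ")


class TestAlignGapped:
    def test_identity(self):
        a = align_gapped("ACGT" * 5, "ACGT" * 5, 4, 1, 1)
        assert (a.mismatches, a.dna_bulges, a.rna_bulges) == (0, 0, 0)
        assert a.alignment_string == "M" * 20

    def test_single_rna_bulge(self):
        # window lost one guide base -> one RNA bulge, no mismatches
        a = align_gapped("ACGTACGT", "ACGACGT", 0, 0, 1)
        assert (a.mismatches, a.dna_bulges, a.rna_bulges) == (0, 0, 1)
        assert sorted(a.alignment_string) == sorted("MMMMMMM" + "R")

    def test_single_dna_bulge(self):
        a = align_gapped("ACGTACGT", "ACGTTACGT", 0, 1, 0)
        assert (a.mismatches, a.dna_bulges, a.rna_bulges) == (0, 1, 0)

    def test_budget_exceeded_returns_none(self):
        assert align_gapped("AAAAAAAA", "AAATTTAA", 2, 0, 0) is None

    def test_n_in_window_counts_as_mismatch(self):
        a = align_gapped("ACGT", "ACNT", 1, 0, 0)
        assert a.mismatches == 1
        assert align_gapped("ACGT", "ACNT", 0, 0, 0) is None

    def test_matches_exhaustive_enumeration_oracle(self):
        """Minimal (bulges, mismatches) equals exhaustive gap placement for
        all short guide/window pairs with bulge budgets <= 1."""
        rng = random.Random(20240901)
        checked = 0
        for _ in range(300):
            lg = rng.randint(3, 10)
            delta = rng.choice([-1, 0, 1])
            lw = lg + delta
            if lw < 2:
                continue
            g, w = random_seq(rng, lg), random_seq(rng, lw)
            max_mm = rng.randint(0, 3)
            got = align_gapped(g, w, max_mm, 1, 1)
            want = oracle_align(g, w, max_mm, 1, 1)
            if want is None:
                assert got is None, (g, w, max_mm)
            else:
                assert got is not None, (g, w, max_mm)
                assert (got.mismatches, got.dna_bulges, got.rna_bulges) == want
            checked += 1
        assert checked > 250


class TestFindOfftargets:
    def test_perfect_self_match(self):
        g = parse_guide(CCR5_GUIDE)
        genome = {"chr1": CCR5_GUIDE + "AGG"}
        sites = find_offtargets(genome, g, SearchParams(max_mismatches=0))
        assert len(sites) == 1
        s = sites[0]
        assert (s.chrom, s.start, s.end, s.strand) == ("chr1", 0, 20, "+")
        assert s.mismatches == 0 and s.is_on_target
        assert s.pam_sequence == "AGG"

    def test_pam_gate_blocks_everything(self):
        g = GuideRNA(CCR5_GUIDE, pam_pattern="ATT")
        genome = {"chr1": CCR5_GUIDE + "AGG"}
        # no ATT adjacent on either strand
        assert find_offtargets(genome, g, SearchParams(max_mismatches=4)) == []

    def test_guide_longer_than_genome_is_empty_not_error(self):
        g = parse_guide(CCR5_GUIDE)
        assert find_offtargets({"chr1": "ACGT"}, g) == []

    def test_minus_strand_site_reported_in_forward_coordinates(self):
        g = parse_guide(CCR5_GUIDE)
        insert = revcomp(CCR5_GUIDE + "TGG")
        genome = {"chr1": "TTTTT" + insert + "TTTTT"}
        sites = find_offtargets(genome, g, SearchParams(max_mismatches=0))
        assert len(sites) == 1
        s = sites[0]
        assert s.strand == "-"
        assert (s.start, s.end) == (5 + 3, 5 + 23)
        assert s.site_sequence == CCR5_GUIDE

    def test_n_bases_never_match(self):
        g = parse_guide("ACGTACGTAC")
        genome = {"chr1": "ACGTACGTNC" + "TGG"}
        assert find_offtargets(genome, g, SearchParams(max_mismatches=0)) == []
        hits = find_offtargets(genome, g, SearchParams(max_mismatches=1))
        assert len(hits) == 1 and hits[0].mismatches == 1

    def test_matches_bruteforce_oracle_on_random_genome(self):
        """A 5 kb seeded random genome scanned at 3 mismatches yields the
        exact site set of the exhaustive per-position scan."""
        rng = random.Random(5150)
        genome = {"chr1": random_seq(rng, 5000), "chr2": random_seq(rng, 2000)}
        guide = parse_guide(random_seq(rng, 20))
        params = SearchParams(max_mismatches=3)
        got = {(s.chrom, s.start, s.end, s.strand, s.mismatches)
               for s in find_offtargets(genome, guide, params)}
        assert got == oracle_scan(genome, guide.protospacer, "NGG", 3)

    def test_reverse_complement_symmetry(self):
        """Reverse-complementing the genome maps each +site [s, e) to a
        -site [L - e, L - s) with the same mismatch count."""
        rng = random.Random(99)
        seq = random_seq(rng, 3000)
        guide = parse_guide(random_seq(rng, 20))
        params = SearchParams(max_mismatches=3)
        fwd = find_offtargets({"c": seq}, guide, params)
        rev = find_offtargets({"c": rc(seq)}, guide, params)
        L = len(seq)
        flipped = {(s.chrom, L - s.end, L - s.start,
                    "-" if s.strand == "+" else "+", s.mismatches) for s in fwd}
        assert {(s.chrom, s.start, s.end, s.strand, s.mismatches)
                for s in rev} == flipped

    def test_mismatch_budget_monotonicity(self):
        rng = random.Random(4242)
        genome = {"c": random_seq(rng, 4000)}
        guide = parse_guide(random_seq(rng, 20))
        prev: set = set()
        for mm in range(4):
            cur = {(s.chrom, s.start, s.end, s.strand)
                   for s in find_offtargets(genome, guide, SearchParams(max_mismatches=mm))}
            assert prev <= cur
            prev = cur

    def test_bulge_search_finds_gapped_site(self):
        g = parse_guide("ACGTACGTACGTACGTACGT")
        # drop guide base 10 -> site needs one RNA bulge
        site = g.protospacer[:10] + g.protospacer[11:]
        genome = {"chr1": "TTTTT" + site + "TGG" + "TTTTT"}
        assert find_offtargets(genome, g, SearchParams(max_mismatches=0)) == []
        sites = find_offtargets(
            genome, g, SearchParams(max_mismatches=0, max_rna_bulges=1))
        assert len(sites) >= 1
        best = sites[0]
        assert best.rna_bulges == 1 and best.mismatches == 0

    def test_five_prime_pam(self):
        g = GuideRNA("ACGTACGTACGTACGTACGT", pam_pattern="TTTV", pam_side="five_prime")
        genome = {"chr1": "CC" + "TTTA" + g.protospacer + "CC"}
        sites = find_offtargets(genome, g, SearchParams(max_mismatches=0))
        assert len(sites) == 1
        assert (sites[0].start, sites[0].end) == (6, 26)
        assert sites[0].pam_sequence == "TTTA"


class TestSitesBed:
    def test_roundtrip_bed6(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t100\t120\tsite1\t0\t+\nchr2\t5\t25\tsite2\t0\t-\t3\n")
        sites = read_sites_bed(p)
        assert [(s.chrom, s.start, s.end, s.strand) for s in sites] == [
            ("chr1", 100, 120, "+"), ("chr2", 5, 25, "-")]
        assert sites[0].mismatches is None and sites[1].mismatches == 3
        out = tmp_path / "o.bed"
        write_sites_bed(sites, out)
        again = read_sites_bed(out)
        assert [(s.chrom, s.start, s.end, s.strand, s.mismatches) for s in again] \
            == [(s.chrom, s.start, s.end, s.strand, s.mismatches) for s in sites]

    def test_inverted_coordinates_named_with_line(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t120\t100\tx\t0\t+\n")
        with pytest.raises(MalformedRecordError, match="line 1"):
            read_sites_bed(p)

    def test_too_few_columns(self, tmp_path):
        p = tmp_path / "bad.bed"
        p.write_text("chr1\t100\t120\tok\t0\t+\nchr1\t5\n")
        with pytest.raises(MalformedRecordError, match="line 2"):
            read_sites_bed(p)

    def test_missing_strand_defaults_plus(self, tmp_path, caplog):
        p = tmp_path / "s.bed"
        p.write_text("chr1\t1\t21\n")
        with caplog.at_level("WARNING"):
            sites = read_sites_bed(p)
        assert sites[0].strand == "+"
        assert "defaulting" in caplog.text

    def test_three_valid_lines_conserved_in_order(self, tmp_path):
        p = tmp_path / "s.bed"
        p.write_text("".join(f"chr1\t{i * 100}\t{i * 100 + 20}\ts{i}\t0\t+\n"
                             for i in range(3)))
        sites = read_sites_bed(p)
        assert [s.start for s in sites] == [0, 100, 200]
        assert all(s.mismatches is None for s in sites)


class TestDedupe:
    def test_min_mismatch_kept(self):
        a = OffTargetSite("chr1", 10, 30, "+", mismatches=4)
        b = OffTargetSite("chr1", 10, 30, "+", mismatches=2)
        out = dedupe_sites([a, b])
        assert len(out) == 1 and out[0].mismatches == 2

    def test_distinct_input_sorted(self):
        sites = [OffTargetSite("chr2", 5, 25, "+", mismatches=1),
                 OffTargetSite("chr1", 50, 70, "-", mismatches=0),
                 OffTargetSite("chr1", 5, 25, "+", mismatches=2)]
        out = dedupe_sites(sites)
        assert [(s.chrom, s.start) for s in out] == [("chr1", 5), ("chr1", 50), ("chr2", 5)]

    @given(st.lists(st.tuples(st.sampled_from(["chr1", "chr2"]),
                              st.integers(0, 5), st.integers(0, 4),
                              st.sampled_from("+-")), max_size=50))
    @settings(derandomize=True, max_examples=60)
    def test_matches_grouping_oracle(self, raw):
        sites = [OffTargetSite(c, s * 10, s * 10 + 20, strand, mismatches=mm)
                 for c, s, mm, strand in raw]
        out = dedupe_sites(sites)
        # oracle: set-based grouping keeping the min mismatch per locus
        best: dict = {}
        for s in sites:
            k = (s.chrom, s.start, s.end, s.strand)
            best[k] = min(best.get(k, 99), s.mismatches)
        assert {(s.chrom, s.start, s.end, s.strand): s.mismatches for s in out} == best
        assert [(s.chrom, s.start) for s in out] == sorted((s.chrom, s.start) for s in out)


def test_read_guides_plain_and_tsv(tmp_path):
    plain = tmp_path / "g.txt"
    plain.write_text(f"{CCR5_GUIDE}\n# comment\nACGTACGTACGTACGTACGT\n")
    gs = read_guides(plain)
    assert [name for name, _ in gs] == ["guide1", "guide2"]
    tsv = tmp_path / "g.tsv"
    tsv.write_text(f"ccr5\t{CCR5_GUIDE}\n")
    assert read_guides(tsv)[0][0] == "ccr5"
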