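"""Gene model loading, segment derivation, tracks and function tables."""

import gzip

import pytest

from casrisk.annotation_store import (
    derive_promoters,
    load_function_tables,
    load_gene_models,
    load_genome,
    load_track,
    merge_intervals,
    strip_version,
    subtract_intervals,
    write_track,
)

GFF_ONE_GENE = """##gff-version 3
chr1\tsrc\tgene\t101\t400\t.\t+\t.\tID=G1;gene_id=G1;gene_name=g1;gene_biotype=protein_coding
chr1\tsrc\ttranscript\t101\t400\t.\t+\t.\tID=T1;Parent=G1;transcript_id=T1
chr1\tsrc\texon\t101\t200\t.\t+\t.\tParent=T1
chr1\tsrc\texon\t301\t400\t.\t+\t.\tParent=T1
"""

GTF_ONE_GENE = (
    'chr1\tsrc\tgene\t101\t400\t.\t+\t.\tgene_id "G1"; gene_name "g1"; gene_biotype "protein_coding";\n'
    'chr1\tsrc\ttranscript\t101\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
    'chr1\tsrc\texon\t101\t200\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
    'chr1\tsrc\texon\t301\t400\t.\t+\t.\tgene_id "G1"; transcript_id "T1";\n'
)


class TestGenome:
    def test_two_record_fasta(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1 description here\nACGTACGT\nACGT\n>chr2\nTTTT\n")
        g = load_genome(p)
        assert set(g) == {"chr1", "chr2"}
        assert len(g["chr1"]) == 12 and len(g["chr2"]) == 4

    def test_empty_file_is_error(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text("")
        with pytest.raises(ValueError):
            load_genome(p)

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "g.fa"
        p.write_text(">chr1\nACGT\n>chr1\nTTTT\n")
        with pytest.raises(ValueError, match="duplicate"):
            load_genome(p)

    def test_gzip_equals_plain(self, tmp_path):
        plain = tmp_path / "g.fa"
        plain.write_text(">chr1\nACGTACGT\n")
        gz = tmp_path / "g.fa.gz"
        with gzip.open(gz, "wt") as fh:
            fh.write(">chr1\nACGTACGT\n")
        assert load_genome(plain) == load_genome(gz)


class TestGeneModels:
    def test_intron_is_exon_complement(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_ONE_GENE)
        gms = load_gene_models(p)
        g = gms.get("G1")
        assert g.segments["exon"] == [(100, 200), (300, 400)]
        assert g.segments["intron"] == [(200, 300)]

    def test_gtf_and_gff3_give_identical_models(self, tmp_path):
        p1 = tmp_path / "a.gff3"
        p1.write_text(GFF_ONE_GENE)
        p2 = tmp_path / "a.gtf"
        p2.write_text(GTF_ONE_GENE)
        g1 = load_gene_models(p1).get("G1")
        g2 = load_gene_models(p2).get("G1")
        assert (g1.start, g1.end, g1.biotype) == (g2.start, g2.end, g2.biotype)
        assert g1.segments == g2.segments

    def test_overlapping_transcripts_match_perbase_oracle(self, tmp_path):
        """Intron set equals the per-base complement of the exon union over
        two staggered transcripts."""
        gff = (
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t1000\t.\t+\t.\tID=G1;gene_biotype=lncRNA\n"
            "chr1\tsrc\ttranscript\t1\t1000\t.\t+\t.\tID=T1;Parent=G1\n"
            "chr1\tsrc\texon\t1\t150\t.\t+\t.\tParent=T1\n"
            "chr1\tsrc\texon\t401\t600\t.\t+\t.\tParent=T1\n"
            "chr1\tsrc\ttranscript\t1\t1000\t.\t+\t.\tID=T2;Parent=G1\n"
            "chr1\tsrc\texon\t100\t250\t.\t+\t.\tParent=T2\n"
            "chr1\tsrc\texon\t901\t1000\t.\t+\t.\tParent=T2\n"
        )
        p = tmp_path / "a.gff3"
        p.write_text(gff)
        g = load_gene_models(p).get("G1")
        exonic = [False] * 1000
        for iv in [(0, 150), (400, 600), (99, 250), (900, 1000)]:
            for b in range(*iv):
                exonic[b] = True
        per_base_introns = []
        start = None
        for b in range(1000):
            if not exonic[b] and start is None:
                start = b
            if exonic[b] and start is not None:
                per_base_introns.append((start, b))
                start = None
        if start is not None:
            per_base_introns.append((start, 1000))
        assert g.segments["intron"] == per_base_introns
        # exon ∪ intron = gene span, exon ∩ intron = ∅ (per-base)
        cover = [0] * 1000
        for seg in ("exon", "intron"):
            for s, e in g.segments[seg]:
                for b in range(s, e):
                    cover[b] += 1
        assert all(c == 1 for c in cover)

    def test_utrs_flank_cds_strand_aware(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t1\t300\t.\t-\t.\tID=G1;gene_biotype=protein_coding\n"
            "chr1\tsrc\ttranscript\t1\t300\t.\t-\t.\tID=T1;Parent=G1\n"
            "chr1\tsrc\texon\t1\t300\t.\t-\t.\tParent=T1\n"
            "chr1\tsrc\tCDS\t101\t200\t.\t-\t0\tParent=T1\n"
        )
        p = tmp_path / "a.gff3"
        p.write_text(gff)
        g = load_gene_models(p).get("G1")
        # minus strand: right flank is 5'UTR
        assert g.segments["5UTR"] == [(200, 300)]
        assert g.segments["3UTR"] == [(0, 100)]
        assert g.segments["CDS"] == [(100, 200)]

    def test_exon_without_transcript_parent_is_error(self, tmp_path):
        gff = ("##gff-version 3\n"
               "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=G1\n"
               "chr1\tsrc\texon\t1\t50\t.\t+\t.\tID=orphan\n")
        p = tmp_path / "bad.gff3"
        p.write_text(gff)
        with pytest.raises(ValueError, match="transcript parent"):
            load_gene_models(p)


class TestPromoters:
    def test_plus_strand_window(self):
        track = derive_promoters([("chr1", 1000, "+", "G1")], upstream=499, downstream=100)
        r = track.records[0]
        assert (r.start, r.end) == (501, 1101)
        assert r.end - r.start == 600
        assert r.linked_gene_id == "G1"

    def test_minus_strand_mirror(self):
        track = derive_promoters([("chr1", 1000, "-", "G1")], upstream=499, downstream=100)
        r = track.records[0]
        assert (r.start, r.end) == (900, 1500)

    def test_clip_at_chromosome_start(self):
        track = derive_promoters([("chr1", 10, "+", "G1")], upstream=499, downstream=100)
        assert track.records[0].start == 0

    def test_from_gene_model_set(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF_ONE_GENE)
        gms = load_gene_models(p)
        track = derive_promoters(gms, upstream=50, downstream=10)
        r = track.records[0]
        assert (r.start, r.end) == (100 - 50, 100 + 11)


class TestTracks:
    def test_bed4_enhancer_gene_column(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("chr1\t100\t200\tG1\n")
        t = load_track(p, "enhancer")
        assert t.records[0].linked_gene_id == "G1"

    def test_bed3_peak_has_no_link(self, tmp_path):
        p = tmp_path / "p.bed"
        p.write_text("chr1\t100\t200\n")
        t = load_track(p, "regulator_peak")
        assert t.records[0].linked_gene_id is None

    def test_zero_length_interval_rejected(self, tmp_path):
        p = tmp_path / "z.bed"
        p.write_text("chr1\t100\t100\tx\n")
        with pytest.raises(ValueError, match="line 1"):
            load_track(p, "enhancer")

    def test_roundtrip_bed(self, tmp_path):
        p = tmp_path / "e.bed"
        p.write_text("chr1\t100\t200\tenh1\t0\t+\tG1\nchr2\t5\t50\tenh2\t0\t.\t.\n")
        t = load_track(p, "enhancer")
        out = tmp_path / "o.bed"
        write_track(t, out)
        assert load_track(out, "enhancer").records == t.records


class TestFunctionTables:
    def _world(self, tmp_path, **tables):
        paths = {}
        for name, content in tables.items():
            p = tmp_path / f"{name}.tsv"
            p.write_text(content)
            paths[name] = p
        return paths

    def test_cancer_only_gene(self, tmp_path):
        paths = self._world(tmp_path, cancer_genes="gene_id\nG9\n")
        idx = load_function_tables(cancer_genes=paths["cancer_genes"])
        rec = idx.get("G9")
        assert rec.is_cancer_gene and rec.phenotypes == ()

    def test_unknown_gene_is_empty_record_not_error(self, tmp_path):
        idx = load_function_tables()
        rec = idx.get("NOPE")
        assert not rec.phenotypes and not rec.is_cancer_gene
        assert rec.tf_class == "none" and not rec.expression

    def test_duplicate_phenotype_rows_union(self, tmp_path):
        paths = self._world(
            tmp_path,
            phenotypes="gene_id\tphenotype\nG1\tdeafness\nG1\tdeafness\nG1\tanemia\n")
        idx = load_function_tables(phenotypes=paths["phenotypes"])
        assert idx.get("G1").phenotypes == ("deafness", "anemia")

    def test_version_suffix_stripped(self, tmp_path):
        paths = self._world(tmp_path, phenotypes="gene_id\tphenotype\nENSG01.5\tX\n")
        idx = load_function_tables(phenotypes=paths["phenotypes"])
        assert idx.get("ENSG01").phenotypes == ("X",)
        assert idx.get("ENSG01.7").phenotypes == ("X",)

    def test_missing_gene_id_column_names_file(self, tmp_path):
        p = tmp_path / "broken.tsv"
        p.write_text("gene\tphenotype\nG1\tX\n")
        with pytest.raises(ValueError, match="broken.tsv"):
            load_function_tables(phenotypes=p)

    def test_expression_wide_table(self, tmp_path):
        paths = self._world(
            tmp_path, expression="gene_id\tblood\tbrain\nG1\t5.5\t0.1\n")
        idx = load_function_tables(expression=paths["expression"])
        assert idx.get("G1").expression == {"blood": 5.5, "brain": 0.1}
        assert idx.tissues == ["blood", "brain"]


def test_interval_helpers():
    assert merge_intervals([(5, 10), (0, 6), (20, 30)]) == [(0, 10), (20, 30)]
    assert subtract_intervals((0, 100), [(10, 20), (50, 60)]) == \
        [(0, 10), (20, 50), (60, 100)]
    assert strip_version("ENSG0001.12") == "ENSG0001"
    assert strip_version("G1") == "G1"
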