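"""Format I/O: FASTA, GFF3, tabular hits, block tables and Circos links."""

import pytest

from microsynteny import genome_io
from microsynteny.genome_io import FormatError, GeneModel, HomologyHit
from microsynteny.synteny import AnchorRegion, ConservedPair, SyntenyBlock

from conftest import make_annotation, make_gene


class TestFasta:
    def test_single_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">g1\natgaaa\n")
        assert genome_io.read_fasta(p) == {"g1": "ATGAAA"}

    def test_wrapped_record_matches_line_join(self, tmp_path):
        # naive oracle: join all sequence lines per record
        body = ["ATGAAA", "CCCGGG", "TTT"]
        p = tmp_path / "a.fa"
        p.write_text(">g1 description\n" + "\n".join(body) + "\n>g2\nATG\n")
        seqs = genome_io.read_fasta(p)
        assert seqs["g1"] == "".join(body)
        assert seqs["g2"] == "ATG"

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">g1\nATG\n>g1\nCCC\n")
        with pytest.raises(FormatError):
            genome_io.read_fasta(p)

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text("")
        with pytest.raises(FormatError):
            genome_io.read_fasta(p)


GFF = """##gff-version 3
##sequence-region chr1 1 100000
chr1\tt\tgene\t1000\t1011\t.\t+\t.\tID=gA
chr1\tt\tmRNA\t1000\t1011\t.\t+\t.\tID=gA.1;Parent=gA
chr1\tt\tCDS\t1000\t1011\t.\t+\t0\tID=gA.1.c;Parent=gA.1
chr1\tt\tgene\t5000\t5011\t.\t-\t.\tID=gB
chr1\tt\tmRNA\t5000\t5011\t.\t-\t.\tID=gB.1;Parent=gB
chr1\tt\tCDS\t5000\t5011\t.\t-\t0\tID=gB.1.c;Parent=gB.1
chr1\tt\tgene\t3000\t3011\t.\t+\t.\tID=gC
chr1\tt\tmRNA\t3000\t3011\t.\t+\t.\tID=gC.1;Parent=gC
chr1\tt\tCDS\t3000\t3011\t.\t+\t0\tID=gC.1.c;Parent=gC.1
"""


class TestGff:
    def make_genome(self):
        genome = ["A"] * 100000
        genome[999:1011] = list("ATGGCCGCCTAA")     # gA, + strand
        # gB on - strand: spliced CDS is revcomp of the genomic span
        genome[4999:5011] = list("TTACATTGCCAT")    # revcomp -> ATGGCAATGTAA
        genome[2999:3011] = list("ATGAAAGCGTGA")    # gC
        return {"chr1": "".join(genome)}

    def test_genes_sorted_by_coordinate(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF)
        ann = genome_io.read_gff(p, self.make_genome(), species_id="sp")
        assert [g.gene_id for g in ann.genes] == ["gA", "gC", "gB"]
        assert ann.chromosomes["chr1"] == 100000

    def test_minus_strand_reverse_complement(self, tmp_path):
        p = tmp_path / "a.gff3"
        p.write_text(GFF)
        ann = genome_io.read_gff(p, self.make_genome(), species_id="sp")
        # hand-computed reverse complement of TTACATTGCCAT
        assert ann.gene("gB").cds == "ATGGCAATGTAA"
        assert ann.gene("gB").protein == "MAM"

    def test_longest_transcript_kept(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\tt\tgene\t100\t400\t.\t+\t.\tID=g1\n"
            "chr1\tt\tmRNA\t100\t400\t.\t+\t.\tID=g1.1;Parent=g1\n"
            "chr1\tt\tCDS\t100\t399\t.\t+\t0\tID=c1;Parent=g1.1\n"
            "chr1\tt\tmRNA\t100\t400\t.\t+\t.\tID=g1.2;Parent=g1\n"
            "chr1\tt\tCDS\t100\t249\t.\t+\t0\tID=c2;Parent=g1.2\n"
        )
        p = tmp_path / "a.gff3"
        p.write_text(gff)
        genome = "A" * 99 + "ATG" + "GCT" * 98 + "TAA" + "A" * 200
        ann = genome_io.read_gff(p, {"chr1": genome}, species_id="sp")
        assert len(ann.gene("g1").cds) == 300

    def test_gene_without_cds_skipped(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\tt\tgene\t100\t200\t.\t+\t.\tID=orphan\n"
        )
        p = tmp_path / "a.gff3"
        p.write_text(gff)
        ann = genome_io.read_gff(p, {"chr1": "A" * 300}, species_id="sp")
        assert len(ann) == 0


class TestHitsTable:
    def row(self, q, s, e, bits, ident=90.0):
        return f"{q}\t{s}\t{ident}\t100\t5\t0\t1\t100\t1\t100\t{e}\t{bits}"

    def test_parse_and_identity_fraction(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.row("a", "b", "1e-30", 200) + "\n")
        (hit,) = genome_io.read_hits_table(p)
        assert hit.identity == pytest.approx(0.90)
        assert hit.e_value == pytest.approx(1e-30)

    def test_best_hit_reduction_and_idempotence(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(
            self.row("a", "b", "1e-5", 100) + "\n" + self.row("a", "b", "1e-30", 200) + "\n"
        )
        hits = genome_io.read_hits_table(p)
        assert len(hits) == 1
        assert hits[0].e_value == pytest.approx(1e-30)
        # idempotence: writing the reduced set back and re-reading changes nothing
        out = tmp_path / "h2.tsv"
        genome_io.write_hits_table(hits, out)
        again = genome_io.read_hits_table(out)
        assert [(h.query_id, h.subject_id) for h in again] == [("a", "b")]

    def test_self_hit_dropped(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.row("a", "a", "1e-30", 200) + "\n")
        assert genome_io.read_hits_table(p) == []

    def test_non_numeric_evalue_rejected(self, tmp_path):
        p = tmp_path / "h.tsv"
        p.write_text(self.row("a", "b", "oops", 200) + "\n")
        with pytest.raises(FormatError):
            genome_io.read_hits_table(p)


def _toy_block(n_pairs=3, with_dating=None):
    genes_a = [make_gene(f"a{i}", 1000 + 5000 * i, "ATGGCCGCC") for i in range(n_pairs)]
    genes_b = [make_gene(f"b{i}", 1000 + 5000 * i, "ATGGCCGCC", chromosome="chr2")
               for i in range(n_pairs)]
    pairs = [
        ConservedPair(
            gene_a=a.gene_id, gene_b=b.gene_id, same_strand=True, e_value=1e-30,
            coords_a=(a.chromosome, a.start, a.end),
            coords_b=(b.chromosome, b.start, b.end),
        )
        for a, b in zip(genes_a, genes_b)
    ]
    block = SyntenyBlock(
        region_a=AnchorRegion("a0", "sp", "chr1", 1, 50000, [g.gene_id for g in genes_a]),
        region_b=AnchorRegion("b0", "sp", "chr2", 1, 50000, [g.gene_id for g in genes_b]),
        pairs=pairs, n_pairs=n_pairs, orientation="same", quality=1.0,
        scope="within-species",
    )
    block.dating = with_dating
    return block


class TestBlockTable:
    def test_empty_block_list_header_only(self, tmp_path):
        p = tmp_path / "blocks.tsv"
        genome_io.write_block_table([], p)
        assert len(p.read_text().strip().splitlines()) == 1

    def test_dated_row_contains_published_style_values(self, tmp_path):
        from microsynteny.molecular_evolution import BlockDating

        dating = BlockDating(pair_ks=[1.0927] * 5, mean_ks=1.0927, sd_ks=0.4254,
                             date_mya=84.0538, n_used=5)
        p = tmp_path / "blocks.tsv"
        genome_io.write_block_table([_toy_block(5, dating)], p)
        text = p.read_text()
        assert "5" in text and "1.0927" in text and "84.0538" in text

    def test_round_trip(self, tmp_path):
        p = tmp_path / "blocks.tsv"
        genome_io.write_block_table([_toy_block(4)], p)
        df = genome_io.read_block_table(p)
        assert df.loc[0, "anchor_a"] == "a0"
        assert df.loc[0, "n_conserved_pairs"] == 4
        # writing the parsed content again is byte-identical
        p2 = tmp_path / "blocks2.tsv"
        genome_io.write_block_table([_toy_block(4)], p2)
        assert p.read_text() == p2.read_text()


class TestCircosLinks:
    def test_one_line_per_pair_and_exact_coordinates(self, tmp_path):
        block = _toy_block(3)
        p = tmp_path / "links.txt"
        genome_io.write_circos_links([block], p)
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 3
        first = lines[0].split()
        pair = block.pairs[0]
        assert first == [
            pair.coords_a[0], str(pair.coords_a[1]), str(pair.coords_a[2]),
            pair.coords_b[0], str(pair.coords_b[1]), str(pair.coords_b[2]),
        ]

    def test_empty_blocks_empty_file(self, tmp_path):
        p = tmp_path / "links.txt"
        genome_io.write_circos_links([], p)
        assert p.read_text() == ""

    def test_missing_coordinates_rejected(self, tmp_path):
        block = _toy_block(1)
        block.pairs = [
            ConservedPair(gene_a="x", gene_b="y", same_strand=True, e_value=1e-30)
        ]
        with pytest.raises(ValueError):
            genome_io.write_circos_links([block], tmp_path / "links.txt")


class TestGeneModelInvariants:
    def test_translation_must_match(self):
        with pytest.raises(ValueError):
            GeneModel("g", "sp", "chr1", 1, 9, "+", "ATGGCCGCC", "MAX")

    def test_cds_length_multiple_of_three(self):
        with pytest.raises(ValueError):
            make_gene("g", 1, "ATGGCCGC")

    def test_duplicate_ids_rejected(self):
        g = make_gene("g", 1, "ATGGCCGCC")
        h = make_gene("g", 100, "ATGGCCGCC")
        with pytest.raises(ValueError):
            make_annotation([g, h])

    def test_round_trip_identity_on_simulated_annotation(self, tmp_path, small_scenario):
        ann = small_scenario.annotations["aa"]
        genome_io.write_gff(ann, tmp_path / "aa.gff3")
        genome_io.write_fasta(small_scenario.cds["aa"], tmp_path / "aa.fa")
        back = genome_io.read_gff(
            tmp_path / "aa.gff3",
            genome_io.read_fasta(tmp_path / "aa.fa"),
            species_id="aa",
        )
        assert len(back) == len(ann)
        for a, b in zip(back.genes, ann.genes):
            assert (a.gene_id, a.chromosome, a.start, a.end, a.strand, a.cds) == (
                b.gene_id, b.chromosome, b.start, b.end, b.strand, b.cds,
            )
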