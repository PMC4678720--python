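"""Window extraction, annotation parsing and ortholog-table reading."""

from __future__ import annotations

import numpy as np
import pytest

from irescan import genome_io as gio


def write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadFasta:
    def test_minimal_record(self, tmp_path):
        p = write(tmp_path, "a.fa", ">chr1\nACGT\n")
        asm = gio.read_fasta(p, organism_id="o")
        assert asm.chromosomes == {"chr1": "ACGT"}

    def test_header_token_and_case_u_normalization(self, tmp_path):
        p = write(tmp_path, "a.fa", ">c1 description here\nacgu\n")
        assert gio.read_fasta(p, "o").chromosomes == {"c1": "ACGT"}

    def test_duplicate_name_is_fatal(self, tmp_path):
        p = write(tmp_path, "a.fa", ">a\nACGT\n>a\nGGGG\n")
        with pytest.raises(ValueError, match="duplicate"):
            gio.read_fasta(p, "o")

    def test_non_iupac_character_names_record(self, tmp_path):
        p = write(tmp_path, "a.fa", ">weird\nACXT\n")
        with pytest.raises(ValueError, match="weird"):
            gio.read_fasta(p, "o")

    def test_empty_file_is_fatal(self, tmp_path):
        p = write(tmp_path, "a.fa", "")
        with pytest.raises(ValueError):
            gio.read_fasta(p, "o")

    def test_ambiguity_codes_collapse_to_n(self, tmp_path):
        p = write(tmp_path, "a.fa", ">c\nARYT\n")
        assert gio.read_fasta(p, "o").chromosomes["c"] == "ANNT"


class TestReadAnnotation:
    def test_tsv_row(self, tmp_path):
        p = write(
            tmp_path, "g.tsv",
            "gene_id\tchromosome\tstrand\tcds_start\tcds_end\ng1\tchr1\t+\t101\t400\n",
        )
        (gene,) = gio.read_annotation(p, "tsv", organism_id="o")
        assert (gene.gene_id, gene.strand, gene.cds_start, gene.cds_end) == (
            "g1", "+", 101, 400,
        )

    def test_gff3_multi_exon_span(self, tmp_path):
        gff = (
            "##gff-version 3\n"
            "chr1\tsrc\tgene\t101\t400\t.\t+\t.\tID=gene1\n"
            "chr1\tsrc\tCDS\t101\t200\t.\t+\t0\tID=cds1;Parent=gene1\n"
            "chr1\tsrc\tCDS\t301\t400\t.\t+\t0\tID=cds2;Parent=gene1\n"
        )
        p = write(tmp_path, "g.gff3", gff)
        (gene,) = gio.read_annotation(p, "gff3", organism_id="o")
        assert (gene.cds_start, gene.cds_end) == (101, 400)

    def test_unknown_strand_is_fatal(self, tmp_path):
        p = write(
            tmp_path, "g.tsv",
            "gene_id\tchromosome\tstrand\tcds_start\tcds_end\ng1\tchr1\t.\t101\t400\n",
        )
        with pytest.raises(ValueError, match="strand"):
            gio.read_annotation(p, "tsv", organism_id="o")

    def test_coordinates_outside_chromosome(self, tmp_path, toy_assembly):
        p = write(
            tmp_path, "g.tsv",
            "gene_id\tchromosome\tstrand\tcds_start\tcds_end\ng1\tchr1\t+\t101\t9999\n",
        )
        with pytest.raises(ValueError, match="bounds"):
            gio.read_annotation(p, "tsv", organism_id="toy", assembly=toy_assembly)


class TestUpstreamWindow:
    def test_plus_strand_boundary(self):
        chrom = "A" * 60 + "C" * 60
        asm = gio.OrganismAssembly("o", {"c": chrom})
        gene = gio.GeneModel("g", "o", "c", "+", 61, 120)
        region = gio.extract_upstream_window(asm, gene)
        assert region.sequence == "A" * 60 and region.kind == "utr60"

    def test_minus_strand_reverse_complement(self):
        asm = gio.OrganismAssembly("o", {"c": "A" * 100})
        gene = gio.GeneModel("g", "o", "c", "-", 11, 40)
        region = gio.extract_upstream_window(asm, gene)
        assert region.sequence == "T" * 60

    def test_insufficient_flank_is_skipped(self):
        asm = gio.OrganismAssembly("o", {"c": "A" * 100})
        gene = gio.GeneModel("g", "o", "c", "+", 30, 90)
        assert gio.extract_upstream_window(asm, gene) is None

    def test_strand_symmetry_on_random_genomes(self):
        # extraction from the + strand equals the reverse-complemented
        # extraction from the mirrored genome
        rng = np.random.default_rng(3)
        for _ in range(25):
            L = int(rng.integers(150, 400))
            chrom = "".join(rng.choice(list("ACGT"), size=L))
            start = int(rng.integers(61, L - 10))
            end = min(L, start + 8)
            gene = gio.GeneModel("g", "o", "c", "+", start, end)
            fwd = gio.extract_upstream_window(
                gio.OrganismAssembly("o", {"c": chrom}), gene
            )
            mirror = gio.reverse_complement(chrom)
            mgene = gio.GeneModel(
                "g", "o", "c", "-", L - end + 1, L - start + 1
            )
            rev = gio.extract_upstream_window(
                gio.OrganismAssembly("o", {"c": mirror}), mgene
            )
            assert fwd.sequence == rev.sequence

    def test_all_windows_length_60_and_counts_add_up(self, synthetic_data):
        emitted = skipped = 0
        for gene in synthetic_data.genes:
            region = gio.extract_upstream_window(
                synthetic_data.assemblies[gene.organism_id], gene
            )
            if region is None:
                skipped += 1
            else:
                assert region.length == 60
                emitted += 1
        assert emitted + skipped == len(synthetic_data.genes)


class TestNegativeControlWindow:
    def test_plus_strand_index_arithmetic(self):
        chrom = "".join("ACGT"[i % 4] for i in range(140))
        asm = gio.OrganismAssembly("o", {"c": chrom})
        gene = gio.GeneModel("g", "o", "c", "+", 1, 120)
        region = gio.extract_negative_control_window(asm, gene)
        assert region.sequence == chrom[57:117]  # bases 58..117, 1-based

    def test_short_cds_is_skipped(self):
        asm = gio.OrganismAssembly("o", {"c": "A" * 200})
        gene = gio.GeneModel("g", "o", "c", "+", 1, 30)
        assert gio.extract_negative_control_window(asm, gene) is None

    def test_minus_strand_mirror(self):
        rng = np.random.default_rng(5)
        chrom = "".join(rng.choice(list("ACGT"), size=140))
        asm = gio.OrganismAssembly("o", {"c": chrom})
        plus = gio.GeneModel("g", "o", "c", "+", 1, 120)
        mirror = gio.OrganismAssembly("o", {"c": gio.reverse_complement(chrom)})
        minus = gio.GeneModel("g", "o", "c", "-", 140 - 120 + 1, 140)
        a = gio.extract_negative_control_window(asm, plus)
        b = gio.extract_negative_control_window(mirror, minus)
        assert a.sequence == b.sequence


class TestIntergenicRegion:
    def _asm(self, n=700):
        return gio.OrganismAssembly("o", {"c": "A" * n})

    def test_upstream_neighbor(self):
        a = gio.GeneModel("a", "o", "c", "+", 301, 400)
        b = gio.GeneModel("b", "o", "c", "+", 501, 600)
        region = gio.compute_intergenic_region(b, [a, b], self._asm())
        assert region.length == 100

    def test_first_gene_runs_to_contig_edge(self):
        g = gio.GeneModel("g", "o", "c", "+", 51, 150)
        region = gio.compute_intergenic_region(g, [g], self._asm())
        assert region.length == 50

    def test_abutting_genes_give_length_zero(self):
        a = gio.GeneModel("a", "o", "c", "+", 401, 500)
        b = gio.GeneModel("b", "o", "c", "+", 501, 600)
        region = gio.compute_intergenic_region(b, [a, b], self._asm())
        assert region.length == 0 and region.sequence == ""

    def test_minus_strand_upstream_is_rightward(self):
        a = gio.GeneModel("a", "o", "c", "-", 101, 200)
        b = gio.GeneModel("b", "o", "c", "+", 301, 400)
        region = gio.compute_intergenic_region(a, [a, b], self._asm())
        assert region.length == 100  # 201..300, up to b's cds_start boundary


class TestOrthologTable:
    def test_forward_and_reverse_maps(self, tmp_path):
        p = write(
            tmp_path, "og.tsv",
            "og_id\tgene_id\nOG1\tg1\nOG1\tg2\nOG2\tg3\n",
        )
        table = gio.read_ortholog_groups(p)
        assert set(table.members("OG1")) == {"g1", "g2"}
        assert table.og_of("g3") == "OG2" and table.og_of("gX") is None

    def test_gene_in_two_groups_is_fatal(self, tmp_path):
        p = write(tmp_path, "og.tsv", "og_id\tgene_id\nOG1\tg1\nOG2\tg1\n")
        with pytest.raises(ValueError, match="two groups"):
            gio.read_ortholog_groups(p)

    def test_empty_file_warns_and_is_empty(self, tmp_path):
        p = write(tmp_path, "og.tsv", "")
        assert len(gio.read_ortholog_groups(p)) == 0


def test_windows_fasta_roundtrip(tmp_path):
    regions = [
        gio.RegionSequence("g1", "utr60", "ACGT" * 15),
        gio.RegionSequence("g2", "negctrl60", "TTTT" * 15),
    ]
    path = tmp_path / "w.fasta"
    gio.write_windows_fasta(regions, "orgX", path)
    text = path.read_text()
    assert ">g1|orgX|utr60\n" in text and ">g2|orgX|negctrl60\n" in text
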