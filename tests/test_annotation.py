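"""Gene models, UTR extension, IGR derivation and orientation classes."""

import numpy as np
import pytest

from pombeori.annotation import (
    IGR,
    GeneModel,
    classify_orientation,
    classify_second_orientation,
    compute_rpkm,
    derive_igrs,
    read_genes,
    read_genome,
)
from pombeori.intervals import ArmMask, GenomicInterval
from pombeori.simulate import write_gff, write_simulation

GFF_HEADER = "##gff-version 3\n"


def _write(tmp_path, name, text):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestReadGenome:
    def test_two_record_fasta(self, tmp_path):
        p = _write(tmp_path, "g.fa", ">chrA\nacgt\nACGT\n>chrB\nTTTT\n")
        genome = read_genome(p)
        assert set(genome) == {"chrA", "chrB"}
        assert genome["chrA"] == "ACGTACGT"  # uppercased
        assert len(genome["chrB"]) == 4

    def test_duplicate_names_error(self, tmp_path):
        p = _write(tmp_path, "g.fa", ">chrA\nACGT\n>chrA\nTTTT\n")
        with pytest.raises(ValueError, match="duplicate"):
            read_genome(p)

    def test_empty_file_error(self, tmp_path):
        p = _write(tmp_path, "g.fa", "")
        with pytest.raises(ValueError, match="no records"):
            read_genome(p)

    def test_simulated_genome_round_trip(self, tiny_sim, tmp_path):
        paths = write_simulation(tiny_sim, tmp_path)
        genome = read_genome(paths["fasta"])
        assert genome == tiny_sim.genome


def _gene_gff(chrom, start1, end1, strand, gene_id="g1", extra=""):
    return (
        f"{chrom}\tsrc\tgene\t{start1}\t{end1}\t.\t{strand}\t.\tID={gene_id}{extra}\n"
        f"{chrom}\tsrc\tCDS\t{start1}\t{end1}\t.\t{strand}\t.\t"
        f"ID={gene_id}.c;Parent={gene_id}\n"
    )


class TestReadGenes:
    def test_default_utrs_plus_strand(self, tmp_path):
        # ORF [1000,2000) in 0-based half-open = 1001..2000 in GFF
        p = _write(tmp_path, "a.gff3", GFF_HEADER + _gene_gff("c", 1001, 2000, "+"))
        (g,) = read_genes(p)
        assert (g.tss, g.tts) == (707, 2430)
        assert g.span.start == 707 and g.span.end == 2430

    def test_default_utrs_minus_strand(self, tmp_path):
        p = _write(tmp_path, "a.gff3", GFF_HEADER + _gene_gff("c", 1001, 2000, "-"))
        (g,) = read_genes(p)
        assert (g.tss, g.tts) == (2293, 570)

    def test_tss_clamped_at_chromosome_start(self, tmp_path):
        p = _write(tmp_path, "a.gff3", GFF_HEADER + _gene_gff("c", 101, 400, "+"))
        (g,) = read_genes(p, chrom_lengths={"c": 5000})
        assert g.tss == 0

    def test_explicit_utrs_kept(self, tmp_path):
        body = _gene_gff("c", 1001, 2000, "+") + (
            "c\tsrc\tfive_prime_UTR\t951\t1000\t.\t+\t.\tID=g1.u5;Parent=g1\n"
            "c\tsrc\tthree_prime_UTR\t2001\t2100\t.\t+\t.\tID=g1.u3;Parent=g1\n"
        )
        p = _write(tmp_path, "a.gff3", GFF_HEADER + body)
        (g,) = read_genes(p)
        assert (g.tss, g.tts) == (950, 2100)

    def test_dubious_orf_excluded(self, tmp_path):
        body = _gene_gff("c", 1001, 2000, "+") + _gene_gff(
            "c", 5001, 6000, "+", gene_id="g2", extra=";note=dubious ORF"
        )
        p = _write(tmp_path, "a.gff3", GFF_HEADER + body)
        genes = read_genes(p)
        assert [g.gene_id for g in genes] == ["g1"]

    def test_cds_outside_chromosome_error(self, tmp_path):
        p = _write(tmp_path, "a.gff3", GFF_HEADER + _gene_gff("c", 1001, 2000, "+"))
        with pytest.raises(ValueError, match="outside"):
            read_genes(p, chrom_lengths={"c": 1500})

    def test_missing_strand_error(self, tmp_path):
        p = _write(tmp_path, "a.gff3", GFF_HEADER + _gene_gff("c", 1001, 2000, "."))
        with pytest.raises(ValueError, match="strand"):
            read_genes(p)

    def test_read_is_idempotent(self, tiny_sim, tmp_path):
        gff = tmp_path / "genes.gff3"
        write_gff(tiny_sim.genes, gff)
        genes1 = read_genes(gff)
        write_gff(genes1, tmp_path / "again.gff3")
        genes2 = read_genes(tmp_path / "again.gff3")
        assert [(g.gene_id, g.tss, g.tts) for g in genes1] == [
            (g.gene_id, g.tss, g.tts) for g in genes2
        ]


def _gene(chrom, span_start, span_end, strand, gene_id="g"):
    """Gene whose transcribed span is exactly [span_start, span_end)."""
    if strand == "+":
        orf = GenomicInterval(chrom, span_start + 10, span_end - 10, "+")
        return GeneModel(gene_id, orf, span_start, span_end)
    orf = GenomicInterval(chrom, span_start + 10, span_end - 10, "-")
    return GeneModel(gene_id, orf, span_end, span_start)


class TestDeriveIgrs:
    def test_two_genes_on_an_arm(self):
        genes = [_gene("c", 0, 500, "+", "a"), _gene("c", 800, 1200, "+", "b")]
        igrs = derive_igrs(genes, ArmMask(), {"c": 1500})
        assert [(i.interval.start, i.interval.end) for i in igrs] == [
            (500, 800), (1200, 1500),
        ]
        assert igrs[0].orientation == "tandem"
        assert igrs[1].orientation == "edge"

    def test_overlapping_genes_leave_no_igr(self):
        genes = [_gene("c", 0, 600, "+", "a"), _gene("c", 500, 1200, "+", "b")]
        igrs = derive_igrs(genes, ArmMask(), {"c": 1200})
        assert igrs == []

    def test_planted_igrs_recovered_exactly(self, tiny_sim):
        igrs = derive_igrs(
            tiny_sim.genes, tiny_sim.mask, tiny_sim.truth.chrom_lengths
        )
        derived = {(i.interval.chrom, i.interval.start, i.interval.end)
                   for i in igrs}
        planted = {(c, s, e) for c, s, e, _cls in tiny_sim.truth.igr_classes}
        assert planted == derived

    def test_gene_spans_and_igrs_tile_each_arm(self, tiny_sim):
        igrs = derive_igrs(
            tiny_sim.genes, tiny_sim.mask, tiny_sim.truth.chrom_lengths
        )
        for chrom, length in tiny_sim.truth.chrom_lengths.items():
            cover = np.zeros(length, dtype=int)
            for g in tiny_sim.genes:
                if g.orf.chrom == chrom:
                    cover[g.span.start : g.span.end] += 1
            for i in igrs:
                if i.interval.chrom == chrom:
                    cover[i.interval.start : i.interval.end] += 1
            arms = tiny_sim.mask.arms({chrom: length})[chrom]
            arm_mask = np.zeros(length, dtype=bool)
            for a in arms:
                arm_mask[a.start : a.end] = True
            assert (cover[arm_mask] == 1).all()  # no gap, no overlap on arms
            assert (cover[~arm_mask] == 0).all()


class TestOrientation:
    @pytest.mark.parametrize(
        "left_strand,right_strand,expected",
        [("-", "+", "divergent"), ("+", "-", "convergent"),
         ("+", "+", "tandem"), ("-", "-", "tandem")],
    )
    def test_flanking_strand_rule(self, left_strand, right_strand, expected):
        igr = IGR(
            GenomicInterval("c", 500, 800),
            _gene("c", 0, 500, left_strand, "L"),
            _gene("c", 800, 1200, right_strand, "R"),
        )
        assert classify_orientation(igr) == expected

    def test_edge_when_flank_missing(self):
        igr = IGR(GenomicInterval("c", 500, 800), None,
                  _gene("c", 800, 1200, "+", "R"))
        assert classify_orientation(igr) == "edge"

    @pytest.mark.parametrize(
        "strands",
        [("-", "+", "-", "+"), ("+", "-", "+", "-"), ("+", "-", "-", "+")],
    )
    def test_second_orientation_uses_outer_genes(self, strands):
        s1, s2, s3, s4 = strands
        genes = [
            _gene("c", 0, 300, s1, "g1"),
            _gene("c", 400, 700, s2, "g2"),
            _gene("c", 900, 1200, s3, "g3"),
            _gene("c", 1300, 1600, s4, "g4"),
        ]
        igr = IGR(GenomicInterval("c", 700, 900), genes[1], genes[2])
        # second flanks are g1 (left) and g4 (right)
        expected_cls = classify_orientation(
            IGR(GenomicInterval("c", 700, 900), genes[0], genes[3])
        )
        assert classify_second_orientation(igr, genes) == expected_cls

    def test_reflection_invariance(self, tiny_sim):
        """Mirroring the chromosome preserves every orientation class."""
        igrs = derive_igrs(
            tiny_sim.genes, tiny_sim.mask, tiny_sim.truth.chrom_lengths
        )
        length = tiny_sim.truth.chrom_lengths["chr1"]
        flip = {"+": "-", "-": "+"}
        mirrored_genes = []
        for g in tiny_sim.genes:
            span = g.span
            mirrored_genes.append(
                _gene("chr1", length - span.end, length - span.start,
                      flip[g.strand], g.gene_id)
            )
        mirrored = derive_igrs(mirrored_genes, tiny_sim.mask, {"chr1": length})
        orig = sorted(
            (i.interval.start, i.orientation) for i in igrs
            if i.orientation != "edge"
        )
        mirr = sorted(
            (length - i.interval.end, i.orientation) for i in mirrored
            if i.orientation != "edge"
        )
        assert orig == mirr


class TestRpkm:
    def test_hand_values(self):
        g = _gene("c", 0, 1020, "+")
        g.exon_length = 1000
        assert compute_rpkm(g, 10, 1e6) == pytest.approx(10.0)
        assert compute_rpkm(g, 0, 1e6) == 0.0
        g.exon_length = 2000
        assert compute_rpkm(g, 57, 5.7e6) == pytest.approx(5.0)

    def test_zero_total_error(self):
        g = _gene("c", 0, 1020, "+")
        with pytest.raises(ValueError):
            compute_rpkm(g, 10, 0)
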