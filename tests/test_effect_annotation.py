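"""Consequence classification against gene models and reference sequence."""

import numpy as np
import pytest
from Bio.Seq import Seq

from vdmap import (
    GenomeModel,
    Variant,
    annotate_variant,
    classify_consequence,
    locate_in_gene,
    protein_label,
    translate_cds,
)
from vdmap.effect_annotation import AnnotationDataError, reverse_complement
from vdmap.synthetic_cross import _make_gene


def bio_translate(cds: str) -> str:
    """Independent full-length translation (no early stop truncation)."""
    return str(Seq(cds).translate())


def oracle_consequence(v, gene, reference):
    """Whole-CDS oracle: compare full translations of reference and
    mutated CDS, independent of the per-codon implementation path."""
    mutated = reference[: v.pos - 1] + v.alt + reference[v.pos :]

    def cds_of(seq):
        s = "".join(seq[a - 1 : b] for a, b in gene.cds)
        return reverse_complement(s) if gene.strand == "-" else s

    prot_ref = bio_translate(cds_of(reference))
    prot_alt = bio_translate(cds_of(mutated))
    if prot_ref == prot_alt:
        return "synonymous"
    diff = next(i for i, (a, b) in enumerate(zip(prot_ref, prot_alt)) if a != b)
    if prot_alt[diff] == "*":
        return "stop_gained"
    if prot_ref[diff] == "*":
        return "stop_lost"
    return "missense"


def make_toy_genome(seed, strand="+", exons=((101, 200), (301, 420), (501, 562))):
    rng = np.random.default_rng(seed)
    length = 1_000
    seq = bytearray(b"ACGT"[i] for i in rng.integers(0, 4, size=length))
    gene, overlay = _make_gene("toy", "chrT", strand, exons, rng)
    for pos, base in overlay.items():
        seq[pos - 1] = ord(base)
    reference = seq.decode()
    return gene, reference


class TestTranslateCds:
    def test_start_plus_stop(self):
        assert translate_cds("ATGTAA") == "M*"

    def test_matches_per_codon_table_lookup(self):
        rng = np.random.default_rng(3)
        cds = "".join("ACGT"[i] for i in rng.integers(0, 4, size=900))
        expected = bio_translate(cds)
        if "*" in expected:
            expected = expected[: expected.index("*") + 1]
        assert translate_cds(cds) == expected

    def test_length_not_codon_multiple_rejected(self):
        with pytest.raises(ValueError):
            translate_cds("ATGT")

    def test_fixture_slbp_codon_180_is_tyrosine(self, packaged_bundle):
        slbp = next(g for g in packaged_bundle.genome.genes if g.gene_id == "slbp")
        ref = packaged_bundle.genome.reference["chr14"]
        cds = "".join(ref[s - 1 : e] for s, e in slbp.cds)
        assert translate_cds(cds)[179] == "Y"


class TestLocateInGene:
    def test_fixture_stop_variant_in_fifth_exon(self, packaged_bundle):
        slbp = next(g for g in packaged_bundle.genome.genes if g.gene_id == "slbp")
        v = Variant("chr14", 14_800_000, "C", "A")
        region = locate_in_gene(v, slbp)
        assert (region.kind, region.exon_index) == ("cds", 5)

    def test_splice_windows_are_two_intronic_bases(self, packaged_bundle):
        gene = next(g for g in packaged_bundle.genome.genes if g.gene_id == "gene02")
        exon1_end = gene.exons[0][1]
        kinds = [
            locate_in_gene(Variant("chr14", exon1_end + off, "A", "G"), gene).kind
            for off in (1, 2, 3)
        ]
        assert kinds == ["splice_donor", "splice_donor", "intron"]

    def test_acceptor_window_before_downstream_exon(self, packaged_bundle):
        gene = next(g for g in packaged_bundle.genome.genes if g.gene_id == "gene02")
        exon2_start = gene.exons[1][0]
        region = locate_in_gene(Variant("chr14", exon2_start - 1, "A", "G"), gene)
        assert region.kind == "splice_acceptor"

    def test_minus_strand_swaps_donor_and_acceptor(self):
        gene, _ = make_toy_genome(5, strand="-")
        exon1_end = gene.exons[0][1]  # genomic-left exon is the last transcribed
        region = locate_in_gene(Variant("chrT", exon1_end + 1, "A", "G"), gene)
        assert region.kind == "splice_acceptor"

    def test_far_upstream_is_intergenic(self, packaged_bundle):
        slbp = next(g for g in packaged_bundle.genome.genes if g.gene_id == "slbp")
        v = Variant("chr14", slbp.start - 10_000, "A", "G")
        assert locate_in_gene(v, slbp).kind == "intergenic"


class TestClassifyConsequence:
    def test_tac_to_taa_is_stop_gained(self, packaged_bundle):
        slbp = next(g for g in packaged_bundle.genome.genes if g.gene_id == "slbp")
        ref = packaged_bundle.genome.reference["chr14"]
        a = classify_consequence(Variant("chr14", 14_800_000, "C", "A"), slbp, ref)
        assert a.consequence == "stop_gained"
        assert a.codon_change == ("TAC", "TAA")
        assert a.protein_label == "Y180stop"

    def test_tac_to_tat_is_synonymous(self, packaged_bundle):
        slbp = next(g for g in packaged_bundle.genome.genes if g.gene_id == "slbp")
        ref = packaged_bundle.genome.reference["chr14"]
        a = classify_consequence(Variant("chr14", 14_800_000, "C", "T"), slbp, ref)
        assert a.consequence == "synonymous"
        assert a.codon_change == ("TAC", "TAT")

    def test_reference_mismatch_names_position(self, packaged_bundle):
        slbp = next(g for g in packaged_bundle.genome.genes if g.gene_id == "slbp")
        ref = packaged_bundle.genome.reference["chr14"]
        base = ref[14_799_999]
        wrong = next(b for b in "ACGT" if b not in (base, "A"))
        with pytest.raises(AnnotationDataError, match="14800000"):
            classify_consequence(Variant("chr14", 14_800_000, wrong, "A"), slbp, ref)

    @pytest.mark.parametrize("strand", ["+", "-"])
    def test_random_cds_substitutions_match_whole_cds_oracle(self, strand):
        # 500 random substitutions per strand against the independent
        # full-translation oracle
        gene, reference = make_toy_genome(11 if strand == "+" else 12, strand=strand)
        rng = np.random.default_rng(99)
        cds_positions = [p for s, e in gene.cds for p in range(s, e + 1)]
        for _ in range(500):
            pos = int(rng.choice(cds_positions))
            ref_base = reference[pos - 1]
            alt_base = "ACGT"[int(rng.integers(0, 4))]
            if alt_base == ref_base:
                continue
            v = Variant("chrT", pos, ref_base, alt_base)
            got = classify_consequence(v, gene, reference).consequence
            assert got == oracle_consequence(v, gene, reference)

    def test_strand_symmetry_under_genome_mirroring(self):
        # annotating the reverse-complement mirror of the genome with the
        # mirrored gene yields identical consequences
        gene, reference = make_toy_genome(21, strand="+")
        length = len(reference)
        mirror_ref = reverse_complement(reference)
        mirror_exons = tuple(
            sorted((length + 1 - e, length + 1 - s) for s, e in gene.exons)
        )
        from vdmap import GeneModel

        mirror_gene = GeneModel("toy_rc", "chrT", "-", mirror_exons, mirror_exons)
        rng = np.random.default_rng(5)
        cds_positions = [p for s, e in gene.cds for p in range(s, e + 1)]
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for _ in range(100):
            pos = int(rng.choice(cds_positions))
            ref_base = reference[pos - 1]
            alt_base = next(b for b in "ACGT" if b != ref_base)
            fwd = classify_consequence(
                Variant("chrT", pos, ref_base, alt_base), gene, reference
            )
            rev = classify_consequence(
                Variant("chrT", length + 1 - pos, comp[ref_base], comp[alt_base]),
                mirror_gene,
                mirror_ref,
            )
            assert fwd.consequence == rev.consequence
            assert fwd.protein_label == rev.protein_label

    def test_indel_classified_as_indel(self, packaged_bundle):
        slbp = next(g for g in packaged_bundle.genome.genes if g.gene_id == "slbp")
        ref = packaged_bundle.genome.reference["chr14"]
        v = Variant("chr14", 14_800_000, "C", "CA")
        assert classify_consequence(v, slbp, ref).consequence == "indel"


class TestProteinLabel:
    def test_missense_label_form(self):
        gene, reference = make_toy_genome(31)
        # force codon 10 to GCA (Ala) and mutate middle base to make GAA (Glu)
        from vdmap.synthetic_cross import _genomic_pos_of_cds_coord

        pos = _genomic_pos_of_cds_coord(gene, 29)  # codon 10, 2nd base
        seq = list(reference)
        c1 = _genomic_pos_of_cds_coord(gene, 28)
        c3 = _genomic_pos_of_cds_coord(gene, 30)
        seq[c1 - 1], seq[pos - 1], seq[c3 - 1] = "G", "C", "A"
        reference = "".join(seq)
        a = classify_consequence(Variant("chrT", pos, "C", "A"), gene, reference)
        assert a.protein_label == "A10E"

    def test_synonymous_label_repeats_residue(self, packaged_bundle):
        slbp = next(g for g in packaged_bundle.genome.genes if g.gene_id == "slbp")
        ref = packaged_bundle.genome.reference["chr14"]
        from vdmap.synthetic_cross import _genomic_pos_of_cds_coord

        pos = _genomic_pos_of_cds_coord(slbp, 300)  # codon 100 = CTC (Leu)
        a = classify_consequence(Variant("chr14", pos, "C", "T"), slbp, ref)
        assert a.consequence == "synonymous"
        assert a.protein_label == "L100L"

    def test_non_coding_annotation_rejected(self, packaged_bundle):
        ref = packaged_bundle.genome.reference["chr14"]
        base = ref[999]
        alt = "A" if base != "A" else "G"
        a = annotate_variant(Variant("chr14", 1_000, base, alt), packaged_bundle.genome)
        assert a.consequence == "intergenic"
        with pytest.raises(ValueError):
            protein_label(a)


def test_overlapping_genes_keep_most_severe(packaged_bundle):
    # the stop variant annotated against the whole genome resolves to slbp
    a = annotate_variant(Variant("chr14", 14_800_000, "C", "A"), packaged_bundle.genome)
    assert (a.gene_id, a.consequence) == ("slbp", "stop_gained")
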