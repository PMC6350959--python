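"""Coding-consequence annotation of variants against toy gene models.

Each single-nucleotide variant is located within a gene (CDS exon, splice
window, intron, UTR, intergenic), and CDS substitutions are classified by
translating the affected codon with the standard genetic code, producing
labels of the form ``Y180stop`` (tyrosine at CDS codon 180 replaced by a
termination codon).

Conventions:

* CDS codon numbering starts at 1 at the annotated CDS start.
* Splice windows are the 2 intronic bases flanking each exon boundary —
  the canonical GT (donor, 3' of an exon in transcription orientation) and
  AG (acceptor, 5' of an exon).
* One gene model per gene (no isoforms); a variant overlapping several
  genes is annotated against each and the most severe consequence is kept.
* Stop codons are written ``stop`` in labels, mirroring field usage; ``*``
  is used internally.
"""

from __future__ import annotations

from dataclasses import dataclass

from .variant_io import GeneModel, GenomeModel, Variant

# standard genetic code, DNA alphabet
CODON_TABLE: dict[str, str] = {}
_BASES = "TCAG"
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
for _i, _b1 in enumerate(_BASES):
    for _j, _b2 in enumerate(_BASES):
        for _k, _b3 in enumerate(_BASES):
            CODON_TABLE[_b1 + _b2 + _b3] = _AA[16 * _i + 4 * _j + _k]

STOP_CODONS = frozenset(c for c, aa in CODON_TABLE.items() if aa == "*")

_COMPLEMENT = str.maketrans("ACGT", "TGCA")

#: consequence classes ordered most to least severe; used when a variant
#: overlaps several genes and for candidate ranking downstream.
SEVERITY_ORDER = (
    "stop_gained",
    "stop_lost",
    "splice_donor",
    "splice_acceptor",
    "missense",
    "indel",
    "synonymous",
    "UTR",
    "intronic",
    "intergenic",
)

CODING_CONSEQUENCES = frozenset(
    {"synonymous", "missense", "stop_gained", "stop_lost"}
)
PROTEIN_CODING_CONSEQUENCES = frozenset(
    {"missense", "stop_gained", "stop_lost", "splice_donor", "splice_acceptor"}
)


class AnnotationDataError(ValueError):
    """Reference sequence disagrees with a variant's stated ref allele."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate_cds(cds: str) -> str:
    """Translate a CDS with the standard genetic code.

    Translation stops at — and includes — the first stop codon, reported
    as ``*``.  Length must be divisible by 3.
    """
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    cds = cds.upper()
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i : i + 3]
        if any(b not in "ACGT" for b in codon):
            raise ValueError(f"invalid base in codon {codon!r}")
        aa = CODON_TABLE[codon]
        out.append(aa)
        if aa == "*":
            break
    return "".join(out)


@dataclass(frozen=True)
class GeneRegion:
    """Where a position falls within one gene model.

    ``kind`` is one of ``cds``, ``splice_donor``, ``splice_acceptor``,
    ``intron``, ``UTR``, ``intergenic``.  ``exon_index`` is the 1-based
    exon number in *transcription* orientation for positions inside an
    exon, else ``None``.
    """

    kind: str
    exon_index: int | None = None


@dataclass(frozen=True)
class AnnotatedVariant:
    variant: Variant
    gene_id: str | None
    region: GeneRegion
    consequence: str
    codon_change: tuple[str, str] | None = None
    protein_label: str | None = None

    @property
    def pos(self) -> int:
        return self.variant.pos

    @property
    def chrom(self) -> str:
        return self.variant.chrom


def _transcription_exon_index(g: GeneModel, genomic_index: int) -> int:
    """Convert a 0-based genomic-order exon index to 1-based transcription order."""
    if g.strand == "+":
        return genomic_index + 1
    return g.n_exons - genomic_index


def locate_in_gene(v: Variant, g: GeneModel) -> GeneRegion:
    """Locate a variant's position within one gene model.

    Splice windows are the two intronic bases flanking internal exon
    boundaries; the donor window sits 3' of an exon in transcription
    orientation, the acceptor window 5'.
    """
    if v.chrom != g.chrom:
        raise ValueError(f"variant on {v.chrom} but gene {g.gene_id} on {g.chrom}")
    pos = v.pos
    if pos < g.start or pos > g.end:
        return GeneRegion("intergenic")
    for i, (s, e) in enumerate(g.exons):
        if s <= pos <= e:
            if any(cs <= pos <= ce for cs, ce in g.cds):
                return GeneRegion("cds", _transcription_exon_index(g, i))
            return GeneRegion("UTR", _transcription_exon_index(g, i))
    # intronic: find the flanking intron
    for i in range(g.n_exons - 1):
        left_end = g.exons[i][1]
        right_start = g.exons[i + 1][0]
        if left_end < pos < right_start:
            # genomic-left window is 3' of the upstream exon on '+' (donor),
            # 5' of the downstream exon on '-' (acceptor); vice versa right.
            if pos <= left_end + 2:
                return GeneRegion("splice_donor" if g.strand == "+" else "splice_acceptor")
            if pos >= right_start - 2:
                return GeneRegion("splice_acceptor" if g.strand == "+" else "splice_donor")
            return GeneRegion("intron")
    return GeneRegion("intron")  # unreachable for valid models


def _cds_sequence(g: GeneModel, reference: str) -> str:
    """CDS in transcription orientation from the chromosome sequence."""
    seq = "".join(reference[s - 1 : e] for s, e in g.cds)
    return reverse_complement(seq) if g.strand == "-" else seq.upper()


def _cds_coordinate(g: GeneModel, pos: int) -> int:
    """1-based coordinate of a genomic position within the CDS (transcription order)."""
    offset = 0
    plus_coord = None
    for s, e in g.cds:
        if s <= pos <= e:
            plus_coord = offset + (pos - s + 1)
            break
        offset += e - s + 1
    if plus_coord is None:
        raise ValueError(f"position {pos} not in CDS of {g.gene_id}")
    if g.strand == "-":
        return g.cds_length - plus_coord + 1
    return plus_coord


def classify_consequence(
    v: Variant, g: GeneModel, reference: str
) -> AnnotatedVariant:
    """Classify one variant against one gene model.

    ``reference`` is the full chromosome sequence.  For CDS substitutions
    the reference and alternate codons are built from the strand-corrected
    CDS and translated; the consequence follows from the amino-acid change.
    The reference base at the variant position must equal the variant's
    ref allele.
    """
    seq = reference
    if v.is_snv:
        base = seq[v.pos - 1].upper()
        if base != v.ref:
            raise AnnotationDataError(
                f"reference base {base} at {v.chrom}:{v.pos} != variant ref {v.ref}"
            )
    region = locate_in_gene(v, g)
    gene_id = g.gene_id if region.kind != "intergenic" else None
    if not v.is_snv:
        return AnnotatedVariant(v, gene_id, region, "indel")
    if region.kind in ("splice_donor", "splice_acceptor"):
        return AnnotatedVariant(v, g.gene_id, region, region.kind)
    if region.kind in ("UTR", "intron", "intergenic"):
        cons = {"UTR": "UTR", "intron": "intronic", "intergenic": "intergenic"}[region.kind]
        return AnnotatedVariant(v, gene_id, region, cons)

    # CDS substitution
    cds_seq = _cds_sequence(g, seq)
    c = _cds_coordinate(g, v.pos)
    codon_number = (c - 1) // 3 + 1
    within = (c - 1) % 3
    codon_start = (codon_number - 1) * 3
    ref_codon = cds_seq[codon_start : codon_start + 3]
    alt_base = v.alt if g.strand == "+" else v.alt.translate(_COMPLEMENT)
    alt_codon = ref_codon[:within] + alt_base + ref_codon[within + 1 :]
    ref_aa = CODON_TABLE[ref_codon]
    alt_aa = CODON_TABLE[alt_codon]
    if ref_aa == alt_aa:
        cons = "synonymous"
    elif alt_aa == "*":
        cons = "stop_gained"
    elif ref_aa == "*":
        cons = "stop_lost"
    else:
        cons = "missense"
    return AnnotatedVariant(
        v, g.gene_id, region, cons,
        codon_change=(ref_codon, alt_codon),
        protein_label=_label(ref_aa, codon_number, alt_aa),
    )


def _label(ref_aa: str, codon_number: int, alt_aa: str) -> str:
    r = "stop" if ref_aa == "*" else ref_aa
    a = "stop" if alt_aa == "*" else alt_aa
    return f"{r}{codon_number}{a}"


def protein_label(a: AnnotatedVariant) -> str:
    """Protein-change label for a coding annotation, e.g. ``Y180stop``."""
    if a.consequence not in CODING_CONSEQUENCES or a.protein_label is None:
        raise ValueError(f"no protein label for consequence {a.consequence!r}")
    return a.protein_label


def annotate_variant(v: Variant, genome: GenomeModel) -> AnnotatedVariant:
    """Annotate a variant against all overlapping genes; keep the most severe.

    With no overlapping gene on the chromosome the variant is intergenic.
    """
    candidates: list[AnnotatedVariant] = []
    for g in genome.genes_on(v.chrom):
        candidates.append(classify_consequence(v, g, genome.reference[v.chrom]))
    scored = [a for a in candidates if a.consequence != "intergenic"]
    if not scored:
        if v.is_snv and v.chrom in genome.reference:
            base = genome.reference[v.chrom][v.pos - 1].upper()
            if base != v.ref:
                raise AnnotationDataError(
                    f"reference base {base} at {v.chrom}:{v.pos} != variant ref {v.ref}"
                )
        return AnnotatedVariant(v, None, GeneRegion("intergenic"), "intergenic")
    return min(scored, key=lambda a: SEVERITY_ORDER.index(a.consequence))


def annotate_table(table, genome: GenomeModel) -> list[AnnotatedVariant]:
    """Annotate every variant in a table, preserving table order."""
    return [annotate_variant(v, genome) for v in table]
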