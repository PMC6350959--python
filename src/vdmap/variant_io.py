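"""Readers and writers for the standard formats the pipeline touches.

Variants travel as VCF 4.2 with per-sample ``AD`` allele depths; gene models
as GFF3 (1-based, closed intervals); toy reference sequences as FASTA; and
SSLP marker panels as three-column TSV.  Everything is validated into the
internal types on load so downstream stages can assume the invariants.

All coordinates are 1-based throughout the package, matching the VCF and
GFF3 standards; no half-open conversion layer exists anywhere.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pysam
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

log = logging.getLogger(__name__)

ZYGOSITY_LABELS = ("unclassified", "hom_alt", "het", "low_confidence")
SOURCE_LABELS = ("mutant_pool", "sibling_pool", "strain_list")

_BASES = frozenset("ACGT")


class VcfFormatError(ValueError):
    """A VCF record lacks required fields (e.g. allele depths)."""


class GffValidationError(ValueError):
    """A gene model violates a structural invariant."""


class MarkerParseError(ValueError):
    """A marker-table row cannot be parsed."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Variant:
    """A bi-allelic called sequence variant with pooled allele depths.

    ``zygosity`` is the pool-level call: ``hom_alt`` means the alternate
    (mutagenized-strain) allele is effectively fixed in the pool, ``het``
    that both alleles segregate.  ``source`` records which sample the call
    came from.
    """

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    ref_depth: int = 0
    alt_depth: int = 0
    zygosity: str = "unclassified"
    source: str = "mutant_pool"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref!r}) at {self.chrom}:{self.pos}")
        if self.ref_depth < 0 or self.alt_depth < 0:
            raise ValueError("allele depths must be non-negative")
        if self.zygosity not in ZYGOSITY_LABELS:
            raise ValueError(f"unknown zygosity label {self.zygosity!r}")
        if self.source not in SOURCE_LABELS:
            raise ValueError(f"unknown source label {self.source!r}")

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def total_depth(self) -> int:
        return self.ref_depth + self.alt_depth

    @property
    def alt_fraction(self) -> float:
        """Alternate-allele read fraction; 0.0 at zero depth."""
        d = self.total_depth
        return self.alt_depth / d if d else 0.0

    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    def with_zygosity(self, zygosity: str) -> "Variant":
        return replace(self, zygosity=zygosity)


@dataclass(frozen=True)
class VariantTable:
    """Sorted, duplicate-free collection of variants.

    Records are ordered by (chrom, pos, ref, alt); the same key never
    appears twice.  Construct through :meth:`from_records`, which sorts
    and rejects duplicates.
    """

    records: tuple[Variant, ...] = ()

    @classmethod
    def from_records(cls, records: Iterable[Variant]) -> "VariantTable":
        recs = sorted(records, key=lambda v: v.key)
        seen: set[tuple[str, int, str, str]] = set()
        for v in recs:
            if v.key in seen:
                raise ValueError(f"duplicate variant key {v.key}")
            seen.add(v.key)
        return cls(tuple(recs))

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {v.key for v in self.records}

    def chroms(self) -> list[str]:
        return sorted({v.chrom for v in self.records})


@dataclass(frozen=True)
class GeneModel:
    """A single-isoform gene: exons and CDS as 1-based closed intervals.

    Exons are stored in genomic order regardless of strand; ``strand``
    records transcription orientation.  The CDS must be contained in exons
    and its total length divisible by 3.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    cds: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise GffValidationError(f"{self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise GffValidationError(f"{self.gene_id}: no exons")
        prev_end = 0
        for s, e in self.exons:
            if s < 1 or e < s:
                raise GffValidationError(f"{self.gene_id}: bad exon interval ({s}, {e})")
            if s <= prev_end:
                raise GffValidationError(
                    f"{self.gene_id}: exons unsorted or overlapping at ({s}, {e})"
                )
            prev_end = e
        for cs, ce in self.cds:
            if not any(s <= cs and ce <= e for s, e in self.exons):
                raise GffValidationError(
                    f"{self.gene_id}: CDS interval ({cs}, {ce}) not contained in any exon"
                )
        if self.cds_length % 3 != 0:
            raise GffValidationError(
                f"{self.gene_id}: CDS length {self.cds_length} not divisible by 3"
            )

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    @property
    def n_exons(self) -> int:
        return len(self.exons)


@dataclass(frozen=True)
class MarkerPanel:
    """SSLP markers: (marker_id, chrom, pos) with unique ids."""

    markers: tuple[tuple[str, str, int], ...] = ()

    def __post_init__(self) -> None:
        ids = [m[0] for m in self.markers]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate marker ids")
        for mid, _, pos in self.markers:
            if pos < 1:
                raise ValueError(f"marker {mid}: position must be >= 1")

    def __len__(self) -> int:
        return len(self.markers)

    def position(self, marker_id: str) -> tuple[str, int]:
        for mid, chrom, pos in self.markers:
            if mid == marker_id:
                return chrom, pos
        raise KeyError(marker_id)

    def interval(self, left: str, right: str) -> tuple[str, int, int]:
        """Closed interval between two markers on the same chromosome."""
        c1, p1 = self.position(left)
        c2, p2 = self.position(right)
        if c1 != c2:
            raise ValueError(f"markers {left} and {right} on different chromosomes")
        return c1, min(p1, p2), max(p1, p2)


@dataclass(frozen=True)
class GenomeModel:
    """Toy genome: chromosome lengths, reference sequence and gene models."""

    chrom_lengths: Mapping[str, int]
    reference: Mapping[str, str]
    genes: tuple[GeneModel, ...] = ()

    def genes_on(self, chrom: str) -> list[GeneModel]:
        return [g for g in self.genes if g.chrom == chrom]


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def _info_field(rec: "pysam.VariantRecord", key: str):
    # pysam raises ValueError("Invalid header") when querying an INFO key
    # the header does not declare; treat that as absent
    try:
        if key in rec.info:
            return rec.info[key]
    except ValueError:
        pass
    return None


def _depths_for_alt(rec: "pysam.VariantRecord", alt_index: int) -> tuple[int, int]:
    """Extract (ref_depth, alt_depth) for one alt allele of a record."""
    if rec.samples and "AD" in rec.format:
        ad = rec.samples[0].get("AD")
        if ad is not None and ad[0] is not None and len(ad) > alt_index + 1:
            return int(ad[0]), int(ad[alt_index + 1])
    info_ad = _info_field(rec, "AD")
    if info_ad is not None:
        vals = info_ad if isinstance(info_ad, tuple) else (info_ad,)
        if len(vals) > alt_index + 1 and vals[0] is not None:
            return int(vals[0]), int(vals[alt_index + 1])
    raise VcfFormatError(
        f"record {rec.chrom}:{rec.pos} {rec.ref}>{','.join(rec.alts or ())}: "
        "no AD allele depths in FORMAT or INFO"
    )


def read_vcf(path: str | Path, source: str | None = None) -> VariantTable:
    """Read a VCF 4.x into a :class:`VariantTable`.

    Multi-allelic records are split into one variant per alt allele.  The
    zygosity call is taken from the ``ZYG`` INFO key when present, else
    ``unclassified``.  ``source`` overrides the ``SRC`` INFO key; when
    neither is given the default is ``mutant_pool``.  Unsorted input is
    sorted on load with a logged notice.
    """
    records: list[Variant] = []
    last_key: tuple[str, int] | None = None
    sorted_in = True
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if last_key is not None and (rec.chrom, rec.pos) < last_key:
                sorted_in = False
            last_key = (rec.chrom, rec.pos)
            zyg = _info_field(rec, "ZYG") or "unclassified"
            src = source or _info_field(rec, "SRC") or "mutant_pool"
            for i, alt in enumerate(rec.alts or ()):
                rd, ad = _depths_for_alt(rec, i)
                records.append(
                    Variant(
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        ref_depth=rd,
                        alt_depth=ad,
                        zygosity=zyg,
                        source=src,
                    )
                )
    if not sorted_in:
        log.info("input VCF %s was unsorted; records sorted on load", path)
    return VariantTable.from_records(records)


def _vcf_header(
    table: VariantTable, chrom_lengths: Mapping[str, int] | None
) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    chroms = dict.fromkeys(table.chroms())
    if chrom_lengths:
        chroms.update(dict.fromkeys(chrom_lengths))
    for chrom in chroms:
        length = (chrom_lengths or {}).get(chrom)
        if length:
            header.contigs.add(chrom, length=length)
        else:
            header.contigs.add(chrom)
    header.add_meta(
        "INFO",
        items=[("ID", "ZYG"), ("Number", "1"), ("Type", "String"),
               ("Description", "Pool zygosity call")],
    )
    header.add_meta(
        "INFO",
        items=[("ID", "SRC"), ("Number", "1"), ("Type", "String"),
               ("Description", "Sample source label")],
    )
    header.add_meta(
        "FORMAT",
        items=[("ID", "AD"), ("Number", "R"), ("Type", "Integer"),
               ("Description", "Allelic read depths (ref, alt)")],
    )
    header.add_sample("POOL")
    return header


def write_vcf(
    table: VariantTable,
    path: str | Path,
    chrom_lengths: Mapping[str, int] | None = None,
) -> None:
    """Write a sorted VCF 4.2 with AD depths and ZYG/SRC INFO tags."""
    header = _vcf_header(table, chrom_lengths)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for v in table:
            rec = out.new_record(
                contig=v.chrom,
                start=v.pos - 1,
                stop=v.pos - 1 + len(v.ref),
                alleles=(v.ref, v.alt),
            )
            rec.info["ZYG"] = v.zygosity
            rec.info["SRC"] = v.source
            rec.samples["POOL"]["AD"] = (v.ref_depth, v.alt_depth)
            out.write(rec)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3(path: str | Path) -> tuple[GeneModel, ...]:
    """Read gene/exon/CDS features from a GFF3 file into gene models.

    One :class:`GeneModel` per ``gene`` feature; exon and CDS children are
    associated through GFF3 ``Parent`` attributes (directly or via an
    mRNA).  Structural invariants are enforced; violations raise
    :class:`GffValidationError` naming the gene.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = sorted(
            (f.start, f.end)
            for f in db.children(gene, featuretype="exon", order_by="start")
        )
        cds = sorted(
            (f.start, f.end)
            for f in db.children(gene, featuretype="CDS", order_by="start")
        )
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=tuple(exons),
                cds=tuple(cds),
            )
        )
    return tuple(genes)


def write_gff3(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Emit gene models as GFF3 (gene + exon + CDS rows, 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.start)):
            fh.write(
                f"{g.chrom}\tvdmap\tgene\t{g.start}\t{g.end}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tvdmap\texon\t{s}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )
            for i, (s, e) in enumerate(g.cds, start=1):
                fh.write(
                    f"{g.chrom}\tvdmap\tCDS\t{s}\t{e}\t.\t{g.strand}\t0\t"
                    f"ID={g.gene_id}.cds{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into {name: uppercase sequence}."""
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# marker tables / strain lists
# ---------------------------------------------------------------------------


def read_marker_table(path: str | Path) -> MarkerPanel:
    """Read a 3-column TSV (marker_id, chrom, pos); '#' lines are comments."""
    markers: list[tuple[str, str, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise MarkerParseError(f"row {lineno}: expected 3 tab-separated columns")
            mid, chrom, pos_s = fields[:3]
            try:
                pos = int(pos_s)
            except ValueError:
                raise MarkerParseError(
                    f"row {lineno}: non-numeric position {pos_s!r}"
                ) from None
            markers.append((mid, chrom, pos))
    return MarkerPanel(tuple(markers))


def write_marker_table(panel: MarkerPanel, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# marker_id\tchrom\tpos\n")
        for mid, chrom, pos in panel.markers:
            fh.write(f"{mid}\t{chrom}\t{pos}\n")


def read_strain_list(path: str | Path) -> VariantTable:
    """Read a strain-background variant list from VCF or 5-column TSV.

    The TSV form carries (id, chrom, pos, ref, alt); depths are unknown and
    stored as zero.
    """
    path = Path(path)
    if path.suffix.lower() == ".vcf" or str(path).endswith(".vcf.gz"):
        return read_vcf(path, source="strain_list")
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 5:
                raise MarkerParseError(
                    f"row {lineno}: expected 5 columns (id, chrom, pos, ref, alt)"
                )
            _, chrom, pos_s, ref, alt = fields[:5]
            try:
                pos = int(pos_s)
            except ValueError:
                raise MarkerParseError(
                    f"row {lineno}: non-numeric position {pos_s!r}"
                ) from None
            records.append(
                Variant(chrom=chrom, pos=pos, ref=ref, alt=alt, source="strain_list")
            )
    return VariantTable.from_records(records)
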