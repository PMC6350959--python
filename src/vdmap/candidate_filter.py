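"""Reduction of the mutant pool's variants to ranked causal candidates.

The narrowing scheme: keep homozygous-alt calls from the mutant pool,
subtract variants that are homozygous in the phenotypically wild-type
sibling pool or present in strain-background lists, restrict to the mapped
(or marker-defined) interval, and keep protein-coding consequences only.
Survivors are ranked by consequence severity and proximity to the mapping
peak, with full per-variant filter provenance.
"""

from __future__ import annotations

from dataclasses import dataclass

from .effect_annotation import (
    AnnotatedVariant,
    GenomeModel,
    PROTEIN_CODING_CONSEQUENCES,
    annotate_table,
)
from .variant_io import VariantTable

#: default severity ranking for candidates (most severe first); splice
#: donor and acceptor share a tier.
DEFAULT_SEVERITY = {
    "stop_gained": 0,
    "stop_lost": 0,
    "splice_donor": 1,
    "splice_acceptor": 1,
    "missense": 2,
}


@dataclass(frozen=True)
class CandidateProvenance:
    passed_zygosity: bool = True
    passed_subtraction: bool = True
    in_interval: bool = True
    protein_coding: bool = True

    @property
    def all_passed(self) -> bool:
        return (
            self.passed_zygosity
            and self.passed_subtraction
            and self.in_interval
            and self.protein_coding
        )


@dataclass(frozen=True)
class CandidateReport:
    """Ranked candidates with per-variant filter provenance."""

    candidates: tuple[AnnotatedVariant, ...]
    provenance: dict[tuple[str, int, str, str], CandidateProvenance]
    interval_used: tuple[str, int, int]

    def __len__(self) -> int:
        return len(self.candidates)

    @property
    def top(self) -> AnnotatedVariant:
        return self.candidates[0]


def subtract_variants(
    mutant: VariantTable, *removals: VariantTable
) -> VariantTable:
    """Remove from ``mutant`` every variant keyed in any removal table.

    Matching is exact on (chrom, pos, ref, alt); input order is preserved.
    """
    drop: set[tuple[str, int, str, str]] = set()
    for table in removals:
        drop |= table.keys()
    return VariantTable.from_records(v for v in mutant if v.key not in drop)


def subtract_by_position(
    mutant: VariantTable, *removals: VariantTable
) -> VariantTable:
    """Position-only subtraction (chrom, pos) for background lists that may
    report different alt alleles."""
    drop: set[tuple[str, int]] = set()
    for table in removals:
        drop |= {(v.chrom, v.pos) for v in table}
    return VariantTable.from_records(
        v for v in mutant if (v.chrom, v.pos) not in drop
    )


def filter_by_zygosity(table: VariantTable, zygosity_class: str) -> VariantTable:
    """Keep records whose zygosity call matches exactly.

    ``low_confidence`` records never pass any class filter.
    """
    return VariantTable.from_records(
        v for v in table if v.zygosity == zygosity_class and v.zygosity != "low_confidence"
    )


def restrict_to_interval(
    table: VariantTable, chrom: str, start: int, end: int
) -> VariantTable:
    """Keep variants with position in the closed interval [start, end] on chrom."""
    if start > end:
        raise ValueError(f"interval start {start} > end {end}")
    return VariantTable.from_records(
        v for v in table if v.chrom == chrom and start <= v.pos <= end
    )


def filter_protein_coding(
    annotated: list[AnnotatedVariant],
) -> list[AnnotatedVariant]:
    """Keep protein-coding consequences (missense, stop, splice); drop
    synonymous, UTR, intronic, intergenic and indel annotations."""
    return [a for a in annotated if a.consequence in PROTEIN_CODING_CONSEQUENCES]


def rank_candidates(
    candidates: list[AnnotatedVariant],
    peak_pos: int,
    severity: dict[str, int] | None = None,
) -> list[AnnotatedVariant]:
    """Order candidates by severity class, then |pos - peak|, then position."""
    sev = severity or DEFAULT_SEVERITY
    worst = max(sev.values(), default=0) + 1
    return sorted(
        candidates,
        key=lambda a: (
            sev.get(a.consequence, worst),
            abs(a.pos - peak_pos),
            a.pos,
        ),
    )


def export_candidates_tsv(
    report: CandidateReport, path, peak_pos: int | None = None,
    header_lines: tuple[str, ...] = (),
) -> None:
    """Candidate table as TSV: chrom, pos, ref, alt, gene, consequence,
    protein_label, distance_to_peak, rank."""
    chrom, start, end = report.interval_used
    if peak_pos is None:
        peak_pos = (start + end) // 2
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        fh.write(
            "# chrom\tpos\tref\talt\tgene\tconsequence\tprotein_label\t"
            "distance_to_peak\trank\n"
        )
        for rank, a in enumerate(report.candidates, start=1):
            v = a.variant
            fh.write(
                f"{v.chrom}\t{v.pos}\t{v.ref}\t{v.alt}\t{a.gene_id or '.'}\t"
                f"{a.consequence}\t{a.protein_label or '.'}\t"
                f"{abs(v.pos - peak_pos)}\t{rank}\n"
            )


def candidate_variant_table(report: CandidateReport) -> VariantTable:
    """The surviving candidates as a plain variant table (for VCF export)."""
    return VariantTable.from_records(a.variant for a in report.candidates)


def build_candidate_report(
    mutant: VariantTable,
    removals: list[VariantTable],
    genome: GenomeModel,
    interval: tuple[str, int, int],
    peak_pos: int | None = None,
    match_position_only: bool = False,
) -> CandidateReport:
    """Run the full narrowing scheme and assemble a ranked report.

    ``mutant`` must carry zygosity calls; ``removals`` are the sibling
    homozygous table and strain-background lists.  ``peak_pos`` defaults
    to the interval midpoint for the proximity tie-break.
    """
    chrom, start, end = interval
    hom = filter_by_zygosity(mutant, "hom_alt")
    subtract = subtract_by_position if match_position_only else subtract_variants
    surviving = subtract(hom, *removals)
    in_interval = restrict_to_interval(surviving, chrom, start, end)
    annotated = annotate_table(in_interval, genome)
    coding = filter_protein_coding(annotated)
    if peak_pos is None:
        peak_pos = (start + end) // 2
    ranked = rank_candidates(coding, peak_pos)

    # per-filter flags are computed independently so the provenance of a
    # variant failing an early filter still records the later ones
    removal_keys: set[tuple[str, int, str, str]] = set()
    removal_pos: set[tuple[str, int]] = set()
    for t in removals:
        removal_keys |= t.keys()
        removal_pos |= {(v.chrom, v.pos) for v in t}
    coding_keys = {a.variant.key for a in coding}
    provenance = {
        v.key: CandidateProvenance(
            passed_zygosity=v.zygosity == "hom_alt",
            passed_subtraction=(
                (v.chrom, v.pos) not in removal_pos
                if match_position_only
                else v.key not in removal_keys
            ),
            in_interval=v.chrom == chrom and start <= v.pos <= end,
            protein_coding=v.key in coding_keys,
        )
        for v in mutant
    }
    return CandidateReport(tuple(ranked), provenance, interval)
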