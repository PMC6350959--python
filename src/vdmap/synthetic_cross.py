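"""Simulation of the F2 intercross and pooled RNA-seq allele counts.

The screen crosses a mutagenized carrier strain to a polymorphic mapping
strain; F1 fish are intercrossed and F2 embryos phenotype-sorted into a
mutant pool (homozygous for the mutagenized haplotype at the causal locus)
and a sibling pool.  Each F2 embryo carries two independent recombinant F1
gametes; crossovers per chromosome are Poisson with uniform breakpoints
(no interference, linear genetic map), so allele frequencies at
strain-diagnostic SNPs in the mutant pool decay as 1 − r with Haldane
recombination fraction r from the causal locus.

Read counts model pooled RNA-seq only through site depth: per SNP, depth
is Poisson and alt reads binomial around the pool allele frequency with a
symmetric per-read error.  SNPs with zero depth or zero alt reads are not
called and are omitted, as a variant caller would.

`build_packaged_fixture` constructs the deterministic packaged chr14 toy
dataset: a 54 Mb chromosome carrying a toy *slbp* gene whose CDS codon 180
is TAC, a C→A stop-gained variant at 14,800,000, twelve missense and one
splice-donor companion candidates inside the z4896–z6847 marker interval,
engineered background variants that the sibling/strain subtraction
removes, and a 445-bp amplicon pair whose mutant allele alone carries a
DdeI site (fragments 418 + 27).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .effect_annotation import (
    CODON_TABLE,
    STOP_CODONS,
    classify_consequence,
    reverse_complement,
)
from .variant_io import (
    GeneModel,
    GenomeModel,
    MarkerPanel,
    Variant,
    VariantTable,
    write_fasta,
    write_gff3,
    write_marker_table,
    write_vcf,
)

MUTAGENIZED = "mutagenized"
MAPPING = "mapping"


class SimulationError(RuntimeError):
    """The simulated cross could not fill the requested pools."""


@dataclass(frozen=True)
class CrossConfig:
    """Parameters of the simulated intercross and pooled sequencing.

    Defaults emulate the study conditions: pools of 30 embryos, ~50× mean
    coverage at strain-diagnostic SNPs spaced ~20 kb apart, one crossover
    per chromosome per meiosis on average, and a causal locus at 14.8 Mb
    on a 54 Mb chromosome 14 (a second, unlinked chromosome 15 is carried
    along to show absence of signal).
    """

    seed: int
    chrom_lengths: Mapping[str, int] = field(
        default_factory=lambda: {"chr14": 54_000_000, "chr15": 48_000_000}
    )
    snp_spacing: float = 20_000.0
    map_length: float = 1.0  # Morgans per chromosome
    causal_locus: tuple[str, int] = ("chr14", 14_800_000)
    pool_size: int = 30
    mean_coverage: float = 50.0
    error_rate: float = 0.001
    missort_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.pool_size < 1:
            raise ValueError("pool_size must be >= 1")
        if self.mean_coverage < 0:
            raise ValueError("mean_coverage must be >= 0")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")
        chrom, pos = self.causal_locus
        if chrom not in self.chrom_lengths or not 1 <= pos <= self.chrom_lengths[chrom]:
            raise ValueError("causal locus outside its chromosome")
        if not 0 <= self.missort_rate < 0.5:
            raise ValueError("missort_rate must be in [0, 0.5)")


def _stream(seed: int, key: int) -> np.random.Generator:
    """Independent deterministic RNG stream derived from the config seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(key,)))


@dataclass(frozen=True)
class HaplotypeMosaic:
    """One recombinant gamete chromosome as parental segments.

    Segments tile [1, length] without gaps; adjacent segments come from
    different parents.
    """

    chrom: str
    segments: tuple[tuple[int, int, str], ...]

    def __post_init__(self) -> None:
        prev_end = 0
        prev_parent = None
        for start, end, parent in self.segments:
            if start != prev_end + 1 or end < start:
                raise ValueError("segments must tile the chromosome without gaps")
            if parent == prev_parent:
                raise ValueError("adjacent segments must differ in parent")
            prev_end, prev_parent = end, parent

    @property
    def length(self) -> int:
        return self.segments[-1][1]

    def parent_at(self, pos: int) -> str:
        for start, end, parent in self.segments:
            if start <= pos <= end:
                return parent
        raise ValueError(f"position {pos} outside chromosome")

    def parents_at(self, positions: np.ndarray) -> np.ndarray:
        """Boolean array: True where the mutagenized parent contributed."""
        ends = np.array([e for _, e, _ in self.segments], dtype=np.int64)
        parents = np.array(
            [p == MUTAGENIZED for _, _, p in self.segments], dtype=bool
        )
        idx = np.searchsorted(ends, positions, side="left")
        return parents[idx]


@dataclass(frozen=True)
class Embryo:
    """An F2 embryo: two recombinant gametes per chromosome."""

    haplotypes: Mapping[str, tuple[HaplotypeMosaic, HaplotypeMosaic]]

    def is_mutant(self, causal_locus: tuple[str, int]) -> bool:
        chrom, pos = causal_locus
        h1, h2 = self.haplotypes[chrom]
        return h1.parent_at(pos) == MUTAGENIZED and h2.parent_at(pos) == MUTAGENIZED


def simulate_haplotype(
    chrom: str, config: CrossConfig, rng: np.random.Generator
) -> HaplotypeMosaic:
    """One F1 gamete chromosome: Poisson(map_length) crossovers at uniform
    breakpoints, starting parent a fair coin."""
    length = config.chrom_lengths[chrom]
    n_xo = int(rng.poisson(config.map_length))
    breaks = sorted(set(int(b) for b in rng.integers(1, length, size=n_xo)))
    parents = [MUTAGENIZED, MAPPING]
    phase = int(rng.integers(0, 2))
    segments = []
    start = 1
    for i, b in enumerate(breaks):
        segments.append((start, b, parents[(phase + i) % 2]))
        start = b + 1
    segments.append((start, length, parents[(phase + len(breaks)) % 2]))
    return HaplotypeMosaic(chrom, tuple(segments))


def _draw_embryo(config: CrossConfig, rng: np.random.Generator) -> Embryo:
    haplotypes = {
        chrom: (
            simulate_haplotype(chrom, config, rng),
            simulate_haplotype(chrom, config, rng),
        )
        for chrom in sorted(config.chrom_lengths)
    }
    return Embryo(haplotypes)


def simulate_pools(
    config: CrossConfig, rng: np.random.Generator | None = None
) -> tuple[list[Embryo], list[Embryo]]:
    """Draw F2 embryos until both phenotype-sorted pools are filled.

    An embryo shows the mutant phenotype iff both gametes carry the
    mutagenized parent at the causal locus (recessive, fully penetrant);
    ``missort_rate`` flips the observed phenotype.  Raises
    :class:`SimulationError` with the observed mutant fraction if the
    mutant pool cannot be filled within a bounded number of draws.
    """
    if rng is None:
        rng = _stream(config.seed, 1)
    mutants: list[Embryo] = []
    siblings: list[Embryo] = []
    n_drawn = 0
    n_true_mutant = 0
    max_draws = max(400, 200 * config.pool_size)
    while (len(mutants) < config.pool_size or len(siblings) < config.pool_size):
        if n_drawn >= max_draws:
            raise SimulationError(
                f"could not fill pools after {n_drawn} embryos "
                f"(observed mutant fraction {n_true_mutant / n_drawn:.3f})"
            )
        embryo = _draw_embryo(config, rng)
        n_drawn += 1
        is_mut = embryo.is_mutant(config.causal_locus)
        n_true_mutant += is_mut
        observed = is_mut
        if config.missort_rate and rng.random() < config.missort_rate:
            observed = not observed
        if observed and len(mutants) < config.pool_size:
            mutants.append(embryo)
        elif not observed and len(siblings) < config.pool_size:
            siblings.append(embryo)
    return mutants, siblings


def snp_panel(
    config: CrossConfig,
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Strain-diagnostic SNP positions and alleles per chromosome.

    Positions are laid down with exponential spacing; the alt allele is
    the mutagenized-strain allele.  Deterministic for a given config seed,
    and shared by the mutant and sibling pools.
    """
    rng = _stream(config.seed, 0)
    bases = np.array(list("ACGT"))
    panel: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for chrom in sorted(config.chrom_lengths):
        length = config.chrom_lengths[chrom]
        n_guess = int(length / config.snp_spacing * 1.5) + 50
        gaps = rng.exponential(config.snp_spacing, size=n_guess)
        pos = np.cumsum(gaps).astype(np.int64) + 1
        while pos[-1] < length:  # pragma: no cover - astronomically rare
            extra = rng.exponential(config.snp_spacing, size=50)
            pos = np.concatenate([pos, pos[-1] + np.cumsum(extra).astype(np.int64)])
        pos = np.unique(pos[(pos >= 1) & (pos <= length)])
        ref_idx = rng.integers(0, 4, size=len(pos))
        alt_idx = (ref_idx + rng.integers(1, 4, size=len(pos))) % 4
        panel[chrom] = (pos, bases[ref_idx], bases[alt_idx])
    return panel


def simulate_variant_table(
    pool: Sequence[Embryo],
    config: CrossConfig,
    source: str,
    rng: np.random.Generator | None = None,
) -> VariantTable:
    """RNA-seq-derived allele counts at the strain-diagnostic SNP panel.

    Per SNP: pool alt-allele frequency f = mutagenized chromosomes /
    (2 · pool size); depth ~ Poisson(mean coverage); alt reads ~
    Binomial(depth, f·(1−e) + (1−f)·e).  SNPs with zero depth or zero alt
    reads are omitted.
    """
    if rng is None:
        rng = _stream(config.seed, 2 if source == "mutant_pool" else 3)
    panel = snp_panel(config)
    records: list[Variant] = []
    for chrom in sorted(config.chrom_lengths):
        pos, refs, alts = panel[chrom]
        haps = [h for e in pool for h in e.haplotypes[chrom]]
        k = np.zeros(len(pos), dtype=np.int64)
        for h in haps:
            k += h.parents_at(pos)
        f = k / len(haps)
        depth = rng.poisson(config.mean_coverage, size=len(pos))
        p = f * (1.0 - config.error_rate) + (1.0 - f) * config.error_rate
        alt_reads = rng.binomial(depth, p)
        keep = (depth > 0) & (alt_reads > 0)
        for i in np.flatnonzero(keep):
            records.append(
                Variant(
                    chrom=chrom,
                    pos=int(pos[i]),
                    ref=str(refs[i]),
                    alt=str(alts[i]),
                    ref_depth=int(depth[i] - alt_reads[i]),
                    alt_depth=int(alt_reads[i]),
                    source=source,
                )
            )
    return VariantTable.from_records(records)


# ---------------------------------------------------------------------------
# deterministic packaged fixture
# ---------------------------------------------------------------------------

MARKER_INTERVAL = ("chr14", 10_750_000, 17_260_000)
CAUSAL_LOCUS = ("chr14", 14_800_000)
_CHR14_LENGTH = 54_000_000

_NONSTOP_CODONS = sorted(set(CODON_TABLE) - STOP_CODONS)


@dataclass(frozen=True)
class FixtureBundle:
    """The deterministic packaged chr14 dataset reproducing the candidate
    accounting: 14 protein-coding candidates, one stop-gained (Y180stop)."""

    genome: GenomeModel
    mutant_table: VariantTable
    sibling_table: VariantTable
    strain_list: VariantTable
    markers: MarkerPanel
    amplicon_wt: str
    amplicon_mut: str
    causal_locus: tuple[str, int] = CAUSAL_LOCUS
    interval: tuple[str, int, int] = MARKER_INTERVAL

    def write(self, outdir: str | Path, include_reference: bool = True) -> dict[str, Path]:
        """Emit the bundle as FASTA / GFF3 / VCF / TSV files; returns paths."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "genes": outdir / "genes.gff3",
            "mutant": outdir / "mutant.vcf",
            "sibling": outdir / "sibling.vcf",
            "strain": outdir / "strain.vcf",
            "markers": outdir / "markers.tsv",
            "amplicons": outdir / "amplicons.fa",
        }
        write_gff3(self.genome.genes, paths["genes"])
        lengths = dict(self.genome.chrom_lengths)
        write_vcf(self.mutant_table, paths["mutant"], chrom_lengths=lengths)
        write_vcf(self.sibling_table, paths["sibling"], chrom_lengths=lengths)
        write_vcf(self.strain_list, paths["strain"], chrom_lengths=lengths)
        write_marker_table(self.markers, paths["markers"])
        write_fasta(
            {"amplicon_wt": self.amplicon_wt, "amplicon_mut": self.amplicon_mut},
            paths["amplicons"],
        )
        if include_reference:
            paths["reference"] = outdir / "reference.fa"
            write_fasta(dict(self.genome.reference), paths["reference"])
        return paths


def _genomic_pos_of_cds_coord(g: GeneModel, c: int) -> int:
    """Inverse of the CDS coordinate map (c is 1-based, transcription order)."""
    plus = g.cds_length - c + 1 if g.strand == "-" else c
    offset = 0
    for s, e in g.cds:
        span = e - s + 1
        if plus <= offset + span:
            return s + (plus - offset - 1)
        offset += span
    raise ValueError(f"CDS coordinate {c} out of range for {g.gene_id}")


def _make_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    exons: Sequence[tuple[int, int]],
    rng: np.random.Generator,
    forced_codons: Mapping[int, str] | None = None,
) -> tuple[GeneModel, dict[int, str]]:
    """Build an all-CDS toy gene and the reference-base overlay it implies.

    The coding sequence starts ATG, ends with a stop, and is free of
    internal stops; ``forced_codons`` pins specific codons (1-based).
    Returns the gene model and {genomic position: base} overlay, including
    canonical GT/AG intron edges.
    """
    gene = GeneModel(
        gene_id=gene_id, chrom=chrom, strand=strand,
        exons=tuple(exons), cds=tuple(exons),
    )
    n_codons = gene.cds_length // 3
    codons = [
        _NONSTOP_CODONS[i]
        for i in rng.integers(0, len(_NONSTOP_CODONS), size=n_codons)
    ]
    codons[0] = "ATG"
    codons[-1] = "TAA"
    for number, codon in (forced_codons or {}).items():
        codons[number - 1] = codon
    cds_seq = "".join(codons)
    genomic_cds = reverse_complement(cds_seq) if strand == "-" else cds_seq
    overlay: dict[int, str] = {}
    i = 0
    for s, e in gene.exons:
        for pos in range(s, e + 1):
            overlay[pos] = genomic_cds[i]
            i += 1
    # canonical splice dinucleotides: GT..AG in transcription orientation
    for j in range(gene.n_exons - 1):
        left_end = gene.exons[j][1]
        right_start = gene.exons[j + 1][0]
        donor, acceptor = ("GT", "AG") if strand == "+" else ("CT", "AC")
        # plus: left side of intron is donor GT, right side acceptor AG;
        # minus: plus-strand bases are revcomp, donor at the right side
        if strand == "+":
            overlay[left_end + 1], overlay[left_end + 2] = "G", "T"
            overlay[right_start - 2], overlay[right_start - 1] = "A", "G"
        else:
            overlay[left_end + 1], overlay[left_end + 2] = "C", "T"
            overlay[right_start - 2], overlay[right_start - 1] = "A", "C"
    return gene, overlay


def _missense_variant(
    g: GeneModel, codon_number: int, reference: str, rng: np.random.Generator
) -> Variant:
    """Engineer a missense SNV in the middle base of the given codon."""
    c = (codon_number - 1) * 3 + 2
    pos = _genomic_pos_of_cds_coord(g, c)
    ref_base = reference[pos - 1]
    for alt_base in "ACGT":
        if alt_base == ref_base:
            continue
        v = Variant(
            chrom=g.chrom, pos=pos, ref=ref_base, alt=alt_base,
            ref_depth=0, alt_depth=int(rng.integers(40, 61)),
        )
        if classify_consequence(v, g, reference).consequence == "missense":
            return v
    raise AssertionError("no missense substitution found")  # pragma: no cover


def _scrub_pattern(seq: bytearray, protect: range) -> None:
    """Remove every CTNAG match outside ``protect`` by flipping its G."""
    changed = True
    while changed:
        changed = False
        for i in range(len(seq) - 4):
            if i in protect:
                continue
            window = seq[i : i + 5].decode()
            if (
                window[0] == "C" and window[1] == "T"
                and window[3] == "A" and window[4] == "G"
            ):
                seq[i + 4] = ord("C")
                changed = True


def _build_amplicons(rng: np.random.Generator) -> tuple[str, str]:
    """445-bp amplicon pair: only the mutant allele carries one DdeI site,
    placed so digestion yields 418 + 27 bp fragments."""
    bases = b"ACGT"
    seq = bytearray(bases[i] for i in rng.integers(0, 4, size=445))
    # engineered region (0-based 417..421): wildtype CTTCG, mutant CTTAG;
    # the C->A change at index 420 mirrors the causal point mutation class
    seq[417:422] = b"CTTCG"
    seq[410:417] = b"AAAAAAA"
    seq[422:429] = b"AAAAAAA"
    protect = range(410, 429)
    _scrub_pattern(seq, protect)
    wt = seq.decode()
    mut_arr = bytearray(seq)
    mut_arr[420] = ord("A")
    mut = mut_arr.decode()
    return wt, mut


def _overlay_variant(
    chrom: str, pos: int, reference: str, rng: np.random.Generator, **kw
) -> Variant:
    """SNV at a position, ref taken from the reference, alt a different base."""
    ref_base = reference[pos - 1]
    alts = [b for b in "ACGT" if b != ref_base]
    alt_base = alts[int(rng.integers(0, 3))]
    kw.setdefault("ref_depth", 0)
    kw.setdefault("alt_depth", int(rng.integers(40, 61)))
    return Variant(chrom=chrom, pos=pos, ref=ref_base, alt=alt_base, **kw)


def build_packaged_fixture(seed: int = 1) -> FixtureBundle:
    """Deterministic chr14 toy dataset reproducing the candidate accounting.

    After homozygosity filtering, subtraction of sibling-homozygous and
    strain-list variants, restriction to the 10.75–17.26 Mb marker
    interval, and protein-coding filtering, exactly 14 candidates remain:
    12 missense, 1 splice-donor and 1 stop-gained (TAC→TAA, Y180stop) at
    chr14:14,800,000.  Bit-reproducible for a given seed.
    """
    rng = np.random.default_rng(seed)
    chrom = "chr14"
    length = _CHR14_LENGTH

    # random reference chromosome, then overlay gene sequences
    base_lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    ref_arr = bytearray(base_lut[rng.integers(0, 4, size=length)].tobytes())

    # toy slbp: 7 exons, 300 codons, codon 180 = TAC whose third base sits
    # at 14,800,000; codon 100 = CTC (4-fold Leu) to host a synonymous SNV
    slbp_exons = (
        (14_791_461, 14_791_560),
        (14_793_561, 14_793_680),
        (14_795_681, 14_795_760),
        (14_797_761, 14_797_910),
        (14_799_911, 14_800_110),
        (14_802_111, 14_802_210),
        (14_804_211, 14_804_360),
    )
    gene_defs: list[tuple[str, str, tuple[tuple[int, int], ...], dict[int, str]]] = [
        ("slbp", "+", slbp_exons, {180: "TAC", 100: "CTC"}),
        ("gene02", "+", ((11_000_001, 11_000_300), (11_001_301, 11_001_600),
                         (11_002_601, 11_002_900)), {}),
        ("gene03", "+", ((12_100_001, 12_100_300), (12_101_301, 12_101_600),
                         (12_102_601, 12_102_900)), {}),
        ("gene04", "-", ((13_300_001, 13_300_300), (13_301_301, 13_301_600),
                         (13_302_601, 13_302_900)), {}),
        ("gene05", "+", ((14_200_001, 14_200_300), (14_201_301, 14_201_600),
                         (14_202_601, 14_202_900)), {}),
        ("gene06", "+", ((15_600_001, 15_600_300), (15_601_301, 15_601_600),
                         (15_602_601, 15_602_900)), {}),
        ("gene07", "+", ((16_800_001, 16_800_300), (16_801_301, 16_801_600),
                         (16_802_601, 16_802_900)), {}),
    ]
    genes: list[GeneModel] = []
    for gene_id, strand, exons, forced in gene_defs:
        gene, overlay = _make_gene(gene_id, chrom, strand, exons, rng, forced)
        genes.append(gene)
        for pos, base in overlay.items():
            ref_arr[pos - 1] = ord(base)
    reference = ref_arr.decode()
    genome = GenomeModel(
        chrom_lengths={chrom: length},
        reference={chrom: reference},
        genes=tuple(genes),
    )
    by_id = {g.gene_id: g for g in genes}

    # --- the 14 candidates -------------------------------------------------
    candidates: list[Variant] = []
    # 1 stop-gained: codon 180 TAC -> TAA at 14,800,000
    assert reference[14_800_000 - 1] == "C"
    candidates.append(
        Variant(chrom=chrom, pos=14_800_000, ref="C", alt="A",
                ref_depth=0, alt_depth=int(rng.integers(40, 61)))
    )
    # 1 splice-donor: first intronic base after exon 1 of gene02
    donor_pos = by_id["gene02"].exons[0][1] + 1
    assert reference[donor_pos - 1] == "G"
    candidates.append(
        Variant(chrom=chrom, pos=donor_pos, ref="G", alt="A",
                ref_depth=0, alt_depth=int(rng.integers(40, 61)))
    )
    # 12 missense spread over the toy genes
    missense_plan = [
        ("slbp", 50), ("slbp", 120), ("slbp", 250),
        ("gene02", 40), ("gene02", 210),
        ("gene03", 33), ("gene03", 170),
        ("gene04", 25), ("gene04", 222),
        ("gene05", 90), ("gene06", 145), ("gene07", 60),
    ]
    for gene_id, codon_number in missense_plan:
        candidates.append(
            _missense_variant(by_id[gene_id], codon_number, reference, rng)
        )

    # --- variants each downstream filter removes ---------------------------
    # non-coding homozygous variants inside the interval
    syn_pos = _genomic_pos_of_cds_coord(by_id["slbp"], 300)  # codon 100, 3rd base
    assert reference[syn_pos - 1] == "C"
    synonymous = Variant(chrom=chrom, pos=syn_pos, ref="C", alt="A",
                         ref_depth=0, alt_depth=int(rng.integers(40, 61)))
    intron_mid = (by_id["gene03"].exons[0][1] + by_id["gene03"].exons[1][0]) // 2
    noncoding = [
        synonymous,
        _overlay_variant(chrom, intron_mid, reference, rng),
        _overlay_variant(chrom, 13_800_000, reference, rng),
    ]
    # homozygous in the sibling pool as well -> removed by subtraction
    shared_with_sibling = [
        _overlay_variant(chrom, p, reference, rng)
        for p in (11_200_000, 12_500_000, 14_500_000, 16_200_000)
    ]
    # present in the strain-background list, inside the interval
    strain_in_interval = [
        _overlay_variant(chrom, p, reference, rng)
        for p in (10_900_000, 13_100_000, 15_900_000)
    ]
    # outside the interval and on the strain list
    strain_outside = [
        _overlay_variant(chrom, p, reference, rng)
        for p in (2_000_000, 5_000_000, 8_000_000, 20_000_000, 30_000_000, 45_000_000)
    ]
    # heterozygous in the mutant pool -> removed by the zygosity filter
    het_in_mutant = [
        _overlay_variant(chrom, p, reference, rng,
                         ref_depth=int(rng.integers(20, 31)),
                         alt_depth=int(rng.integers(20, 31)))
        for p in (11_500_000, 12_000_000, 14_000_000, 15_000_000, 16_500_000)
    ]

    mutant_table = VariantTable.from_records(
        [replace(v, source="mutant_pool") for v in (
            *candidates, *noncoding, *shared_with_sibling,
            *strain_in_interval, *strain_outside, *het_in_mutant,
        )]
    )
    # sibling pool: shares the subtraction homs; carries the candidates as
    # heterozygous calls (~1/3 alt, the 2:1 carrier ratio among siblings);
    # plus a couple of sibling-only homozygous calls off the interval
    sibling_records = [
        replace(v, source="sibling_pool") for v in shared_with_sibling
    ]
    for v in candidates:
        sibling_records.append(
            replace(v, source="sibling_pool",
                    ref_depth=int(rng.integers(30, 38)),
                    alt_depth=int(rng.integers(14, 20)))
        )
    sibling_records += [
        _overlay_variant(chrom, p, reference, rng, source="sibling_pool")
        for p in (25_000_000, 40_000_000)
    ]
    sibling_table = VariantTable.from_records(sibling_records)

    strain_records = [
        replace(v, source="strain_list", ref_depth=0, alt_depth=0)
        for v in (*strain_in_interval, *strain_outside)
    ]
    strain_list = VariantTable.from_records(strain_records)

    markers = MarkerPanel((
        ("z4896", chrom, 10_750_000),
        ("z6847", chrom, 17_260_000),
    ))
    amplicon_wt, amplicon_mut = _build_amplicons(rng)
    return FixtureBundle(
        genome=genome,
        mutant_table=mutant_table,
        sibling_table=sibling_table,
        strain_list=strain_list,
        markers=markers,
        amplicon_wt=amplicon_wt,
        amplicon_mut=amplicon_mut,
    )
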