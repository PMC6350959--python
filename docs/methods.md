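# Methods

## The cross and what the simulator emulates

The design is a zebrafish F2 intercross: a mutagenized carrier strain is
outcrossed to a polymorphic mapping strain, F1 hybrids are intercrossed,
and F2 embryos are sorted by phenotype into a mutant pool and a sibling
pool. The simulator represents each F2 embryo as two independent
recombinant F1 gametes per chromosome. Per gamete and chromosome the
crossover count is Poisson with mean equal to the chromosome's genetic
length (no crossover interference), breakpoints are uniform on the
physical sequence (a linear genetic↔physical map), and the starting
parental phase is a fair coin. An embryo is a phenotypic mutant iff both
gametes carry the mutagenized parent at the causal locus — a fully
penetrant recessive. Pools are filled to the configured size by rejection
sampling; a `missort_rate` option flips observed phenotypes to let users
explore imperfect sorting, and defaults to 0.

Under this model the probability that a selected gamete carries the
mapping-strain allele at map distance *d* Morgans from the causal locus
is the Haldane recombination fraction r = (1 − e^(−2d))/2, so the
expected mutant-pool alt fraction is 1 − r. The test suite verifies this
decay to within 0.05 absolute in 50 recombination-fraction bins, the
0.25 mutant fraction, and the 2/3 heterozygote fraction among siblings
over 10,000 simulated embryos.

Pooled RNA-seq is modelled only at the level of called variants:
strain-diagnostic SNP positions are laid down with exponential spacing
(mean 20 kb), site depth is Poisson, and alt reads are binomial around
the pool allele frequency with a symmetric per-read error. Sites with
zero depth or zero alt reads are omitted, as a variant caller would omit
them. Not modelled: read-level data, base qualities, gene-level
expression weights (every SNP is equally "transcribed"), allele-specific
expression, overdispersion of RNA-seq coverage, and variant-caller
artefacts. Passing tests therefore demonstrate correctness of the
mapping arithmetic under idealized pool-seq noise, not robustness to
RNA-seq-specific biases such as uneven transcript coverage.

### Defaults (one choice, stated once)

| parameter | default | why |
| --- | --- | --- |
| pool_size | 30 embryos | the pool size the protocol prescribes |
| mean_coverage | 50× | realistic pooled RNA-seq depth at expressed SNPs |
| snp_spacing | 20 kb | ~2,700 diagnostic SNPs on a 54 Mb chromosome, typical for a strain pair |
| map_length | 1 Morgan/chromosome | zebrafish chromosomes average ~100 cM |
| error_rate | 0.001 | post-filter per-read miscall rate |
| chrom_lengths | chr14 54 Mb, chr15 48 Mb | the focal chromosome plus an unlinked control |
| causal_locus | chr14:14,800,000 | matches the packaged fixture gene |
| seed | mandatory | bit-reproducibility is part of the contract |

## Zygosity calls and the kernel-density profile

A pooled site is `low_confidence` below 5 total reads, `hom_alt` when the
alt read fraction is ≥ 0.9, else `het`. The thresholds are flags; the
defaults are chosen to be robust at ~50× pooled coverage: at depth 50 a
truly fixed site fails the 0.9 cut only if ≥ 6 reads are errors, while a
1:1 site passes it with probability < 10⁻⁸.

The mapping profile is an equal-weight Gaussian kernel density of
`hom_alt` positions per chromosome (bandwidth 1 Mb, grid step 10 kb,
grid points 1, 1+step, … ≤ chromosome length). There is no boundary
correction: kernel mass extending past the chromosome ends is simply
lost, so the density integrates to slightly less than 1 for positions
near the ends. The peak is the global argmax over homozygous profiles
(leftmost grid point on ties, lexicographic chromosome order across
chromosomes — determinism over elegance), and the reported interval is
the contiguous grid run around the peak with density ≥ half the peak
height. The heterozygous profile is computed and exported alongside for
plotting; an optional ratio mode is deliberately not the default. The
classic allele-frequency view (Nadaraya–Watson smoothing of alt
fractions with the same kernel) is exported in the same table.

The 1 Mb bandwidth reflects the mapping resolution of a 30-embryo pool —
the method localizes to megabases, not kilobases. A known limitation
follows: with 60 selected gametes and ~50× coverage the homozygous-call
probability decays from ~1 at the locus to 50% only ~7 Mb away, so the
density surface is a broad plateau and its argmax has a standard
deviation of roughly 2 Mb across replicate crosses (the acceptance suite
measures this directly). The peak reliably identifies the correct
chromosome and a several-megabase neighbourhood; pinning the position to
~1 Mb requires larger pools, deeper coverage, or the marker interval —
which is why candidate filtering defaults to the interval, not the peak.

## Candidate narrowing

Filters are intersective and commute; each variant's report row records
four independent provenance flags (passed zygosity, survived
subtraction, in interval, protein-coding). Subtraction matches exact
(chrom, pos, ref, alt) keys; a position-only mode exists for background
lists from other strains that may report different alt alleles. The
mutant table is restricted to `hom_alt` calls before subtraction — the
variant the screen seeks must be homozygous in the mutant pool. Ranking
is severity first (stop > splice donor/acceptor > missense; the order is
configurable), then distance to the peak, then position.

## Consequence annotation

One gene model per gene (no isoforms), 1-based closed coordinates as in
GFF3. CDS codon numbering starts at 1 at the annotated CDS start; splice
windows are the two intronic bases flanking internal exon boundaries
(canonical GT/AG), and wider windows are deliberately not called splice.
For a CDS substitution the reference codon is read from the
strand-corrected CDS and the consequence follows from translating
reference and alternate codons with the standard genetic code. Labels
use `stop` rather than `*` (`Y180stop`). Variants overlapping several
genes are annotated against each and the most severe consequence is
reported. Indels are accepted by the parser but annotated only as
`indel`; frame analysis is out of scope. The per-codon path is verified
against an independent whole-CDS translation oracle on 1,000 random
substitutions and under reverse-complement mirroring of the genome.

## Restriction digestion

Enzyme sites are IUPAC patterns matched on the given strand with all
overlapping matches reported; a match starting at position *m* cuts the
backbone after position *m* + offset − 1 (DdeI = C^TNAG, offset 1).
Fragments are the runs between cuts; digestion is always complete
(no partial digest or star activity). Two alleles are called
distinguishable on a gel when, after sorting fragments descending and
padding with zero-length entries, some pair differs by at least the
stated resolution (default 10 bp — small fragments that run off the gel
therefore never distinguish alleles on their own).

## The packaged fixture

`build_packaged_fixture(seed)` builds a bit-reproducible 54 Mb chr14 toy
dataset: seven all-CDS toy genes inside the 10.75–17.26 Mb SSLP interval
(one minus-strand), a toy *slbp* whose CDS codon 180 is TAC with its
third base at 14,800,000, and variant tables engineered so the full
pipeline leaves exactly 14 protein-coding candidates — 12 missense, 1
splice-donor, 1 stop-gained (C→A, TAC→TAA, `Y180stop`). The
12/1/1 split within the total of 14 is a fixture choice. Background
variants exercise every filter: heterozygous mutant calls, variants
shared with the sibling pool, strain-list variants inside and outside
the interval, and synonymous/intronic/intergenic survivors of
subtraction. The amplicon pair is 445 bp differing at one base (C→A),
with the DdeI site placed so the mutant allele digests to 418 + 27 bp;
the true site position within the real assay's amplicon is not public,
so only the fragment arithmetic is reproduced. The toy gene models are
synthetic: they reproduce the published facts about the locus (exon
count context, codon 180, fragment lengths), not real coordinates.

## Numerical and interface choices

* All coordinates are 1-based throughout (VCF/GFF3 convention); no
  half-open conversion layer exists.
* Multi-allelic VCF records are split on load; downstream logic sees
  bi-allelic records only, keyed on (chrom, pos, ref, alt).
* Percentages round half-up (25.7069… → 25.7 at one decimal; 6.31… → 6
  at zero decimals); whether a printed "6%" was truncated or rounded is
  not decidable, rounding is assumed. Across-experiment SD uses the n−1
  denominator and is reported as absent for a single experiment.
* ΔΔCt assumes amplification efficiency exactly 2;
  efficiency-corrected variants are out of scope.
* KDE evaluation is a chunked exact Gaussian sum (no FFT approximation),
  matching a brute-force double loop to < 10⁻⁹.
* Every CLI output carries a provenance header (version, config hash,
  seed); identical config + seed reproduce outputs byte for byte.

## Problem sizes used in the test and acceptance runs

Simulations use the default two-chromosome genome (~5,000 SNPs per
pool), pools of 30 embryos, and up to 20 independent seeds for the
recovery statistics; Mendelian ratios use 10,000 embryos on a single
chromosome; oracle comparisons use ≤ 200 KDE positions and 1,000 random
coding substitutions. These sizes keep the whole suite under a minute
on one CPU while leaving the statistical assertions well-powered.
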