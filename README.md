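# vdmap

Mapping-by-sequencing for forward-genetic screens in zebrafish (and other
F2-intercross designs): localize a recessive causal mutation from pooled
RNA-seq of phenotype-sorted embryos, narrow the variant list by
subtraction and consequence filtering, and verify RFLP/dCAPS genotyping
assays in silico.

## Who this is for

A screen has produced a recessive mutant. Carriers from the mutagenized
strain are outcrossed to a polymorphic mapping strain, F1 fish are
intercrossed, and F2 embryos are sorted by phenotype into a mutant pool
and a sibling pool (~30 embryos each). Each pool is RNA-sequenced and
variants are called with per-allele read depths. `vdmap` takes those VCFs
and answers: *where is the mutation, and which variant is it?*

## Method

At a strain-diagnostic SNP, let the alternate allele be the
mutagenized-strain allele with pooled read depths giving the alt fraction
*f*. Sites are classified as effectively homozygous (*f* ≥ 0.9 at depth
≥ 5), heterozygous, or low-confidence. In the mutant pool every selected
gamete carries the mutagenized haplotype at the causal locus, so the
expected alt fraction at recombination fraction *r* from it is 1 − *r*:
homozygous calls pile up around the mutation and segregate 1:1 elsewhere.

The mapping statistic is a Gaussian kernel density of homozygous (and,
for comparison, heterozygous) SNP positions along each chromosome,

&nbsp;&nbsp;&nbsp;&nbsp;f̂(x) = (1/n) Σᵢ φ((x − pᵢ)/h) / h,&nbsp;&nbsp;h = 1 Mb by default,

whose argmax is the peak and whose half-height run is the reported
interval. A classic allele-frequency mode (Nadaraya–Watson smoothing of
per-variant alt fractions) is also provided.

Candidates are then narrowed by set subtraction keyed on
(chrom, pos, ref, alt): homozygous sibling-pool variants and
strain-background lists are removed, survivors are restricted to the
mapped (or SSLP-marker) interval, annotated against gene models
(missense / stop / splice-window ±2 bp / synonymous / UTR / intronic),
and ranked by severity and proximity to the peak, yielding labels such as
`Y180stop`.

A synthetic-cross module simulates the whole design — Poisson crossovers,
phenotype sorting, Poisson/binomial read counts — and builds a
deterministic chr14 toy dataset so every stage is testable without
external data. The genotyping module digests amplicon pairs with IUPAC
enzyme patterns (DdeI ships in the enzyme table) to confirm that alleles
separate on a gel.

## Worked example

Everything below is reproducible from the packaged fixture; no external
data needed.

```
$ vdmap simulate --seed 1 --out out/sim --fixture packaged
$ vdmap map --vcf out/sim/mutant.vcf --out out/map
peak	chr14	14460001	14.460 Mb
interval	chr14:10450001-16390001
```

The homozygosity density peaks at 14.46 Mb on chromosome 14 with a
half-height interval of roughly 10.5–16.4 Mb — the mutation is inside it.
Filtering against the sibling pool, the strain-background list and the
SSLP marker interval (z4896–z6847, 10.75–17.26 Mb):

```
$ vdmap filter --mutant-vcf out/sim/mutant.vcf --sibling-vcf out/sim/sibling.vcf \
    --strain-list out/sim/strain.vcf --gff3 out/sim/genes.gff3 \
    --reference out/sim/reference.fa --markers out/sim/markers.tsv \
    --marker-left z4896 --marker-right z6847 --out out/cand
candidates	14
top	chr14	14800000	stop_gained	Y180stop
```

Fourteen protein-coding variants survive; the only stop-gained one sits
at 14.8 Mb in exon 5 of the toy *slbp* gene (TAC→TAA, tyrosine 180 to a
premature stop) and ranks first. The genotyping assay distinguishes the
alleles:

```
$ vdmap digest --amplicons out/sim/amplicons.fa
amplicon_wt	445	445
amplicon_mut	445	418,27
distinguishable	yes
```

The wildtype 445-bp amplicon is uncut; the mutant allele carries the
engineered DdeI site and digests to 418 + 27 bp. Small screen statistics:

```
$ vdmap stats --clutch clutch.tsv --decimals 1
clutch	control	25.7
clutch	rescued	6.3
```

25.7% affected embryos in the control clutch is the Mendelian quarter for
a fully penetrant recessive; rescue drops it to ~6%.

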