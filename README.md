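# triomap

Trio-based whole-genome rare-variant discovery for livestock:
runs-of-homozygosity (ROH) mapping, Mendelian variant filtering, cohort
screening and evidence-based classification — plus a gene-dropping
simulator that generates fully truth-annotated consanguineous pedigrees
so the entire pipeline is testable without controlled-access sequencing
data.

## The problem

A recessively inherited congenital disorder appears in a handful of
unrelated animals born to normal parents inside a closed breeding
population. Each case is sequenced together with its sire and dam, and
compared against a large multi-breed control cohort. Finding the causal
allele then reduces to a chain of well-defined computations:

1. **QC** the jointly genotyped SNVs: biallelic autosomal sites called
   in all individuals with minor allele frequency > 0.05 and
   Hardy–Weinberg equilibrium exact-test p > 10⁻⁶.
2. **Verify parentage** from the genotypes themselves, using
   method-of-moments identity-by-descent estimates
   (PI_HAT = Z1/2 + Z2 ≈ 0.5 for true parent–offspring pairs).
3. **Map autozygosity**: sliding-window ROH detection (20-SNV windows,
   ≤ 4 hets per window, segments ≥ 200 kb, ≥ 66 SNVs, ≥ 1 SNV/50 kb)
   and the genomic inbreeding coefficient
   F_ROH = Σ ROH length / autosomal SNV-covered genome length.
4. **Filter genotype patterns** over each trio: a homozygous allele
   shared by all cases, private recessive alleles per case
   (case hom-alt, both parents het, ≤ 1 homozygous control), and two
   dominant de novo scenarios (isolated post-zygotic; sire germline
   mosaicism).
5. **Screen cohorts and classify**: allele frequencies and homozygote
   counts per population, breed specificity, and a transparent rule
   table combining segregation, rarity, in-silico deleteriousness votes
   and gene-level evidence into likely pathogenic / uncertain /
   likely benign labels.

The package ships the published cohort genotype-count table for the
eleven private homozygous protein-changing variants of three white-coat
Simmental calves, and reproduces its arithmetic and classification
exactly (see below).

## Worked example

`examples/discover_recessive_variant.py` simulates a sire–daughter
trio plus 100 unrelated controls, implants a recessive missense allele
in a pigmentation candidate gene inside an autozygous segment, and runs
the full pipeline:

```
simulated 104 samples x 23200 SNVs; implanted causal variant 1:5006389:T:G (TYR)
22815 SNVs pass QC (MAF > 0.05, HWE p > 1e-6, complete calls)
case ROH: 9 segments, F_ROH = 0.238 (expected ~0.25 for a sire-daughter mating)

7 candidate variants survive the recessive filter:
    variant_id   gene   impact  control_hom  roh_length_bp  votes         classification
10:1233822:C:A  G10_3 MODERATE            1        9975570      0          likely_benign
17:9149876:T:C G17_29 MODERATE            1        9940463      0          likely_benign
 1:5006389:T:G    TYR MODERATE            0        6153946      4      likely_pathogenic
23:3769535:A:G G23_11 MODERATE            1              0      0          likely_benign
29:1663995:G:T  G29_5 MODERATE            0        5851612      0          likely_benign
 2:8432667:G:T  G2_27     HIGH            0        9972630      0 uncertain_significance
 2:8446326:G:A  G2_27     HIGH            0        9972630      0 uncertain_significance

the implanted variant is recovered and classified 'likely_pathogenic' inside a 6.2 Mb ROH (truth IBD segment: 6.1 Mb)
```

The case's genomic inbreeding (0.238) matches the kinship of its
parents (a sire–daughter mating, F = 0.25); the implanted variant is
the only candidate that segregates, is absent from controls, sits in a
known candidate gene and carries ≥ 3 deleterious in-silico votes, so it
alone is labeled likely pathogenic.

The other examples cover the shipped variant table
(`screen_variant_table.py` — prints the 0.0187 Simmental allele
frequency of the GRID1 variant and the 2/5/4 label split), ROH and
F_ROH across pedigree templates (`roh_and_inbreeding.py`), and
QC/parentage checks (`relatedness_check.py`). A thin CLI mirrors the
library: `triomap simulate|qc|relatedness|roh|filter|screen|classify`.

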