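# Methods

`triomap` implements the analysis core of a trio-based whole-genome
rare-variant discovery study in cattle: three unrelated affected
calf/sire/dam trios sequenced against a large multi-breed control
cohort, with autozygosity mapping used to corroborate recessive
candidates. This note documents the models, the defaults and why they
were chosen, what the simulator does and does not emulate, and the
places where the design was genuinely open.

## Genotype model and quality control

All computation happens on a samples × sites matrix of diploid
biallelic calls coded 0/1/2 (copies of the alternate allele) with −1
for missing. Coordinates are 1-based inclusive; only the conversion to
BED at export switches to 0-based half-open. Multi-allelic VCF records
are split per alternate allele and phasing is ignored — no implemented
statistic uses phase. Sex chromosomes are excluded on load: the
analysis is defined over the 29 bovine-style autosomes.

The pre-ROH QC filter retains sites that are (i) called in all
individuals, (ii) minor allele frequency > 0.05, and (iii)
Hardy–Weinberg equilibrium exact-test p > 10⁻⁶. MAF is computed over
non-missing calls, which with complete-call enforcement equals the
all-sample frequency. The HWE test is the exact conditional test: given
the observed allele counts, the p-value is the total probability of all
heterozygote counts (same parity) whose conditional probability does
not exceed the observed one — the standard two-sided "probability mass
at most observed" convention, without mid-p. The implementation uses a
log-gamma formulation of the conditional distribution, normalized per
allele-count stratum, with a 10⁻¹⁰ relative tolerance when comparing
outcome probabilities so exact rational ties are not lost to floating
point. Against exact integer enumeration it agrees to < 10⁻¹² relative
error for every genotype configuration with n ≤ 200.

## Relatedness and parentage

Pairwise relatedness uses the method-of-moments estimator of the IBD
state probabilities (Z0, Z1, Z2) from observed identity-by-state
counts and their allele-frequency expectations, with negative
intermediate estimates projected onto the probability simplex and
PI_HAT = Z1/2 + Z2. Allele frequencies are pooled over the full loaded
cohort, cases included, mirroring a joint-genotyped single-breed panel.
No small-sample bias correction is applied; at the cohort sizes the
package targets (≥ 100 samples, ≥ 5,000 informative sites) the
estimator recovers parent–offspring pairs at PI_HAT 0.50 and duplicates
at 1.00 in simulation.

Parentage verification flags each declared parent–offspring pair PASS
when PI_HAT ∈ [0.4, 0.6] and Z0 ≤ 0.1 (configurable; the conventional
parent–offspring expectation is Z1 ≈ 1), and reports the
opposing-homozygote (Mendelian-error) rate alongside. Note that in a
sire–daughter mating the sire is simultaneously parent and maternal
grandsire of the case, so his true sharing exceeds 0.5 and he can fall
outside the default window; the window is a check for *ordinary*
parent–offspring pairs, and the report is designed to be read, not only
thresholded.

## Runs of homozygosity

The detector is a sliding-window method: a window of `window_snv` = 20
consecutive SNVs moves one SNV at a time; a window passes when it
contains ≤ 4 heterozygous and ≤ 1 missing calls; each SNV is scored by
the proportion of windows covering it that pass, and qualifies for a
run when that proportion exceeds 0.05 and its own call is not
heterozygous (a heterozygous SNV can never be a run member — runs of
*homozygosity*). Maximal stretches of consecutive qualifying SNVs
become segments when they span ≥ 200 kb, contain ≥ 66 SNVs, and average
at least one SNV per 50 kb. Window size, het/missing allowances,
length, count and density thresholds and the hit fraction are all
parameters. Two of these are design choices the published parameter
lists leave open: the per-window missing allowance (set to 1,
configurable) and whether density is evaluated per window or per
segment (implemented per segment). Segment bounds sit at the first and
last qualifying SNV positions, so reported lengths are distances
between genotyped markers.

F_ROH is the summed segment length divided by the autosomal genome
length covered by SNV positions — 2,488,313,529 bp for the full-scale
bovine SNV set this models, and `n_autosomes × chrom_length_bp` for
simulated genomes. Overlapping segments are an invariant violation and
raise. The shared-ROH search returns the maximal intervals covered by
at least one segment of *every* profile, via a boundary sweep; an empty
result is meaningful (it excludes a single shared causal allele).

The implementation is vectorised (cumulative sums over windows); the
test suite and acceptance script hold it equal to an independent
explicit-loop implementation of the same rule on randomized
chromosomes. One caveat found during design: at the *segment* level,
tightening `max_het_per_window` is not perfectly monotone — splitting a
run can create a sub-run that newly passes the per-segment density
filter — so the monotonicity property is asserted where it is a
theorem: the qualifying-SNV set, and the min-length/min-count filters.

## Mendelian filtering scenarios

Four genotype-pattern filters over protein-changing sites (impact HIGH
or MODERATE; annotation is consumed from the VCF, never computed):

* **recessive_private** — case 2, sire 1, dam 1 (parents are obligate
  carriers), and at most one homozygote among controls ("no more than
  once in the homozygous state"); heterozygous carriers among controls
  are allowed.
* **recessive_shared** — the intersection across trios of the private
  filter, for a single allele common to all cases.
* **denovo_postzygotic** — case 1, both parents 0, allele absent from
  every control.
* **denovo_mosaic** — case 1, sire 1 (germline mosaicism detectable in
  semen-derived DNA), dam 0, allele absent from all controls excluding
  the case's sire.

A missing call inside the trio disqualifies the site for that trio
(conservative, since the recessive model makes parents obligate
carriers); skipped counts are logged. Missing control genotypes count
as non-carriers — how missing controls were treated upstream is not
documented, so the permissive reading is used and flagged here. The
recessive filters run on the full (not MAF-filtered) matrix: a private
recessive allele is precisely the kind of site a MAF > 0.05 screen
deletes. ROH detection, by contrast, runs on the QC-filtered set, and
candidates are annotated with the containing case ROH by position.

## Cohort screening and classification

`screen_cohorts` aggregates per-population genotype-count triples:
allele frequency (2·n_varvar + n_refvar)/(2·n_total), optional removal
of the case from flagged cells, and breed specificity (variant alleles
confined to a single breed across all populations of the variant). The
shipped table of the 11 case variants reproduces the published
Simmental allele frequency of the GRID1 missense variant (0.0187,
case included, WGS + array cohorts combined), the 1,243 variant-free
array-genotyped Simmental for the TYR variant, and the 3 non-case NSMF
homozygotes.

Classification is a deliberately transparent rule table rather than a
full guideline engine, because the exact criterion-to-label mapping
used in guideline-based interpretation is judgement-laden and not
mechanically specified. The default table:

* **likely_pathogenic**: segregation consistent with the model AND at
  most 1 unaffected homozygote AND ≥ 3 of 5 in-silico tools deleterious
  AND gene-level or rarity-level support (known depigmentation
  candidate gene, breed-restricted occurrence, or predicted loss of
  function).
* **likely_benign**: ≤ 1 in-silico vote AND not loss-of-function AND
  (≥ 2 unaffected homozygotes OR no candidate-gene evidence).
* otherwise **uncertain_significance**.

The breed-specificity arm exists because a deleterious, perfectly
segregating missense allele restricted to one breed (the GRID1 case)
warrants a pathogenic call even outside the known gene list; the
loss-of-function exclusion in the benign rule keeps unscorable
frameshifts (0 predictor votes by construction) at uncertain rather
than benign. With the shipped evidence profiles this reproduces all 11
published labels (2 likely pathogenic / 5 uncertain / 4 likely benign).
The label is monotone: more in-silico support or fewer unaffected
homozygotes never moves a variant toward benign. Every fired rule is
reported. In-silico verdicts are always inputs (a vote count per
variant, 0–5 for the five predictors modeled); the package never
computes them. The shipped evidence table is a reconstruction from
narrative descriptions (the original supplementary tables are not
distributed) and is marked synthetic.

## The simulator

The generator exists so that every downstream stage can be validated
against known inheritance truth without the original sequencing data
(which sits in a controlled-access archive of ~110 genomes plus a
multi-thousand-genome consortium set). It gene-drops founder haplotypes
through a pedigree:

* **Genome**: 29 autosomes of 10 Mb (a desk-scale stand-in; all
  kb-denominated ROH thresholds remain exercisable), 800 SNVs per
  chromosome by default (23,200 sites, of which ≥ 20,000 typically
  survive QC in a 104-sample cohort), positions uniform, founder
  alternate-allele frequencies uniform on [0.05, 0.5].
* **Transmission**: per meiosis, crossover count Poisson with rate
  10⁻⁸ Morgan/bp (1 cM/Mb), crossover positions uniform, starting
  haplotype fair. Haplotype *ancestry* (founder-haplotype id per site)
  is tracked explicitly, so autozygosity is known exactly.
* **Templates**: sire–daughter mating (parent kinship 1/4), a
  first-cousin-style loop with the common ancestor couple ≥ 2
  generations back (kinship 1/16 at minimal depth, halving per added
  generation), and an outbred control template. Template depths are
  parameters, not estimates of the real (unpublished) loop depths.
* **Causal implantation**: recessive mode places the allele on one
  haplotype of the loop's shared ancestor and re-draws the causal
  chromosome's meioses until the case is homozygous (rejection
  sampling, so recombination shapes realistic IBD segment boundaries
  instead of being forced). The truth table records the implanted
  variant, the case's surrounding IBD segment, and everyone's carrier
  status. De novo and mosaic modes instead set the case (and for
  mosaic the sire) heterozygous post-drop with everyone else
  homozygous reference. The causal variant is annotated as a missense
  (MODERATE) change in a known pigmentation candidate gene by default,
  with 4 of 5 predictor votes; background MODERATE sites draw votes
  from a benign-leaning distribution and HIGH (LoF) sites carry 0
  votes, because missense predictors cannot score them.
* **Noise**: optional symmetric genotype-error and missingness rates
  (defaults 0 — the published genotypes are post-QC consensus calls);
  with both at 0 the output is Mendelian-consistent by construction
  except at the implanted site in the de novo modes.

What the simulator does **not** emulate: background linkage
disequilibrium beyond pedigree-induced IBD, realistic recombination
maps or hotspots, allele-frequency spectra of real SNV panels,
genotype-likelihood uncertainty, structural variants, and real
annotation complexity. Consequently, passing the simulation-based
acceptance checks demonstrates that the *algorithms* recover implanted
truth under the stated inheritance model — not that the pipeline's
power or false-positive rate on real WGS data matches the study's.

One scaling effect matters for interpretation: with 10 Mb chromosomes
and 0.1 Morgan per chromosome per meiosis, IBD tracts are
chromosome-scale, so a sire–daughter case (F ≈ 0.25) is autozygous
over whole chromosomes and three such cases can coincide anywhere by
chance. The three-trio negative-control study therefore uses the loop
template (F ≈ 1/16), where implanted segments remain the dominant
autozygosity signal; the check itself is the causal condition — no
region homozygous in all three cases contains any implanted causal
site, while each case's own site sits in its own detected ROH.

## Problem sizes and determinism

Default study sizes, chosen as the smallest that keep every threshold
meaningful: 100 controls, 800 SNVs × 29 autosomes per replicate, 50
replicates for the recovery study, 200 randomized 2,000-SNV chromosomes
for the ROH oracle sweep, and the exhaustive HWE comparison over all
genotype configurations with n ≤ 200. A fixed seed makes every emitted
file byte-identical across runs; `scripts/acceptance.py` derives all
stream seeds from its `--seed` argument.

## Known limitations

* The rule-table classifier is a transparent approximation of
  guideline-based interpretation, not an implementation of it.
* The method-of-moments relatedness estimator is uncorrected for
  finite-sample allele-frequency bias and assumes site independence.
* ROH detection implements only the window rule (no consecutive-runs
  mode), and density/missing-allowance conventions are explicit
  parameters precisely because published parameter lists underdetermine
  them.
* Genotype likelihoods (PL/GQ) are not modeled; calls are taken as
  given.
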