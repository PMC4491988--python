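# Methods

## Study design the package models

The unit of analysis is a multiplex consanguineous family in which a
recessive lethal fetal phenotype recurs. Under full penetrance and a
rare causal allele, every affected fetus is homozygous by descent (HBD)
at the causal locus, and the locus lies inside the affected's
autozygome. The package's four analysis stages — autozygome
delineation, variant filtering, cross-family mapping, founder-allele
detection — all follow from that single premise, and the simulator
exists to generate data in which the premise is true by construction so
each stage can be verified against exact truth.

## Pedigrees and inbreeding

Pedigrees are validated directed structures (acyclic, parents present,
founders parentless). Kinship is the standard recursion
φ(a,a) = (1+F_a)/2, φ(a,b) = [φ(father_b, a) + φ(mother_b, a)]/2
(recursing through the deeper individual), with founders non-inbred and
mutually unrelated; the inbreeding coefficient of an individual is the
kinship of its parents. Built-in union builders give the three designs
relevant in practice: first cousin (offspring F = 1/16), double first
cousin (1/8) and second cousin (1/64). The test suite checks these
against an independent Wright path-counting implementation.

## Gene dropping

* **Recombination**: Haldane model — crossover count per meiosis Poisson
  with mean (chromosome length in Mb) × rate, positions uniform, no
  interference. The rate defaults to 0.01 crossovers/Mb (1 cM/Mb), the
  genome-wide human average.
* **Genome**: 22 autosomes with lengths rounded from the human
  reference (≈ 2,879 Mb total), configurable. Sex chromosomes are
  excluded: the designs mapped are autosomal recessive.
* **Representation**: each haplotype is a breakpoint/label mosaic over
  founder haplotypes, so identity by descent is exact, not inferred;
  an individual is autozygous wherever its two mosaics share a label.
  Across replicates the mean autozygous genome fraction converges to the
  pedigree F (verified at 3-standard-error tolerance for all three
  union designs).
* **Genotypes**: the marker panel emulates a genotyping array with one
  marker per 30 kb. Per-marker alternate-allele frequencies are
  Beta(2,2) (array SNPs are ascertained to be common; mean
  heterozygosity outside ROH ≈ 0.4); an optional uniform range replaces
  the Beta when a hard minimum MAF is wanted. Missing calls are injected
  uniformly at 0.5 % — arrays have missingness but no canonical rate, so
  a typical post-QC value was fixed once.

## Planted causal variant and background exome

The causal allele rides on a single founder haplotype. Family
simulation conditions, by rejection sampling (cap 10,000 attempts, then
a named failure), on all affected children being autozygous for the
*same* founder haplotype at the planted position — the stronger
same-haplotype form is required for founder-variant semantics.
Chromosomes are independent under Haldane, so only the planted
chromosome is re-drawn during rejection; the rest of the genome is
dropped once after acceptance. The causal record is emitted homozygous
in affecteds, heterozygous or absent in other carriers, annotated to
pass every filter (frequency 0, missense with PolyPhen 0.999 / SIFT 0 /
high conservation by default; any consequence class can be planted).

Background variants model the annotated exome call set after primary
QC, scaled to desk size: 1,000 records per exome, of which 80 % exceed
the 0.1 % frequency cutoff (common SNPs), positions uniform over the
genome (so the fraction outside true-IBD segments is emergent,
≈ 1 − F), consequence mix 50 % non-coding / 20 % synonymous / 25 %
missense / 4 % LoF-class / 1 % in-frame, and 95 % of carriers
heterozygous — rare variants are almost never homozygous outside
autozygous segments. In-house cohort frequencies are binomial draws from
2 × 560 chromosomes at the population frequency. PolyPhen/SIFT scores of
background missense variants are uniform and conservation is N(0,1);
with the default cutoffs the expected number of background variants
surviving the full cascade is ≈ 0.03 per family, which is what makes the
planted variant the unique survivor in the large majority of replicates.
These rates were fixed from the above reasoning, not tuned.

## ROH calling

AutoSNPa-style callers do not publish a formal run definition, so the
caller uses a deterministic, oracle-checkable one: a run is a maximal
contiguous marker window containing at most `max_het` heterozygous
calls (default 1) and `max_missing` missing calls (default 5), never
bridging an inter-marker gap above `max_gap_bp` (default 1 Mb — an
assay-desert guard), found by a two-pointer sweep. Qualifying runs
(strictly longer than 2 Mb — the published criterion is "> 2 Mb" — and
≥ 50 supporting markers) are unioned into the per-sample autozygome;
overlapping qualifying runs, possible when a tolerated het sits near a
boundary, merge. Equivalence with an exhaustive O(n²) enumeration of
maximal tolerant windows is asserted over thousands of random vectors.

Coordinates are 0-based half-open (BED) internally; VCF's 1-based
positions are converted at the io boundary only.

## Variant filter cascade

Five rules, evaluated for every variant so retention is independent of
filter order, each verdict recorded in a per-variant trace:

1. **frequency** — max over population sources and the in-house cohort
   ≤ 0.001; absent annotation = 0 (novelty is the frequency-0 special
   case of the rule). A config switch makes the in-house rule
   presence/absence instead of thresholded.
2. **consequence** — class in the coding/splicing set.
3. **zygosity** — strictly homozygous (compound heterozygotes are out of
   scope by design; the autozygome logic is inherently homozygous).
4. **autozygome** — the 1-based position falls inside the affected's
   autozygome.
5. **pathogenicity** — LoF classes pass unconditionally; missense and
   in-frame indels need conservation ≥ cutoff and PolyPhen ≥ 0.9 and
   SIFT ≤ 0.05. Published pipelines state "predicted to be pathogenic by
   PolyPhen and SIFT" without numeric cutoffs; 0.9/0.05 are the
   tool-conventional choices and are exposed in config. The conservation
   default (1.2816) is the 90th percentile of the simulator's N(0,1)
   conservation score. Missing scores on a missense variant fail closed
   with a logged warning.

## HBD-LOD mapping

No linkage statistic is standard for this design, so the package uses
the minimal likelihood-ratio score implied by the model: under full
penetrance, P(affected HBD at the causal locus) = 1, while at an
unlinked locus it is F. An affected therefore contributes
log10(1/F) where its autozygome covers the position, and −∞ (exclusion)
otherwise; contributions add over affecteds and families. The
genome-wide maximum is bounded by Σ log10(1/F) — 1.20 for one
first-cousin proband, 2.41 for two — so a single family can never reach
the conventional threshold of 3, which is exactly why the founder
families must be combined. Scanning evaluates the score at every marker
and reports maximal runs above threshold. Called ROH (not true IBD)
defines HBD at scan time; the approximation is quantified in the
recovery tests (~99 % of two-family replicates recover the planted
locus at threshold 2). For display, −∞ is clamped to −10 in reports;
peak calling keeps exclusion semantics.

Founder-mutation detection groups retained variants identical by
(chrom, pos, ref, alt) across families; `shared_haplotype_span` measures
the surrounding interval over which all carriers are homozygous for
identical calls (missing calls tolerated up to a per-flank cap), since a
long shared homozygous haplotype is the expected footprint of descent
from a common ancestor.

## What the simulator does and does not capture

It reproduces the features the analysis relies on: long autozygous
tracts with the right expected genome fraction and length scale, array
genotypes with realistic heterozygosity and missingness, a rare-variant
frequency spectrum with a planted fully penetrant causal allele.
It does not model linkage disequilibrium, population structure or
relatedness between founders, mutation/genotyping error inside ROH
beyond the het tolerance, X-linkage, imprinting, reduced penetrance, or
compound heterozygosity. Passing tests therefore demonstrate
correctness of the algorithms under the stated model, not robustness to
every artifact of real array/exome data.

## Problem sizes and numerical choices

Default test/verification sizes: calibration 500 gene-drop replicates
on a 3,000 Mb genome; filter-recovery 500 families at default simulator
parameters; peak recovery 200 two-family replicates on the full default
genome (~96,000 markers). All randomness flows from explicit seeds;
identical parameters give byte-identical outputs, including through the
CLI (the run manifest records seed, package version and a hash of the
analytic parameters — not file paths — so moved inputs do not change the
fingerprint). Ties and degenerate inputs: empty variant lists and empty
autozygomes are valid (everything filters out; scans return no peaks);
zero-length intervals are dropped at normalization; an affected with
F = 0 is rejected by the mapping score with a named error since the
HBD likelihood ratio is undefined for a non-consanguineous union.

## Known limitations

* The HBD-LOD is single-point and ignores marker allele frequencies;
  it cannot exploit partial information the way multipoint likelihoods
  do, and its −∞ exclusions are only as reliable as the ROH calls.
* The 2 Mb / 50-marker ROH thresholds miss short autozygous segments
  (old inbreeding loops), and the conditioned causal tract is shorter
  than 2 Mb in roughly 0.7 % of first-cousin replicates — a known,
  quantified gap between called-ROH and true-IBD filtering.
* The in-house frequency model treats the cohort as a random sample of
  the population; real in-house databases share founders with the study
  families.
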