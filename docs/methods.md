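# Methods

## Model

`gwacc` treats a variant as a binary classifier of a binary phenotype and
scores it by contingency. For each variant, samples with known phenotype
are split into WT (code 0) and MUT (code 1); their genotypes are coded
REF (0), ALT (1) or missing (−2). Eight statistics on a single 0–100 %
scale follow from the four cell counts and the class totals (formulas in
the README). Two families:

- **realistic** — denominators are the *scored* samples only; measures
  correspondence among the data you actually have.
- **pessimistic** — denominators are the full class sizes N_WT, N_MUT,
  N_ALL = N_WT + N_MUT, so every missing genotype counts against the
  variant. With a disproportional phenotype (e.g. 1 mutant vs 299 wild
  types) this is the informative ranking: many variants tie at realistic
  100 %, and the pessimistic columns re-rank them by how much of the
  evidence is actually present. Missing_WT_gen / Missing_MUT_gen report
  the same information directly as a percentage of each class.

The averages (Avr_acc, Avr_acc_pes) weight the two classes equally
regardless of class size; the combined forms weight samples equally and
can therefore be dominated by the larger class.

Assumptions: the phenotype is binary (binning a quantitative trait is the
user's responsibility); one variant is scored at a time (no LD modeling,
no multi-locus effects); multiallelic sites are scored as REF vs any-ALT.

## Undefined values

A statistic with a zero denominator (an empty class, or a class with no
scored genotypes) is NA, and an average containing an undefined component
is NA. NA never raises; filtering drops NA rows. This is deliberate: a
class with no evidence has no defined accuracy, and silently substituting
0 or 100 would corrupt rankings in exactly the disproportional datasets
the pessimistic statistics exist for.

## Orientation: `cal` and `flip`

`cal` declares which phenotype class the reference genome belongs to
(`ref_is_wt` by default; `ref_is_mut` swaps the REF/ALT roles before
counting — note this differs from swapping the phenotype labels when
genotypes are missing). With `flip=True` each variant is evaluated in
both orientations and the one with the larger Avr_acc is reported
(`Flipped` column records the choice). The swap is applied before all
eight statistics, so the pessimistic columns flip jointly with the
realistic ones. Tie-breaks: equal Avr_acc keeps the `cal` orientation; a
defined Avr_acc beats an undefined one. With no missing data flip
guarantees Avr_acc ≥ 50 (antisymmetry: swapping alleles maps defined
Avr_acc to 100 − Avr_acc).

## Genotype decoding

- VCF decoding goes through htslib (cyvcf2). Biallelic records use the
  per-sample genotype classes directly; multiallelic records fall back to
  per-allele logic where any genotype composed entirely of non-REF
  alleles codes 1 (a binary REF-vs-rest contract). Any genotype with a
  missing allele, or ploidy > 2, codes −2.
- Heterozygotes have no natural place in a binary REF/ALT contrast; the
  default `het_mode="missing"` excludes them (keeping the
  realistic denominators meaningful), with `"alt"` and `"ref"` available
  for dominant/recessive codings.
- HapMap (GAPIT dialect): REF is the first allele of the `alleles`
  field, ALT the second (no reference genome is consulted); single-letter
  IUPAC and double-letter dialects are both accepted; `N`/`NN` are
  missing; an IUPAC ambiguity letter matching exactly the {REF, ALT} pair
  is a heterozygote, any other letter codes −2. A malformed alleles field
  voids the whole row (−2) with a warning.
- Chromosome labels are kept verbatim but joined/ordered through a
  normalizer (strip leading "chr", strip leading zeros; natural numeric
  order, non-numeric labels last).

## Rounding and output

All computation is in full double precision; half-up rounding to 2
decimals is applied only when writing tables or plot labels, and whole
numbers are rendered without trailing zeros ("81", not "81.00"). Missing
values serialize as "NA".

## p-value join

GWAS results are user-supplied (the scoring is fitting-model-independent).
The join key is the normalized (chrom, pos) pair; column mapping is
explicit (`colmap`) or by dialect preset (GAPIT, PLINK, TASSEL).
Duplicate positions keep the smallest p with a warning; p outside (0, 1]
has no finite −log10 and becomes NA with a warning.

## Plots

Manhattan plots put −log10(p) on y and color points by an accuracy metric
through a gray→saturated ramp (default bounds 0–100 %): gray→blue on
even-numbered chromosomes, gray→red on odd, so the accuracy accent and
the chromosome alternation coexist. The genome-wise view concatenates
chromosomes with a cosmetic gap of 2 % of the genome span; the
chromosome-wise view labels the top-k points (default 3) with their
metric value in parentheses. No significance line is drawn unless the
user supplies a threshold. Both functions return the exact
(x, y, color-value) table they drew — tests assert on that table, never
on pixels.

## Synthetic cohort generator

`gwacc.simulate` emits matched VCF / HapMap / phenotype / GWAS-results
files for one cohort and returns the per-variant class counts tallied
*during* generation, so the pipeline can be checked against ground truth
that never passed through the code under test. It models exactly what the
statistics consume: class sizes, a per-variant concordance probability
(P(WT carries REF) = P(MUT carries ALT)), and independent genotype/
phenotype missingness. Defaults mirror a proportional flower-color-style
design (42 WT, 98 MUT, 5 % unphenotyped, concordance 0.9, 2 % missing
genotypes). Deliberately absent: linkage disequilibrium, realistic allele
frequencies, heterozygous calls, genotyping error that correlates with
phenotype. Passing tests on generated data therefore validate the
counting and algebra, not robustness to population structure.

`glabrous_case_tables()` is the deterministic rare-phenotype benchmark:
299 WT + 1 MUT samples over 12 fully concordant chromosome-9 variants
whose per-variant missing-WT counts are {4,4,5,5,5,5,5,7,11,50,57,63}
(the first k WT samples per variant are the missing ones; which samples
are missing does not affect any statistic). The single mutant carries ALT
everywhere; annotation strings let the effect extractor reproduce the
expected labels, the missense p.Ala25Thr among them.

## Problem sizes

The routine test suite runs at desk scale (tens of samples × tens of
variants, 1000 randomized cohorts for the oracle-equivalence check) plus
one end-to-end run at 50,000 variants × 300 samples — the scale of a
regional scan of a resequenced panel — covering file writing, htslib
import, scoring with flip, the p-value join and both plots. Larger
genotyping-chip datasets (tens of thousands of markers genome-wide) are
the same code path; memory is one int8 per call.

## Known limitations

- Binary phenotypes only; no covariates, no multi-class support.
- Accuracy is a descriptive concordance measure, not a test statistic:
  no p-value, no multiple-testing correction is attached to it.
- VCF region extraction is a linear scan (no tabix); fine at the target
  scale, wasteful on biobank-scale files.
- Case-study totals that depend on external
  panels are not reproduced here; the deterministic benchmark reproduces
  the reference per-variant accuracy table instead.
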