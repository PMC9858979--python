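# gwacc

Genotype–phenotype concordance ("accuracy") scoring for GWAS results.

A GWAS p-value measures how well a variant fits an association model; it
does not directly measure how well the variant's alleles track the
phenotype. `gwacc` post-processes GWAS results for a **binary** phenotype
(wild type / mutant) by scoring every variant's *direct correspondence* to
the phenotype on a 0–100 % scale, independently of the fitting model. This
is aimed at "GWAS to gene" work — picking a high-accuracy tagging marker
from a genotyping panel, turning it into a **synthetic phenotype**, and
re-scoring a resequenced panel around it to rank candidate causative
mutations — for any species, from standard VCF or HapMap input.

## The statistics

Per variant, samples of known phenotype are cross-tabulated into
N<sub>WT-REF</sub>, N<sub>WT-ALT</sub>, N<sub>MUT-REF</sub>,
N<sub>MUT-ALT</sub> (class totals N<sub>WT</sub>, N<sub>MUT</sub>,
N<sub>ALL</sub> = N<sub>WT</sub> + N<sub>MUT</sub> include samples with
missing genotype). Realistic accuracies use only scored samples:

    Acc_WT        = 100 · N_WT-REF / (N_WT-REF + N_WT-ALT)
    Acc_MUT       = 100 · N_MUT-ALT / (N_MUT-REF + N_MUT-ALT)
    Avr_acc       = (Acc_WT + Acc_MUT) / 2
    Comb_acc_real = 100 · (N_WT-REF + N_MUT-ALT) / (N_WT-REF + N_WT-ALT + N_MUT-REF + N_MUT-ALT)

Pessimistic accuracies count missing genotypes against the variant —
essential when the phenotype is strongly disproportional (one mutant among
hundreds of wild types):

    Acc_pes_WT    = 100 · N_WT-REF / N_WT
    Acc_pes_MUT   = 100 · N_MUT-ALT / N_MUT
    Avr_acc_pes   = (Acc_pes_WT + Acc_pes_MUT) / 2
    Comb_acc_pes  = 100 · (N_WT-REF + N_MUT-ALT) / N_ALL

A zero denominator makes a statistic undefined (NA), and an average with
an undefined component is NA.

## Worked example

The bundled benchmark rebuilds a rare-phenotype cohort: 299 pubescent
(WT) and 1 glabrous (MUT) soybean accessions over the 12 variants of a
4 Mbp chromosome-9 window that correspond perfectly to the phenotype,
differing only in how many WT genotypes are missing.

```python
import gwacc

gen, phen = gwacc.glabrous_case_tables()
acc = gwacc.calc_accuracy(gen, phen)
print(acc.data[["POS", "Avr_acc", "Avr_acc_pes", "Acc_pes_WT", "Comb_acc_pes",
                "Missing_WT_gen"]].round(2).head(3))
```

```
        POS  Avr_acc  Avr_acc_pes  Acc_pes_WT  Comb_acc_pes  Missing_WT_gen
0  46340547    100.0        99.33       98.66         98.67            1.34
1  47953315    100.0        99.33       98.66         98.67            1.34
2  47318232    100.0        99.16       98.33         98.33            1.67
```

Every variant has Avr_acc 100 (each scored WT carries REF, the single
mutant carries ALT), but the pessimistic columns separate them: row 0 has
4 of 299 WT genotypes missing, so Acc_pes_WT = 100·295/299 = 98.66 and
Comb_acc_pes = 100·296/300 = 98.67. Variants with 50+ missing WT
genotypes fall to ~80 % pessimistic accuracy — missingness, not
discordance, is what distinguishes the candidates. Only one of the 12 is
a missense variant (`missense_variant p.Ala25Thr`), making it the top
causative-mutation candidate.

The same pipeline from the shell, including a p-value join, an accuracy
filter, and Manhattan plots colored by accuracy (blue ramp on even
chromosomes, red on odd):

```sh
gwacc acc --vcf cohort.vcf --phenotype phen.txt --gwas results.csv \
      --flip --filter-metric Avr_acc --filter-threshold 80 \
      --plot --plot-chrom 9 --out run1
gwacc synth --vcf panel.vcf --locus 9:47548832 --out synthetic_phen
gwacc simulate --n-wt 42 --n-mut 98 --n-variants 1000 --outdir sim/
```

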