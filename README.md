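# triadglm

Joint log-linear modelling of **parental allelic-interaction effects** and
**fetal genotype effects** in case-parent triads and dyads at diallelic SNPs.

The core model treats the 15 Mendelian-consistent (mother, father, child)
dosage combinations as multinomial/Poisson cells with a transmission-
multiplicity offset. On top of the parental main-dose terms it supports

* fetal parameterizations: none, multiplicative dose-response (`dose`), or a
  free single-/double-dose response (`free`);
* parental interaction codings: `multiplicative`, `dominant`,
  `complementary` (parents homozygous for opposite alleles) and
  `threshold` (combined parental effect-allele count ≥ k).

Complete triads are fitted by Newton-Raphson on the offset Poisson
likelihood; families with one missing parent enter via the marginal
likelihood and an EM algorithm, with standard errors from the observed-data
information. Effects are reported as relative risks with 95% CIs and Wald
p-values; a genome-wide scan driver adds minor-allele orientation, MAF
filtering, Benjamini-Hochberg q-values, a Hardy-Weinberg test and the
genomic inflation factor. A simulation engine draws triad/dyad data at the
cell level and estimates power/type-I error for any scenario.

## Package layout

| module               | contents                                                        |
| -------------------- | --------------------------------------------------------------- |
| `triadglm.cells`     | triad/dyad cell enumeration, classification, count tables       |
| `triadglm.design`    | model specs, interaction/fetal codings, design matrices         |
| `triadglm.fit`       | Newton/EM maximum likelihood, Wald effects, HWE and LR tests    |
| `triadglm.simulate`  | cell-level simulation, power/type-I Monte-Carlo driver          |
| `triadglm.scan`      | per-SNP genome scan, FDR q-values, genomic lambda, TSV output   |
| `triadglm.plink`     | PLINK 1 bed/bim/fam reader/writer, pedigree resolution          |
| `triadglm.datasets`  | synthetic family-genotype tables and filesets for testing       |

## CLI

```sh
# genome scan from a PLINK fileset (or --doses TSV)
triadglm scan --bed data.bed --bim data.bim --fam data.fam \
    --fetal free --parental complementary --min-maf 0.01 \
    --out scan.tsv --qq-out qq.tsv

# Monte-Carlo power for the interaction Wald test
triadglm power --maf 0.10 --maf 0.15 --rr-int 2.2 --model complementary \
    --n-triads 1336 --reps 1500 --alpha 5e-8 --seed 1 --out power.tsv

# simulate a synthetic dataset (dose TSV and optionally a PLINK fileset)
triadglm simulate --n-snps 100 --n-triads 1000 --maf 0.2 --rr-int 1.5 \
    --seed 7 --out doses.tsv --plink-prefix sim

# single-SNP fit from a count-table TSV
triadglm fit --counts counts.tsv --fetal free --parental complementary
```

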