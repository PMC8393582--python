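# slafbsa

A toolkit for bulked-segregant analysis of pooled reduced-representation
(SLAF-seq) data in an animal-breeding setting, modelled on marketing-weight
selection in geese.  It implements the complete computational chain of such a
study — and a synthetic-data generator that emulates the study design — so
every stage can be exercised, tested and rerun without any sequencing data:

1. **Sib-based breeding values.**  A nested paternal half-sib model
   (sires × dams × full-sib progeny) is fitted by expected-mean-squares
   ANOVA; the sire variance gives the additive variance
   (σ²ₛᵢᵣₑ = ¼σ²A), and each gosling's estimated breeding value is
   â = ½(âⱼ + âₖ) + h²𝓌·e, with parental values taken as
   h²-shrunken family-mean deviations, e the deviation from the full-sib
   family mean and h²𝓌 = ½σ²A/σ²ₑ the within-family heritability.
2. **Extreme bulks and pooled-locus statistics.**  The 20 lowest- and
   20 highest-EBV males form two DNA pools.  Per locus, the toolkit computes
   the Phred quality Q = −10·log₁₀(p), the Euclidean distance between the
   bulks' base-fraction vectors, the per-bulk SNP index M/(M+P) and its
   between-bulk difference, and applies the joint filter
   ED ≥ 0.7 ∧ |Δ(SNP index)| ≥ 0.5 ∧ Q ≥ 30, plus
   transition/transversion accounting.
3. **Bulk association.**  Pearson χ² (1 df) on each locus's 2×2 table of
   focal-allele depths, Benjamini–Hochberg and Bonferroni adjustment, and
   staged candidate selection (Bonferroni survivors / top-k).
4. **Genotype–trait analysis.**  Shapiro–Wilk normality check, one-way ANOVA
   with Duncan's multiple-range lettering, allele/genotype frequencies, and
   additive ({0,1,2}) / dominance ({0,1,1}) / recessive ({0,0,1}) effect
   regressions with AIC.
5. **SNP networks.**  Per locus the AIC-best genotype-mode coding
   (additive / dominant / over-dominant), stepwise multiple regression with a
   p < 0.05 entry/stay rule, enumeration of surviving 2–4-locus networks
   ranked by AIC, per-locus homozygote substitution effects in grams, and
   Spearman correlation matrices with average-linkage clustering.
6. **Relative expression.**  2^−ΔΔCT quantification against a reference gene
   and a calibrator genotype group, with two-tailed t-tests between genotype
   groups (on log₂ RQ by default).

The synthetic generator produces Mendelian-consistent genotypes in a
sib-structured flock, phenotypes with a configured narrow-sense heritability
(default 0.29), Poisson/multinomial pooled base depths at ~25× per bulk with a
sequencing-error-driven quality value, and replicate-structured qPCR CT
tables.

## Worked example

```python
from slafbsa.config import RunConfig
from slafbsa.pipeline import run_pipeline

cfg = RunConfig(out_dir="bsa_out", seed=3)
cfg.simulation.seed = 3
res = run_pipeline(cfg)
print(res.sib_results.summary())
print("candidates:", res.candidates)
print(res.networks[0].summary())
```

prints

```
Sib-family model of marketing weight
============================================
No. observations                         320
No. sire families                         20
No. full-sib families                     80
Trait mean (kg)                       3.8822
--------------------------------------------
sigma2_sire (kg^2)                   0.01218
sigma2_dam (kg^2)                    0.01756
sigma2_within (kg^2)                 0.21481
sigma2_A = 4*sigma2_sire             0.04870
h2 (narrow-sense)                     0.1991
h2w (residual)                        0.1134
mean EBV (kg)                       -0.00000
============================================
candidates: ['L0633', 'L0334', 'L0846', 'L0490', 'L0934', 'L0308']
SNP network (2 loci)   R2=0.191  AIC=-273.26
locus       mode               coef (kg)           p  subst. (g)
L0633       additive              0.2411    3.18e-06         482
L0846       additive             -0.1207      0.0287        -241
```

The fitted sib model recovers a heritability estimate around the simulated
0.29 (0.20 on this 320-gosling draw — family-level estimates are noisy at
flock scale), the mean EBV is zero by construction, and the bulk screen's top
candidate `L0633` is the planted major locus (true effect 0.32 kg per allele;
the network reports a 482 g homozygote substitution, i.e. ~0.24 kg/allele).
The expression stage then detects the planted 1.5-fold up-regulation between
homozygote groups of the top candidate (mean RQ 1.36, p = 1.4 × 10⁻⁵).

The same stages are available from the shell:

```sh
bsa run --seed 3 --out-dir bsa_out        # full pipeline
bsa score --in depths.tsv --out scored.tsv --ed-min 0.7 --delta-min 0.5
bsa test  --in scored.tsv --out assoc.tsv --alpha 0.05 --top-k 31
bsa ebv --pheno phenotypes.csv --out ebv.csv
bsa networks --geno genotypes.tsv --pheno phenotypes.csv --out networks.json
bsa express --ct ct_table.csv --calibrator ref_hom --out expression.csv
```

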