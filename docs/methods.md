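# Methods

This note records the models, default parameters and design choices behind
`slafbsa`, in the order the pipeline runs them.

## Synthetic study design

The generator emulates a commercial goose flock phenotyped for marketing
weight (MW, body weight at nine weeks, kg) under a nested paternal half-sib
mating design: `n_sires` sires each mated to `dams_per_sire` dams, with
`progeny_per_dam` full sibs per dam.  Defaults (20 × 4 × 4 = 320 progeny,
roughly 160 of them male) mirror a flock in which ~167 males are phenotyped;
family sizes are not dictated by the emulated study and are plain
configuration.

**Genotypes.**  Loci are independent biallelic SNPs.  Founder alt-allele
frequencies are Uniform(0.1, 0.9) (causal loci default to 0.5, the most
informative case for a planted signal); founders are Hardy–Weinberg draws and
progeny receive one allele from each parent (Bernoulli(dosage/2) per gamete),
so Mendelian consistency holds exactly and is asserted in tests.
Substitution classes are drawn with a 69.96% transition fraction so synthetic
panels reproduce a ti/tv ratio near 2.33.  Linkage is not simulated.

**Phenotypes.**  MW = mean + sex offset + causal genotypic values (centred)
+ polygenic BV + N(0, σ²E).  Genotypic values per alt-dosage {0,1,2} are
additive {0, a, 2a}, dominant {0, 2a, 2a} or over-dominant {0, d, 0}.  With
σ²P = `trait_sd`² and h² = `heritability`, the polygenic additive variance is
h²σ²P minus the additive variance already contributed by causal loci
(2pqα² with α = a + d(1−2p)); a configuration whose causal loci exceed the
additive budget is rejected.  σ²E = (1−h²)σ²P, so realised narrow-sense
heritability matches the configured value in expectation (dominance modes add
a small amount of dominance variance on top of σ²P).  True breeding values
(polygenic + Σα(g−2p)) are retained for validation.

**Defaults.**  h² = 0.29 and a male trait mean of 4.11 kg with a −0.6 kg
female offset match the emulated flock; `trait_sd` = 0.5 kg (CV ≈ 12%, a
realistic figure for gosling body weight, giving σ²A ≈ 0.0725 kg²).  The
causal architecture is deliberately "major gene plus polygenes": per-allele
effects [0.32, 0.1, 0.08, 0.07, 0.06] kg.  The four minor effects span the
range implied by reported homozygote-substitution effects for this trait
(110–400 g ⇒ ~0.055–0.2 kg per allele).  The lead locus is sized so that an
extreme-bulk contrast of the magnitude such studies report (ED ≥ 0.7, i.e. a
bulk allele-frequency difference ≥ 0.5) is reachable: with 20-individual
bulks selected on EBVs of accuracy ~0.6, small-effect loci produce bulk
frequency differences of only 0.3–0.4 and can never pass the printed filter —
an extreme-bulk design fundamentally presupposes a major locus.

**Pooled depths.**  Per locus and bulk, total depth ~ Poisson(`mean_depth`,
default 25 per bulk ⇒ ~50 combined), base counts multinomial around the
bulk's true alt frequency; a read is miscalled with probability
`sequencing_error_rate` (default 0.001), uniformly to the other three bases.
The emitted quality value is −10·log₁₀(error_rate) (capped at 60 when the
error rate is zero, where the Phred transform is undefined).  One quality
value per locus is carried; per-base qualities are not modelled.

**CT tables.**  Reference-gene CT is constant (18 cycles) plus Gaussian
noise; target CT = reference + baseline ΔCT (5 cycles) − log₂(fold change)
+ noise, with three technical replicates per sample and seven biological
samples per genotype group by default.

**What the generator does not emulate** — and hence what passing tests do
not establish about real data: linkage disequilibrium and haplotype
structure, genotyping/variant-calling error, shared-environment (litter/pen)
effects beyond the dam variance, genotype×sex interaction, and
amplification-efficiency differences in qPCR.

## Breeding values

Variance components of the nested sire/dam model come from Henderson-style
expected mean squares with the standard unbalanced-design coefficients
(verified against lme4 REML on balanced data, and against simulation truth
in the test suite); negative solutions are clipped at zero.  σ²A = 4σ²ₛᵢᵣₑ via
the paternal half-sib covariance; h² = σ²A/σ²P is clipped to [0, 1].  The
within-family heritability is implemented exactly as ½σ²A/σ²ₑ with σ²ₑ the
within-full-sib-family residual variance; a `h2w_definition="phenotypic"`
switch substitutes the total phenotypic variance in the denominator for users
who prefer the textbook shrinkage.  Parental breeding values are estimated as
h²-shrunken progeny-family-mean deviations — the simplest sib-consistent
choice, made explicit so the EBV orientation is auditable.  The pipeline fits
both sexes after removing the sex mean difference (full- and half-sib
information from the whole flock) and then selects the extreme bulks from the
male stratum.

## Pooled-locus statistics

ED operates on within-bulk base **fractions**, not raw depths: only
fraction-space distances lie in [0, √2] and match the magnitudes such
studies report; for a biallelic locus ED = √2·|Δ allele frequency|.
The SNP index of a bulk is M/(M+P) with M the alternative-allele and P the
reference-allele depth (orientation recorded per locus).  The joint filter
uses inclusive thresholds (ED ≥ 0.7, |Δ(SNP index)| ≥ 0.5, Q ≥ 30); the
delta form is filtered because per-bulk indices alone do not separate bulks.
Multi-allelic contamination (miscalled bases) contributes to ED through the
full 4-vector but not to the SNP index.  No sliding-window smoothing along
chromosomes is applied.

## Bulk association

Each locus's 2×2 table of focal-allele read depths (bulk × allele) is tested
by Pearson χ² with 1 df and no continuity correction (expected counts are
large in the ~25× regime; a count-based variant can be fed in by
constructing the table from called genotypes instead).  Benjamini–Hochberg
and Bonferroni adjustments preserve input order; ranking ties break by locus
id for determinism.  Candidate selection prefers Bonferroni survivors at the
5% family-wise level, capped at the top-k (default 31) smallest raw
p-values.

## Genotype–trait analysis

One-way ANOVA per locus; Duncan's multiple range test assigns letters using
studentized-range quantiles at the stepwise protection level
αₚ = 1 − (1−α)^(p−1) for a span of p ordered means, harmonic-mean group size
for unequal n, and the convention that a range inside a non-significant
range is itself non-significant.  Classes with fewer than two observations
are dropped with a warning; a zero-variance trait raises rather than
returning an undefined F.  The additive/dominance/recessive decomposition
fits three separate single-predictor regressions on {0,1,2}/{0,1,1}/{0,0,1}
codings of alt-allele dosage — slopes, not genotype-mean contrasts — with the
constant-free Gaussian AIC n·ln(RSS/n) + 2k (absolute AIC values are
therefore comparable within this package only).

## SNP networks

Single-locus mode selection fits additive (0,1,2), dominant-ref (0,0,2),
dominant-alt (0,2,2) and over-dominant (0,1,0) codings and keeps the AIC
minimiser, breaking ties toward the simpler genetic hypothesis.  Stepwise
selection (forward with a stay-check, or backward) uses partial-F p < 0.05
to enter and stay; collinear codings drop the later-entering locus with a
warning.  Because the original search protocol behind published multi-marker
"networks" is rarely stated, the toolkit enumerates **all** subsets of the
stepwise survivors of size 2–4 whose members remain jointly significant and
ranks them by AIC — reproducing the networks-of-each-size structure without
guessing a traversal order.  The homozygote substitution effect of a member
is coef × (code₂ − code₀) × 1000 g (2000·coef for additive loci);
over-dominant members predict no homozygote contrast and are excluded from
the report by default.  Spearman matrices use midrank ties; display order
comes from average-linkage clustering of 1 − |ρ|.

## Relative expression

ΔCT averages technical replicates within sample; ΔΔCT is taken against the
mean ΔCT of the calibrator group (the reference-homozygote group by
default), so the calibrator's geometric-mean RQ is exactly 1.  Group
comparisons are two-tailed t-tests on log₂ RQ = −ΔΔCT by default — RQ is
log-normal under Gaussian CT noise — with raw-RQ testing available via
configuration.

## Numerical and formatting choices

All randomness flows from a single integer seed per run (stage-level streams
are derived as seed+1, seed+2 …), and output bundles are byte-identical
across reruns: file headers carry the package version, seed and a hash of
the analysis configuration (paths excluded).  Tables are UTF-8 TSV/CSV with
`#`-prefixed metadata, `NA` for missing values and 1-based coordinates; a
VCF shim maps two-sample AD fields onto the locus-depth table.  Report
percentages and depth folds round to two decimals; full precision is kept
internally.

## Problem sizes used in the checks

The test suite validates heritability recovery on 100 sires × 5 dams × 8
progeny over 50 replicates, EBV accuracy on a 2 000-progeny population,
filter/test calibration on 1 000–2 000 simulated null loci, network recovery
on 400-progeny populations with 10 loci over 100 replicates, and ΔΔCT
recovery over 25 replicates of 7 + 7 samples — sizes chosen to make the
Monte-Carlo error small relative to each tolerance while the full suite
stays inside a coffee break on one CPU.

## Known limitations

The sib model is a nested two-factor approximation, not an animal-model
BLUP with a full relationship matrix; maternal and common-environment
effects are absorbed into the dam variance and inflate nothing but the dam
component under the simulated design, whereas in real flocks they would bias
h² if interpreted naively.  The filter thresholds are taken as printed and
inclusive; they are not power-optimal for small-effect loci (see the
major-gene note above).  Stepwise selection with per-step α = 0.05 carries
the usual multiplicity optimism at scale; the enumerated networks are
descriptive models, not causal claims.
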