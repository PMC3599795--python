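# Methods

## The measurement model

A qPCR well containing quantity *q* of amplifiable template, read by a
probe with per-cycle amplification base *E*, crosses the fluorescence
threshold at

    Ct = c0 − ln(q) / ln(E) + ε,   ε ~ Normal(0, σ_rep)

where *c0* is the probe's intercept (the Ct of one unit of template) and
σ_rep the pipetting-replicate noise. With *E* = 2 each halving of template
costs exactly one cycle. Everything the package computes follows from this
one relation.

**Relative expression.** For each patient the target gene's mean cDNA Ct
is referenced against the single grand mean of all pooled housekeeper Ct
values (three genes × three replicates = nine values; pooling is one grand
mean, not a mean of per-gene means): ΔCt = mean(target) − mean(pooled
housekeepers), relative expression = 2^−ΔCt. This assumes perfect doubling
for both target and reference; no efficiency-corrected (Pfaffl-style)
variant is provided. Adding a constant to every Ct leaves ΔCt unchanged,
and rel_expr is strictly monotone in both means — both are tested
properties.

**Allelic ratios.** A dual-labelled allelic-discrimination well reads the
two alleles simultaneously (FAM = minor-allele probe, VIC = major, fixed
per assay configuration so that a ratio of 0.36 always means a
minor-allele deficit). The raw well ratio is 2^(VIC Ct − FAM Ct); FAM and
VIC readings sharing a replicate index are paired into one well. Because
the two probes can differ in chemistry and intercept, the raw ratio of a
perfect 1:1 mixture is not 1; the same sample's genomic DNA estimates that
assay-specific 1:1 point, and

    corrected ratio = mean(cDNA well ratios) / mean(gDNA well ratios)

cancels any channel offset exactly (an algebraic identity at zero noise,
a tested invariant otherwise). Arithmetic means are used at both the
normalisation and cohort level, matching how allelic-ratio averages are
conventionally reported; a `log_scale` option switches both steps to
geometric means for sensitivity analysis. Note one consequence of the
arithmetic choice: swapping the channel labels inverts every raw well
ratio exactly, but inverts the corrected ratio only approximately
(exactly under `log_scale`).

**Significance.** The per-sample test is a two-sided Mann–Whitney U of the
raw cDNA well ratios against the raw gDNA well ratios — raw, not
corrected, since corrected gDNA wells would be compared against their own
mean. With the default 5 + 5 replicates the test is exact and its smallest
attainable two-sided p is 2/252 ≈ 0.0079. The cohort test compares the
per-patient mean cDNA ratios against the per-patient mean gDNA ratios
(two-sided Mann–Whitney); per-patient means rather than pooled wells keep
patients exchangeable units. Test policy throughout the package: exact
permutation distribution when both groups have ≤ 8 observations and the
pooled sample is tie-free; otherwise the midrank normal approximation with
tie correction and no continuity correction. Omitting the continuity
correction makes the two-group Kruskal–Wallis statistic exactly the square
of the standardised U and makes their p-values agree — a tested
equivalence. A fully tied pooled sample returns p = 1. All tests are
two-sided and no multiple-testing correction is applied; the stratified
output labels its sidedness.

**Assay QC.** Discrimination: observed well ratios of artificial allele
mixtures are regressed on the expected mixture ratios in log2–log2 space
by ordinary least squares; slope ≈ 1 and r² ≈ 1 certify linear
discrimination, and `detectable(r)` reports whether a ratio lies inside
the validated mixture range. The default mixture grid is two-fold steps
from 8:1 to 1:8, which brackets the effect sizes of interest with margin.
Efficiency: mean Ct per dilution point is regressed on log10(input), and
the amplification base is the standard dilution-slope definition
E = 10^(−1/slope) (slope −3.3219 ⇔ E = 2 ⇔ 100%); percent efficiency is
(E − 1) × 100. A non-monotone dilution profile is logged as a warning but
still fitted. Default pass thresholds (slope ∈ [0.9, 1.1], r² ≥ 0.98) are
conventions, exposed in the CLI.

**Association.** The allelic (per-chromosome) test on a 2×2 allele-count
table: OR = (a/b)/(c/d), Wald 95% CI = exp(ln OR ± 1.96·√(1/a + 1/b +
1/c + 1/d)), Pearson chi-square with 1 df and no Yates correction. When
only printed frequencies and diploid cohort sizes are available, counts
are reconstructed as round(freq × 2N); this reconstruction reproduces a
published example (OR 1.069, CI 1.015–1.127) to printed precision. Zero
cells get the Haldane–Anscombe +0.5 correction with a warning. Genotypic
and covariate-adjusted trend tests are out of scope; published GWAS
p-values computed under unknown covariate models are therefore only
approximated by the allelic chi-square.

**LD and haplotypes.** From four two-locus haplotype frequencies:
D = p_AB − p_A p_B, D′ = |D|/D_max with the usual sign-dependent D_max,
r² = D²/(p_A q_A p_B q_B). Monomorphic loci make LD undefined and are
returned flagged rather than raising. Unphased genotypes are handled by an
EM estimator in which the double heterozygote is the only phase-ambiguous
class; with none present EM reduces exactly to gamete counting.
Convergence: max frequency change < 1e−8 or 1000 iterations
(non-convergence flagged, best estimate returned); the observed-data
log-likelihood is non-decreasing across iterations (tested).

## The synthetic cohort

The generator emulates the study conditions the analyses assume:

- **Genotypes**: each patient is two independent draws from an
  eight-haplotype distribution over (rs2615977 T/G, rs1676486 C/T,
  rs9659030 A/G). The default distribution is constructed from the panel
  MAFs (0.239, 0.202, 0.173) and signed pairwise disequilibria chosen to
  match pairwise r² = 0.03 / 0.08 / 0.09, with a three-way term of −0.0124
  to keep all eight frequencies non-negative (the implied D′ are
  0.61 / 0.35 / 0.33; the published D′/r² pairs are not exactly jointly
  attainable, and r² was preferred since it drives power). Phase is kept
  in the truth record for validating the EM estimator but never exposed to
  the analyses.
- **Expression**: per-patient log2 baseline ~ Normal(0, 4), whose range
  across 30 patients exceeds 200-fold essentially always, matching the
  observed between-patient spread; housekeepers are constant apart from
  replicate noise (baselines 24 / 18 / 10 cycles for HPRT1 / GAPDH / 18S,
  typical instrument values).
- **Allelic wells**: 5 replicates per template. gDNA wells carry the two
  alleles 1:1; cDNA wells carry minor = r × major, where r = 0.36 (the
  default true ratio) whenever the patient is heterozygous at the causal
  SNP rs1676486, else 1. A per-assay override (`assay_true_ratios`) can
  pin any assay's ratio, reproducing phenomenologically the observation
  that imbalance at one transcript SNP need not appear at another — no
  mechanism is modelled. Replicate noise defaults to σ_rep = 0.1 cycles,
  independent between the FAM and VIC channels (the dual-probe assay
  shares a well, but absent a known within-well correlation the default is
  independence, with `channel_noise_correlation` exposed).
- Hip/knee, age and sex are decorative covariates with no simulated
  effect, since none is modelled downstream.

Identical configurations (same seed) give bit-identical cohorts; genotype
and plate generation use separate seed streams.

What the generator does *not* emulate: RNA degradation kinetics, plate
spatial or batch effects, undetermined wells, allele-specific probe
cross-hybridisation, and population structure. Passing tests therefore
show that the estimators recover their own generative truth under
realistic noise — not that real cartilage data are free of those
artefacts.

## Problem sizes and numerical choices

Simulation-backed checks use cohorts of 22 heterozygotes (5 + 5 wells) —
the informative sample size of the motivating study — with 200 replicate
cohorts for ratio-recovery checks (true ratios 0.25–2 recovered within
5%), 1000 replicates for type-I-error and CI-coverage calibration, and
500 for the uniformity of null stratified p-values; the EM validation uses
5000 patients. Undetermined Ct wells are excluded from all means and tests
(logged per well); a patient needs at least two usable wells per template
(configurable) or is skipped with a warning at the model level and raises
at the function level. Corrected ratios are exact to 1e−12 of their
defining identity mean(cDNA)/mean(gDNA); genotype classes with zero
members are dropped before testing, and a comparison needs at least two
non-empty classes.

## Known limitations

- Perfect-doubling (2^−ΔCt) quantification only; use the QC efficiency
  estimate to judge whether that assumption holds for an assay.
- The allelic association is the plain count-based test; it cannot
  reproduce covariate-adjusted GWAS statistics.
- The EM estimator is two-locus; three-locus haplotype frequencies are a
  generator-side concept only.
- The per-sample exact test at 5 + 5 wells cannot yield p < 0.0079;
  per-sample significance saturates rather than scales with effect size.
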