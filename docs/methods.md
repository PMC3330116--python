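# Methods

`twinewas` implements a twin-cohort epigenome-wide analysis pipeline —
methylation heritability, cis-meQTL mapping, EWAS for age and
age-related phenotypes, MZ-discordance scans, a
genotype–methylation–phenotype mediation-overlap screen, and functional
annotation — together with a synthetic twin-cohort generator that
supplies ground truth for every stage. This note records the models,
the generator's assumptions, the numerical choices, and what the
synthetic results do and do not demonstrate.

## The twin mixed model

Every association scan fits, per CpG probe (or per trait, in the GWAS),
the Gaussian linear mixed model

    y = X β + u_family + u_mzpair + ε,
    u_family ~ N(0, σ²_f),  u_mzpair ~ N(0, σ²_z),  ε ~ N(0, σ²_e),

where `u_family` is shared by the two members of any twin pair and
`u_mzpair` only by monozygotic co-twins. The implied within-pair
covariance is σ²_f for DZ pairs and σ²_f + σ²_z for MZ pairs, which is
the random-effect encoding of "family structure and zygosity": zygosity
enters as an extra shared intercept, not as a fixed effect, and MZ
covariance is never below DZ covariance. A defensible alternative
reading — a zygosity-group intercept common to all MZ individuals —
would not reproduce the twin covariance ordering within families and is
not used; the pair-level reading is the implemented one.

Fixed effects are an intercept, methylation-chip dummies, the sample's
ordinal position on the chip, and the term under test (age, a
phenotype, or SNP dosage; sex and age join in the replication model).
Significance of the tested term is a likelihood-ratio test between the
full and the reduced model, both fitted by maximum likelihood; REML is
available for variance-component reporting. Complete-case analysis is
used throughout (no imputation); an individual whose co-twin drops out
of the complete-case set is treated as a singleton of its zygosity.

### Computation

Families have at most two members, so the marginal covariance is block
diagonal with 2×2 blocks. An orthonormal sum/difference rotation of
each pair diagonalises every block; after the rotation the rows fall
into five homoscedastic groups (MZ sums, DZ sums, differences, non-MZ
singletons, MZ singletons) whose GLS weights are scalar functions of
the variance ratios b = σ²_f/σ²_e and c = σ²_z/σ²_e. The weighted
normal equations are then linear combinations of five precomputed
cross-product matrices, so one profile-likelihood evaluation costs
O(p²) independent of sample size, and the (b, c) optimisation is
vectorised across all probes of a scan: a coarse logarithmic grid
(8 × 8 points including the zero boundary) followed by a zooming 3×3
pattern search (shrink factors 2.5 → 1.03). Single fits continue
shrinking until the log-likelihood gain drops below 1e-8 (at most 200
rounds); permutation rescans warm-start the full model from the null
model's ratios. β and σ²_e are profiled in closed form at every
candidate. Variance ratios below 1e-4 are reported as zero. When a
component is unidentifiable (no DZ pairs and no singletons, or no MZ
pairs) it is fixed at zero and absorbed by the other component rather
than left to drift.

### Small-sample LRT scaling

With the study-scale design (~17 fixed parameters at n = 172, mostly
chip dummies) the plain ML chi-square LRT is measurably liberal,
because the ML residual variance is biased downward by the fixed-effect
dimension. Scans therefore scale the LRT statistic by (n − p)/n before
the χ²₁ tail — a Bartlett-type correction that is exact-rate-restoring
in the OLS limit and asymptotically a no-op. The standalone
`lrt_pvalue` helper applies no scaling. Genome-wide significance never
rests on the χ² approximation alone: every scan's threshold comes from
its permutation FDR, which absorbs residual miscalibration.

### Permutation FDR

FDR(t) = (mean permuted hits at p ≤ t) / (observed hits at p ≤ t),
monotonised q-value style (running minimum from large t downward); the
5% threshold is the largest observed p with monotonised FDR ≤ 0.05.
The permutation unit differs by scan, matching what each null must
break:

* **cis-meQTL** (10 replicates): methylation sample labels are shuffled
  against genotypes — whole columns move together, preserving
  co-methylation; twin structure is deliberately not preserved because
  it is the genotype–methylation pairing that the null severs. The best
  SNP per probe is kept per replicate (ties by |distance|, then SNP id).
* **EWAS** (100 replicates by default): methylation profiles move
  between families in blocks within strata of (family size, zygosity) —
  co-twins travel together, so twin correlation, co-methylation and
  each phenotype's missingness pattern survive under the null. Strata
  with fewer than 3 families make the permutation space degenerate and
  abort. This family-block construction is also the null for the
  mediation overlap ("permuting the methylation data only").
* **MZ-DMR** (100 replicates): the phenotype-difference vector is
  shuffled across pairs.

With very few true signals the realized false-discovery proportion of
any such estimator is highly variable (the denominator is a handful of
hits); calibration checks therefore pool over replicates and plant
enough signals for the FDP to be statistically meaningful.

## Estimators

* **ICC**: one-way random-effects ICC(1,1) = (MSB − MSW)/(MSB + MSW)
  from the pair-level ANOVA — symmetric in twin ordering, which is why
  the one-way variant is the standard twin-concordance choice. Pairs
  must be assayed in the same batch; ICCs and heritabilities are
  computed within batch.
* **Heritability**: the Falconer-style 2(ICC_MZ − ICC_DZ), reported raw
  (not truncated to [0, 1]); genome-wide summaries are means over
  probes with bootstrap percentile CIs and a paired Wilcoxon test of
  the two ICC distributions.
* **Inverse-normal transform**: rank-based with the Blom offset
  (r − 3/8)/(n + 1/4), average ranks for ties, missing values passed
  through; constant probes return all-NaN and are skipped. meQTL scans
  require it; EWAS runs on raw betas with a normalised companion run
  for rank-concordance checking.
* **MZ-DMR scan**: OLS of the within-pair methylation difference on the
  within-pair phenotype difference (intercept included — twin ordering
  is arbitrary but batch effects can shift differences; a no-intercept
  sensitivity flag exists), overall-regression F p-value; the
  age-corrected variant adds the pair's shared age to both models. The
  regression direction (methylation on phenotype) is fixed because the
  simple-regression F is symmetric and the direction extends cleanly
  when age enters. Traits need ≥ 12 complete same-batch pairs.
* **Mediation overlap**: a set-overlap screen, not an effect
  decomposition — meQTL FDR-significant (probe, SNP) pairs, filtered to
  SNPs with GWAS P ≤ 0.001 and probes with ap-DMR P ≤ 0.01 for the same
  trait. The null reruns the cis scan on family-block-permuted
  methylation and takes the top-k probes by best cis p (k = observed
  probe count, ties by probe id).
* **Enrichment**: probe-in-category proportion ratio against the full
  panel, bootstrap percentile 95% CI over resampled DMR sets. BED
  intervals are 0-based half-open; CpG coordinates are 1-based points;
  a point on an interval boundary resolves by the half-open convention.
* **Replication**: discovery DMRs re-tested in a second cohort
  (mixed-model scan with sex and age, or Spearman on unrelated
  subsets); summary fractions keep all discovery DMRs in the
  denominator, counting untested probes as non-replicating.

## The synthetic cohort generator

Defaults reproduce the study conditions: 33 MZ pairs, 43 DZ pairs and
20 singletons (172 women), ages uniform on 32–80 with co-twins sharing
age, chips of 12 samples assigned round-robin over family blocks in
shuffled order, and two batches in a 93:79 split. Phenotypes follow
trait = intercept + (age slope)·age + family effect + noise with the
study's per-trait age slopes and observed-data fractions;
missingness is completely at random (no mechanism is specified for the
real data). Residual SDs and intercepts are chosen for realistic trait
scales (e.g. SBP σ = 15 mmHg). Traits are independent given age unless
explicitly coupled to designated probes (the mediation and discordance
architectures); the joint phenotype distribution of the real cohort is
not modelled.

Methylation betas arise as the inverse logit of Gaussian liabilities.
This preserves the additive covariance structure the twin models assume
while bounding values to [0, 1]; liability SDs are kept modest
(total ≈ 0.3–0.4 around per-probe baselines drawn mostly in the
unmethylated range), so the squashing is locally near-linear and
liability-scale heritability survives to the beta scale — the
heritability-recovery checks confirm the mapping is unbiased to within
Monte-Carlo error. Liability components per probe class:

* additive genetic (heritable class): shared fully by MZ co-twins,
  half by DZ (two half-variance draws, one family-shared); variance set
  from the target h² against all non-genetic components;
* cis-meQTL (meqtl class): per-allele effect on a causal SNP placed
  within the cis window; genotypes follow Hardy–Weinberg founders with
  per-SNP Mendelian transmission, so DZ co-twins share each allele with
  probability 1/2 (not a global 0.5 correlation — this is what makes
  within-pair meQTL behaviour correct);
* age drift (age class): linear in age, hyper-methylating with
  probability 0.98 by default, slope 0.012 liability units/year
  (≈ 2×10⁻³ beta units/year at a beta of 0.3 — the magnitude of the
  strongest real age DMRs);
* shared family environment, chip and chip-order effects;
* co-methylation: an Ornstein–Uhlenbeck field along each chromosome, so
  the correlation between two probes is exactly exp(−d/scale)
  (scale 2 kb by default) — decay over 1–2 kb as observed;
* iid noise; optional coupling of designated probes to lymphocyte
  counts (Dirichlet cell proportions × log-normal total count) and of
  expression to gene-mean methylation with negative sign.

Probe-level truth (baselines, effect signs, classes, causal SNPs) is
drawn from a random stream salted separately from individual-level
noise, so cohorts of different size generated from the same seed share
the same probe effects — which is what makes replication designs
(e.g. 22 younger MZ pairs against the 172-twin discovery cohort)
possible. A `truth.tsv` sidecar records every probe's class and true
effects, making each scan's sensitivity and realized FDP measurable.

What the generator does **not** emulate: linkage disequilibrium,
chromosome-scale probe density, sex chromosomes beyond an annotation
split (the cohort is all-female), genotype imputation uncertainty,
probe-sequence artefacts, and cell-composition confounding beyond the
optional lymphocyte coupling. Passing tests therefore demonstrate that
the estimators recover the effects the models describe under their own
assumptions — not that those assumptions hold in any particular real
dataset.

## Problem sizes

The default test suite and the acceptance script run the pipeline at
panel sizes of 120–1,000 probes with 5–20 replicates and 5–10
permutations per FDR estimate; these sizes give the calibration and
recovery checks adequate statistics while keeping a full run in
minutes on one core. The analysis drivers use a 600-probe panel with
the full permutation counts (10 for meQTL, 50–100 for EWAS/MZ). All
statistics scale to larger panels without modification.

## Known limitations

* The χ² LRT is asymptotic; the (n−p)/n scaling removes the dominant
  finite-sample bias but inference at genome-wide thresholds should
  rely on the permutation FDR, as the pipeline does.
* With only 1–2 true signals the realized FDP of permutation FDR is
  noisy by construction (small denominators).
* The discordance power calculation for a within-pair correlation of
  0.83 in 20 pairs at α = 2.03×10⁻⁶ gives ≈ 42% by exact-test Monte
  Carlo (the Fisher-z approximation says 56%); the published comparison
  point of 35% could not be reproduced from the stated inputs by any
  standard construction, and the estimator here reports its own CI
  rather than asserting that figure.
* Heritability estimates use the Falconer difference only; no
  likelihood-based ACE/ADE decomposition is provided.
* Region-level (multi-probe) DMR calling, trans-meQTLs, LD pruning,
  motif and GO enrichment are out of scope.
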