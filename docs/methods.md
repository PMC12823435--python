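# Methods

`rvburden` implements a rare-coding-variant burden-analysis pipeline for
case-control exome cohorts: functional variant classing, genotype-level
QC, gene discovery against a control group enlarged with an external
reference dataset, burden regressions on per-individual counts, a joint
rare-variant x polygenic-score model and a C-alpha dispersion test.
Because the cohorts this kind of study uses are access-restricted, the
package ships a synthetic-data generator that reproduces the statistical
structure the analysis assumes; all tests and the worked examples run on
synthetic cohorts.

## Variant classing

Variants carry a single most-severe consequence (severity order:
stop-gained > frameshift > splice-site > missense > synonymous > other).
Categories:

* **PTV** — stop-gained, frameshift or essential splice-site *and* a
  loss-of-function prediction flag. A truncating consequence without the
  flag is demoted to "other": the definition is conjunctive.
* **severe DMV** — missense with MPC > 3 (strict).
* **moderate DMV** — missense with 2 ≤ MPC ≤ 3 (both ends inclusive, so
  MPC = 3 is moderate).
* **synonymous** — kept as a calibration/sanity category.

Burden classes: class I = PTV + severe DMV; class II = moderate DMV.

Rarity is a combined allele count across all contributing datasets,
AC ≤ 5 on autosomes and X PAR. On X non-PAR, males carry one X, so the
threshold is rescaled by the chromosome count per individual,
`t × (n_males + 2 n_females) / (2 (n_males + n_females))`, and floored
(3 for the sample composition used in the worked examples, where the
factor is 3.53). Floor rather than round: an integer allele-count
threshold of "three or less" is the conservative reading of a scale
factor of 3.53. "Ultra-rare" (the clinical-sample mode) means a cohort
singleton absent from an external reference panel.

## Genotype QC

Per-call filters (all thresholds strict, as phrased "lower than"):
VQSR fail; DP < 10 or > 1000; hom-ref with GQ < 25; hom-alt with
PL(HomRef) < 25 or alt reads < 90% of depth; het with PL(HomRef) < 25,
alt fraction < 25% of informative reads, informative reads < 90% of
depth, or a two-tailed exact binomial allele-balance probability
< 1e-9. Two choices the phrasing leaves open:

* the allele-balance test is two-tailed — a one-tailed version would
  pass heterozygotes with every read on the reference allele;
* the 25%-alt-reads denominator is informative reads (ref + alt), not
  DP, consistent with the informative-reads rule's own definition.

Call-rate filtering runs exactly three passes — variants < 90%, samples
< 95%, variants < 95% — each over what the previous pass retained. On
the fixtures used this is a fixed point of itself; that is asserted, not
assumed. Sample-level exclusions (sex mismatch, duplicates, ancestry,
contamination > 5%, chimeras > 5%, relatedness pi-hat ≥ 0.2) need raw
reads or genome-wide data and are consumed as precomputed flags.

## Gene discovery

Harmonization before testing: (1) only regions with ≥ 80% of samples at
≥ 10x coverage in *both* datasets; (2) only genes whose rare synonymous
rate is strictly higher in controls than cases (a case-ward synonymous
excess signals dataset artefacts, not biology); (3) only genes with a
strictly higher case rate of the tested class.

Per gene/class, a two-tailed Fisher's exact test on the 2×2 of counts
vs remaining exposure. The autosomal unit defaults to alleles (exposure
2n per group) with a carrier-unit option; the X analysis is
carrier-based and sex-stratified (female, male, combined), with male
non-PAR alleles up-counted to two in allele-based burdens. Odds ratios
are cross-product ratios, +infinity when only cases carry variants; a
Haldane-corrected OR is emitted alongside for plotting. Ranking ties
break by (p, −OR, gene id) for deterministic output.

Genes qualifying in both classes ("dual") are additionally combined by
a weighted z-score meta-analysis: two-tailed p-values are converted
one-sided (the direction restriction guarantees the enrichment
direction), `z_meta = (w1 z1 + w2 z2)/sqrt(w1^2 + w2^2)`, upper-tail p.
Weights are the ratio of the standardized class effects from the
category-level enrichment model (fixed 0.55 for the X analysis); they
can be overridden. Dual genes are reported at the minimum p of their
three tests.

Multiple-testing accounting differs by context, both conventions
implemented as printed: autosomes count every calibrated gene once plus
two extra tests per dual gene (15,603 genes + 2×347 = 16,297 tests,
alpha 3.07e-6 at the published tallies); X counts only
direction-passing genes, three tests each plus one meta per dual gene
(78×3 + 44×3 + 6 = 372, alpha 1.34e-4).

## Burden regressions

Logistic regression of case status (or a binary outcome) on the
per-individual qualifying count, adjusted for birth year, sex, ten PCs,
total variant count, rare synonymous count, coverage metrics and
sequencing wave (one-hot). Exposure is the integer count for category
and gene-set burdens, carrier status where the hypothesis is "one or
more" qualifying variants. Wald 95% CIs on the log-odds scale. Detected
separation or non-convergence falls back to a Firth-type bias-reduced
fit (Jeffreys-penalized score), flagged in the output — tiny gene sets
in small comorbid subgroups separate routinely and should yield finite
estimates rather than failures. Comorbidity scans skip subgroups below
50 individuals (configurable; no principled value exists, 50 keeps the
within-subgroup fits stable). The disorder-gene-set family is
Bonferroni-corrected at 0.05/7.

The IQ model is OLS of IQ on the ultra-rare class-I count with the
clinical covariate scheme (sex, PCs, ultra-rare synonymous count, total
variants).

The joint PGS analysis cuts the PGS into five equal-count bins on the
modeled individuals (after exclusions, not before: bins should be
quantiles of the analysed set), with ties broken by stable sort on
(value, id) so assignment is order-invariant. Ten strata = bins ×
carrier status; case status is regressed on nine dummies plus the
standard covariates, reference = pentile 1 non-carrier (OR ≡ 1 by
construction). Empty strata are dropped from the design and flagged.

## C-alpha

For unit i (genes here; a variant-level alternative is a config choice)
with n_i total rare-allele copies of which y_i fall in group A, and p0
the expected group-A share:

    T = Σ_i [(y_i − n_i p0)² − n_i p0 (1 − p0)]
    c = Σ_i Σ_{u=0}^{n_i} [(u − n_i p0)² − n_i p0 (1−p0)]² Bin(u; n_i, p0)

Z = T/√c with a one-sided upper-tail p (over-dispersion is the
alternative of interest). The permutation p (default 10,000 rounds,
seeded) permutes carrier group labels: conditional on the observed
group-A total, permuted allocations are multivariate hypergeometric
over units, T is re-scored, and the add-one estimator
`(1 + #{T* ≥ T})/(n_perm + 1)` is reported, so resolution is
1/(n_perm + 1). Degenerate inputs (all n_i = 0) raise an explicit
error rather than returning a value.

## Synthetic data

Per-(individual, gene, class) counts are independent Poisson; rare
variant counts are sparse and every downstream model consumes counts,
so no haplotype or LD structure is simulated. Case enrichment is
planted by exponential tilting: cases draw at rate λ·OR in risk genes.
Tilting makes the planted per-allele OR *exactly* identifiable by
retrospective logistic regression, because
Poisson(λe^β)(x)/Poisson(λ)(x) ∝ e^{βx} — the case-control likelihood
the downstream models fit. (An alternative scheme, retaining carrier
status with planted odds, is exact on the carrier scale instead; the
count-scale version was chosen to match the count exposure coding.)

Defaults emulate the study conditions: per-gene baseline rates
(class I 6e-5, class II 1e-4, synonymous 5e-4 per individual) chosen so
a genome-scale panel gives roughly one rare class-I allele and ~10 rare
synonymous alleles per exome; when a reduced panel is simulated, rates
are scaled so the per-person load of the set under test stays realistic
(e.g. class-I load ≈ 0.15 in constrained genes). Comorbidity
prevalences among cases follow registry frequencies (ID 0.186,
ASD 0.307, SCZ 0.046, SUD 0.135, DBD 0.116, multimorbidity 0.609);
comorbid cases carry an extra rate multiplier in configured gene sets.
The PGS is standard normal with a +0.4 s.d. case shift. Per-gene rate
dispersion is a gamma multiplier with configurable CV (default 0.5) —
real per-gene mutation-rate dispersion is not identifiable from
published tallies, so it is a parameter, not a constant. The external
control set gets aggregate counts, a coverage mask with a configurable
dropout fraction below the 80% threshold, and a multiplicative
distortion of synonymous rates emulating cross-dataset call-rate
differences. One master seed expands into named sub-streams
(SeedSequence spawning), so identical configs are bit-identical and
stages are individually reproducible.

The aggregate fast path (`simulate_gene_counts`) draws per-gene totals
binomially over the allele exposure rather than Poisson, so counts
respect the 2n bound and the conditional law of a count given the gene
total is exactly Fisher's hypergeometric null — which matters for
calibration checks at high counts.

What the generator does **not** emulate: reads or haplotypes, LD,
de novo/inheritance structure, relatedness, ancestry admixture, real
per-gene mutability differences beyond the gamma dispersion, or
covariate-count confounding (covariates shift between groups but are
independent of counts given status). Passing tests therefore show the
statistical machinery is correct under the assumed count model, not
that the pipeline is robust to artefacts those features cause in real
exomes.

## Verification design and problem sizes

* Exact-test oracle: Fisher p-values are compared with an independent
  exhaustive hypergeometric enumeration for every table with margins up
  to 25 and a seeded sample of tables with margins up to 60 (the full
  ≤ 60 grid is several million tables; the sampled tail adds no new
  code path, only larger margins).
* C-alpha: permutation p is checked against exact enumeration over all
  label allocations on inputs with ≤ 10 copies; the variance formula is
  checked against a 100,000-draw binomial Monte-Carlo oracle.
* Null calibration: gene-level Fisher p-values are checked for
  uniformity (KS at 0.01) on 2,000 null genes simulated at ~1,600
  alleles per gene. The high-count regime is deliberate: exact
  conditional tests are discrete and sub-uniform, and their p-value
  distribution only approaches uniform as the per-table support grows;
  at sparse counts the meaningful check is the rejection rate, which is
  verified separately (and the type-I error of the logistic burden
  model over 1,000 null replicates at n = 2,000).
* Recovery: the planted per-allele OR 1.35 in constrained genes is
  refit in 50 replicates at n = 9,000/9,000 (CI coverage ≥ 90%); the
  planted −2.25 IQ effect likewise at n = 962; a planted carrier-OR-12
  gene must rank first and pass the exome-wide threshold in ≥ 80% of 20
  replicates at 9,000 cases vs 54,000 controls over a 2,000-gene panel.

## Known limitations

* The direction-restricted two-tailed Fisher test is effectively
  one-sided after filtering; the reported two-tailed p is kept for
  comparability, and the meta-analysis converts it one-sided
  explicitly.
* The Firth fallback reports Wald intervals from the penalized
  information; profile-penalized intervals would be preferable at very
  small counts.
* C-alpha permutes carrier labels without covariate adjustment; no
  SKAT-style alternative is provided.
* The kinship-corrected replication test and PGS construction are out
  of scope; PGS values and sample-level QC flags are inputs.
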