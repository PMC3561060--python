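# Methods

## The analysis protocol

Each study site is scanned exhaustively: every SNP × every phenotype × every
race/ethnicity stratum, always under an additive genetic model in which the
genotype enters as the dosage d ∈ {0, 1, 2} of the *coded allele*.  Strata
are analyzed entirely separately — allele frequencies, phenotype
distributions and effect sizes all differ across ancestry groups, and
pooling would confound genotype with ancestry.

Per phenotype kind:

* **Continuous** — OLS of y on d with intercept; the slope β is the effect
  per coded-allele copy, with a two-sided t-test on the slope.  The fit is
  repeated on log(1+y).  The +1 offset exists so measurements recorded as
  zero stay in the analysis; values in (−1, 0) are transformed with a
  warning and values below −1 are an error.  Raw and transformed fits are
  *separate result rows* distinguished by the `transform` field, because the
  appropriate scale is phenotype-specific and the downstream replication
  criterion operates on phenotype-classes, not scales.
* **Binary** — maximum-likelihood logistic regression; β is the log-odds per
  allele copy, with a two-sided Wald p.  Results are withheld (logged, not
  emitted) on perfect/quasi-complete separation or non-convergence.
* **Categorical (k ≥ 3 levels)** — binned into k "A versus not A" binary
  phenotypes, each fit by logistic regression.  True binaries are analyzed
  once, not as two complementary bins, which would duplicate every test.

Every test is a complete-case analysis of the (dosage, phenotype) pair; the
analyzed sample size n and the CAF computed over those same subjects are
recorded per test.  Gates, all configurable: minimum n (default 10), minimum
minor-allele count (default 5, logistic fits only), monomorphic-in-stratum
SNPs skipped.  Setting both gates to 0 reproduces a fully permissive scan.
Two-sided p-values throughout: pleiotropy scanning has no defensible prior
direction across thousands of phenotypes.  Covariate adjustment is off by
default (the primary scan is a marginal screen) but both fits accept a
covariate matrix.

OLS fits use the closed-form simple-regression solution
(`scipy.stats.linregress`; `statsmodels.OLS` when covariates are supplied);
logistic fits use `statsmodels.Logit` with Wald inference.  The oracles in
the test suite (hand normal equations, brute-force likelihood maximization)
are independent of both code paths.

## Harmonization

Sites report results in a standardized one-row-per-test template
(tab-delimited; empty field = missing; floats at full `repr` precision so
the round trip is bit-identical).  Before cross-site comparison:

* **Allele alignment.**  A result coded on the registry's other allele gets
  β → −β, CAF → 1−CAF, and the coded allele rewritten; a coded allele
  matching neither registry allele is a hard error.  The operation is
  idempotent, audited (one record per flip), and exact — it is the algebraic
  identity that refitting on 2−d satisfies.  A/T and C/G SNPs are flagged
  strand-ambiguous; the flag is informational (no frequency-based strand
  inference is attempted).
* **Phenotype-classes.**  The phenotype → class map is a curated input file,
  never inferred: automatic string/ontology matching is a documented
  non-goal, and keeping curation external keeps results auditable.  Unmapped
  phenotypes stay in the result set with an empty class (visible in sun
  plots) but cannot replicate.  `derive_class_candidates` produces the
  curator's worklist: per-study deduplicated phenotype lists restricted to
  p < 0.01.
* **Effective direction.**  sign(β) × polarity, where polarity (+1/−1/none)
  lives in the phenotype dictionary.  Polarity −1 marks inversely-phrased
  items ("never hypertensive" inside class Hypertension); none marks items
  where direction comparison is not phenotypically meaningful — such
  results count toward site significance but abstain from the direction
  check.

## Replication criterion

Group results by (SNP, phenotype-class, stratum).  A group is flagged iff

* results with p < `p_threshold` (default 0.01) come from ≥ `min_sites`
  (default 2) **distinct sites** — substudies collapse to their site, and
  several significant phenotypes within one site count once; and
* all sub-threshold results with a relevant direction share one effective
  sign (`require_direction`, default on).

Direction consistency deliberately binds only to sub-threshold results:
above-threshold results are uninformative noise and never veto.  One
consequence worth knowing: flagging is monotone in `p_threshold` for the
site-count criterion, but with the direction requirement a *stricter*
threshold can occasionally rescue a group by dropping its only discordant
sub-threshold result.  The test suite asserts the exact (site-count)
monotonicity and documents this caveat.

Under the global null with two independent two-sided tests per group,
P(flag) = p²·½ (both significant × signs agree) = 5×10⁻⁵ at p = 0.01; the
acceptance suite verifies the empirical rate over 2×10⁶ simulated null
groups against the 99% binomial band.

Availability — the number of sites where both the SNP was genotyped and at
least one class phenotype measured — is tabulated per group
(`tabulate_by_availability`) because the opportunity to replicate varies
enormously across classes.  A per-study Bonferroni report (α/#tests) is
provided as the within-study alternative the pipeline does not use for
discovery: it ignores the strong correlation between phenotypes and offers
no cross-study corroboration.

## Classification

Flagged groups are labelled against a known-association catalog
(SNP, trait term, PMID) through a curated class↔trait relation map:
**known** if any catalog trait for the SNP maps to the class with relation
`same`; else **related** if any maps `related`; else **novel**.  Matching is
case-insensitive after whitespace normalization, with no fuzzy matching —
the same/related boundary is scientific judgement and stays in the mapping
file.  Classification depends only on (SNP, class); labels partition the
flagged set and can only move toward known as the catalog grows.

## Synthetic data

The generator emulates the structure the analysis assumes: 2–5 sites with
different per-stratum sample sizes, overlapping SNP panels from one master
registry, different phenotype panels, and mixed phenotype kinds.

* Genotypes: dosage ~ Binomial(2, MAF) per stratum (Hardy–Weinberg).
* Continuous: y = μ + σ·(√ρ·F_class + √(1−ρ)·ε) + Σ β·d, with one N(0,1)
  factor per (class, subject) giving within-class equicorrelation ρ.
* Binary: logit P(y=1) = logit(prev) + Σ β·d — the same link the engine
  fits, so planted log-odds are directly recoverable.
* Categorical: multinomial logits; a planted effect shifts level 1.
* Missingness: MCAR at configured genotype/phenotype rates.

One master seed drives per-study `SeedSequence` spawns; identical configs
give byte-identical output.

Default conditions (used by the test suite and acceptance script): 3 sites —
EA 5,000 / AA 2,000; EA 1,200 / AA 400; EA 4,000 / AA 1,500 / H 800 — over a
45-SNP master registry with per-study panels of 28–40 SNPs and 40–58
phenotypes from a 60-phenotype master panel (20 classes; 60% continuous,
25% binary, 15% three-level categorical), ρ = 0.35, MCAR 2%/5%.  Planted
effects include one pleiotropic SNP with linear effects in two classes, two
catalogued ("known") effects, and one stratum-specific effect.  Consortium
data at the largest published scales (≈80 SNPs × thousands of phenotypes ×
n ≈ 13,000) are reachable by config; the defaults are sized so a full
pipeline run completes in well under a minute while preserving every
structural feature.  The acceptance script runs the default pipeline at
`scale=0.15` and the calibration/power studies at their stated sizes
(2×10⁶ null groups; 200 recovery replicates at n = 5,000; 40 pleiotropy
replicates at 3 × n = 1,500).

What the generator does **not** emulate — hence what green tests do not
show about real data: linkage disequilibrium between SNPs (a real scan can
credit a hit to a tag SNP, as with Duffy-region variants and white-cell
counts in African-ancestry samples), admixture and family structure,
informative missingness, survey weights, and inter-site heterogeneity in
measurement protocols beyond naming.

## Numerical and design choices

* Result template floats serialize via `repr` (shortest round-trip form);
  the write∘read identity is property-tested.
* Logistic non-convergence, separation (detected by statsmodels or by an
  unbounded-SE post-check, SE > 10³) and one-class outcomes are withheld
  results with logged reasons, never rows with garbage estimates.
* Scan output order is deterministic: stratum, SNP (registry order),
  phenotype (panel order), raw before log1p, categorical bins by level —
  so diffing two result files is meaningful.
* Sun-plot radii are clipped at −log₁₀ p = 30 (configurable) for
  legibility; color semantics are red < 0.01, grey < 0.05.  SVG rendering
  pins the matplotlib hash salt and omits the date so output is
  byte-stable on one platform.
* The worked-example fixture's three LDL-C rows lack published standard
  errors and exact sample sizes; SEs are reconstructed as |β|/Φ⁻¹(1−p/2)
  and ns approximated from the same studies' cholesterol panels.  They are
  labelled as reconstructions and no test consumes those two fields.
* Strata and trait terms are free strings, not enums; new ancestry groups
  or catalog vocabularies need no code change.

## Known limitations

No LD model, no meta-analytic pooling of effect sizes (replication is by
vote, matching the criterion it implements, not inverse-variance synthesis),
no survey-design weights, no Firth/exact logistic for rare outcomes, and no
automated phenotype ontology mapping.  The replication criterion's false
discovery behaviour is characterized analytically only for the two-site
independent-test case; correlated phenotypes within a class make the
effective number of independent tests per group smaller than the row count.
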