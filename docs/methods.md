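# Methods

This note documents the statistical model behind `cytovar`, the
generator that validates it, the numerical choices made where the design
was open, and what the passing tests do and do not establish.

## Outcome model

Cytokine concentrations are treated as lognormal: every analysis runs on
natural-log concentrations, with values below the analyte's lower limit
of quantification (LLOQ) clamped to the LLOQ before the transform.  The
natural log is used throughout so that exponentiated regression
coefficients read directly as fold changes.  "Induced cytokine levels"
means the stimulated-condition log concentrations (not
stimulated-minus-null differences); this matches plotting raw
concentrations per condition, and is switchable at the call sites.

### Induction rule and SLMD

A cytokine is flagged induced when its median concentration under a
stimulation deviates at least 30% (either direction; the threshold is a
parameter) from the null-condition median.  When the null median sits on
the LLOQ floor the ratio is uninformative, so any stimulated median
above the floor flags induction.  The standardized log mean difference
is mean(stimulated) − mean(null) over complete donor pairs divided by
the SD (ddof = 1) of the paired per-donor differences, computed on log
concentrations (the log is a deliberate choice, consistent with the rest
of the pipeline, and exposed as a switch).  Zero-SD entries are
non-finite and excluded from the complete-linkage/Euclidean clustering;
scipy's linkage breaks distance ties by the lower original index, which
makes the dendrogram deterministic given input order.

### Responder detection

For a stimulation with a bimodal response (anti-CD3+CD28-style, where an
FcγRIIA polymorphism prevents response in a subset of donors), k-means
with k = 2 on the log concentrations of a caller-chosen cytokine set
separates responders from non-responders; the cluster with the larger
centroid norm is the responder class, 25 seeded restarts keep the best
inertia, and the seed is a required argument.  Which cytokines feed the
clustering is left explicit because the induced set varies by panel.
All downstream analyses of that stimulation run on responders only.

## Donor-variable screen

Eligibility: numeric variables always; a categorical variable with L
observed levels only when at least ⌈L/2⌉ levels each hold ≥ 5% of its
non-missing donors (guards against levels too sparse to estimate).

The test is a likelihood-ratio comparison of nested ordinary
least-squares fits.  For Gaussian outcomes the profile log-likelihood
gives statistic `n·ln(RSS_reduced/RSS_full)`, referred to χ² with as
many degrees of freedom as effective parameters added (the rank
difference of the two designs).  An exact F test on the same RSS pair is
available as a cross-check (`cytovar.stats.nested_f_test`); the
chi-square LRT is canonical here.  The age-interaction variant adds
variable × age columns to the full model only, so the LRT tests main
effect and interaction jointly.

Missingness is handled by complete-case analysis per model pair, with
`n_used` recorded on every result row.  Confidence intervals use t
quantiles at the residual degrees of freedom.

Multiple testing: Benjamini–Yekutieli step-up (valid under arbitrary
dependence — the cytokines of one stimulation are correlated), applied
over exactly the eligible-variable × induced-cytokine family of one
stimulation, never pooled across stimulations.  The display gate is
adjusted p < 0.01.  Pairwise group contrasts (e.g. never/past/current
smokers) use two-sided Wilcoxon rank-sum tests — exact for small
tie-free groups, normal approximation with tie correction otherwise —
Holm-adjusted across pairs (the adjustment method is a parameter; Holm
is the default because it is valid without independence assumptions).

## Mediation screen

The screen is covariate elimination, not a causal effect decomposition:
mediator M "eliminates" the association of variable V with cytokine Y
when the baseline LRT (V added to age/sex/batch) is significant but the
LRT of `Y ~ V × M + age + sex + batch` against `Y ~ M + age + sex +
batch` is not.  The interaction term is always in the full model (a
no-interaction variant is an option).  Both gates use BY-adjusted p at
α = 0.01 — the baseline adjusted across the cytokines of the
stimulation, the with-mediator p across the whole mediator × cytokine
matrix of the panel; both p values are reported so other gates can be
applied post hoc.  Mediator transforms: cell counts log(x + 0.5)
(half-count offset for zeros), proteins log(x), CpG beta values
untransformed (logit-beta available).  A mediator collinear with the
variable is flagged untestable rather than eliminated.

CpG–cytokine association tests are restricted to CpGs on the same
chromosome within 1 Mb (closed interval) of the cytokine gene TSS,
tested by the same LRT with age/sex/batch plus major cell-count
covariates, and Benjamini–Hochberg adjusted at FDR < 0.05.  The list of
smoking-associated CpGs is consumed as an input; its derivation is out
of scope.

## Response-pQTL scan

SNPs are filtered to minor allele frequency strictly above 5% (computed
on non-missing dosages).  Per (SNP, induced cytokine) the model is OLS
of log concentration on additive dosage plus covariates: age, sex,
batch, and the stimulation's main associated cell subset (a default
mapping ships with the package and is overridable; e.g. monocytes for
LPS/E. coli/C. albicans, CD4pos for SEB, CD8posEMRA for anti-CD3+CD28,
CD45pos for BCG, cDC3 for poly I:C, CD3pos for influenza).  Cytokines
identical to the stimulus agonist are excluded — they are added to the
culture and do not reflect endogenous secretion.

For speed the covariates are projected out of phenotypes and genotypes
once per scan (Frisch–Waugh–Lovell), with residual degrees of freedom
n − rank(covariates) − 1; numerical equivalence to per-SNP full fits is
the engine's core correctness contract, verified to 10⁻¹⁰ relative
tolerance in the tests.  Missing dosages are mean-imputed per SNP for
the matrix path (the count is logged).

cis/trans: a SNP is cis for a cytokine when it lies within 1 Mb (closed
interval, 1-based coordinates) of the gene's TSS on the same chromosome,
otherwise trans; unknown TSS yields "unclassified" and the trans
detection threshold.  Records are pre-filtered at the class detection
thresholds (10⁻³ cis, 10⁻⁵ trans) and then Bonferroni-adjusted over the
single full family of the scan — all retained SNPs × all tested
cytokines of that stimulation (the dual thresholds act as reporting
pre-filters before one Bonferroni family; whether correction should span
stimulations jointly is ambiguous, and per-scan is implemented and
recorded in the scan metadata).  Hits require adjusted p < 0.05.

Conditional analysis appends the conditioning SNP's dosage to the
covariates; tested SNPs in perfect LD with it are flagged untestable.
Genotype × smoking interaction adds dosage × smoking-status terms,
LRT against the no-interaction model, BY-adjusted over the tested hits,
with exponentiated interaction coefficients and 95% CIs.

## Variance partitioning

Each regressor group's share of a cytokine's variance is its LMG
(Shapley) value: the R² gain from adding the group, averaged over all
orderings of the groups.  A multi-level factor is one group — all its
treatment-coded columns enter together — so "smoking status" moves as a
unit; so do a SNP's dosage or a CpG's beta.  Shares are nonnegative and
sum to the full-model R² (efficiency), exchangeable groups receive equal
shares (symmetry), and groups orthogonal to everything get their
marginal R².  Exact mode memoizes subset R² values keyed by bitmask and
is capped at 20 groups (2^20 fits); each subset is fitted directly by
least squares — correctness, not speed, is the contract here, so no
incremental QR/sweep updating is attempted.  Sampled mode averages
sequential gains over seeded random orderings and reports a Monte-Carlo
standard error per share.  The inclusion gate for the reported
decompositions is adjusted p < 0.05 on the screen results (the screen's
0.01 display gate is stricter; both thresholds are exposed and the
report records which was used).

## Synthetic cohorts

The generator emulates the cohort design the pipeline targets; its
defaults are the study conditions, not tuning knobs:

| parameter | default | rationale |
| --- | --- | --- |
| n_donors | 1000 | cohort size; analyses typically use 955 (public-consent subset) |
| age | uniform within 5 equal decade strata, 20–69 y | balanced design |
| sex | 50/50 within decade | balanced design |
| batch | 2 levels | two production batches of stimulation tubes |
| smoking prevalence | 0.50 / 0.25 / 0.25 never/past/current | plausible for a Western European adult cohort |
| CMV seroprevalence | 0.35 | typical adult seroprevalence in that population |
| BMI | N(24.5, 3.8²), clipped 16–45 kg·m⁻² | healthy-adult range |
| noise_sd | 1.0 | log-scale residual SD of cytokine responses |
| stimulated / null log level | 4.6 / 0.7 | induced analytes sit far above the null condition |
| LLOQ | 0.5 | concentration floor |
| responder split | 29.5% non-responders for anti-CD3+CD28 | bimodal response fraction |

Log cytokine levels are intercept + age + sex + batch effects + planted
variable effects + mediator paths + genotype effects + N(0, noise_sd);
concentrations are the exponentials, so they are lognormal and strictly
positive.  The null condition carries no stimulation effects.
Non-responders are a mixture component at null-condition level for
exactly one configurable stimulation.  Genotypes are Hardy–Weinberg
dosages; LD pairs are generated at the haplotype level so a target
haplotype correlation r yields dosage r² ≈ r².  CpG beta values follow a
logit-scale model: baseline − (per-pack-year coefficient)·pack-years +
(reversion coefficient)·years-since-quit (past smokers only) + noise,
giving current-smoker hypomethylation, an intermediate state in past
smokers, and reversion toward baseline with time since cessation.
CMV-seropositive donors carry elevated memory-compartment cell counts.
Mediation chains are full mediation by default (variable → mediator →
cytokine with no direct path), so the elimination screen has an
unambiguous positive control; a `direct` coefficient produces partial
mediation.  A planted effect on a categorical variable applies to one
named level or, by default, to all non-reference levels (an
"ever-smoker" effect when planted on smoking status).

One global seed drives a SeedSequence whose children are consumed in a
fixed order (covariates, cells, proteins, genotypes, methylation,
cytokines, responders), so adding one table never perturbs the others
and identical (config, seed) pairs are bit-identical.

What the generator does **not** emulate: the empirical covariance of
real cytokine panels beyond the stated model, immunoassay measurement
error, flow-cytometry gating noise, population structure or
relatedness, LD beyond explicit pairs, and cell-type heterogeneity of
methylation.  Passing recovery tests therefore demonstrate correctness
of the inferential machinery under the assumed generative model — not
robustness to the messier features of real cohort data.

## Validation problem sizes

The test suite and `scripts/acceptance.py` validate with simulations
sized to be decisive yet quick: type-I control of the screen with 136
variables × 13 cytokines at n = 955 over 50 seeds (20 in the script);
recovery of a 1.5-fold smoking effect over 100 seeds (40), with CI
coverage over ~1,000 additional single-cytokine replicates (400);
mediation directionality over 40 seeds (20) of an 8-mediator panel at
n = 400; pQTL engine equivalence on 1,000 SNPs × 4 cytokines at n = 500
and family-wise error on 5,000 SNPs × 4 cytokines over 30 (20) null
seeds; conditional discrimination in a two-SNP LD block (haplotype
r = 0.8, dosage r² ≈ 0.64) over 30 (20) seeds; variance-share recovery
of a planted 6%/5% smoking/age split over 50 (25) seeds.

## Numerical notes and degenerate inputs

- Rank decisions use `numpy.linalg.lstsq`/`matrix_rank` defaults; a full
  design that is rank deficient raises a collinearity error naming the
  aliased columns; a variable adding no effective parameter raises an
  insufficient-variation error rather than returning df = 0.
- LRT statistics are clipped at 0 (they are nonnegative up to floating
  point); subset R² values are clipped to [0, 1].
- Identical donors in responder detection give a degenerate
  single-cluster result (everyone a responder, with a warning).
- Tables are written as TSV with "#" provenance headers (config hash,
  seed, stage) and "." for missing; reads do not treat the literal
  strings "null"/"NA" as missing, since "null" is a condition name.
- Exit codes: 0 success, 2 configuration error, 3 data error,
  4 numerical failure.

## Known limitations

- Outcomes are log-scale Gaussian only; no GLMs, mixed models or
  kinship correction (donors are modelled as unrelated).
- The mediation screen is directional evidence, not a natural
  direct/indirect effect decomposition.
- Bonferroni families are per-scan; a cross-stimulation family would be
  stricter.
- Mean imputation of missing dosages slightly attenuates pQTL slopes at
  high missingness; the missing count is logged so callers can filter.
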