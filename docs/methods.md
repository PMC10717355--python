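# Methods

## The collapsing burden model

The unit of analysis is the gene. For each sample and gene, rare variants
(population minor allele frequency < 1%; unknown frequency counts as rare,
since absence from reference databases is itself evidence of rarity) are
classified into four mutually exclusive classes by Sequence Ontology term:

| class | terms |
|---|---|
| PTV | stop_gained, frameshift_variant, splice_acceptor_variant, splice_donor_variant, start_lost, stop_lost |
| MIS | missense_variant, inframe_insertion, inframe_deletion, protein_altering_variant |
| SYN | synonymous_variant, stop_retained_variant |
| NON | everything else (intronic, UTR, regulatory, …) |

Multi-term annotations take the most severe class (PTV > MIS > SYN > NON).
The mapping is a configuration, not a law; it follows common collapsing
practice.

The default collapsing statistic is CAST-style **carrier** status (≥ 1
qualifying variant of the class in the gene). A `unit="count"` switch
instead compares summed per-sample counts (capped at 2, against diploid
allele denominators 2n); carrier is the default because burden tests on
carrier indicators are the standard reading of "is this variant class more
frequent in cases". Per gene and class, a one-sided Fisher's exact test
(exact hypergeometric upper tail) asks whether carriers are enriched in
cases. One-sided is deliberate: the scan screens for risk, not protection.

**Near-neutral background filter.** Synonymous and non-coding variation
should be exchangeable between groups; a gene whose SYN or NON p-value falls
below `alpha_background = 0.05` is flagged as confounded (population
structure, coverage, annotation artefacts) and excluded from selection. The
0.05 default is a convention and configurable. Note the cost: with a ~5%
one-sided false-flag rate per background class, roughly one in ten truly
causal genes is discarded by chance; this is visible in the recovery rates
below.

**Risk score and permutation null.** Gene evidence is combined as
`2·(−log10 P_PTV) + (−log10 P_MIS)`, weighting truncating evidence double.
Because the two p-values are dependent and discrete, the score's null
distribution is taken from B label permutations (group sizes preserved):
`perm_p = (1 + #{null ≥ observed}) / (1 + B)`, the add-one estimator, which
is valid for any B and bounded below by 1/(B+1). The scan is vectorised —
carrier matrices multiply a matrix of permuted label vectors and one-sided
tail probabilities are read from per-gene lookup tables — so the production
default B = 10,000 over thousands of genes runs in seconds on one core.

**Selection tiers.** *risk_gene*: not background-flagged and
`P_PTV < 0.05` or `P_MIS < 0.05`. *potential_causative*: not flagged,
`P_PTV < 0.01` or `P_MIS < 0.01`, and Benjamini–Hochberg q of the
permutation p (computed across background-clean genes) below 0.01. An
arithmetic consequence worth knowing: q for a gene at the permutation floor
is `m / ((B+1)·rank)`, so with B = 1,000 and a 100-gene panel no *single*
gene can clear q < 0.01 — about a tenth of the panel must tie at the floor.
Genome-scale scans at B = 10,000 face the same constraint. The canonical
recovery scenario therefore plants 12 risk genes, and real scans reporting
FDR-selected genes necessarily had many genes at the floor.

**Calibration.** With ties counted conservatively (`≥`), permutation
p-values of a discrete statistic are slightly super-uniform. On null
cohorts (500 genes, 200/400 samples, B = 200) a KS uniformity test still
passes (p > 0.01) for the canonical seeds, but across many seeds it flags
the mild conservatism in roughly one seed in six. A mid-p tie-break would
remove this at the cost of the estimator's simple validity guarantee; the
conservative estimator is kept.

## Propensity matching

Case probability is fitted by logistic regression on gestational age, sex
and maternal gestational hypertension (rows with missing covariates are
excluded and logged; constant covariates are dropped, degenerating to an
intercept-only fit). Matching is greedy 1:k nearest-neighbour without
replacement on the logit of the propensity, cases visited in descending
propensity order; exact ties go to the smallest control id. An optional
caliper (logit units) drops matches beyond it. Standardised mean differences
use the pooled pre-match SD so before/after values share a scale.

Matching reliably *shrinks* imbalance (20/20 seeds in the canonical
scenario) but does not push the gestational-age SMD below 0.1: with case GA
36.5 ± 3.3 weeks against control GA 38.0 ± 2.0, the most preterm cases have
no on-support controls, and the propensity also trades GA against
hypertension within a score stratum. A caliper tightens but does not
eliminate this. This is a property of the simulated covariate overlap, not
of the matcher.

## Cohort statistics

Categorical comparisons use Pearson chi-square **without** continuity
correction, `χ² = N(ad−bc)²/((a+b)(c+d)(a+c)(b+d))`, df = 1 — the variant
that reproduces published baseline-table p-values exactly — with Fisher's
exact test when any expected cell is below 5 or a margin is empty.
Continuous comparisons default to Welch's unequal-variance t-test; the
Wilcoxon rank-sum alternative uses the exact null for small untied samples
and the tie-corrected normal approximation otherwise. Logistic odds ratios
are ML fits with Wald intervals; complete or quasi-complete separation is
detected (fitted probabilities at the boundary or exploding standard
errors) and raised, never silently reported.

## Prognosis models

Genetic predictors are **per-gene** 2/1/0 burden scores over the risk genes
(2 = any PTV in the gene, 1 = missense only, 0 = otherwise; a sample with
both scores 2). Per-gene columns are the default because a single summed
score discards which gene carries the burden; `mode="sum"` provides the
aggregate. Risk genes and screened clinical factors are derived from the
training split only; the test and external validation sets are scored by
the frozen pipeline (a leakage guard in the suite verifies that shuffling
validation labels cannot change predictions).

Both models are gradient-boosted tree classifiers; hyperparameters maximise
mean cross-validated AUC over a small grid (trees {50, 100, 150}, depth
{1, 2, 3}, learning rate 0.1, minimum leaf 10) under 10-fold
cross-validation repeated 3 times, then the winner is refit on all training
data. The train/test split (7:3) is stratified by outcome so a ~14%-
prevalence outcome is present in both splits; an unstratified mode exists.
AUC confidence intervals and the two-model comparison use DeLong's
nonparametric variance (validated against an independent R implementation
to 7 digits); with a single observation in a class the variance term is
taken as zero rather than undefined.

## The synthetic cohort generator

The generator emulates the statistical skeleton of a NICU SGA/AGA
case-control cohort; its defaults are the study conditions used throughout
the tests.

- **Groups.** 627 cases / 1,317 controls by default (the scan-sized cohort);
  scenario helpers use smaller sizes (below).
- **Variants.** Counts per (sample, gene, class) are Poisson with the rate
  chosen so the carrier probability (count ≥ 1) equals the configured value:
  PTV 0.02, MIS 0.05, SYN 0.05, NON 0.08 per gene — order-of-magnitude
  choices for rare variation on a clinical exome panel, not estimates of any
  specific dataset. A planted (gene, class, OR) multiplies the carrier odds
  in cases by OR; planting on SYN builds a confounded gene the background
  filter should catch. SYN/NON rates are otherwise group-independent, so the
  filter is exercised as a no-op under the null.
- **Covariates.** Gestational age case 36.5 ± 3.3 vs control 38.0 ± 2.0
  weeks; 60.7% male; maternal hypertension 25.9% vs 10%; gestational
  diabetes 18.4% vs 15%; maternal covariates missing at ~1% to exercise
  missing-data paths. Organ-system flag prevalences follow observed NICU SGA
  rates (cardiovascular 71.8% … dermatologic 3.6%, congenital malformation
  42.2%).
- **Outcome.** Poor prognosis (death ∪ growth delay ∪ neurodevelopmental
  delay, partitioned 35/27/38% with 7% co-occurrence) is logistic:
  intercept −3.45 plus the natural logs of the six clinical odds ratios a
  univariable screen retains (neurologic 3.1, metabolic 2.22, skeletal 3.25,
  respiratory 2.6, immune 2.01, craniofacial 3.31) plus `burden_coef` per
  unit of 2/1/0 burden in planted genes. The default intercept yields ~14%
  prevalence with no genetic term.

Three canonical scenarios fix the simulation conditions:

| scenario | conditions | purpose |
|---|---|---|
| `scenario_null` | 200/400, 500 genes, no planting | calibration |
| `scenario_planted_scan` | 300/600, 100 genes, 12 PTV genes at OR 8 + 2 SYN-confounded | power / filtering |
| `scenario_prognosis` | 600 SGA, 100 genes, 12 risk genes, `burden_coef` 1.5, intercept −5.8 | model ordering |

`burden_coef = 1.5` makes the genetic log-odds contribution roughly twice
the clinical one, matching the reported magnitude of AUC improvement when
genetic predictors join clinical ones (0.74 → 0.9); the −5.8 intercept
compensates the planted-burden mean so prevalence stays near 14%.

**What the generator does not model** — and hence what passing tests do not
establish about real cohorts: linkage and gene-gene correlation, population
stratification, relatedness, coverage/batch artefacts (the background filter
is only exercised through explicit SYN planting), variant-level effect-size
heterogeneity within a gene, and informative missingness. Power and
calibration results transfer to real data only insofar as those features are
benign.

## Problem sizes and numerical choices

The validation studies run at 100–500 genes and 600–1,500 samples with
B = 200–1,000 permutations and 20 seeds, sizes at which the whole suite
completes in minutes on one core while leaving Monte-Carlo error well below
the asserted margins; the pipeline defaults (B = 10,000, 10-fold × 3 CV)
remain the production settings. Permutation exceedance uses a 1e-12 slack on
score comparison so identical tables compare equal under floating-point
log10. Genes with zero carriers in both groups get p = 1 for that class and
can never be selected. Zero-margin chi-square tables return p = 1 with a
warning; zero pooled SD with equal means defines SMD = 0, with unequal means
it is an error.
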