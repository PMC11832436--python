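# Methods

## Stratification model

Every patient is compared against a single pooled control reference: the
per-gene arithmetic mean of the control samples on the linear intensity
scale (a geometric-mean option exists for log-symmetric data).  Fold changes
use the signed convention: ratio r ≥ 1 is reported +r, r < 1 as −1/r, so
|FC| ≥ 1 always and "−1.5" means 1.5-fold down.  The index gene's signed FC
classifies the patient — *up* at FC ≥ +1.5, *down* at FC ≤ −1.5, otherwise
*unchanged*.  Boundaries are inclusive because the observed up-range starts
exactly at +1.5.  A patient value of exactly 0 is assigned a capped signed
FC of −64 (configurable) rather than −∞; genes whose control reference is 0
are excluded from all FC computation and reported.  Classification is
invariant to global positive rescaling of the matrix, and stratum labels
partition the patient set by construction.

Per-gene, per-patient **direction calls** apply the same rule gene-wise:
+1 at FC ≥ +threshold, −1 at ≤ −threshold, else 0.  Calls at a stricter
threshold are always a subset of calls at a looser one.

## Differential expression

Each stratum is contrasted against the controls with the Wilcoxon–
Mann–Whitney test using mid-ranks.  For total n ≤ 12 the two-sided p is
computed by exact enumeration of all C(n, n_a) rank assignments (counting
assignments whose U deviates from n_a·n_b/2 at least as much as observed);
this stays valid under ties, where classical exact tables do not.  Larger
samples use the tie-corrected normal approximation with continuity
correction, which agrees with the exact p to within 0.0155 at n = 6 + 6
(exhaustive bound) and ever closer as n grows.  Multiplicity is handled with
Benjamini–Hochberg step-up q values (order-preserving).  A gene is a DEG
when q < .05 and the cohort signed FC — the cohort **median** patient value
against the control reference, an aggregation choice made here — has
magnitude ≥ 1.5.

**Concordance**: for each cohort DEG, the fraction of that cohort's patients
whose individual direction call equals the DEG's sign (zero calls count
against); the summary statistic is the fraction of DEGs concordant in more
than half the patients.

## Gene-set enrichment

The ranking orders genes by a chosen score (signed FC by default; the test
statistic is the alternative and the choice is recorded in the run config),
descending, ties broken by gene id ascending so runs are reproducible.  The
running sum increments at set members by |score|^w normalised over the hit
scores (w = 1 by default; with all-zero hit scores the increments fall back
to 1/N_h) and decrements at non-members by 1/(N − N_h); ES is the signed
maximum deviation.  A set covering the whole universe or none of it is an
error (the latter distinct from zero enrichment).

The null is **gene-label permutation** — the set is reassigned to uniformly
random position subsets of the same size — because the phenotype labels are
already consumed upstream by the stratification.  NES divides the observed
ES by the mean |ES| of same-sign permutations; p is add-one smoothed over
same-sign permutations, so p = 0 never occurs and a degenerate null yields
NES = 1, p = 1.  If no permutation shares the observed sign, NES is reported
undefined and the set fails with a diagnostic.  Default 1000 permutations,
seeded.  Two pass rules are evaluated: |NES| > 1 ∧ p < .05 for pathway
collections and the one-sided NES > 1 ∧ p < .05 for immune-cell marker
panels; the collection's category tag selects which applies, and both are
always reported.  Matrisome-style panels are handled by membership
annotation (genes in no panel are labelled unannotated; counts conserve
(gene, panel) memberships).

## Cohort statistics

G-tests use G = 2 Σ O ln(O/E) with 0·ln 0 ≡ 0; zero *expected* cells are an
error, not smoothed.  Williams' (1976) correction divides G by
q = 1 + (k² − 1)/(6N(k − 1)) for goodness of fit and
q = 1 + (N Σ 1/row − 1)(N Σ 1/col − 1)/(6N(r − 1)(c − 1)) for independence
before the chi-square tail.  This choice reproduces the one checkable
published categorical p value (89 vs 86 against an equal split → .821).
Null calibration at N = 50, k = 2 keeps the type-I error within [.03, .07]
at nominal .05.  Multi-way comparisons use α/n_way, reported rounded to
3 dp (.017, .025) with full precision retained internally; all reported p
values are rounded to 3 dp the same way.

Continuous comparisons dispatch on per-group Shapiro–Wilk at α = .05 (a
fixed convention): all-normal goes to the equal-variance t-test or one-way
ANOVA, otherwise Wilcoxon rank-sum or tie-corrected Kruskal–Wallis;
all-identical data short-circuits to H = 0, p = 1, and groups with n < 3
force the nonparametric branch with a log notice.  Spearman correlation is
Pearson on mid-ranks with the t approximation at n − 2 df; zero rank
variance is an explicit error.  These standard tests are delegated to
scipy/statsmodels behind this module's interface.

The median CI takes order statistics x(j), x(k) with j the largest index
whose Binomial(n, ½) lower tail stays within (1 − level)/2 and k = n+1−j;
achieved coverage is reported, and when even j = 1 overshoots the budget
(n ≤ 5 at 95%) the widest interval is returned flagged unattainable.

## Regulators and targets

The recurrence rule admits a candidate regulator when the same direction
call occurs in ≥ 10 patients of a stratum, evaluated per direction per
stratum (a gene may pass "up in the up-stratum" and "down in the
down-stratum" independently); a pooled-strata reading is available as an
option.  The pass set is monotone non-increasing in the patient threshold.
Stratum proportion differences use the 2×2 Williams-corrected independence
G-test at the two-way α = .025.  The target ledger de-duplicates the master
list, keeps per-gene provenance tags, and reports overlaps as
100·|master ∩ evidence|/|master| to 1 dp — hence 87/188 → 46.3% and
146/188 → 77.7%.  The shipped ledger constructor is a synthetic stand-in
built from published set sizes alone; its identifiers are placeholders and
only the set arithmetic is meaningful.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes, not
any one data set.  Expression is built on the log2 scale: per-gene control
baselines uniform on [3, 10] (arbitrary, seed-fixed), additive Gaussian
noise (default SD 0.4, a realistic within-group spread for normalised
array/RNA intensities), planted shifts, then exponentiation — so
fold-change semantics are exact in the noise-free limit and noise is
multiplicative log-normal on the linear scale.  Defaults mirror the study
conditions: 66 controls, 396 patients split (117, 159, 120); index-gene
signed FCs drawn log-uniformly within 1.5…21.3 (up), −7.5…−1.5 (down) and
±1.45 (unchanged, kept a hair inside the threshold).  Planted programs
shift disjoint gene blocks by direction·log2(effect) in one stratum only;
the defaults sketch the biology under study (autophagy/OXPHOS up and
complement down with high FGF21; fibrosis up and lipid transport down with
low FGF21) with effects 2–2.5×.  Histology scores come from
stratum-specific categorical distributions whose defaults give the
down-stratum higher fibrosis and inflammation — the direction of the
clinical table without matching its values — and a null model with
identical distributions is provided for association-free testing.  NAS is
always the sum of its three components where components are known;
missingness fractions follow the reported per-variable Ns (sex known for
175/396, components for 162/396, NAS/fibrosis for 328/396).  One integer
seed drives independent substreams for expression, covariates and gene
sets, so outputs are bitwise reproducible and the gene-set collection does
not depend on call order.

A `with_strong_effects()` variant (index FC pulled to ≥ 2.5-fold, unchanged
within ±1.15, noise SD 0.15) defines the separable regime used for
recovery analyses: there the stratification recovers ≥ 99% of planted
labels at full cohort size.

**What the generator does not emulate** — and hence what passing tests do
not demonstrate about real data: probe-level microarray artefacts, batch
structure across pooled source studies (a single homogeneous batch is
emitted), count-based RNA-seq sampling noise, gene–gene correlation beyond
the planted programs, and any dependence of DEG effects on covariates.
Recovery and concordance figures on synthetic cohorts are design checks of
the machinery, not estimates of performance on biopsy data.

## Problem sizes and runtime choices

Simulation-based checks use sizes chosen to make Monte-Carlo error small
relative to the asserted margins while keeping the suite quick: 10,000
replicates for type-I and coverage calibration, 200 seeds (100 in the
acceptance script) for the null-FDR check at 100 genes × 20 + 20 samples,
20–40 seeds for power-style checks, and 200–1000 label permutations per
enrichment call.  Null-FDR assertions allow two Monte-Carlo standard errors
above the nominal .05, since the mean of a ~Bernoulli(.05) proportion over
a few hundred seeds fluctuates at the percent scale.

## Known limitations

- The exact rank-sum branch enumerates C(n, n_a) assignments and is
  restricted to n ≤ 12; beyond that the normal approximation's small
  discrepancies (≤ 0.0155 at 6 + 6, shrinking with n) are accepted.
- NES calibration uses gene-label permutation only; phenotype permutation
  would require carrying sample labels into the enrichment stage.
- The three-group categorical p values of a full clinical table depend on
  table-construction details that a 2×c Williams G-test on marginal counts
  does not pin down; only the two-cell sex-balance statistic is treated as
  a reproducible reference value.
- Per-study control references and batch correction are out of scope; the
  pooled-control design matches the single-batch generator.
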