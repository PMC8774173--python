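# Methods

## Scope and data model

`cfpanel` models a multi-analyte liquid-biopsy experiment in which three
analyte classes are measured per plasma sample by real-time qPCR: a panel of
cancer-associated point mutations (one mutation assay + one reference assay
per target), a panel of gene regions quantified in MBD-captured methylated
and unmethylated cfDNA fractions, and a panel of circulating miRNAs with an
exogenous spike-in control. The on-disk representation is four comma-
delimited tables (sample sheet + three long-format Ct tables) plus a YAML
panel configuration carrying per-assay ΔCt cutoffs, the region and miRNA
lists, the spike-in identity and the instrument Ct ceiling.

Undetermined Cts are first-class: empty cells, the literal `Undetermined`,
and any Ct at or above the ceiling (default 40 cycles — instruments cap
their cycle count, and non-amplification means no detectable template) map
to one NaN sentinel. All downstream rules are written against that sentinel;
an undetermined Ct never silently becomes a number.

Group labels are a closed vocabulary (healthy + 9 solid-tumor types, with
`liver` additionally accepted on input so that raw cohorts containing a
group destined for exclusion still validate). Exclusions are declarative —
individually listed samples with reasons, and a minimum group size — and the
exclusion log plus retained samples always partition the input exactly.

## Per-analyte feature derivation

**Mutation calls.** ΔCt = Ct(mutation assay) − Ct(reference assay); a call
is positive iff ΔCt is defined and ≤ the assay cutoff. The direction of the
inequality reflects the assay design: mutant template present ⇒ the mutation
assay amplifies nearly as early as its reference ⇒ small ΔCt. An
undetermined Ct on either side yields a negative call (non-amplification is
non-detection), which makes calling monotone in ΔCt. Mutation burden is the
per-sample count of positive calls.

**Methylation percent.** For each region,
m% = 100 / (1 + 2^(CtMe − CtUnMe)). This is the standard two-fraction
abundance estimator at 100 % amplification efficiency: each cycle of Ct gap
corresponds to a factor of 2 in template. It is bounded in (0, 100), equals
50 at equal Cts, and satisfies m%(a, b) + m%(b, a) = 100 — both properties
are enforced by tests. If either fraction is undetermined the value is
absent, not zero: a missing measurement is not evidence of 0 % methylation.

**miRNA expression.** Candidate miRNAs undetermined in too many samples
(default: ≥ 50 % of samples; a reference-sample rule is also available) are
dropped with a log. Remaining Cts are normalized per sample against the
global mean of the sample's detected candidate miRNAs (spike-in excluded,
kept only for QC): rel_expr = mean Ct − Ct, so higher = more abundant and a
constant plate/yield shift on all of a sample's Cts cancels exactly. Each
miRNA is then z-scored across all samples with the n−1 standard deviation
(the convention of mainstream statistics packages); z-scores are computed
over the whole cohort, not within subgroups. Samples with fewer than two
detected miRNAs cannot be normalized and are flagged out.

**Feature matrix.** The three blocks are joined on their common samples into
one samples × features table with an analyte-class tag per column. Under
the default strict-complete policy any column containing a missing value is
dropped (the discriminant has no missing-data mechanism), as are constant
columns; both removals are logged so column counts always reconcile.

## Cohort statistics

Classical tests wrap scipy: Pearson χ² on 2×2 tables without continuity
correction (df = 1), pooled-variance two-sample t (with mean difference,
standard error and 95 % CI — the layout in which such results are
conventionally reported), Spearman rank correlation with average ranks for
ties, and one-way ANOVA. A pooled rather than Welch t-test was chosen to
match the classical "independent-samples t-test" default; two-group ANOVA
satisfies F = t² against it, which the suite checks. The decision-tree split
of samples on a binary feature is deliberately restricted to a single
documented split (feature × tumor-status χ²): growing a full CHAID tree
would require merge heuristics and corrections that cannot be pinned down,
and only the first split is scientifically load-bearing here. Pairwise
per-group contrasts (behind letter-coded group comparisons) apply no
multiple-testing correction by default, with Bonferroni available.

## Biomarker selection

Selection runs independently per cancer type against the healthy controls:

1. **Dichotomization.** Continuous features are binarized at the threshold
   maximizing |φ| (Pearson correlation of the binarized feature with the
   class indicator), scanning every midpoint between consecutive distinct
   values; ties break toward the smallest threshold. This is deterministic
   and exhaustive; φ is also the ranking statistic, so the threshold choice
   and the ranking optimize the same quantity.
2. **Ranking.** Features are sorted by |φ| (ties: lexicographic id) and the
   top k kept, default k = 4 — small candidate sets guard against the
   spurious correlations a 100+-feature panel generates at these sample
   sizes.
3. **Exhaustive subset search.** Every non-empty subset of the candidates is
   scored by S = 2·FN + FP, where FN/FP come from leave-one-out discriminant
   classification of type-vs-healthy on the subset (LOOCV rather than
   resubstitution, for consistency with the classifier's protocol; a
   resubstitution mode exists for sensitivity analysis). Minimum S wins;
   ties break toward smaller subsets, then lexicographic order. A guard
   refuses k > 20 (2^k blow-up).
4. **Redundancy elimination.** While any pair in the winner exceeds the
   pairwise-|correlation| ceiling (default 0.9), the member with the weaker
   outcome correlation is dropped, most-correlated pair first. The ceiling
   is configurable because no canonical value exists; 0.9 removes
   near-duplicates without touching genuinely complementary markers.

The false-negative weight of 2 encodes the screening context: missing a
tumor is costlier than a false alarm that triggers follow-up diagnostics.

## Discriminant classification

The classifier is a two-class Fisher linear discriminant built from class
means and the pooled within-class covariance, exposed statsmodels-style:
`DiscriminantAnalysis(X, y).fit()` returns a results object with the weight
vector, classification threshold and `summary()`. Numerical choices:

* **Pseudo-inverse + tiny ridge.** The pooled covariance is inverted as
  pinv(Σ + 1e-8·(tr Σ/p)·I). The pseudo-inverse handles p > n (DA1 uses more
  features than samples) and duplicated columns deterministically with no
  tuning parameter; the tiny relative ridge keeps directions with zero
  within-class variance but separated class means (e.g. a perfectly
  separating binary feature), which a bare pseudo-inverse would annihilate.
  At 1e-8 relative scale the ridge is far below measurement noise and leaves
  nonsingular problems numerically unchanged (verified against an
  independent LDA implementation).
* **Priors.** Equal by default — the healthy group is an order of magnitude
  smaller than the tumor group, and proportional priors would let the
  classifier buy accuracy by ignoring controls. Proportional mode is a flag.
* **Ties** (score exactly 0) predict tumor, consistent with the
  false-negative-averse cost.

**LOOCV.** Each sample is predicted by a model refit from scratch on the
other n−1; the held-out signed discriminant scores feed the ROC (AUC via the
rank construction, equal to Mann–Whitney U/(n₊·n₋), ties counted half — an
identity the tests verify). A fold whose training set drops below two
members of a class predicts the larger remaining class and is logged, with
an extreme finite score standing in for the missing discriminant value.
Confusion counts use tumor as the positive class throughout; accuracy,
sensitivity and specificity are reported in percent and recomputable from
the stored confusion exactly.

**Feature-set harness.** Five canonical sets are evaluated on the AR−
subgroup (DA1 all features, DA2 mutations, DA3 methylation, DA4 miRNAs, DA5
selected biomarkers), all excluding the AR call itself, since AR already
defines the split. The two-step model routes AR-positive samples directly to
the tumor class — justified when AR positivity is absent in controls — and
classifies the AR− remainder with the downstream discriminant; combined
sensitivity therefore can only gain from the split when AR+ is
tumor-enriched.

## Synthetic cohort generator

The generator emulates the study conditions at Ct level; its defaults *are*
those conditions, not tuning knobs:

| parameter | default | origin |
|---|---|---|
| group sizes | healthy 15; bladder 20, brain 9, breast 30, colorectal 28, lung 29, ovarian 19, prostate 27, stomach 23, pancreas 12 | study cohort layout |
| per-group stage counts | exact counts summing to 39/81/77 over stages I–III | study cohort layout |
| AR+ prevalence | CRC .857, bladder .80, prostate .667, breast .60, lung .483, stomach .261, ovarian .20, brain .111, pancreas .083, healthy 0 | reported per-type rates |
| mutation burden | AR+ tumors 7.5, AR− tumors 4.8, healthy 1.33 (Poisson, AR call included) | reported means; implied overall tumor mean ≈ 6.19 vs the reported 6.15 |
| cfDNA conc. (ng/µL) | stage I/II/III 0.435/1.091/2.506, healthy 0.557; lognormal, log-sd 0.5 | reported stage means; lognormal is the conventional choice for concentrations |
| Ct noise | additive Gaussian, sd 0.25 cycles | typical qPCR replicate scatter |
| biological spread | methylation-gap sd 0.8 cycles, miRNA Ct sd 1.0 cycles | chosen once as realistic inter-subject variability |
| planted effects | methylation: −1.5 cycles on the CtMe−CtUnMe gap (≈ 26 %→50 % m%); miRNA: −2.0 Ct (4-fold up); mutation: 15× allocation weight | sized so the selection stage recovers planted markers in ≥ 90 % of seeds at study sample sizes |

Positive mutation calls are realized by drawing ΔCt below the cutoff
(negative: above it or undetermined), so the generator exercises the real
calling path rather than injecting binary features. Burdens are allocated
across the non-AR detected assays by weighted sampling without replacement,
which plants type-specific mutation enrichment while preserving the burden
distribution. Four miRNAs are emitted below the detection limit so the
detection filter's accounting (47 candidates → 43 retained) is exercised; 7
mutation assays never amplify and fall out as constant columns. A
study-shaped *raw* cohort variant adds a 7-member liver group and one
listed-for-exclusion sample (recorded with stage 3, the domain maximum),
which the default exclusion rules remove to give the 212-sample analyzed
cohort. `null_config` zeroes every group effect for type-I-error
calibration.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: correlated co-mutation structure beyond the AR
burden link, batch effects other than a per-sample miRNA yield shift, PCR
efficiency below 100 %, assay cross-reactivity, and realistic missingness
mechanisms (missingness here is planted, not informative). Synthetic
separability is also stronger than clinical reality in places — e.g. the
stage–cfDNA Spearman ρ comes out near 0.8 because stage means are the only
concentration signal, whereas real cohorts show much weaker rank
correlation. Classifier metrics on synthetic cohorts characterize the
implementation, not expected clinical performance.

## Problem sizes and determinism

Default demonstration and test problem sizes: one 212-sample cohort for
end-to-end runs (seconds), 50 seeds for parameter-recovery checks, 10 seeds
× 9 types for planted-marker recovery, 3 seeds for null calibration —
sufficient for the sampling-error bands used while keeping the suite quick
to iterate on. All randomness flows from a single `numpy` Generator seeded
from the config; a given config reproduces every table byte-for-byte, and
each pipeline bundle carries a manifest (seed, config hash, version) that
suffices to regenerate it.

## Known limitations

* The per-assay ΔCt cutoffs, full assay list and miRNA panel of a real
  instrument deployment are site-specific configuration; the shipped default
  panel is a synthetic stand-in with uniform cutoffs (8 cycles).
* Whether mutation cutoffs should be one-sided (implemented) or two-sided
  windows is assay-chemistry-dependent and not configurable yet.
* The discriminant assumes shared within-class covariance; no quadratic
  discriminant or probability calibration is provided.
* Only the first split of the decision-tree stage is implemented (by
  design); multi-level trees and multi-class tissue-of-origin prediction are
  out of scope.
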