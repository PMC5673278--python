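# Methods

This note documents the statistical procedures implemented in `thymeth`,
the choices made where the design was genuinely open, and what the
synthetic cohorts do and do not establish about behaviour on real data.

## Data model

Beta values are methylation fractions in [0, 1], probes × samples, with
missing measurements carried as NaN; every per-probe statistic is
pairwise-complete over the samples it uses.  Probe annotations follow the
450k manifest conventions: 1-based hg19-style coordinates,
manifest-style chromosome labels, semicolon-split multi-gene associations,
island relations normalised to island / shore / shelf / open-sea.  A probe
counts as a *promoter* probe when at least one of its gene associations is
TSS200, TSS1500, 5′UTR or first exon; multi-gene conflicts are not
resolved further.  Histologies map onto five lesion classes (NT; BTL =
adenoma/goiter/thyroiditis; PTC; FTC/HCC; PDTC/ATC), and the good/poor
prognosis labels (GP/PP) are defined only for well-differentiated
carcinomas: GP requires ≥ 5 years of event-free follow-up, PP a confirmed
recurrence; multifocal PP primaries are excluded from classifier training
and evaluation because multifocal tumours plausibly have independent
clonal origins.

## Probe-level QC

Five exclusion rules run in a fixed order — cross-reactive, SNP (MAF >
5%), sex-associated, detection p > 0.05 in ≥ 5% of samples, bead count
< 3 in ≥ 5% of samples — and each removed probe is attributed to the
first rule that matched, so the removal counts partition the input.  The
"≥ 5% of samples" count is `ceil(0.05·n)`, the conservative reading when
5% of the cohort is not an integer; the thresholds are parameters, not
constants.  The three flag rules are inputs (annotation columns), not
computed: in particular the sex-associated flag may come from a published
list and is not restricted by construction to X/Y probes.  Normalisation
(e.g. beta-mixture quantile methods) and batch correction are published
procedures this package deliberately does not re-derive; `filter_probes`
exposes a `normalizer` callable hook and otherwise assumes its input is
already normalised.

## Differential methylation

Effect size is Δβ, the difference of group mean beta values.  The test
statistic is a moderated *t*: per-probe residual variances `s_g²` with
`d_g = n_a + n_b − 2` residual df are shrunk toward a scaled
inverse-chi-square prior `(d_0, s_0²)` fitted by the method of moments on
`log s²` (the prior df comes from a trigamma inversion of the excess
spread of log-variances; when the observed spread does not exceed what a
common variance predicts, the moment estimate is non-finite and all
variances shrink fully to `s_0²`, with a logged warning).  The moderated
statistic is `t = Δβ / (s̃ √(1/n_a + 1/n_b))` on `d_0 + d_g` df, two-sided,
since hyper- and hypomethylation are both of interest.  The implementation
is validated to machine precision against the standard Bioconductor
empirical-Bayes reference in the test suite.

Tests run on beta values directly, not M-values, so the significance gate
and the |Δβ| effect gate share one scale; a Welch *t* is provided as a
cross-check statistic.  Whether the original analyses of this kind use
betas or M-values is generally ambiguous; the choice is isolated in
`ContrastSpec.statistic`.  Multiplicity is controlled by Bonferroni with
`m` = number of probes surviving QC, per contrast.  A probe is *called*
(hyper/hypo) only when adjusted p < 0.05 **and** |Δβ| > 0.2, so under a
null cohort the joint gate calls essentially nothing while the p-gate
alone stays at its nominal level (checked within binomial 99% bounds).

Context summaries report, per direction, proportions over gene-region
categories (multi-valued region annotations resolved by promoter-first
precedence, or collapsed to promoter/body/intergenic) and over island
relations.  Exclusivity analysis marks a probe exclusive to a class and
direction when no other contrast calls it in the same direction; shared
sets are reported per class pair.

## The prognostic cascade and DLDA

Stage 1 takes probes differential between PDTC/ATC and NT (|Δβ| > 0.2,
adjusted p < 0.05) that are promoter-annotated — the premise being that
promoter changes fixed in undifferentiated tumours, which are
poor-prognosis by definition, may mark the aggressive minority of
well-differentiated tumours.  Stage 2 keeps candidates with
|Δβ(PP−GP)| > 0.1 whose sign matches the stage-1 shift and whose GP mean
stays within 0.1 of both NT and BTL.  The sign-concordance and
GP-vs-controls gates are one defensible formalisation of "exclusively
altered in PP"; they are isolated in `CascadeConfig` for sensitivity
analysis.  The BTL control matters because lymphocytic thyroiditis shares
inflammation-driven methylation with aggressive tumours; without it,
inflammatory benign lesions would be predicted high-risk.

DLDA uses per-probe class means and a pooled (not per-class) within-class
variance with a floor of 1e-6 beta² — standard diagonal LDA, numerically
guarded against zero-variance probes.  The decision threshold is 0 (equal
priors): the training prevalence (8 PP / 48 GP) reflects cohort
construction, not population risk.  Weights satisfy
`sign(w_j) = sign(Δβ(PP−GP)_j)` by construction, matching the reference
panel where the reported per-probe score signs track the Δβ signs; the
reference panel's absolute score scaling comes from an undocumented tool
and is treated as sign/relative-magnitude information only.

Risk tiers: low iff score ≤ max score over NT samples, else intermediate
iff score ≤ threshold (ties go down), else high.  Scores below the NT
minimum are still "low" — the published rule names a single boundary.  A
model whose NT maximum exceeds the threshold is rejected at construction
(the stratification would be incoherent).  Tiers are invariant to jointly
rescaling weights, threshold and NT range by a positive constant.

LOOCV is deterministic.  Two modes are provided because published
pipelines of this kind are ambiguous about whether probe selection was
repeated inside the loop: `full_cascade` re-runs the stage-2 filter and
DLDA fit per fold (stage 1 contrasts PDTC/ATC with NT and is unaffected by
holding out a WDTC sample, so it is computed once); `fixed_probes` refits
DLDA only.  Selection inside the loop can only remove optimism, so
`fixed_probes` is never more pessimistic on average — a property checked
over 20 simulated cohorts.  Folds whose training classes become too small
to fit are flagged, excluded and reported rather than aborting.
`apply_fixed_signature` applies a trained model to an external cohort with
no refitting of weights, threshold or NT range, after re-applying the
training inclusion rules.

## Survival and clustering

Kaplan–Meier curves and the log-rank test are computed via lifelines
(product-limit estimator; hypergeometric-variance log-rank without
continuity correction, df = groups − 1); the test suite validates them
against a hand-computed product-limit example and the exponential closed
form.  A cohort with no events yields χ² = 0, p = 1, not an error.
Unsupervised clustering restricts to the k most variable probes (variance,
ddof = 1, ties broken lexicographically by probe id), computes sample
distances as 1 − Pearson correlation, applies average linkage and cuts at
k clusters; labels are renumbered by first appearance so the result is
sample-order invariant.  The distance and linkage follow the customary
defaults of array-analysis tools; both are deliberate, config-visible
choices since the variability criterion behind any particular published
probe count (e.g. a "most variable 8016" set) is not derivable, `k_probes`
is a required argument rather than a default.

## Synthetic cohorts

The generator emulates the statistical structure the pipeline assumes, at
the cohort sizes of the motivating design: 50 NT, 17 BTL, 60 PTC, 10
FTC/HCC, 4 PDTC/ATC, with 48 GP (43 PTC + 5 FTC) and 8 PP (6 PTC + 2 FTC)
well-differentiated cases.

* **Beta distributions.** Per-probe baselines are drawn from a three-mode
  logit-normal mixture (modes at β ≈ 0.10/0.50/0.85 with weights
  0.45/0.10/0.45, probe-level spread 0.6 on the logit scale), reproducing
  the bimodal 450k shape.  Logit-normal rather than Beta draws because
  additive logit effects compose cleanly with batch effects.  Per-sample
  noise is Gaussian on the logit scale (sd 0.45, i.e. beta-scale sd
  ≈ 0.04–0.11 depending on the baseline — typical within-tissue 450k
  variability); two batches with probe × batch shifts of sd 0.1.
* **Planted effects.** Defaults mirror the observed direction structure:
  BTL and FTC/HCC predominantly hypermethylated vs NT (|Δβ| = 0.30), PTC
  predominantly hypomethylated (0.30), PDTC/ATC with the largest burden
  (500 probes, |Δβ| = 0.35, mostly hypo).  A 21-probe poor-prognosis
  panel (4 hyper / 17 hypo, matching the reference panel's split) is
  planted on promoter probes in PDTC/ATC at |Δβ| = 0.35 and in WDTC-PP at
  0.35 × 0.35 ≈ 0.12 — the attenuation factor is 0.35 so that the PP
  shift sits just above the 0.1 cascade gate, the regime the method is
  designed for.
* **Calibration.** After noise is drawn, each planted probe's target-group
  logit shift is solved (Brent) so the *realized* group-mean Δβ equals the
  target exactly; expectation-scale planting cannot guarantee the ±0.02
  realized-Δβ contract at group sizes of 4–10.  Probes whose baseline
  leaves no room for the requested shift are ineligible; if the budget
  cannot be filled, the generator raises rather than silently attenuating.
* **Artifacts.** 2% of probes fail the detection rule and 2% the
  bead-count rule (by construction, in ≥ 5% of samples); flags are planted
  at 1.5% (cross-reactive), 2% (SNP) and ~2% (sex chromosomes).  Planted
  effects avoid flagged/failing probes so truth tables survive QC.
* **Outcomes.** PP samples get exponential recurrence times (mean 24
  months); GP samples are censored between 60 and 120 months (the 5-year
  inclusion rule); `simulate_survival` separately generates tier-driven
  exponential times (defaults 0.002/0.01/0.03 events·month⁻¹ for
  low/intermediate/high) censored at 120 months for survival-analysis
  testing.

**What passing tests show — and don't.** The planted signal is exactly
calibrated, uncorrelated across probes, Gaussian on the logit scale, and
free of tumour-purity, probe-chemistry (Infinium I/II) and cell-composition
effects.  Cascade recovery and near-perfect LOOCV on these cohorts
demonstrate correctness of the algorithms — the cascade finds exactly what
its gates define, DLDA matches the likelihood classifier it is — not that
real recurrence prediction achieves comparable sensitivity or specificity.
The published figures of this kind (sensitivity ≈ 0.6, specificity ≈ 0.9)
come from real cohorts whose effect sizes sit much closer to the gates;
reproducing them requires the corresponding external datasets
(`scripts/external_validation.py`).

## Problem sizes and numerics

Default simulations use 20 000 probes (scaled-down from the ~485k array,
preserving all rate parameters); smaller fixtures in the test suite use
1500–10 000.  Brent root-finding uses an xtol of 1e-12 on the logit shift;
trigamma inversion runs Newton iterations to relative 1e-8; DLDA variances
are floored at 1e-6; survival times are strictly positive and censoring
caps must be positive.  All randomness flows from a single integer seed
through `numpy.random.default_rng`; identical seeds give bit-identical
cohorts, and the classifier path (cascade, DLDA, LOOCV) contains no
randomness at all.

## Known limitations

* No IDAT/raw-array processing, normalisation or batch correction —
  inputs are assumed normalised.
* Bonferroni only; no FDR alternatives.
* The moderated t assumes approximately Gaussian within-group noise on
  the beta scale; near-boundary probes (β ≈ 0 or 1) are skewed, which the
  calibration tests cover only at moderate group sizes.
* No covariate adjustment in differential testing, no Cox regression (a
  tier-annotated survival table can be exported for external fitting),
  no probability calibration for the classifier, and no alternative
  classifiers.
* The exclusivity formalisation in the cascade is one reading of a
  qualitative rule; alternatives can be explored via `CascadeConfig`.
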