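# Methods

`osteomorph` quantifies cranial skeletal development in stained zebrafish
larvae from three kinds of tabular input: named 2-D landmark annotations on
Alcian-blue (cartilage) or Alizarin-red (bone) images, per-structure ordinal
ossification scores, and qPCR cycle-threshold tables. This note documents the
models, the numerical choices, and what the synthetic generators do and do
not emulate.

## Landmark ontologies and morphometry

Landmarks are named anatomical points in image pixel coordinates (origin
top-left, y downward). Bilateral elements of the ventral view carry `_up` /
`_down` suffixes; midline elements are unpaired. Three vocabularies ship with
the package:

- **cartilage_21** — 3 midline points (anterior, ethmoid plate, posterior)
  plus 9 bilateral pairs (articulation, ceratohyal exterior/interior,
  hyosymplectic, Meckel's cartilage, ceratobranchials 1–4), with the 8
  retained inter-landmark distances.
- **bone_29** — the 15-landmark core (anguloarticular, anterior,
  branchiostegal ray 1, entopterygoid, maxilla, notochord, opercle, and the
  three summits a/b/c of the triangular parasphenoid) plus the elements
  annotated only in the chemical-treatment cohorts (branchiostegal ray 2,
  cleithrum, ceratobranchial 5, ceratohyal, dentary, hyomandibular). The
  bone ceratohyal is annotated with exterior and interior points per side,
  mirroring the cartilage convention; this is the package's fixed reading of
  the 29-landmark set, chosen because it is the only expansion of the listed
  element families that yields exactly 29 points. The exact historical
  membership is not machine-checkable, so treat this as a documented
  convention, not an anatomical fact.
- **bone_15** — the 15-landmark core used for the hypergravity cohorts; it
  carries the same 13 measures, all of which resolve within the subset.

Measures are Euclidean distances (pixels), interior angles (radians, vertex
listed first, computed from normalized direction vectors and clipped into
[0, π]) and the shoelace triangle area (pixels²). The three parasphenoid
"angles between summits" are implemented as the interior angle at each
summit — the only reading under which the three values are the angles of the
parasphenoid triangle and sum to π. No Procrustes superimposition, scale
normalization or mm calibration is applied: values stay on the raw pixel
scale of each image, which is appropriate only when magnification is
constant within an experiment (a documented limitation). A measure is
missing iff a constituent landmark is missing; missingness is never imputed
and every test uses its own complete cases.

PCA screening of candidate measures (`screen_measures_pca`) standardizes
complete rows, drops measures with raw variance below `variance_floor`
(default 1e-6, i.e. effectively constant) and, within any pair correlated at
|r| ≥ `redundancy_r` (default 0.95), drops the member with the smaller
absolute loading on the first principal component. Both thresholds are
configurable because only the intent (remove invariable or redundant
measures), not the cutoffs, is fixed by the analysis design; the procedure
is deterministic given the table.

Group comparisons use the Welch t-test by default (`equal_var=True`
recovers Student's); three or more conditions use one-way fixed-effects
ANOVA. Stars follow the usual convention (* p<0.05, ** p<0.01,
*** p<0.001, strict inequalities).

## Ossification scoring

Each bone element is assigned one of four ordered categories relative to a
typical control larva: `absent < early < advanced < over`. Categories are
analyst-assigned inputs; the package never infers them from coordinates.

The **global score** of a larva is the sum over scored elements of the
category weight, default 0/1/2/4 (any strictly increasing integer weights
are accepted). Sides of bilateral elements contribute separately, so the
default 8 element families yield 16 contributing elements; with advanced
ossification worth 2 this puts a typical control in the mid-20s to low-30s,
consistent with the study-scale cohorts the presets emulate. The element set
entering the score is data-driven (whatever structures are scored), since
the canonical list is not fixed. The score is additive over disjoint element
sets and strictly monotone in single-category upgrades; both properties are
tested.

For cohort reporting, bilateral sides are pooled into one count stream per
element family (n doubles) and cumulated frequencies are given in percent,
rounded to 2 decimal places.

## Ordinal association statistics

Per structure, group × class counts form a contingency table; classes with
zero total count across all groups are collapsed away first (4 → 3 classes;
idempotent; an error if fewer than 2 classes survive).

- **Pearson X²** (`scipy.stats.chi2_contingency`, no continuity correction)
  with df = (r−1)(c−1). Expected cells below 5 produce a warning, not an
  error, because the small-cohort tables of this domain routinely violate
  the rule and the statistic is still reported.
- **Proportional odds.** The cumulative-logit model
  `logit P(Y ≤ k | x) = α_k − β·x` is fit by maximum likelihood on the
  grouped multinomial counts (monotone cutpoints via a log-difference
  reparameterization, Nelder–Mead then BFGS polish; the fit is authored
  in-package and cross-checked against an independent ordered-regression
  implementation in the tests). `OR = exp(β)` is the common odds ratio of
  reaching a higher ossification class under treatment. Wald p-values and
  CIs by default (finite-difference observed information), likelihood-ratio
  p available by flag.
- **Separation.** Tables where one group concentrates in extreme classes
  can send β to infinity. The fit flags |β| > 8 or a singular information
  matrix, refits with a ridge penalty 0.5·λ·β² (λ = 1 by default) and
  reports a profile-(penalized-)likelihood 95% CI; `separation_flag` is set
  so downstream consumers know the estimate is regularized. A ridge penalty
  was chosen over a Jeffreys-prior (Firth) penalty because the latter needs
  the expected-information determinant inside the objective, which is
  numerically fragile on tables this small; the ridge fallback is standard,
  robust and clearly flagged. For dichotomized comparisons the classical
  2×2 odds ratio with optional Haldane–Anscombe 0.5 correction is also
  exposed.
- **Grouped contrast.** For the reduced-gravity design the three
  hypergravity-exposed conditions (3g, 3g>1g, 3g>axe) are pooled by summing
  counts and contrasted against the 1g sample with the same two tests.

Significance is strict (p < 0.05 by default). No multiple-testing
correction is applied to the per-structure tests, matching the original
analysis style; reports carry the number of tests performed, and an
explicitly labelled Benjamini–Hochberg switch exists as an extension.

## qPCR quantification

Technical replicates are averaged on the Ct scale (standard practice).
Per biological replicate, ΔCt = Ct_target − Ct_reference; ΔΔCt is the
condition-mean ΔCt minus the calibrator-mean ΔCt, and the fold change is
2^−ΔΔCt, so the calibrator fold is exactly 1 by construction. Dispersion is
the SD of per-replicate folds. Amplification efficiency is fixed at 2 (the
2^−ΔΔCt assumption); no efficiency correction is attempted. The reference
gene is chosen from the housekeeping panel (gapdh, ef1a, actb) as the
candidate with the smallest SD of its condition-mean Ct — a simple,
deterministic stand-in for the informal "most stably expressed" criterion,
with ties broken by panel order. ΔΔCt is invariant to any constant added to
all Ct values, and swapping the calibrator inverts folds on noiseless data;
both invariances are tested.

## Synthetic data generators

The generators exist so that every stage is testable without images or RNA:

- **Landmarks:** template mean shape + per-condition displacement vectors +
  iid Gaussian landmark noise (default SD 2 px, a plausible manual
  re-annotation scatter at this image scale); landmarks are dropped with
  per-condition probabilities to emulate missing structures. An optional
  random rigid transform per larva exists but is off by default, since real
  ventral-view images are roughly aligned — and every measure is invariant
  to it anyway. The templates are stylized: they reproduce the topology of
  a ventral head view at a realistic pixel scale, not the metric anatomy of
  real larvae.
- **Ossification:** per structure × condition 4-class multinomials, or a
  latent proportional-odds parameterization (cutpoints + per-condition
  shift) for parameter-recovery studies.
- **Ct tables:** target Ct = baseline − log2(true fold) + N(0, replicate SD
  0.15 cycles); the reference gene is flat. Default 4 biological × 3
  technical replicates.

All generators are pure functions of (configuration, seed) using numpy's
PCG64 `default_rng`; emitted CSVs record the seed in a `#` header line and
byte-identical reproduction under a fixed seed is tested.

### Preset scenarios and their tuning constants

The presets encode the study-scale effect sizes as generator ground truth.
Element-family multinomials (absent, early, advanced, over) were solved
analytically so that the *expected* global score over the 16 contributing
elements equals the documented cohort means; they are fixed constants, not
fitted quantities:

| preset | condition | multinomial (p_absent, p_early, p_advanced, p_over) | E[score] |
|---|---|---|---|
| vitd3_like | control | (0.13125, 0.25, 0.55, 0.06875) | 26 |
| vitd3_like | VitD3 | (0.059375, 0.10, 0.70, 0.140625) | 33 |
| pth_like | control | br1 (0, .10, .90, 0); entopterygoid (0, 1/29, 28/29, 0); anguloarticular (.21, .19, .60, 0); others (0.125275, 0.25, 0.55, 0.074725) | 27 |
| pth_like | PTH | br1 unchanged; entopterygoid (0, .60, .40, 0); anguloarticular (.94, .04, .02, 0); others (0.554, 0.25, 0.18, 0.016) | 13.5 |
| hyperg_like / rgp_like | 1g | (0.153125, 0.35, 0.45, 0.046875) | 23 |
| hyperg_like / rgp_like | 3g-exposed | (0.115625, 0.25, 0.55, 0.084375) | 27 |

The PTH preset additionally pins the documented per-structure frequencies
(94% vs 21% absent anguloarticular with 19% early / 60% advanced controls;
60% early entopterygoid under treatment vs 1-in-29 controls; branchiostegal
ray 1 unaffected); the five remaining families share one multinomial solved
to make the expected totals exact. Matching the score *means* was the
design goal; the implied score SDs (≈3–4) are close to but not exactly the
cohort SDs, since a sum of independent per-element draws cannot reproduce
arbitrary variance without element correlations the data do not constrain.

Landmark displacements per preset are round numbers of the right sign and
magnitude (e.g. +20 px between maxillae under VitD3, a shortened
parasphenoid under PTH, +16 px posterior widening at 3g) chosen to be
detectable at n≈25 with 2 px noise; they emulate the direction of the
reported shape effects, not their exact pixel values, which depend on
magnification.

What passing tests on these cohorts shows: the estimators recover known
ground truth of the assumed forms (Gaussian landmark scatter, independent
multinomial categories, log-scale Ct noise). What they do not show:
robustness to annotation bias, inter-annotator disagreement, correlated
element development within a larva, magnification drift between images, or
qPCR efficiency ≠ 2.

## Problem sizes and tolerances

Unit and property tests run at small n (tens of larvae, hundreds of random
geometry instances). Calibration checks use 1000-replicate null simulations
(type-I bands [0.03, 0.07] at the 2-group 4-class chi-square, [0.04, 0.06]
for t/ANOVA); ordinal parameter recovery uses 500 replicates at n=200 per
group (mean β̂ within ±0.1 of 1.5). `scripts/acceptance.py` reports cohort
score means at n=1000 per condition and qPCR fold recoveries as geometric
means over 25 simulated 4-replicate experiments, sizes at which Monte-Carlo
error is small relative to the quantities themselves. Geometric identities
are asserted to 1e-9 (absolute or relative as appropriate), the likelihood
optimum against a brute-force grid to 1e-6.

## Known limitations

- Pixel-scale measures are comparable only within constant-magnification
  image sets.
- The proportional-odds model assumes a common β across cut-points; no
  test of that assumption is performed on 2-group tables (it is saturated
  for 2 classes and weakly identified at these n).
- The ridge fallback under separation shrinks |β| toward 0; its CI is a
  penalized-profile interval, not a frequentist guarantee.
- The reference-gene criterion uses only between-condition SD; true
  stability measures (e.g. pairwise-variation algorithms) need more genes
  and replicates than these designs carry.
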