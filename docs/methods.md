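# Methods

This note documents the models, decision rules, numerical choices and
limitations of `her2mbc`, stage by stage.

## HER2 status assignment

**Model.** Log2(x + 1) ERBB2 expression is treated as a two-component
Gaussian mixture, fit by EM (scikit-learn `GaussianMixture`, 10 random
restarts with fixed sub-seeds, tolerance 1e−8, at most 500 iterations).
Two components on a log scale is the simplest model consistent with the
bimodal histogram an amplified/non-amplified cohort produces; no attempt is
made to model intermediate amplification states.

**Cross-point.** The expression cut is the root of
`w₁·N(x; μ₁, σ₁) = w₂·N(x; μ₂, σ₂)` between the ordered component means,
found by bisection to 1e−12. When the weights are extreme enough that the
weighted densities do not cross between the means, the midpoint of the
means is used and the fit is flagged (`cross_point_fallback`); downstream
classifiers refuse flagged fits rather than silently degrade.

**ROC transfer.** The intermediate high/low call is transferred to an
absolute copy-number threshold by scanning every candidate cut — midpoints
between consecutive sorted unique CN values plus ±∞ sentinels — and
choosing the maximiser of Youden's J (sensitivity + specificity − 1).
Distance to the (0, 1) ROC corner is implemented as an alternative
criterion; Youden is the default because it is the standard single-number
optimum and treats the two error types symmetrically. Ties are broken
toward the larger threshold so positive calls are conservative. A marker
that is anti-informative for the labels (maximum J not exceeding the
maximum J of the reversed orientation) is refused rather than silently
inverted.

**Boundary convention.** Strict inequalities throughout: expression must be
strictly above the cross-point for an intermediate high call, and CN must
be strictly above the threshold for a HER2+ call. The ESR1 classifier
mirrors this on the opposite side (at the cross-point is *low*).

## Composite risk score

Binary features (PIK3CA, CDK12, Amp-peak-6, above-median DBS3) score 1
when present; prior therapy lines score 0.25 / 0.5 / 0.75 / 1 for
0 / 1 / 2–3 / ≥ 4 lines; the high-risk label requires a total of at least
2.25. The 2.25 cut is a fixed constant of the scoring rule, not refit.

**Item encoding.** All screened items are categorical: mutations and CN
regions yes/no; signature contributions above/below the cohort median
(strictly above counts as above, so an at-median sample is "below");
continuous counts (mutation count, SV count, ploidy) are dichotomised at
the cohort median — the encoding rule specifies the cut only for
signatures, so extending the median cut to the other continuous items is a
documented assumption. The DBS3 median is computed over the cohort being
scored; a reference distribution can be supplied instead when scoring a
subset against a larger cohort.

**Screening and selection.** One Cox proportional-hazards fit per item
(lifelines, Efron tie handling — the standard choice, unstated in the
original procedure), Wald p, two-sided α = 0.05. Forward selection is
strict: the model is seeded with the most significant univariate item,
remaining significant items are tried in ascending univariate-p order, a
candidate is kept only if its multivariable p stays below α, and accepted
items are never removed. Items with monotone likelihood (complete
separation) are flagged and excluded rather than reported with divergent
hazard ratios.

**Validation mode.** On targeted-panel data without signatures or therapy
history, a sample is high risk when any of PIK3CA, CDK12 or Amp-peak-6 is
present. Amp-peak-6 is called from SEG input: at least one segment
overlapping chr8:32280146–47560553 with copy number strictly above 1.5.
SEG coordinates are treated as 1-based fully-closed intervals (the CBS/IGV
convention; the convention used for the region limits is not documented
upstream, so this is an explicit assumption), overlap requires ≥ 1 bp with
closed endpoints, and segment values are compared to the threshold as raw
numbers with no log/linear transformation. The three validation features
were mutually exclusive in the data the rule was designed for;
co-occurrence is tolerated but logged.

## Expression profile

Four groups (HER2± × prior anti-HER2), per-gene Kruskal–Wallis, select at
unadjusted p < 0.001 (strict). The threshold is deliberately uncorrected —
it is a screening rule, not an inference — and chromosome 17 genes are
excluded regardless of p as potential ERBB2 co-amplification passengers.
Cohorts missing one of the four combinations degrade to a 3-group test
with a warning. Selected genes are log2(x + 1)-transformed and median
centred per gene; samples are Pearson-correlated; agglomerative clustering
uses distance 1 − r with average linkage (Ward and complete are exposed as
options and the choice is recorded in the run manifest), cut into k = 4
flat clusters by default.

Signature scores are the mean of gene-wise median-centred log2 expression
over the gene set — invariant to per-gene additive shifts and to genes
outside the set. MAPK-high means strictly above the cohort median score.
Gene lists are user-supplied files (one symbol per line); the external
reference lists are not redistributed, and the synthetic generator plants
its own. The ESR1 low/high split reuses the mixture machinery; whether the
original analysis used a mixture or a fixed cut is unknown, so the mixture
choice is flagged in output metadata.

## Synthetic cohorts

The generator (`her2mbc.synthetic`) emulates, per sample:

* **Copy number / expression:** log2 ERBB2 CN from N(1.10, 0.25) for
  non-amplified and N(4.50, 0.55) for amplified samples (10% amplified by
  default, n = 700), i.e. background CN ≈ 2.1 and amplified CN ≈ 23 with a
  wide gap; log2 ERBB2 expression N(5, 1) / N(10, 1) conditional on the
  amplification truth.
* **Mutations:** Bernoulli flags at the published prevalences (PIK3CA 0.39,
  CDK12 0.13; TP53 0.63 as a comparison gene).
* **Signatures:** Dirichlet within each class (SBS/DBS/ID/SV), which
  guarantees the sum-to-one contract; the DBS3 concentration parameter is
  raised (α = 8) for a designated 12% high fraction so both the ">10%
  contribution" and the "above median" reading of DBS3 positivity are
  exercisable.
* **Survival:** exponential PFS with hazard `h₀·exp(Σ βᵢxᵢ)` using the
  published hazard ratios (5.53, 3.47, 18.07, 3.91; 1.43 per prior-lines
  category) on the *planted* feature indicators, h₀ = ln 2/300 per day
  (median 300 days for a baseline patient; the exponential is the simplest
  proportional-hazards-consistent baseline, as none is published), and
  independent exponential censoring whose default rate (2.7765e−3/day) was
  solved analytically so the expected censoring fraction is 20% under the
  default feature mix (`expected_censoring_fraction` computes the exact
  2⁴ × 4 lattice expectation).
* **Expression structure:** 1000 null genes; 100 effect genes in four
  blocks of 25, each block shifted +3 noise-SD in one HER2 × prior group;
  30 chromosome 17 passenger genes shifted only in amplified samples; 25
  planted MAPK and 25 ESR1-module genes (+1.5 SD in ER pos-to-low and
  ESR1-high samples respectively); ESR1 itself bimodal at log2 3/8; 11.5%
  of primary-ER+ samples switch to the low ESR1 component.
* **Segments:** every sample gets background chr8/chr5 segments around
  CN 1; Amp-peak-6-positive samples (35%) get a 2 Mb segment inside the
  region at CN 1.6 + Exp(1); ~30% of negative samples get an in-region
  segment at CN 0.7–1.4 to exercise the threshold.

One integer seed drives a single NumPy Generator; identical parameters
give bit-identical cohorts. The generator does **not** model tumor purity,
clonality, read-level noise, gene–gene correlation beyond the planted
blocks, or informative censoring — so passing recovery tests demonstrates
the decision rules behave as specified under their own assumptions, not
that they are robust to real-data artefacts.

## Statistics

Mann–Whitney U for two groups, Kruskal–Wallis for more (midrank ties,
two-sided); Fisher exact for 2×2 tables, chi-square for larger; Hochberg
step-up correction implemented directly from the formula
`adj(i) = min_{j≥i} (n−j+1)·p(j)` (cross-checked against statsmodels in
the tests), with Benjamini–Hochberg selectable. TMB is variants per Mb
with a configurable denominator defaulting to 2859 Mb (non-N autosomal +
sex hg19; the denominator the original analysis used is unstated);
TMB-high is strictly above 10/Mb. The cohort mutation-frequency comparison
fits a linear-probability model (OLS on the 0/1 indicator against cohort +
TMB) so the cohort coefficient is a risk difference on the probability
scale; logistic regression is available as an option.

## Problem sizes and numerical conventions

Recovery suites run at the cohort sizes the generator defaults to (n = 700
for calling/clustering, n = 69 × 50 replicates for the risk-score
Kaplan–Meier separation, n = 200 × 50 for forward selection), with the
expression background trimmed to a few hundred null genes where only the
genomic stages are under test. EM uses 10 restarts with a fixed seed;
bisection tolerances are 1e−12; ROC ties break toward the larger
threshold; all boundary comparisons (cross-point, CN threshold, score cut,
TMB-high, signature filter, median splits) follow the conventions stated
above and are recorded in the run manifest.

## Known limitations

* The published cohort's absolute numbers (68/736 HER2+, the 9.954 CN
  threshold, 878 selected genes, the Table-1 hazard ratios, the cluster
  enrichment p values) derive from restricted patient data and are not
  recomputable here; the package validates the *rules and their recovery
  behaviour*, not those constants.
* The screening list is generic over whatever items the encoder produces;
  the original 95-item list is not reconstructable in full.
* The ROC optimality criterion and the ESR1 low/high rule are documented
  assumptions (Youden; mixture cross-point) where the upstream description
  names none.
* No support for competing risks, time-dependent covariates, or
  IHC/FISH-based HER2 assignment.
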