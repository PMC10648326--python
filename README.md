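# her2mbc

Analysis pipeline for HER2-amplified metastatic breast cancer (MBC) cohorts
profiled by whole-genome and RNA sequencing. It packages, as tested and
reusable code, three bespoke procedures such studies need downstream of the
standard variant-calling and normalisation pipelines:

1. **HER2 status calling** from ERBB2 expression and copy number. Log2
   ERBB2 expression of the RNA-seq samples is fit with a two-component
   Gaussian mixture; the cross-point of the weighted component densities
   (where `w₁·N(x; μ₁, σ₁) = w₂·N(x; μ₂, σ₂)` between the means) gives an
   intermediate high/low call. That call is then transferred to an absolute
   copy-number threshold by ROC analysis (Youden's J = sensitivity +
   specificity − 1), so that every sample — including those without RNA —
   is called HER2+ iff CN strictly exceeds the threshold.
2. **A composite genomic risk score** for progression-free survival (PFS)
   on anti-HER2 therapy. Candidate items are encoded categorically,
   screened by univariate Cox proportional-hazards regression, and combined
   by strict forward selection. The five-feature score sums PIK3CA
   mutation, CDK12 mutation, Amp-peak-6 gain (chr8p11.23), above-median
   DBS3 signature contribution (1 point each) and prior therapy lines
   (0.25/0.5/0.75/1 for 0/1/2–3/≥4 lines); a patient is high risk when the
   total is ≥ 2.25. A three-feature validation mode for targeted-panel data
   labels a sample high risk when any of PIK3CA/CDK12/Amp-peak-6 is
   present, with Amp-peak-6 read from SEG segments overlapping
   chr8:32280146–47560553 at CN > 1.5.
3. **A HER2-driven expression profile.** Samples are split into four groups
   (HER2± × prior anti-HER2 therapy); genes with Kruskal–Wallis p < 0.001
   across the groups — excluding chromosome 17, which may be co-amplified
   passenger signal — are median centred, samples are Pearson-correlated and
   hierarchically clustered (1 − r, average linkage, k = 4), with
   Fisher/chi-square cluster enrichment. ESR1 low/high, meta-ER status
   (e.g. primary-ER+ with low metastatic ESR1 = "pos-to-low") and gene-set
   signature scores (MAPK, ESR1 module; high = strictly above the cohort
   median) classify the clusters biologically.

Because real cohorts of this kind are access-restricted, the package ships
a first-class synthetic-cohort generator (`her2mbc.synthetic`) that
emulates the statistical structure the analyses assume — bimodal ERBB2
expression conditional on a copy-number mixture, Dirichlet signature
contributions, Bernoulli mutation flags at published prevalences,
exponential PFS under the published hazard ratios — with a complete
ground-truth table, so every stage can be validated end to end.

## Worked example

Simulate a default cohort (n = 700, 10% ERBB2-amplified) and run the
calling, scoring and survival stages:

```
$ her2mbc simulate --out demo --seed 17
wrote 10 files under demo

$ cd demo/inputs
$ her2mbc her2-call --expr expression.tsv --annot gene_annotation.tsv \
      --features-dir . --out ../calls.tsv
CN threshold 6.6424 (sens 1.000, spec 0.995); grid in ../calls.roc.tsv

$ her2mbc risk-score --clinical clinical.tsv --features-dir . --out ../scores.tsv
$ head -4 ../scores.tsv
sample_id  pik3ca  cdk12  amp_peak6  dbs3  prior_lines  total  label  mode
S0001      1.0     0.0    0.0        0.0   0.25         1.25   low    full_5feature
S0002      0.0     1.0    0.0        0.0   0.25         1.25   low    full_5feature
S0003      1.0     0.0    0.0        0.0   0.5          1.5    low    full_5feature

$ her2mbc survival --scores ../scores.tsv --clinical clinical.tsv --out ../km.tsv
log-rank p = 2.171e-45; curves in ../km.tsv
```

The derived CN threshold (6.64 here) lands in the gap between the
generator's non-amplified and amplified copy-number components, and the
intermediate expression call transfers to it with sensitivity 1.00 /
specificity 0.995 against the mixture labels. Each patient's row shows the
five component scores and their sum; S0001 carries only a PIK3CA mutation
and no prior lines (1 + 0.25 = 1.25 < 2.25, low risk). At n = 700 the
high/low risk groups separate extremely sharply (log-rank p ≈ 2e−45); at a
clinically realistic n = 69 the median separation is still p ≤ 0.001 (see
below). `her2mbc profile` adds gene selection, clustering, enrichment and
the ESR1/MAPK classifiers; `her2mbc run --config run.yaml --out DIR` runs
all stages and writes a manifest of every threshold actually applied.

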