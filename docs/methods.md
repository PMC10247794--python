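# Methods

## The problem

Hepatocellular carcinoma (HCC) sheds DNA into plasma, where it is diluted
by cell-free DNA from blood and other tissues in an unknown, sample-specific
ratio. A quantitative methylation difference between tumor and normal tissue
is therefore unreliable in plasma; a *categorical* difference — CpG sites
that are essentially unmethylated in every normal tissue and blood sample
but substantially methylated in tumors — survives dilution, because any
methylated molecule at such a site is evidence of tumor DNA. epiLiver
implements marker discovery under this categorical criterion, the published
weighted scores built on the discovered markers, and the plasma classifier
that combines them, together with a synthetic-cohort generator that makes
every stage testable without controlled-access clinical data.

## Marker discovery (array betas)

Discovery operates on probe x sample matrices of beta values (fraction
methylated, in [0, 1]).

1. **Methylation-resistant sites.** A probe is resistant in a panel when
   every beta is strictly below `max_beta = 0.1` and the across-sample
   median is strictly below `max_median = 0.02` (even-length medians are
   the mean of the central pair). Resistant lists from independent panels
   (somatic tissues, blood) are intersected exactly. Note the resistant
   set is not formally antitone in the sample dimension: adding samples
   always weakly lowers the max criterion's pass set, but can move a
   probe's *median* below 0.02 and re-admit it. Appending samples at or
   above each probe's running maximum can only shrink the set, and that is
   the property the test suite asserts.
2. **Categorical filter.** Among resistant candidates, keep probes
   methylated above 0.2 in at least 50% of HCC samples while *no* control
   sample exceeds 0.2.
3. **Differential shortlist.** Welch's two-sample t-test per candidate,
   Bonferroni-adjusted with a fixed factor of 450,000 (the array's test
   count, deliberately conservative and independent of how many candidates
   survive earlier filters; overridable). Survivors need
   `p * 450000 < 0.05` and `|delta| > 0.2`; the top 20 by |delta| (ties by
   adjusted p, then probe ID) are kept. Zero-variance probes get p = 0
   when the group means differ and p = 1 otherwise.
4. **Panel reduction.** An L1-penalized logistic path (liblinear, penalty
   grid C in logspace(-2, 3, 40) from strong to weak) selects the support
   at the strongest penalty whose support size is at most `target_size = 4`
   with training AUC >= 0.99; if no path point qualifies, the
   `target_size` largest-|coefficient| probes at the weakest penalty are
   returned. Identical columns are collapsed to the lexicographically
   smallest probe ID before fitting, making selection deterministic.
5. **Tissue-of-origin site.** Against a mixture of other cancers and
   blood (no non-malignant liver, which shares the liver-lineage signal),
   probes with `delta > 0.5` and Bonferroni Q < 1e-20 are shortlisted
   (at most 7); a multivariable OLS of the label on the shortlisted betas
   picks the probe with the largest |coefficient|.
6. **Score weights.** OLS of the 0/1 label on panel betas; a collinear
   design raises an error naming the dependent probes.
7. **Enrichment.** Hypergeometric upper/lower tail per annotation feature
   with fold = (k/n)/(K/N); both tails include the observed point mass, so
   `p_enrich + p_deplete >= 1`.

## Published scores

    HCC-detect = 0.75*b(VASH2) + 0.43*b(GRID2IP) + 0.64*b(CHFR) + 0.8*b(CCNJ) + 0.064
    HCC-spec   = 1.35*b(F12) + 0.18

The combined (sum) score calls a tissue sample HCC when it strictly
exceeds the threshold (0.87 against all tissues; 1.1 against other liver
disease; boundary values are negative calls, a convention the source
equations leave open). An equal-weight detect variant (mean of the four
betas) is provided. The ROC AUC is the Mann-Whitney statistic (ties worth
1/2), which equals the trapezoidal area under the full curve;
sensitivity-at-specificity s is the largest sensitivity over thresholds
with specificity >= s.

## Plasma M scores

Per CpG, methylation% = 100 * n_meth / (n_meth + n_unmeth), recomputed
from counts (the coverage file's percent column is validated to 0.1 but
never used). Each amplicon is summarized by the *median* over its CpGs,
robust to one spuriously methylated site. QC uses the minimum per-CpG
depth within an amplicon — the most conservative reading of a per-gene
read floor — with `min_reads = 100`; a mean-depth rule is available via
`depth_rule="mean"`. Failing samples carry missing scores and never enter
classifier fits.

The log2 normalization is `log2(median% + pseudocount)` with pseudocount
1, so a fully unmethylated region contributes 0; a pseudocount of 0.001
(the zero-replacement used for log-scale plotting in the source data) is
exposed via configuration, since the exact zero-handling of the published
transform is not documented. `m_detect` is the sum over CHFR, VASH2, CCNJ
and GRID2IP; `m_spec` is the F12 term alone.

## Classification

Each M score feeds a univariable logistic regression fit by maximum
likelihood with a ridge stabilizer of 1e-6 on both parameters (gradient
tolerance 1e-8). The ridge keeps estimates finite under perfect
separation, which categorical markers produce routinely; it is recorded in
the model metadata. The epiLiver statistic is `p_detect + p_spec` in
[0, 2], called HCC when strictly above 1.62 (a fixed operating constant;
a Youden-style chooser is provided separately for re-deriving thresholds).
AFP is positive when strictly above 400 ng/mL; the combined rule is an OR
(missing AFP defers to epiLiver). Consequences of the OR rule — combined
sensitivity >= either component, specificity <= either — are asserted as
properties.

Bootstrap group differences resample each group with replacement B = 1000
times; the CI is the 2.5/97.5 percentile of the mean differences and the
two-sided p is `2 * min(P(diff<=0), P(diff>=0))`, floored at 1/B.
Cross-validation uses the validation-set approach: three random 50%
train/test splits (resplit up to 100 times until both classes appear on
both sides), refitting both logistic models per split.

## Power

Power of the two-sided two-sample t-test from the noncentral-t
distribution (df = 2n-2, noncentrality delta/(sd*sqrt(2/n))); the minimal
n is found by doubling + bisection, valid because power is increasing in
n. The normal-approximation closed form is exposed for cross-checking and
undershoots the exact solver by up to ~3 subjects at moderate n. For the
headline designs the solver gives 39 per group (sd 0.31, delta 0.2) and
23 (sd 7.96, delta 6.77). The source study's remaining per-gene plasma
sizes (F12 8, VASH2 17, CHFR < 10, GRID2IP 142) do not match any
noncentral-t or normal-approximation computation we could reproduce
(10, 18, 27, 133 here); its calculator is unknown, so those figures are
not used as checks.

## Synthetic cohorts

The generators define the study conditions; all randomness flows from an
explicit integer seed through `numpy.random.default_rng`.

**Tissue cohort** (default 2000 probes; 50 each of HCC, non-HCC liver
disease, blood, other somatic tissue, non-HCC cancer). Background probes
draw Beta(mean 0.01, concentration 50) *truncated below 0.1*, so
methylation-resistant sites are resistant by construction — this is what
licenses the exact-recovery tests; real arrays have heavy-tailed outliers
that this deliberately removes. 30% of probes are variably methylated
everywhere (Beta mean 0.4, conc 4) and fall out of the resistant filter.
Four planted detect markers are methylated — Beta(mean 0.5, conc 20)
truncated below 0.25 — in an *exact* round(f * n_HCC) of HCC samples, with
per-marker fractions (0.59, 0.57, 0.52, 0.50) spanning the observed
per-gene positivity range; one planted spec marker (Beta mean 0.7) is
methylated in all HCC and liver-disease samples, plus three liver-lineage
decoys at sub-threshold effect size (mean 0.3). Truncation and exact
counts make the planted categorical separation deterministic rather than
merely probable.

**Plasma cohort** (default 50 healthy, 50 CHB, 100 HCC). Stage mix
A/B/C/D = 0.113/0.285/0.351/0.251 (the clinical cohort's proportions, with
the rare stage-0 cases folded into A). Tumor fraction per HCC sample is
Beta(2, 2) scaled by stage multipliers 0.3/0.5/0.7/0.8 — the study
reports no tumor fractions, so these are chosen once to exercise
stage-stratified sensitivity and give a cohort-mean tf near 0.3. Region
depth is negative binomial (mean 4000, dispersion 5), shared by all CpGs
of an amplicon (5-15 CpGs each, fixed per region); per-CpG methylated
reads are Binomial(depth, tf*m_tumor + (1-tf)*eps) with per-amplicon
tumor methylation 0.6-0.9 and flat error eps = 0.005. A 1.25% fraction of
samples is planted with one region below 100 reads to exercise QC.

**AFP.** Log-normal per group: healthy median 4 (sigma 1.0), CHB 12,
non-HCC cancer 8 (sigma 1.2); HCC stage medians 150/600/1500/4000 (sigma
1.5), rising with stage as in the clinical demographics. Missingness
defaults: 60%/55%/50% in the non-HCC groups, 7% in HCC.

What the simulators do *not* emulate: probe-level annotation structure,
age/sex effects, batch effects, bisulfite-conversion bias beyond a flat
error rate, fragment-level features, and the heavy-tailed outliers of
real arrays. Passing the recovery and end-to-end tests therefore shows
the algorithms are correct under the stated generative model, not that
the markers would be rediscovered from real public data.

## Problem sizes and determinism

Default test and pipeline sizes (2000 x 250 tissue matrix, 200-sample
plasma cohort, B = 1000 bootstrap, five recovery seeds) were chosen so the
full suite exercises every chain end to end in well under a minute while
leaving the planted signals at realistic strength. Every stochastic
operation takes an explicit seed; pipeline runs emit a manifest (seed,
config hash, package version) sufficient to reproduce their artifacts
byte for byte.

## Known limitations

- The 1.62, 0.87 and 1.1 thresholds are treated as given constants; the
  criterion used to derive them from ROC curves is not documented in the
  source, so re-derivation on new data should use `youden_threshold` or an
  application-specific operating point.
- The L1 path selection rule (support <= target with AUC >= 0.99) is this
  package's choice; only the use of penalized regression itself is
  documented upstream. The rule is recorded in panel output metadata.
- The Bonferroni factor is literally 450,000, not the exact probe count.
- `fit_logistic` is univariable by design (one M score at a time),
  matching how the probability models are combined; it is not a general
  logistic regression.
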