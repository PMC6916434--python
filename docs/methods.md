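# Methods

`methsig` dissects colon-cancer DNA methylation into two CpG classes with
distinct dynamics: **CC-neutral CpGs (CCN-CpGs)**, hypermethylated in all
colon cancers and drifting with age in healthy mucosa under lifestyle
modulation, and **CIMP-CpGs**, hypermethylated specifically in serrated-
pathway samples (SSA/P precursors and CIMP cancers). This note documents
the models, parameter choices, and the limits of what the synthetic
validation shows.

## Differential methylation

Statistics are computed on M-values, `M = log2(beta / (1 - beta))` with
beta clamped to `[eps, 1 - eps]` (default `eps = 1e-6`); the clamp keeps
the transform finite at boundary values and is a purely numerical
convention. Per probe, an ordinary-least-squares model with fixed-effect
indicator columns for sample group, colon location, and batch is fitted on
the probe's non-missing samples (no interaction terms). Probes with fewer
than `rank + 1` usable samples are flagged and excluded downstream.

Residual variances are moderated with the classical empirical-Bayes
scaled-F prior: the hyperparameters `(d0, s0^2)` are estimated by method
of moments on log variances — matching the sample mean and variance of
`log s_g^2` to the digamma/trigamma moments of the prior, with the
trigamma inverse solved by Newton iteration — and each probe's variance is
squeezed to `s~^2 = (d0 s0^2 + d_g s_g^2) / (d0 + d_g)`. The moderated t
uses `d0 + d_g` degrees of freedom. When the between-probe spread of log
variances does not exceed the chi-square sampling term, `d0 = +inf` (point
-mass prior). The implementation is cross-checked against the reference R
implementation (limma `lmFit`/`eBayes`) in the test suite and agrees to
six significant digits on the moderated t, p, and hyperparameters.

`logFC` is the raw difference of group-average M-values and `delta_beta`
the difference of group-average beta values, both on probe-wise complete
cases; the t/p come from the covariate-adjusted model contrast. Because
the mean of a logit is not the logit of a mean, the signs of `logFC` and
`delta_beta` can disagree for probes with near-zero differences (Jensen
gap); they agree for any materially differential probe, and the DMC rule
requires both to clear thresholds in the same direction anyway.

DMC thresholds (strict inequalities): BH-adjusted p < 1e-4, |logFC| > 2,
|delta_beta| > 0.10, applied per direction. A replicate-consistent variant
(delta-beta beyond +/-5% in every replicate) is provided for noisy paired
cell-line designs where the moderated test is underpowered.

## Signature assembly

The hypermethylated sets of the two cancer-vs-healthy-mucosa contrasts are
partitioned into nonCIMP-specific / CIMP-specific / common. Common CpGs
significantly more methylated in CIMP than nonCIMP cancers (unadjusted
p < 0.01 from the CIMP-vs-nonCIMP contrast of the *same* fitted
three-group model, and delta-beta > 0.10) are reallocated to the CIMP
class. CIMP-CpG = CIMP-specific plus reallocated; CCN-CpG = everything
else. Every hypermethylated CpG is classified exactly once, which the
pipeline asserts.

Set enrichment uses Fisher's exact test computed by exact integer
hypergeometric summation (two-sided: all margin-fixed tables no more
probable than the observed one). The odds ratio is the sample
cross-product ratio, with Haldane–Anscombe +0.5 on all cells when any
cell is zero. The enrichment universe defaults to all probes surviving
filtering.

## Age drift and MRR

Per-CpG drift rates are OLS slopes of beta on age/10 (beta change per
decade) across healthy-mucosa samples, complete cases, minimum three
samples. Rates are fitted on the beta scale, not M, because the
methylation-rate-ratio (MRR) is interpreted as a ratio of proportion-scale
slopes. MRR = median rate of one probe set (or exposure stratum) over
another, with a two-sided Wilcoxon rank-sum p comparing the rate
distributions (exact when the smaller side has <= 8 untied observations,
otherwise normal approximation with tie and continuity corrections).
Samples with unknown exposure status are excluded, never imputed. MRRs
with negative or zero denominator medians are flagged rather than
silently reported.

The "age-hypermethylated" CpG set for enrichment comparisons is defined
operationally as probes with a significant positive age slope in healthy
mucosa (slope t-test, p < 0.01); any externally supplied probe set can be
substituted.

## Clustering

Samples are clustered on probes with across-sample SD > 0.16 (strict,
ddof = 1). The node model is a beta mixture in mean/precision form
`Beta(mu*phi, (1-mu)*phi)`: probes are independent within a component,
with per-component per-probe means and a per-component precision pooled
across probes — pooling keeps the parameter count linear in probes and the
fits stable at small leaves. Values are clamped to `(1e-3, 1 - 1e-3)`
before likelihoods. EM uses a safeguarded generalized M-step (weighted
moment update refined by Newton steps, accepted through a line search), so
the log-likelihood is provably nondecreasing and asserted each iteration;
`k = 2` fits use a k-means initialization plus four random restarts, best
likelihood wins, all deterministic given the seed.

Recursive partitioning splits a node when `BIC(k=2) < BIC(k=1)` with
`k (J + 1) + (k - 1)` free parameters, both children have at least
`min_leaf = 5` samples, and depth <= 4. Sample order never affects the
partition (profiles are processed in sorted-id order; node seeds derive
from the node path). Note that on data with uncorrected batch effects the
tree may legitimately sub-split a biological cluster along batch — on the
default synthetic cohort the top split separates the planted cancer
subtypes exactly and one subtype leaf subdivides by batch. A Ward-linkage
hierarchical alternative on Euclidean beta distance is provided.

The BIC split rule is a declared substitute for the original recursively
partitioned mixture model's level-weighted split criterion, whose exact
settings are not reproducible here; it is validated by recovery properties
(adjusted Rand index against planted partitions), not by matching any
particular package's output.

## Precursor analysis

Lesion-vs-normal change is the signed within-pair beta difference averaged
over complete pairs, summarized by its median over a signature. Groups
without matched normals (the cancer groups in the default synthetic
cohort) use the group-mean minus healthy-mean difference instead. Median
shifts are tested by rank-sum against a comparison vector or a zero
reference. Methylation–expression coupling is Pearson correlation between
per-gene expression and gene-level methylation (unweighted mean over the
gene's signature probes).

Cross-platform inputs (arrays vs bisulfite sequencing) are assumed to be
reduced to beta-scale matrices upstream; converting read counts to
proportions is an input convention, not an implemented parser.

## Synthetic cohort

The generator plants the structure the pipeline is meant to find. Default
study conditions (recorded in `fixtures/default_config.yaml`): 2,000
probes — 300 CCN (baseline 0.08), 300 CIMP (baseline 0.10), 100 hypo
(baseline 0.90), 1,300 background (0.10 / 0.85); 100 healthy-mucosa
samples with ages uniform on 40–80 years, 20 cancers per subtype, 12 TA
and 12 SSA/P each with a matched normal. Effects: +0.30 beta at CCN probes
in all cancers, +0.17 at CIMP probes in SSA/P and +0.28 in CIMP cancers
(the observed median precursor-to-cancer progression), −0.30 at hypo
probes in cancers. CCN drift rates are N(0.03, 0.01^2) beta/decade
(truncated positive); CIMP probes drift five-fold slower, so the planted
CCN:CIMP rate ratio is 5. Lifestyle exposure (aspirin, HRT; prevalence
0.3, 5% unknown) halves the drift rate at every drifting CpG,
multiplicatively across exposures. Drift is anchored at the cohort entry
age (baseline = expected methylation at age 40).

Beta noise uses concentration phi = 50, giving per-probe SDs of ~0.05–0.07
at mid-range means, comparable to array replicate scatter. Batch
(SD 0.2) and proximal-location (SD 0.1) shifts are applied additively on
the M scale and back-transformed, so the covariate-adjusted linear model
is exactly well specified — failures of adjustment indicate bugs, not
model mismatch. Missingness (2%) is completely at random and stands in
for detection-p filtering. One seed drives deterministic sub-streams for
probes, samples, covariates, noise, and missingness; identical configs
give bit-identical cohorts.

What the synthetic validation does **not** show: real beta values are
bimodal with probe-type chemistry biases; real batch effects are not
mean-zero Gaussian on M; real age drift is nonlinear at the extremes;
missingness correlates with signal intensity; and group labels in real
cohorts are themselves imperfect. Passing recovery tests demonstrates the
algorithms are implemented correctly under their stated assumptions, not
that the thresholds are optimal for any particular real data set.

## Problem sizes and determinism

Test and acceptance runs use the desk-scale defaults above (2,000 probes,
~190 samples); moderation hyperparameter recovery uses 50,000 simulated
variances; the Fisher implementation is checked by exhaustive enumeration
over all 2x2 tables with total <= 40. All stochastic steps take explicit
seeds; the pipeline report is byte-identical across reruns of the same
config and seed.
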