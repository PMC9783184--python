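# Methods

This note documents the models and procedures implemented in
`adipostage`, the assumptions behind them, the defaults and why they were
chosen, and what the synthetic-data experiments do and do not demonstrate.

## Lipid shorthand nomenclature

Species names follow the compact convention used by untargeted lipidomics
software: a class token (`TG`, `DG`, `PC`, `PE`, `LPC`, `LPE`, `SM`,
`ChE`, `Cer`, `Hex1Cer`; the registry is a plain editable mapping) followed
by a parenthesized body of slash-separated chains `C:D`, each optionally
carrying an ether suffix `e` and the first optionally a sphingoid
long-chain-base prefix `d` (di-hydroxy) or `t` (tri-hydroxy).  A body with
a single token is always read as a *summed composition* (total carbons :
total double bonds) with no resolved chains — `PC(34:2e)` and `LPE(18:1e)`
both parse this way.  Parsing is case-sensitive; serialization is the
exact inverse, and the parser proves the invariant that resolved chains
sum to the stated totals.

Choices worth noting:

- The `e` suffix is recorded as a single ether-linkage boolean wherever it
  appears; O-alkyl vs O-alkenyl (plasmalogen) subtypes are not
  distinguished because shorthand names do not encode them.
- `ChE` is ambiguous in the wild (cholesterol vs cholesteryl ester); the
  registry carries both readings in the display name and treats it as one
  class.
- Unparseable rows in a species table are dropped with a warning by
  default so one vendor artifact does not kill a run; `strict=True`
  upgrades this to an error.

## Differential feature analysis

Effect size is the log2 ratio of group means of raw abundances, with a
pseudocount (default: half the smallest nonzero value in the table)
guarding zeros.  For matrices already on the log2 scale (expression data
throughout this pipeline), `log_scale=True` switches the effect to the
plain group-mean difference, which is the correct log-fold-change there.

The default test is the two-tailed Student's t with pooled variance on
log2 values, which is the named test of the study design and is exactly
calibrated under the generator's log-normal model; Welch's t, the
Wilcoxon rank-sum and the two-sample Kolmogorov–Smirnov tests are
available as configuration.  No multiple-testing correction is applied by
default: the gates reproduced here are raw p-value gates
(|log2FC| > 1 and p < 0.05 for both lipids and genes — the printed linear
thresholds "fold change > 1 / < −1" can only be meant on the log2 scale,
since a signed linear threshold of ±1 is vacuous, and the gene gate
"> 2 / < −2" is the same 2-fold rule).  Zero-variance features under the
t-family tests report p = 1 with a warning rather than failing.

Top-K heatmap selection orders significant features by p-value, breaking
ties by larger |log2FC| then lexical id, so selection is deterministic.
PCA centers features without unit-variance scaling by default (abundance
data live on comparable scales after logging; autoscaling is a flag).

## Batch correction

The parametric empirical-Bayes location-scale model is implemented in
full: per-gene standardization by the batch-size-weighted grand mean and
the pooled residual variance about batch means, per-batch additive
(gamma) and multiplicative (delta²) effects with normal and inverse-gamma
priors whose hyperparameters come from method-of-moments fits across
genes, and conditional posterior means iterated to a relative tolerance
of 1e-4 (max 100 iterations).  Corrected data are the back-transformed
standardized residuals with the shrunken effects removed.

Two deliberate conventions:

- The pooled variance is the *unbiased* residual variance (denominator
  N − #batches).  The EB machinery is exactly equivariant to this choice;
  it makes delta estimates exactly 1 for effect-free equal-size batches,
  so applying a no-effect model is the identity and re-correcting
  corrected data is a no-op in that regime.  A cross-check test shows the
  corrected output agrees with `sva::ComBat` to 1e-8 after the one
  documented rescale sqrt((N−k)/N) on deviations from the grand mean
  (the reference uses the biased pooled variance).
- When the across-gene spread of a moment estimate is exactly zero the
  prior degenerates to a point mass at the common value — the continuous
  limit of the moment equations — instead of emitting infinities.

Shrinkage means correction is not literally idempotent on noisy data: a
second pass moves values by a few percent of the first pass (true of the
reference implementation as well); exact idempotence holds in the
degenerate point-mass-prior limit and is tested there.

Expression inputs are assumed log2-transformed (log2(x+1) for
count-derived matrices) before correction.  Cross-species merging of
human tumor and mouse culture matrices intersects gene symbols
case-insensitively; symbol collisions resolve to the higher-mean row, and
unmatched genes are dropped with a count.  No biological covariates are
protected by default — with tumors and cultures in disjoint batches the
design is confounded by construction, and the model warns accordingly;
the staging score is robust to this because it contrasts within-batch
quantities (see below).  For designs where groups span batches,
``covariate_cols`` (CLI ``--protect-col``) adds dummy-coded covariates to
the standardization design so their effects survive correction; a
covariate nested within one batch makes that design singular and is
rejected.

## Staging against the SVF time course

The stromal vascular fraction differentiates into mature adipocytes over
roughly ten days in culture, so its per-day expression profiles form a
staged reference.  For each sampled day d, replicates are averaged into
x_d and compared to the tumor-group mean T̄ and the pooled normal-tissue
mean N̄ on the corrected log2 matrix over the shared gene set:

    relative_distance(d) = ‖x_d − T̄‖₂ − ‖x_d − N̄‖₂
    similarity(d)        = 1 / relative_distance(d)

The stage call is argmin_d relative_distance.  The literal reciprocal is
reported per day, but note its shape: when the SVF profile is closer to
the tumor than to normal tissue the reciprocal is *negative*, approaching
zero from below as the match improves, so "taller bar = closer stage"
only holds after taking magnitudes.  Both the literal value and a
display-mode 1/|d_T − d_N| (flagged non-literal) are exported; the stage
call itself uses the relative distance, which is monotone-consistent with
either reading.  Days with |d_T − d_N| below 1e-9 are flagged undefined
rather than reported as huge reciprocals; exact ties between days go to
the earlier day with a tie flag.  A gene-subsampling diagnostic
(`best_day_stability`) reports how often an 80% subsample reproduces the
full-set call.

Because every distance is between profiles measured in the *same* batch
layout, an additive batch offset common to all SVF samples cancels in the
comparison across days, which is why staging survives the confounded
tissue/culture correction.

## Preranked enrichment

Genes are ranked by signed log2 fold change (or signed −log10 p), ties
broken lexically.  For a gene set with hits at ranked positions, the
running sum at position i is the accumulated hit mass (weights |s|^p,
p = 1 by default, normalized to unit total) minus the uniform baseline
i/N; the enrichment score is the signed maximum deviation.  At p = 0 this
is exactly the one-sample Kolmogorov–Smirnov statistic of hit positions
against uniform, giving the closed form ES = 1 − 1/N for a single
top-ranked hit.  This baseline convention was chosen over the
misses-only-ECDF variant because it has that clean analytic limit; for
set sizes well below N the two are numerically close.  Sets that miss the
ranked list entirely, or span it entirely, are flagged not-computable.

Significance comes from size-matched gene-label permutations (the
preranked interface has no per-sample phenotypes to permute): NES is ES
divided by the mean of same-signed null scores, and the permutation p
counts same-signed null scores at least as extreme, with the +1
correction so p ≥ 1/(n+1).  The selection gate is (NES > 1 or NES < −1)
and p < alpha.  Gene-label permutation ignores inter-gene correlation, so
on strongly structured rankings the gate can run mildly anti-conservative
— the null simulations in the acceptance suite measure its false-selection
rate on exchangeable rankings.

## Synthetic cohorts

`simulate_expression` builds, on the log2 scale directly (Gaussian noise;
a Poisson-lognormal count mode exists for realism checks):

- 2,000 genes with baselines ~N(7, 1.5²); 400 differentiation-program
  genes whose day trajectories are monotone sigmoids with per-gene
  midpoints U(0.5, 9.5) and switch widths U(0.3, 0.8), half replaced by
  transient Gaussian pulses (width U(0.8, 2.0)) emulating early waves such
  as mitotic clonal expansion.  Staggered switch times and transient
  waves are what give the trajectory genuine curvature in expression
  space; a single shared time shape would make consecutive day profiles
  colinear and staging degenerate.
- SVF samples at days 0–10 (3 replicates/day), two tumor groups generated
  from the day-4 and day-0 profiles plus a shared 100-gene malignancy
  signature (|log2| 0.5–1), and 13 normals at the mature end of the
  trajectory (day 14 on the sigmoid clock) — mirroring the 6 + 7 + 13
  cohort shape of the study design.
- Per-sample noise sd 0.5 log2 units; the culture batch carries a
  per-gene additive shift ~N(2.0, 0.2²) and noise scale ×1.5.

`simulate_lipidomics` draws species log2 abundances around class means
(noise sd 0.4) with class-level group effects — defaults +2 for TG/DG,
−2 for PC/PE/SM, −1 for ChE (log2, WDLPS-like over DDLPS-like) — and
emits grammar-valid names covering multi-chain, summed-composition, ether
and sphingoid forms.  `simulate_batch_study` provides a two-batch,
one-condition design (batch orthogonal to biology) for batch-recovery
benchmarking.  Every planted perturbation, and nothing else, is recorded
in the `GroundTruth` sidecar; identical seed and config give bit-identical
output.

What passing on this generator shows — and does not.  It shows the
pipeline's estimators are correct and calibrated under a log-normal,
gene-independent noise model with an idealized differentiation geometry.
Real data add inter-gene correlation (which the enrichment null ignores),
heavier-tailed noise, library-size and composition artifacts, imperfect
orthology between mouse SVF and human tumors, and tumor purity effects;
none of these are emulated, so recovery rates here are upper bounds on
real-data behavior.

## Problem sizes and numerical choices

Default experiment sizes are desk-scale by design: 2,000 genes / 300
species cohorts, 100-seed stage-recovery runs, 50 × 2,000 null tables for
test calibration, and 200-permutation nulls per gene set (1,000 where
power is measured).  Convergence tolerance for the EB iterations is 1e-4;
staging tie/undefined tolerance 1e-9; fraction-mode compositions are
validated to sum to 1 within 1e-9.  All randomness flows through
`numpy.random.default_rng` seeds carried in configs or CLI flags; the CLI
writes floats with a fixed `%.10g` format so outputs are byte-stable.

## Known limitations

- The staging score compares group means only; no per-sample staging or
  uncertainty on the best-day call beyond the subsampling diagnostic.
- The enrichment module deliberately omits FDR q-values and leading-edge
  reporting; the selection gate reproduced here is a raw-p gate.
- The parser targets shorthand names as printed by common pipelines; full
  structural nomenclature (sn-positions, stereochemistry, oxidized
  lipids) is out of scope.
- Covariate protection in the batch model handles categorical covariates
  only, and cannot help the fully confounded tissue/culture design, where
  it is mathematically unidentifiable.
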