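# Methods

This note documents the models, conventions and design choices behind
`emtsig`, in the spirit of a statistical methods appendix. It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Differential screen

Per gene, tumor vs normal samples are compared by Welch's
unequal-variance t-test applied to log2(TPM + 1). The log transform
stabilizes variance and matches the box-plot conventions of bulk
expression portals, which do not publish their test scale; the +1 offset
keeps zeros finite. The test is two-sided (both up- and down-regulation
are of interest) and the primary call threshold is the nominal p ≤ 0.05
with no multiplicity correction — the criterion the screen is designed
to mirror. A Benjamini–Hochberg option (`bh_correct=True`) is available
and can only shrink the call set. Degenerate genes (zero variance in
both groups with equal means) return p = 1 with a flag; genes with fewer
than two observations in a group are reported untestable rather than
silently dropped.

## Survival screen

**Estimators.** Kaplan–Meier is the standard product-limit estimator;
censored observations leave the risk set without a step. The two-group
log-rank test accumulates, at each distinct event time, observed minus
hypergeometric-expected events in one group with the matching variance;
the statistic is χ² with 1 df. Hazard ratios use the Pike one-step O/E
estimator HR = (O_A/E_A)/(O_B/E_B) with log-scale 95% CI
exp(±1.96·√(1/E_A + 1/E_B)); it is built from the same tables as the
log-rank test and keeps the module free of model fitting. Note that the
O/E estimator is mildly attenuated toward 1 for strong effects, and that
dichotomizing a continuous per-SD effect yields a between-group HR larger
than exp(β) (the group means sit roughly ±0.8 SD apart); parameter-
recovery tests therefore use a binary-expression recipe whose true group
HR is exact.

**Cutpoint scan.** Candidates are the distinct observed expression
values within [Q1, Q3], quartiles by linear interpolation
(`numpy.quantile` default) — any fixed convention works but must be
pinned for reproducibility. Splits are low ≤ c < high; only distinct
observed values produce distinct splits, so nothing else is scanned.
"Best" is the smallest log-rank p, ties broken toward the smaller
cutoff. Candidates leaving an arm below `min_group_size` (default 5)
are skipped; a scan with no admissible candidate (e.g. constant
expression) raises `ScanEmptyError` rather than returning a vacuous
result.

**Minimum-p adjustment.** The minimum p over tens to hundreds of
correlated candidate splits is strongly anti-conservative (the
acceptance suite measures a null rejection rate of roughly 5–6× the
nominal α at n = 60). The adjustment is a permutation test of the scan
as a whole: expression is permuted against the (time, event) pairs B
times, the full scan is repeated, and
p_adj = (1 + #{b : min-p_b ≤ min-p_obs})/(B + 1). Permutation was chosen
over analytic corrections because it is assumption-free, exact at the
chosen B, and directly testable; B defaults to 1000 (minimum 100), and
the smallest attainable p_adj is 1/(B + 1). Internally the scan is
evaluated in expression-rank space, so each permutation replicate costs
one bincount over (candidate bucket × risk segment) cells plus
cumulative sums on the candidate-by-event-time grid.

**Coherence rule.** A gene is prognostic only when all three endpoints
(DMFS, OS, RFS) are individually significant at `alpha_surv` *and* the
three hazard-ratio directions agree; direction `worse` means high
expression is hazardous. By default the adjusted p is compared against
`alpha_surv` (`use_adjusted_p=True`): the nominal minimum p does not
control its level, and the three-endpoint rule is meant to guard against
chance findings, which an anti-conservative per-endpoint p would
undermine. Setting `use_adjusted_p=False` reproduces a nominal-p
reading.

## Signature derivation

The consensus filter counts, for each gene, the number of distinct
source studies reporting it and retains genes with support ≥
`min_studies` (default 2). The final intersection matches gene symbols
exactly as printed — no synonym or alias resolution — because the
derivation operates on published symbol lists; CKMT1A and CKMT1B are
kept as separate entries even where their statistics coincide. Discordant
overlaps (up & protective, or down & hazardous) are reported with
`concordant = false` rather than discarded: the concordant set is the
signature, but the complement is needed for audit. On the packaged
tables the worse-prognosis panel prints 33 rows while the accompanying
text counts 32 genes (CKMT1A/CKMT1B share identical p-values); the
fixture reproduces the printed table and the discrepancy is surfaced
here, not resolved.

The full pipeline screens only consensus genes, keeps the diagnostic and
prognostic tables independent, and intersects last — the order of the
original derivation.

## Phenotype analysis

Band intensities are normalized per patient by the β-actin channel,
cancelling gel-loading scale (classification is invariant to multiplying
a patient's lane by a constant). ND ("not detected") is missing, not
zero. Ratio conventions are forced by the arithmetic: ND denominator
with positive numerator → +∞ (mesenchymal side), ND numerator with
positive denominator → 0 (epithelial side), both ND → unclassifiable.
Class boundaries on the Vimentin/E-cadherin ratio are <1 epithelial,
[1, 10] hybrid, >10 mesenchymal; the closed middle interval is the only
reading consistent with "<1", "1 to 10" and ">10". Markers resolved as
several bands enter ratios as the summed band intensity (default), with
per-band values retained for isoform-level correlations; the dominant-
band alternative is a caller choice, since published ratios do not state
which was used. Pearson correlations use pairwise-complete observations
and the t-transform p on n − 2 df, reported nominally (an optional BH
step exists).

## Synthetic-data generators

All generators are pure functions of their parameter record including
the seed.

*Expression*: log-normal per group on the log2 scale (default mean 5,
SD 1.5) with per-gene log2 mean shifts in the tumor group. Defaults
n = 200/200 for screening studies.

*Survival*: exponential event times under proportional hazards,
hazard = h₀·exp(Σ β_g z_g) with z the standardized expression — the
simplest law satisfying the proportional-hazards assumption the screen
relies on. Censoring is independent uniform administrative censoring on
[0, max_follow_up] applied to a `censor_rate` fraction of patients
(registry-style follow-up; the realized censored fraction is at most
`censor_rate`). Defaults: n = 500, baseline hazard 0.1/unit time,
censor rate 0.3.

*Densitometry*: each of n = 95 patients draws a latent class from
proportions (0.14, 0.63, 0.23) — the epithelial/hybrid/mesenchymal
composition of the motivating 95-patient panel (13/95, 60/95, 22/95).
Marker log-intensities are normal around class means with residual SD
0.35; the class contrast is carried by VIM (ratio geometric centers
≈ 0.3, 3, 30, one per ratio band) while CDH1 class means are flat, and a
shared per-patient co-abundance factor is added to VIM and CDH1 with its
variance solved so the *marginal* VIM–CDH1 correlation equals
`epithelial_mesenchymal_corr` (default 0.6). This factor cancels exactly
in the VIM/CDH1 ratio, so it reproduces the panel's two qualitative
features simultaneously: a positive epithelial–mesenchymal marker
correlation and a three-decade ratio spread. A per-patient loading
factor multiplies all channels including β-actin (removed by
normalization), and `nd_rate` (default 0.02) of marker entries are
blanked to ND. The ND conventions shift roughly 2% of patients toward
the boundary classes, which the recovery tests absorb.

What the generators do **not** emulate: gene–gene correlation structure,
batch effects, TCGA marginal distributions, competing risks,
non-proportional hazards, isoform-specific band patterns, or
informative censoring. Passing tests therefore demonstrate correctness
and calibration of the *procedures* under their stated assumptions, not
fidelity of any particular published cohort.

## Problem sizes and determinism

Monte-Carlo checks use: 200 random small cohorts for the brute-force
cutpoint oracle, 1000 replicates for log-rank type-I calibration, 200
null datasets (n = 60, B = 199) for the min-p study, 20 seeds for
end-to-end recovery (n = 200/200 expression, n = 500 per survival
endpoint, planted |log2 effect| ≥ 2 and |log-HR| ≥ ln 2), and 20
panels for phenotype recovery — sizes at which the checked bands are
comfortably away from Monte-Carlo noise. B = 199 in the heavy loops
keeps the adjusted-p floor at 0.005, well below the 0.05 threshold being
tested; the package default stays B = 1000. Every stochastic step is
seeded: scans derive per-gene/per-endpoint streams from
`AnalysisConfig.rng_seed` via `SeedSequence`, so reruns are identical.

## Known limitations

- The cutpoint scan reproduces the *procedure* of best-cutoff survival
  portals, not any portal's exact output: probe-set selection, cohort
  composition and the portal's own multiplicity correction are not
  public in reconstructable form. The permutation adjustment is this
  package's documented choice, not a reconstruction.
- Whether published screen p-values are nominal or corrected is not
  stated by the sources the fixtures transcribe; fixtures are taken as
  given.
- The Pike O/E hazard ratio is not a Cox estimate; for strong effects it
  attenuates toward 1.
- Phenotype class counts printed for the motivating panel are generator
  defaults and recovery targets; the underlying per-patient densitometry
  is not in the public text, so they are not recomputable facts.
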