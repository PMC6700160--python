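# Methods

## Model and procedure

### Per-dataset linear models

Each dataset (cell type) is modelled per feature by ordinary least squares:

    y = β₀ + β_RR·1[group=RR] + β_SP·1[group=SP] + β_age·(age − mean age) + β_sex·1[sex=M] + ε

with healthy controls (HC) as the reference level. A single three-group
model is fitted per dataset; the NPC partial statistic is the group-factor
partial F (joint null of β_RR and β_SP, 2 numerator df), and the
per-contrast t statistics — HC-RR: β_RR; RR-SP: β_SP − β_RR, with positive =
upregulated in the later disease stage — come from the same fit. This
mirrors permuting all three labels jointly: one direction-free global
p-value per feature, with the t statistics supplying direction afterwards
(the G1–G5 direction-pattern assignment requires sign agreement between
datasets on both contrasts; any discordance or an exactly-zero t maps to
G5).

Zero-variance covariates (all ages equal, single-sex cohorts) are dropped
with a warning; genuinely collinear designs (e.g. a group perfectly
confounded with sex) raise an error naming the offending columns. Group
indicator columns are only created for groups actually present, so a
two-group dataset yields the classical identity F = t².

Empirical-Bayes variance moderation (scaled-inverse-χ² prior fitted by
method of moments on log s²: d0 from the excess of var(log s²) over
ψ′(df/2), s0² from the mean) is available but **off by default**: the
permutation null makes moderation unnecessary for validity, and an
unmoderated F keeps the observed and permuted statistics exactly
exchangeable. When enabled it is re-estimated inside every permutation. The
moment estimator needs ≥ 50 features and falls back to the identity if its
estimates are non-finite; exactly constant variances pass through unchanged.

### Pairing-constrained permutations

Disease labels are permuted over *distinct individuals*: each permutation is
a plain shuffle of the observed label multiset across individuals, broadcast
to all samples an individual contributes in any dataset. Individuals present
in both datasets therefore carry one label per permutation (preserving the
cross-dataset correlation structure under the null), while dataset-exclusive
individuals participate in the same joint shuffle. Note this makes any two
individuals' labels *exchangeable*, not independent — two draws without
replacement from a finite multiset are weakly negatively dependent, which is
exactly what a label shuffle implies. Covariates stay attached to samples;
only disease labels move (raw-label permutation; Freedman–Lane residual
permutation was considered and left out — with the group effect the only
permuted term and covariates fixed, raw-label permutation matches the
procedure being emulated and is exact under exchangeability).

For small designs the full set of distinct label assignments (the
multinomial coefficient n!/(n_HC! n_RR! n_SP!)) can be enumerated
(`exhaustive=True`, feasible to 10 individuals); otherwise B permutations
are sampled with replacement, with a logged warning if B exceeds the number
of distinct assignments.

### NPC combination

Partial permutation p-values use the pseudocount convention
p = (1 + #{b: F_b ≥ F_obs})/(1 + B), guaranteeing p ∈ (0, 1] and validity.
Each permutation b is itself scored against the full B-column pool
*including itself* (its self-tie supplies the pseudocount), which makes the
observed and permuted partial p-values exchangeable under the null; a
consequence we verify in tests is that with two identical fully-paired
datasets the global p equals the single-dataset partial p exactly.

The combination is Liptak/Stouffer, T = Σ_d w_d Φ⁻¹(1 − p_d), with unit
weights by default (weights are configurable; negative weights rejected).
Before the quantile, p is clipped to ≤ 1 − 1/(2(B+1)) to keep Φ⁻¹ finite.
The global p-value is (1 + #{b: T_b ≥ T_obs})/(1 + B), followed by
Benjamini–Hochberg q-values across features (statsmodels implementation;
an independent double-loop oracle checks it in the tests). Expression and
methylation NPC runs are independent invocations with their own thresholds
(defaults: expression p ≤ 0.001 & FDR ≤ 0.1; methylation p ≤ 0.001 &
FDR ≤ 0.2 — a stricter 10⁻⁴ convention exists for methylation but requires
B ≥ 9999 to be attainable, so the config exposes both and defaults to the
milder one).

### Numerical choices

- **Tie rule.** Permuted statistics within a *relative 1e-6* of the
  reference count as exceedances (conservative). The tolerance matters:
  relabelling symmetries (e.g. swapping two complete group assignments)
  produce permutations whose F is equal in exact arithmetic but differs by
  floating-point round-off — and the fast permutation path (reduced-model
  residualisation, ΔRSS via a 2×2 solve) carries ~1e-9 relative error when
  residuals nearly vanish. 1e-6 absorbs both scatters while remaining far
  below the generic relative gap between genuinely distinct label
  partitions on continuous data.
- **Fast path.** Per dataset the data are residualised on the
  covariate-only design once; for each permutation only the group-dummy
  block changes, so the partial F comes from
  ΔRSS = ‖P_{G̃} y_res‖² with G̃ the residualised dummies — O(features ×
  samples) per permutation instead of a full refit. A permutation that
  empties a group (possible in unpaired designs) is handled by pseudo-inverse.
- **Degenerate statistics.** Numerators below 1e-20 × (coefficient scale)
  are treated as exactly zero (noiseless null fits would otherwise give
  0/0); non-finite observed statistics are flagged and assigned p = 1.
- **Global p lattice.** Global p-values live on the lattice k/(B+1);
  thresholds must be attainable (p ≤ 0.001 needs B ≥ 999; the default is
  B = 1000).

### Cis overlap stage

The strand-aware TSS (+ strand: interval start; − strand: end; unknown:
start with a warning) anchors a strict < 1 Mb window: a probe at exactly
1 Mb is *not* paired. Coordinates are 0-based half-open in memory and
1-based inclusive in written annotation files (noted in their header).
Correlation is Spearman on log2 CPM expression versus beta-value
methylation — being rank-based, the beta/M-value choice is inconsequential —
over the samples of one dataset measured in both modalities (matched by
individual, all disease groups pooled). Two-sided p-values use the
t approximation for n > 10 and the exact permutation distribution over all
n! rank pairings for n ≤ 10 (the identity pairing included, so p > 0).
Pairs with fewer than 5 shared samples are flagged untested rather than
erroring (real cohorts correlate down to n ≈ 15; the guard is for synthetic
edge cases). Per dataset, pairs with |ρ| > 0.5 and p < 0.05 (strict) are
ranked by p; the reported set is the intersection across datasets with both
ranks attached.

### Enrichment stage

Gene sets (GMT) are intersected with the analysis universe and filtered to
effective sizes within [20, 200] (inclusive boundaries: "below 20" and
"above 200" are excluded). Genes are ranked by ascending p-value and each
set is compared to its complement with a one-sided Wilcoxon rank-sum test
(set scores smaller), BH-corrected across sets. This replaces a
two-sample-t-on-fold-change style test with a rank test on the quantity the
procedure actually ranks by — p-values — making the result invariant to any
strictly monotone transform of the scores; the test function is a plug-in
point for alternatives.

## Synthetic data

The generator produces the study structure the analysis assumes, not a
facsimile of any cohort:

- **Design.** Three groups (HC/RR/SP) with configurable sizes; per group,
  round(paired_fraction × n) individuals appear in both datasets, the rest
  are dealt randomly but evenly to one dataset. Defaults (12/12/10
  individuals, 70% paired, 60% female, ages HC 27–62 / RR 26–46 / SP 35–63)
  follow the scale of a typical MS T-cell cohort.
- **Expression.** Negative-binomial counts from a log-linear model: baseline
  log2 CPM ~ N(5, 1.5²); group shifts (default log2 effect 1.0, signs
  random per contrast) on a configurable number of DE features, shared
  across datasets with probability `shared_fraction`; age (N(0, 0.005²)
  per year) and sex (N(0, 0.1²)) effects; an individual-level random effect
  shared across datasets carrying 30% of the biological variance
  (σ_b = 0.4 log2) — the mechanism generating the cross-dataset correlation
  the pairing constraint preserves; library sizes lognormal around 2×10⁶;
  NB dispersion 0.1. Counts convert to log2 CPM with a 0.5 pseudocount,
  and features failing CPM > 1 in *all* samples are dropped and reported.
- **Methylation.** Gaussian M-values (bimodal-plus-midrange baseline
  mixture emulating the hypo/hyper-methylated split of array probes), group
  and covariate effects on the M scale, the same individual-effect
  construction, then beta = inverse-logit2 clipped inside (0, 1).
- **Cis links.** Each requested link places a probe within 1500 bp of a
  gene's strand-aware TSS and couples both features to one standard-normal
  per-individual latent factor. Per-side loadings are chosen so each side
  correlates √|ρ| with the latent (loading λ = σ_noise·√(|ρ|/(1−|ρ|)),
  with the expression-side noise including an analytic count-noise term),
  giving pairwise Spearman ≈ the target ρ; the sign of ρ sets the coupling
  sign (negative = promoter-methylation repression). Cis genes get a high
  fixed baseline (log2 CPM 6) so counting noise does not dominate; cis
  probes a mid-range baseline (beta ≈ 0.5) for maximal dynamic range.
- **Seeding.** A master seed spawns independent substreams per stage
  (design, annotations, latents, expression, methylation), so regeneration
  is byte-identical and adding a stage never perturbs earlier draws.

What the synthetic data do **not** emulate: read-level artefacts, batch
effects, probe cross-reactivity, linkage/co-methylation structure among
features (features are independent given the design), or realistic gene/
probe density along the genome. Passing tests therefore demonstrate the
statistical machinery — calibration, power ordering, recovery — under the
assumed generating model, not performance on any specific real cohort.

## Validation summary

The acceptance suite (tests/test_acceptance.py) checks, at fixed seeds:
exact agreement of exhaustive-permutation global p-values with an
independent brute-force enumeration (6 individuals, 90 assignments, 50
features); type-I error 0.05 ± 0.015 and KS uniformity of global p under a
2000-feature global null (10/10/8 individuals, 70% paired, B = 500);
reduction to the partial p for duplicated fully-paired datasets (within
1/(B+1)); NPC recall ≥ 0.6 on 150 shared log2-effect-1.0 features among
5000 with NPC ≥ each single-dataset recall and all-samples ≥ paired-only
(10 seeds, B = 1000); ≥ 95% recovery of injected ρ = −0.9 cis links at
n = 25 shared samples over 200 seeds with a null pass rate < 5%; and oracle
equivalence of the primitives (OLS/F/t vs normal equations, BH vs the
double-loop definition, Spearman vs the rank formula, Liptak vs
hand-computed quantile sums). `scripts/acceptance.py` recomputes the
calibration, power and recovery quantities from scratch at slightly
reduced replication (5 power seeds, 100 recovery seeds) and writes them as
JSON.

## Known limitations

- Permutation p-values are lattice-valued; very strict thresholds demand
  correspondingly large B (cost grows linearly in B).
- The group-emptying edge case in heavily unpaired designs is handled but
  divides by the nominal 2 numerator df; this is consistent across a run
  (p-values unaffected) but the raw permuted F values are not comparable
  across such permutations.
- Variance moderation approximates a limma-style moderated statistic by
  moments; exact empirical-Bayes fidelity is not claimed.
- The exact Spearman path enumerates n! pairings and is only used for
  n ≤ 10; n = 10 costs a few seconds on first use (the permutation matrix
  is cached per n).
- `StudyDesign` accepts datasets in which the group F is undefined (fewer
  than 2 groups with ≥ 2 samples) with a warning — the permutation
  structure of such designs is still meaningful — and the error surfaces at
  model-fitting time.
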