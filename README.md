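# npcomics

Pairing-constrained permutation **NPC** (non-parametric combination) for
paired multi-omics studies, with downstream cis expression–methylation
correlation and rank-based gene-set enrichment.

## The problem

Clinical multi-omics studies often profile several related cell types (here:
CD4+ and CD8+ T cells from healthy controls and multiple sclerosis patients
in the relapsing-remitting and secondary-progressive stages) in *partially
overlapping* sets of individuals — some people contribute both cell types,
some only one. Per-dataset differential analyses are underpowered at
clinical sample sizes, yet naive pooling ignores that paired samples are
correlated. NPC solves this without distributional assumptions:

1. For each feature *g* and dataset *d*, fit a linear model
   `y_g = β₀ + β_RR·1[RR] + β_SP·1[SP] + β_age·age + β_sex·1[M] + ε` and take
   the group-factor partial F statistic `F_gd` (2 numerator df) as the
   partial-test statistic.
2. Build the null by permuting disease labels **at the individual level**:
   an individual measured in both datasets receives the same permuted label
   in both (preserving the cross-dataset correlation under the null), while
   dataset-exclusive individuals are shuffled freely in the same joint draw.
   Covariates never move.
3. Convert observed and permuted statistics to partial permutation p-values
   `p = (1 + #{b: F_b ≥ F_obs}) / (1 + B)`.
4. Combine across datasets with the Liptak (Stouffer) function
   `T = Σ_d w_d Φ⁻¹(1 − p_d)` and compare the observed `T` to the permuted
   `T` values to obtain one **global p-value** per feature;
   Benjamini–Hochberg q-values control the FDR across features.

Selected genes (global p ≤ 0.001, FDR ≤ 0.1) and methylation probes
(global p ≤ 0.001, FDR ≤ 0.2) feed two downstream stages: probes within
1 Mb (strict) of a gene's strand-aware TSS are correlated with that gene's
expression (Spearman, shared samples per dataset, all disease groups
pooled), keeping pairs with |ρ| > 0.5 and p < 0.05 in **every** dataset; and
per-gene p-values drive a rank-sum gene-set enrichment with the 20–200
effective-size filter.

Because the patient-level data needed to reproduce the original cohort are
not bundled here, the package ships a first-class synthetic-data module
(negative-binomial expression, Gaussian M-value methylation, individual-level
random effects, injected anti-correlated promoter–gene pairs) with full
ground truth, so every stage is testable end to end.

## Worked example

```python
import npcomics as n

cfg = n.StudyConfig(
    n_hc=10, n_rr=10, n_sp=8, paired_fraction=0.7,
    n_genes=2000, n_probes=1000, cis=n.CisPairSpec(10, target_rho=-0.9),
    expression=n.ExpressionTruthSpec(n_de=60, effect_size=1.0))
study = n.simulate_study(cfg, seed=42)

res = n.npc_global([study.expression["CD4"], study.expression["CD8"]],
                   study.design, B=1000, seed=42)
selected = n.select_features(res, p_max=0.001, q_max=0.1)
truth = set(study.expression_truth.de_features())
print(f"{len(selected)} genes selected; "
      f"{len(set(selected) & truth)} of {len(truth)} injected effects recovered")
print(res.table.loc[selected[:3], ["partial_p_CD4", "partial_p_CD8", "global_p", "q"]])
```

prints (exact values depend only on the seed):

```
39 genes selected; 39 of 58 injected effects recovered
            partial_p_CD4  partial_p_CD8  global_p         q
feature_id
G00005           0.001998       0.000999  0.000999  0.050386
G00016           0.000999       0.000999  0.000999  0.050386
G00072           0.000999       0.003996  0.000999  0.050386
```

All 39 selected genes are injected effects (no false positives at these
thresholds), each reaching the strictest attainable global p-value
(1/(B+1) = 0.000999 at B = 1000); two of the 58 surviving injected effects
sit just above the lattice in one cell type (partial p 0.002–0.004) yet the
combination still drives their global p to the floor — the Liptak function
rewarding consistent two-dataset support. The 19 missed effects fall below
the detection threshold at these sample sizes.
The same `res.table` exposes per-dataset F statistics and partial p-values,
so single-dataset and combined analyses can be compared directly.

A command-line surface wraps the same pipeline:

```bash
npcomics all --config config.yaml --outdir results/
npcomics simulate --outdir study/          # synthetic study as TSVs
npcomics npc --design study/design.tsv \
    --matrix CD4=study/expression_CD4.tsv --matrix CD8=study/expression_CD8.tsv \
    --out npc.tsv
```

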