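"""Synthetic paired multi-omics studies with ground truth.

The generators emulate the statistical structure the pairing-constrained
NPC analysis assumes: two datasets (e.g. CD4 and CD8 T cells) whose sample
sets overlap partially at the individual level; three disease groups
(HC/RR/SP); group effects optionally shared across datasets; age and sex
covariate effects; an individual-level random effect that induces the
cross-dataset correlation the pairing constraint preserves; and injected
anti-correlated promoter-probe/gene pairs for the cis overlap stage.

Expression is drawn from a negative-binomial log-linear model and emitted
both as raw counts and log2 CPM; methylation is drawn as Gaussian M-values
(logit2 of beta) and emitted as beta fractions.  Everything is seeded and a
master seed spawns independent per-stage substreams, so regenerating with
the same seed reproduces matrices exactly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import (FeatureAnnotation, InvalidDesignError, OmicsDataset,
                        StudyDesign, SyntheticTruth)

logger = logging.getLogger(__name__)

LN2 = np.log(2.0)

#: age ranges (years) by disease group, following a typical MS case/control
#: cohort: controls span adulthood, RR patients are younger, SP older.
DEFAULT_AGE_RANGES = {"HC": (27.0, 62.0), "RR": (26.0, 46.0), "SP": (35.0, 63.0)}


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# study design


def generate_design(n_hc: int, n_rr: int, n_sp: int, paired_fraction: float = 0.7,
                    age_ranges: dict | None = None, sex_ratio: float = 0.6,
                    dataset_ids: tuple[str, ...] = ("CD4", "CD8"),
                    seed=None) -> StudyDesign:
    """Cohort with ``round(paired_fraction * n_g)`` paired individuals per group.

    Paired individuals contribute one sample to every dataset; the remaining
    individuals are assigned (randomly, but balanced across datasets) to
    exactly one.  Ages are uniform within the group's range, sex is
    Bernoulli(``sex_ratio`` female).
    """
    sizes = {"HC": n_hc, "RR": n_rr, "SP": n_sp}
    for g, n in sizes.items():
        if n < 2:
            raise InvalidDesignError(f"group {g} has {n} individuals; need >= 2")
    if not 0.0 <= paired_fraction <= 1.0:
        raise InvalidDesignError("paired_fraction must lie in [0, 1]")
    ranges = age_ranges or DEFAULT_AGE_RANGES
    rng = _rng(seed)

    rows = []
    k = 0
    for g, n in sizes.items():
        n_paired = int(np.floor(paired_fraction * n + 0.5))
        lo, hi = ranges[g]
        ages = rng.uniform(lo, hi, size=n)
        sexes = np.where(rng.random(n) < sex_ratio, "F", "M")
        # unpaired individuals: shuffle then deal round-robin so datasets
        # stay balanced even at tiny group sizes
        unpaired_idx = rng.permutation(np.arange(n_paired, n))
        assign = {}
        for j, idx in enumerate(unpaired_idx):
            assign[idx] = dataset_ids[j % len(dataset_ids)]
        for i in range(n):
            k += 1
            ind = f"I{k:04d}"
            targets = dataset_ids if i < n_paired else (assign[i],)
            for ds in targets:
                rows.append({"sample_id": f"{ind}_{ds}", "individual_id": ind,
                             "dataset_id": ds, "group": g,
                             "age": float(ages[i]), "sex": str(sexes[i])})
    return StudyDesign(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# annotations


@dataclass
class CisPairSpec:
    """Requested promoter-probe/gene couplings for the overlap stage."""

    n_pairs: int = 0
    max_offset: int = 1500        # bp from the strand-aware TSS
    target_rho: float = -0.9      # target Spearman correlation (negative =
                                  # promoter methylation represses expression)


def generate_annotations(n_genes: int, n_probes: int, chrom_length: int = 100_000_000,
                         cis_pair_spec: CisPairSpec | None = None, seed=None,
                         chrom: str = "chr1",
                         gene_length_range: tuple[int, int] = (1_000, 100_000),
                         ) -> tuple[FeatureAnnotation, pd.DataFrame]:
    """Random gene intervals with strands plus probe positions on one chromosome.

    For each requested cis pair, a probe is placed within ``max_offset`` bp
    of a gene's strand-aware TSS (+ strand: start; - strand: end); remaining
    probes are uniform.  Returns the annotation and the cis-link table
    (gene_id, probe_id, target_rho) for the ground truth.

    Coordinates are 0-based half-open.
    """
    spec = cis_pair_spec or CisPairSpec(0)
    if spec.n_pairs > n_genes:
        raise ValueError(f"{spec.n_pairs} cis pairs requested but only "
                         f"{n_genes} genes")
    if spec.n_pairs > n_probes:
        raise ValueError(f"{spec.n_pairs} cis pairs requested but only "
                         f"{n_probes} probes")
    if abs(spec.target_rho) >= 1:
        raise ValueError("|target_rho| must be < 1")
    if chrom_length < gene_length_range[1] + 2 * spec.max_offset:
        raise ValueError("chromosome too short to place features")
    rng = _rng(seed)

    lengths = rng.integers(*gene_length_range, size=n_genes)
    starts = rng.integers(0, chrom_length - gene_length_range[1], size=n_genes)
    strands = rng.choice(["+", "-"], size=n_genes)
    gene_ids = [f"G{i:05d}" for i in range(n_genes)]
    genes = pd.DataFrame({"feature_id": gene_ids, "feature_type": "gene",
                          "chrom": chrom, "start": starts,
                          "end": starts + lengths, "strand": strands})
    tss = np.where(strands == "+", starts, starts + lengths)

    probe_ids = [f"cg{i:06d}" for i in range(n_probes)]
    pos = rng.integers(0, chrom_length, size=n_probes)
    links = []
    if spec.n_pairs:
        cis_genes = rng.choice(n_genes, size=spec.n_pairs, replace=False)
        for j, gi in enumerate(cis_genes):
            offset = int(rng.integers(-spec.max_offset, spec.max_offset + 1))
            pos[j] = int(np.clip(tss[gi] + offset, 0, chrom_length - 1))
            links.append({"gene_id": gene_ids[gi], "probe_id": probe_ids[j],
                          "target_rho": spec.target_rho})
    probes = pd.DataFrame({"feature_id": probe_ids, "feature_type": "probe",
                           "chrom": chrom, "start": pos, "end": pos,
                           "strand": "."})
    ann = FeatureAnnotation(pd.concat([genes, probes], ignore_index=True))
    cis_links = pd.DataFrame(links, columns=["gene_id", "probe_id", "target_rho"])
    return ann, cis_links


# ---------------------------------------------------------------------------
# effect assignment shared by both generators


def _assign_effects(feature_ids: list[str], dataset_ids: list[str], n_de: int,
                    effect_size: float, shared_fraction: float,
                    rng: np.random.Generator,
                    exclude: set[str] = frozenset()) -> pd.DataFrame:
    """Per feature x dataset table of injected RR/SP coefficient shifts."""
    eligible = [f for f in feature_ids if f not in exclude]
    if n_de > len(eligible):
        raise ValueError(f"{n_de} DE features requested among {len(eligible)}")
    de = set(rng.choice(eligible, size=n_de, replace=False)) if n_de else set()
    rows = []
    for f in feature_ids:
        if f in de:
            s_rr, s_sp = rng.choice([-1.0, 1.0], size=2)
            shared = bool(rng.random() < shared_fraction)
            active = list(dataset_ids) if shared else [rng.choice(dataset_ids)]
            for ds in dataset_ids:
                on = ds in active
                rows.append({"feature_id": f, "dataset_id": ds,
                             "beta_RR": s_rr * effect_size if on else 0.0,
                             "beta_SP": s_sp * effect_size if on else 0.0,
                             "is_de": on, "shared": shared})
        else:
            for ds in dataset_ids:
                rows.append({"feature_id": f, "dataset_id": ds, "beta_RR": 0.0,
                             "beta_SP": 0.0, "is_de": False, "shared": False})
    return pd.DataFrame(rows, columns=["feature_id", "dataset_id", "beta_RR",
                                       "beta_SP", "is_de", "shared"])


def _latent_lambda(noise_sd: float, target_rho: float) -> float:
    """Loading that gives each side correlation sqrt(|rho|) with the latent."""
    c2 = abs(target_rho)  # squared per-side correlation
    return float(noise_sd * np.sqrt(c2 / (1.0 - c2)))


def draw_cis_latents(design: StudyDesign, cis_links: pd.DataFrame,
                     seed=None) -> pd.DataFrame:
    """Standard-normal individual factors, one column per cis link.

    The same table must be passed to both generators for the link to induce
    the target expression-methylation correlation.
    """
    rng = _rng(seed)
    inds = sorted(design.table["individual_id"].unique())
    z = rng.standard_normal((len(inds), len(cis_links)))
    return pd.DataFrame(z, index=inds,
                        columns=[f"{g}|{p}" for g, p in
                                 zip(cis_links["gene_id"], cis_links["probe_id"])])


# ---------------------------------------------------------------------------
# expression


@dataclass
class ExpressionTruthSpec:
    """Parameters of the negative-binomial expression generator.

    ``effect_size`` is the log2 group shift of DE features;
    ``indiv_var_share`` is the fraction of the biological (log-scale)
    variance attributed to the individual effect shared across datasets.
    """

    n_de: int = 0
    effect_size: float = 1.0
    shared_fraction: float = 1.0
    age_effect_sd: float = 0.005   # log2 per year
    sex_effect_sd: float = 0.1     # log2
    dispersion: float = 0.1        # NB dispersion phi (var = mu + phi mu^2)
    biological_sd: float = 0.4     # total biological log2 sd beyond counting noise
    indiv_var_share: float = 0.3
    lib_size: float = 2e6
    lib_size_sigma: float = 0.2    # lognormal sigma of library sizes
    baseline_mean: float = 5.0     # mean log2 CPM
    baseline_sd: float = 1.5
    cpm_filter: float = 1.0        # keep features with CPM > this in all samples
    cis_baseline: float = 6.0      # forced baseline log2 CPM of cis-linked genes


def generate_expression(design: StudyDesign, annotations: FeatureAnnotation,
                        truth_spec: ExpressionTruthSpec | None = None, seed=None,
                        cis_links: pd.DataFrame | None = None,
                        cis_latents: pd.DataFrame | None = None,
                        ) -> tuple[dict[str, OmicsDataset], SyntheticTruth]:
    """NB counts -> log2 CPM per dataset, plus the ground-truth table.

    Features failing the abundance filter (CPM > ``cpm_filter`` in *all*
    samples of all datasets) are dropped from the matrices and reported in
    ``truth.dropped``.
    """
    spec = truth_spec or ExpressionTruthSpec()
    if spec.dispersion <= 0:
        raise ValueError("NB dispersion must be positive")
    rng = _rng(seed)
    genes = annotations.genes()
    feature_ids = list(genes["feature_id"])
    nF = len(feature_ids)
    dataset_ids = design.dataset_ids
    links = cis_links if cis_links is not None else pd.DataFrame(
        columns=["gene_id", "probe_id", "target_rho"])
    cis_gene_set = set(links["gene_id"])

    effects = _assign_effects(feature_ids, dataset_ids, spec.n_de,
                              spec.effect_size, spec.shared_fraction, rng,
                              exclude=cis_gene_set)

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=nF)
    fpos = {f: i for i, f in enumerate(feature_ids)}
    for g in cis_gene_set:
        baseline[fpos[g]] = spec.cis_baseline
    age_eff = rng.normal(0.0, spec.age_effect_sd, size=nF)
    sex_eff = rng.normal(0.0, spec.sex_effect_sd, size=nF)

    inds = sorted(design.table["individual_id"].unique())
    u_sd = spec.biological_sd * np.sqrt(spec.indiv_var_share)
    e_sd = spec.biological_sd * np.sqrt(1.0 - spec.indiv_var_share)
    u = pd.DataFrame(rng.normal(0.0, u_sd, size=(nF, len(inds))),
                     index=feature_ids, columns=inds)

    if len(links) and cis_latents is None:
        logger.warning("cis links present but no shared latents supplied; "
                       "drawing fresh factors (expression side only)")
        cis_latents = draw_cis_latents(design, links, seed=rng)
    # per-side loading so that corr(expression, latent) ~= sqrt(|rho|)
    count_noise_sd = np.sqrt(1.0 / (2 ** spec.cis_baseline * spec.lib_size / 1e6)
                             + spec.dispersion) / LN2
    gene_noise_sd = float(np.hypot(spec.biological_sd, count_noise_sd))

    mean_age = design.table["age"].mean()
    counts_by_ds: dict[str, pd.DataFrame] = {}
    for ds in dataset_ids:
        rows = design.subset(ds)
        nS = len(rows)
        lib = spec.lib_size * np.exp(rng.normal(0.0, spec.lib_size_sigma, size=nS))
        log2cpm = np.tile(baseline[:, None], (1, nS))
        eff_ds = effects[effects["dataset_id"] == ds].set_index("feature_id")
        eff_ds = eff_ds.loc[feature_ids]
        b_rr = eff_ds["beta_RR"].to_numpy(dtype=float)
        b_sp = eff_ds["beta_SP"].to_numpy(dtype=float)
        grp = rows["group"].to_numpy()
        log2cpm += np.outer(b_rr, grp == "RR") + np.outer(b_sp, grp == "SP")
        log2cpm += np.outer(age_eff, rows["age"].to_numpy() - mean_age)
        log2cpm += np.outer(sex_eff, (rows["sex"] == "M").to_numpy())
        log2cpm += u[rows["individual_id"]].to_numpy()
        log2cpm += rng.normal(0.0, e_sd, size=(nF, nS))
        if len(links):
            for col, (_, link) in zip(cis_latents.columns, links.iterrows()):
                lam = _latent_lambda(gene_noise_sd, link["target_rho"])
                z = cis_latents.loc[rows["individual_id"], col].to_numpy()
                log2cpm[fpos[link["gene_id"]]] += lam * z

        mu = (2.0 ** log2cpm) / 1e6 * lib[None, :]
        shape = 1.0 / spec.dispersion
        lam = rng.gamma(shape, scale=mu / shape)
        counts = rng.poisson(lam).astype(np.int64)
        counts_by_ds[ds] = pd.DataFrame(counts, index=feature_ids,
                                        columns=list(rows["sample_id"]))

    # abundance filter across all samples of all datasets
    keep = np.ones(nF, dtype=bool)
    for ds in dataset_ids:
        rows = design.subset(ds)
        lib_obs = counts_by_ds[ds].sum(axis=0).to_numpy(dtype=float)
        cpm = counts_by_ds[ds].to_numpy() / lib_obs[None, :] * 1e6
        keep &= (cpm > spec.cpm_filter).all(axis=1)
    dropped = [f for f, k in zip(feature_ids, keep) if not k]
    if dropped:
        logger.info("abundance filter dropped %d/%d features", len(dropped), nF)

    datasets = {}
    for ds in dataset_ids:
        cnt = counts_by_ds[ds].loc[keep]
        lib_obs = cnt.sum(axis=0).to_numpy(dtype=float)
        log2cpm = np.log2((cnt.to_numpy() + 0.5) / (lib_obs[None, :] + 1.0) * 1e6)
        values = pd.DataFrame(log2cpm, index=cnt.index, columns=cnt.columns)
        datasets[ds] = OmicsDataset(dataset_id=ds, modality="expression",
                                    values=values, counts=cnt)

    effects = effects[~effects["feature_id"].isin(dropped)].reset_index(drop=True)
    truth = SyntheticTruth(effects=effects, cis_links=links.copy(), dropped=dropped)
    return datasets, truth


# ---------------------------------------------------------------------------
# methylation


@dataclass
class MethylationTruthSpec:
    """Parameters of the Gaussian M-value methylation generator.

    Baseline M-values are a bimodal-plus-midrange mixture mimicking the
    hypo/hyper-methylated split of array probes; ``effect_size`` shifts DM
    probes on the M scale.
    """

    n_dm: int = 0
    effect_size: float = 0.5       # M-value shift
    shared_fraction: float = 1.0
    age_effect_sd: float = 0.01    # M per year
    sex_effect_sd: float = 0.1
    m_noise_sd: float = 0.5        # total biological M sd
    indiv_var_share: float = 0.3
    baseline_modes: tuple[float, ...] = (-3.0, 0.0, 3.0)
    baseline_mode_sd: float = 1.0
    baseline_weights: tuple[float, ...] = (0.4, 0.2, 0.4)


def generate_methylation(design: StudyDesign, annotations: FeatureAnnotation,
                         truth_spec: MethylationTruthSpec | None = None, seed=None,
                         cis_links: pd.DataFrame | None = None,
                         cis_latents: pd.DataFrame | None = None,
                         ) -> tuple[dict[str, OmicsDataset], SyntheticTruth]:
    """Gaussian M-values -> beta fractions per dataset, plus ground truth.

    For each cis link the probe shares the per-individual latent factor with
    the linked gene, with the sign of ``target_rho``, so the probe's beta
    anti-correlates with the gene's expression at roughly the target
    Spearman rho.
    """
    spec = truth_spec or MethylationTruthSpec()
    rng = _rng(seed)
    probes = annotations.probes()
    feature_ids = list(probes["feature_id"])
    nF = len(feature_ids)
    dataset_ids = design.dataset_ids
    links = cis_links if cis_links is not None else pd.DataFrame(
        columns=["gene_id", "probe_id", "target_rho"])
    if len(links) and (links["target_rho"].abs() >= 1).any():
        raise ValueError("|target_rho| must be < 1")
    cis_probe_set = set(links["probe_id"])

    effects = _assign_effects(feature_ids, dataset_ids, spec.n_dm,
                              spec.effect_size, spec.shared_fraction, rng,
                              exclude=cis_probe_set)

    modes = rng.choice(len(spec.baseline_modes), size=nF,
                       p=np.asarray(spec.baseline_weights) /
                       np.sum(spec.baseline_weights))
    baseline = (np.asarray(spec.baseline_modes)[modes]
                + rng.normal(0.0, spec.baseline_mode_sd, size=nF))
    fpos = {f: i for i, f in enumerate(feature_ids)}
    for p in cis_probe_set:
        baseline[fpos[p]] = 0.0  # mid-range beta: maximal dynamic range
    age_eff = rng.normal(0.0, spec.age_effect_sd, size=nF)
    sex_eff = rng.normal(0.0, spec.sex_effect_sd, size=nF)

    inds = sorted(design.table["individual_id"].unique())
    u_sd = spec.m_noise_sd * np.sqrt(spec.indiv_var_share)
    e_sd = spec.m_noise_sd * np.sqrt(1.0 - spec.indiv_var_share)
    u = pd.DataFrame(rng.normal(0.0, u_sd, size=(nF, len(inds))),
                     index=feature_ids, columns=inds)

    if len(links) and cis_latents is None:
        logger.warning("cis links present but no shared latents supplied; "
                       "probe/gene correlation will not be induced")
        cis_latents = draw_cis_latents(design, links, seed=rng)

    mean_age = design.table["age"].mean()
    datasets = {}
    for ds in dataset_ids:
        rows = design.subset(ds)
        nS = len(rows)
        M = np.tile(baseline[:, None], (1, nS))
        eff_ds = effects[effects["dataset_id"] == ds].set_index("feature_id")
        eff_ds = eff_ds.loc[feature_ids]
        b_rr = eff_ds["beta_RR"].to_numpy(dtype=float)
        b_sp = eff_ds["beta_SP"].to_numpy(dtype=float)
        grp = rows["group"].to_numpy()
        M += np.outer(b_rr, grp == "RR") + np.outer(b_sp, grp == "SP")
        M += np.outer(age_eff, rows["age"].to_numpy() - mean_age)
        M += np.outer(sex_eff, (rows["sex"] == "M").to_numpy())
        M += u[rows["individual_id"]].to_numpy()
        M += rng.normal(0.0, e_sd, size=(nF, nS))
        if len(links):
            for col, (_, link) in zip(cis_latents.columns, links.iterrows()):
                lam = _latent_lambda(spec.m_noise_sd, link["target_rho"])
                sign = np.sign(link["target_rho"])
                z = cis_latents.loc[rows["individual_id"], col].to_numpy()
                M[fpos[link["probe_id"]]] += sign * lam * z
        beta = expit(M * LN2)  # inverse logit2
        beta = np.clip(beta, 1e-9, 1 - 1e-9)
        values = pd.DataFrame(beta, index=feature_ids,
                              columns=list(rows["sample_id"]))
        datasets[ds] = OmicsDataset(dataset_id=ds, modality="methylation",
                                    values=values)

    truth = SyntheticTruth(effects=effects, cis_links=links.copy())
    return datasets, truth


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class StudyConfig:
    """One-stop configuration for a complete synthetic study."""

    n_hc: int = 12
    n_rr: int = 12
    n_sp: int = 10
    paired_fraction: float = 0.7
    sex_ratio: float = 0.6
    n_genes: int = 2000
    n_probes: int = 2000
    chrom_length: int = 100_000_000
    cis: CisPairSpec = field(default_factory=CisPairSpec)
    expression: ExpressionTruthSpec = field(default_factory=ExpressionTruthSpec)
    methylation: MethylationTruthSpec = field(default_factory=MethylationTruthSpec)


@dataclass
class SyntheticStudy:
    design: StudyDesign
    annotations: FeatureAnnotation
    expression: dict[str, OmicsDataset]
    methylation: dict[str, OmicsDataset]
    expression_truth: SyntheticTruth
    methylation_truth: SyntheticTruth


def simulate_study(config: StudyConfig | None = None, seed=None) -> SyntheticStudy:
    """Generate design, annotations and both modalities from one master seed.

    Each stage consumes an independent substream of the master seed, so
    adding or reconfiguring a later stage never perturbs earlier draws.
    """
    cfg = config or StudyConfig()
    ss = np.random.SeedSequence(seed)
    s_design, s_ann, s_lat, s_expr, s_meth = ss.spawn(5)
    design = generate_design(cfg.n_hc, cfg.n_rr, cfg.n_sp, cfg.paired_fraction,
                             sex_ratio=cfg.sex_ratio, seed=np.random.default_rng(s_design))
    ann, links = generate_annotations(cfg.n_genes, cfg.n_probes, cfg.chrom_length,
                                      cis_pair_spec=cfg.cis,
                                      seed=np.random.default_rng(s_ann))
    latents = draw_cis_latents(design, links, seed=np.random.default_rng(s_lat))
    expr, expr_truth = generate_expression(design, ann, cfg.expression,
                                           seed=np.random.default_rng(s_expr),
                                           cis_links=links, cis_latents=latents)
    meth, meth_truth = generate_methylation(design, ann, cfg.methylation,
                                            seed=np.random.default_rng(s_meth),
                                            cis_links=links, cis_latents=latents)
    return SyntheticStudy(design=design, annotations=ann, expression=expr,
                          methylation=meth, expression_truth=expr_truth,
                          methylation_truth=meth_truth)


def generate_gene_sets(universe: list[str], n_sets: int = 50,
                       size_range: tuple[int, int] = (20, 200),
                       n_enriched: int = 0, signal_genes: list[str] | None = None,
                       signal_fraction: float = 0.8, seed=None):
    """Random gene sets over the universe, optionally spiked with signal genes.

    The first ``n_enriched`` sets draw ``signal_fraction`` of their members
    from ``signal_genes`` (for enrichment-recovery tests); the rest are
    uniform draws.  Returns a :class:`~npcomics.enrichment.GeneSetCollection`.
    """
    from .enrichment import GeneSetCollection

    rng = _rng(seed)
    uni = list(universe)
    signal = list(signal_genes or [])
    if n_enriched and not signal:
        raise ValueError("n_enriched > 0 requires signal_genes")
    if size_range[0] > len(uni):
        raise ValueError("universe smaller than the minimum set size")
    sets = {}
    for k in range(n_sets):
        size = min(int(rng.integers(size_range[0], size_range[1] + 1)),
                   len(uni) - 1)
        if k < n_enriched:
            n_sig = min(int(np.floor(signal_fraction * size + 0.5)), len(signal))
            members = set(rng.choice(signal, size=n_sig, replace=False))
            rest = [g for g in uni if g not in members]
            members |= set(rng.choice(rest, size=size - n_sig, replace=False))
            sets[f"SPIKED_{k:03d}"] = members
        else:
            sets[f"RANDOM_{k:03d}"] = set(rng.choice(uni, size=size, replace=False))
    return GeneSetCollection(sets=sets, universe=set(uni))
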