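"""Cis expression-methylation association (eQTM overlap stage).

Selected genes and probes are paired when the probe lies within 1 Mb
(strict) of the gene's strand-aware TSS on the same chromosome.  Each pair
is then scored per dataset by the Spearman correlation between the gene's
expression and the probe's beta value across the samples measured in both
modalities (matched at the individual level, all disease groups pooled),
and pairs passing |rho| > 0.5 and p < 0.05 in *every* dataset form the
intersection.  Spearman is rank-based, so whether methylation enters as
beta or M-value is inconsequential.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import FeatureAnnotation, OmicsDataset, StudyDesign

logger = logging.getLogger(__name__)

MAX_DIST = 1_000_000
EXACT_N_MAX = 10  # exact permutation p-value at or below this sample count


def compute_tss(genes: pd.DataFrame) -> pd.Series:
    """Strand-aware TSS: + strand -> start, - strand -> end, unknown -> start."""
    strands = genes["strand"].to_numpy()
    unknown = ~np.isin(strands, ["+", "-"])
    if unknown.any():
        logger.warning("%d genes with unknown strand; using start as TSS",
                       int(unknown.sum()))
    tss = np.where(strands == "-", genes["end"], genes["start"])
    return pd.Series(tss, index=genes["feature_id"].to_numpy(), name="tss")


def pair_within_distance(annotations: FeatureAnnotation, gene_ids: list[str],
                         probe_ids: list[str], max_dist: int = MAX_DIST) -> pd.DataFrame:
    """All same-chromosome gene-probe pairs with |probe - TSS| < max_dist.

    Selected features missing from the annotation are skipped with a
    warning.  The result is deduplicated and sorted by (gene_id, distance).
    """
    genes = annotations.genes()
    probes = annotations.probes()
    missing = (set(gene_ids) - set(genes["feature_id"])) | \
              (set(probe_ids) - set(probes["feature_id"]))
    if missing:
        logger.warning("skipping %d selected features without annotation: %s",
                       len(missing), sorted(missing)[:10])
    genes = genes[genes["feature_id"].isin(set(gene_ids))]
    probes = probes[probes["feature_id"].isin(set(probe_ids))]
    if genes.empty or probes.empty:
        return pd.DataFrame(columns=["gene_id", "probe_id", "chrom", "tss",
                                     "probe_pos", "distance"])
    tss = compute_tss(genes)
    g = pd.DataFrame({"gene_id": genes["feature_id"].to_numpy(),
                      "chrom": genes["chrom"].to_numpy(),
                      "tss": tss.to_numpy()})
    p = pd.DataFrame({"probe_id": probes["feature_id"].to_numpy(),
                      "chrom": probes["chrom"].to_numpy(),
                      "probe_pos": probes["start"].to_numpy()})
    merged = g.merge(p, on="chrom")
    merged["distance"] = (merged["probe_pos"] - merged["tss"]).abs()
    merged = merged[merged["distance"] < max_dist]
    merged = merged.drop_duplicates(subset=["gene_id", "probe_id"])
    merged = merged.sort_values(["gene_id", "distance"]).reset_index(drop=True)
    return merged[["gene_id", "probe_id", "chrom", "tss", "probe_pos", "distance"]]


@lru_cache(maxsize=4)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(_iter_permutations(range(n))), dtype=np.int8)


def spearman(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) with a two-sided p-value.

    For n > EXACT_N_MAX the usual t approximation is used; at small n the
    p-value is the exact permutation probability over all n! pairings of
    |rho| at least as large as observed (the identity pairing included, so
    p > 0).
    """
    n = len(x)
    if n < 3:
        return np.nan, np.nan
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(stats.pearsonr(rx, ry).statistic)
    if n > EXACT_N_MAX:
        p = float(stats.spearmanr(x, y).pvalue)
        return rho, p
    perms = _perm_matrix(n)
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum())
    if denom == 0:
        return np.nan, np.nan
    rho_null = (rxc[perms] @ ryc) / denom
    tol = 1e-12
    p = float(np.mean(np.abs(rho_null) >= abs(rho) - tol))
    return rho, p


def correlate_pairs(pairs: pd.DataFrame, expression: OmicsDataset,
                    methylation: OmicsDataset, design: StudyDesign,
                    min_samples: int = 5) -> pd.DataFrame:
    """Spearman rho/p per pair over the dataset's shared samples.

    Samples are matched at the individual level between the expression and
    methylation matrices of one dataset; all disease groups are pooled.
    Pairs with fewer than ``min_samples`` shared samples are flagged
    untested (rho and p NaN) rather than erroring.
    """
    if expression.dataset_id != methylation.dataset_id:
        raise ValueError("expression and methylation must come from one dataset")
    rows = design.subset(expression.dataset_id).set_index("sample_id")
    e_ind = {rows.loc[s, "individual_id"]: s for s in expression.sample_ids}
    m_ind = {rows.loc[s, "individual_id"]: s for s in methylation.sample_ids}
    shared = sorted(set(e_ind) & set(m_ind))
    e_cols = [e_ind[i] for i in shared]
    m_cols = [m_ind[i] for i in shared]
    n = len(shared)

    out = []
    for _, pair in pairs.iterrows():
        g, pr = pair["gene_id"], pair["probe_id"]
        tested = (n >= min_samples and g in expression.values.index
                  and pr in methylation.values.index)
        if tested:
            x = expression.values.loc[g, e_cols].to_numpy(dtype=float)
            y = methylation.values.loc[pr, m_cols].to_numpy(dtype=float)
            rho, p = spearman(x, y)
        else:
            rho, p = np.nan, np.nan
        out.append({"gene_id": g, "probe_id": pr, "rho": rho, "p": p,
                    "n": n if tested else 0, "tested": bool(tested)})
    return pd.DataFrame(out, columns=["gene_id", "probe_id", "rho", "p", "n",
                                      "tested"])


def rank_and_intersect(results: dict[str, pd.DataFrame], rho_min: float = 0.5,
                       p_max: float = 0.05) -> pd.DataFrame:
    """Per dataset keep |rho| > rho_min and p < p_max, rank by p, intersect.

    Returns the pairs significant in every dataset, with each dataset's rho,
    p and rank, sorted by the sum of ranks.
    """
    kept = {}
    for ds, tab in results.items():
        sig = tab[tab["tested"] & (tab["rho"].abs() > rho_min) & (tab["p"] < p_max)]
        sig = sig.sort_values("p").reset_index(drop=True)
        sig["rank"] = np.arange(1, len(sig) + 1)
        kept[ds] = sig
    datasets = sorted(kept)
    if not datasets:
        return pd.DataFrame(columns=["gene_id", "probe_id"])
    merged = None
    for ds in datasets:
        sub = kept[ds][["gene_id", "probe_id", "rho", "p", "rank"]].rename(
            columns={"rho": f"rho_{ds}", "p": f"p_{ds}", "rank": f"rank_{ds}"})
        merged = sub if merged is None else merged.merge(
            sub, on=["gene_id", "probe_id"], how="inner")
    if merged.empty:
        return merged
    merged["rank_sum"] = merged[[f"rank_{ds}" for ds in datasets]].sum(axis=1)
    return merged.sort_values(["rank_sum", "gene_id", "probe_id"]).reset_index(drop=True)
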