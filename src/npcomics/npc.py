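"""Pairing-constrained permutation NPC (non-parametric combination).

Combines per-dataset partial tests into one global permutation p-value per
feature.  The partial statistic is the group-factor F from
:mod:`npcomics.models`; its null is built by permuting disease labels at the
*individual* level, so an individual measured in several datasets carries
the same permuted label everywhere (preserving the cross-dataset correlation
structure), while individuals present in only one dataset are shuffled
freely.  Partial permutation p-values are combined with the Liptak
(Stouffer) function

    T = sum_d w_d * Phi^-1(1 - p_d),

and the global p-value compares the observed T against the T values obtained
by re-running the combination on every permutation.  Covariates never move:
only disease labels are permuted.

Numerical tie rule: permuted statistics within a relative 1e-6 of the
reference value count as exceedances (conservative), so algebraically equal
statistics arising from relabelling symmetries are counted identically
regardless of floating-point evaluation order.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import OmicsDataset, StudyDesign
from .models import (DesignMatrix, _group_dummies, build_design_matrix,
                     _estimate_inv_chisq_prior)

logger = logging.getLogger(__name__)

#: relative tolerance of the exceedance counts (ties count as exceedances)
TIE_RTOL = 1e-6


# ---------------------------------------------------------------------------
# constrained permutations


@dataclass
class PermutationSet:
    """Disease-label permutations constrained by the pairing structure.

    Labels are permuted over *distinct individuals* (a plain shuffle of the
    observed label multiset) and broadcast to every sample the individual
    contributes, in any dataset.
    """

    individual_ids: list[str]
    observed_labels: np.ndarray                    # per individual
    perm_labels: np.ndarray                        # B x n_individuals, dtype '<U2'
    sample_maps: dict[str, np.ndarray]             # dataset -> individual index per sample
    sample_orders: dict[str, list[str]]            # dataset -> sample_id order
    seed: int | None = None
    exhaustive: bool = False

    @property
    def B(self) -> int:
        return self.perm_labels.shape[0]

    def dataset_labels(self, dataset_id: str, b: int) -> np.ndarray:
        """Permuted labels of one dataset's samples for permutation ``b``."""
        return self.perm_labels[b][self.sample_maps[dataset_id]]

    def observed_dataset_labels(self, dataset_id: str) -> np.ndarray:
        return self.observed_labels[self.sample_maps[dataset_id]]

    def check_invariants(self) -> None:
        """Pairing and multiset invariants; raises AssertionError on violation."""
        ref = np.sort(self.observed_labels)
        for b in range(self.B):
            if not np.array_equal(np.sort(self.perm_labels[b]), ref):
                raise AssertionError(f"permutation {b} changed the label multiset")
        # broadcast consistency is structural: every sample indexes into the
        # same individual-level row, so multi-dataset individuals match by
        # construction; verify explicitly anyway.
        for b in range(min(self.B, 50)):
            seen: dict[str, str] = {}
            for ds, idx in self.sample_maps.items():
                labs = self.perm_labels[b][idx]
                for ind_i, lab in zip(idx, labs):
                    ind = self.individual_ids[ind_i]
                    if ind in seen and seen[ind] != lab:
                        raise AssertionError(
                            f"individual {ind} has discordant labels in perm {b}")
                    seen[ind] = lab


def n_distinct_assignments(labels: np.ndarray) -> int:
    """Number of distinct label assignments = multinomial coefficient."""
    n = len(labels)
    out = math.factorial(n)
    for _, k in zip(*np.unique(labels, return_counts=True)):
        out //= math.factorial(int(k))
    return out


def constrained_permutations(design: StudyDesign, dataset_ids: list[str] | None = None,
                             B: int = 1000, seed: int | None = None,
                             exhaustive: bool = False) -> PermutationSet:
    """Draw (or enumerate) individual-level label permutations.

    With ``exhaustive=True`` all distinct assignments of the observed label
    multiset are enumerated (the identity assignment included) and ``B`` is
    ignored; only feasible for small designs (<= 10 individuals).
    """
    if dataset_ids is None:
        dataset_ids = design.dataset_ids
    sub = design.table[design.table["dataset_id"].isin(dataset_ids)]
    ind = (sub.groupby("individual_id")["group"].first()).sort_index()
    ind_ids = list(ind.index)
    obs = ind.to_numpy()
    ind_pos = {i: k for k, i in enumerate(ind_ids)}

    sample_maps, sample_orders = {}, {}
    for ds in dataset_ids:
        rows = sub[sub["dataset_id"] == ds]
        sample_maps[ds] = rows["individual_id"].map(ind_pos).to_numpy()
        sample_orders[ds] = list(rows["sample_id"])

    if exhaustive:
        if len(ind_ids) > 10:
            raise ValueError("exhaustive enumeration limited to <= 10 individuals")
        distinct = sorted(set(_iter_permutations(obs)))
        perm = np.array(distinct)
        logger.info("enumerated %d distinct label assignments", len(distinct))
    else:
        if B < 1:
            raise ValueError("B must be >= 1")
        n_distinct = n_distinct_assignments(obs)
        if B > n_distinct:
            logger.warning("B=%d exceeds the %d distinct label assignments; "
                           "sampling permutations with replacement", B, n_distinct)
        rng = np.random.default_rng(seed)
        perm = np.array([rng.permutation(obs) for _ in range(B)])
    return PermutationSet(individual_ids=ind_ids, observed_labels=obs,
                          perm_labels=perm, sample_maps=sample_maps,
                          sample_orders=sample_orders, seed=seed,
                          exhaustive=exhaustive)


# ---------------------------------------------------------------------------
# p-value machinery


def count_exceedances(perm_stats: np.ndarray, ref: np.ndarray,
                      rtol: float = TIE_RTOL) -> np.ndarray:
    """#{b : perm >= ref} per feature, ties (within rtol) as exceedances.

    ``perm_stats`` is features x B, ``ref`` a feature vector.
    """
    thr = ref - rtol * (np.abs(ref) + 1.0)
    return (perm_stats >= thr[:, None]).sum(axis=1)


def _self_inclusive_counts(perm_stats: np.ndarray, rtol: float = TIE_RTOL) -> np.ndarray:
    """For every permutation column b: #{b' : perm_b' >= perm_b}, self included."""
    F, B = perm_stats.shape
    out = np.empty((F, B), dtype=np.int64)
    for f in range(F):
        row = perm_stats[f]
        order = np.sort(row)
        thr = row - rtol * (np.abs(row) + 1.0)
        out[f] = B - np.searchsorted(order, thr, side="left")
    return out


def partial_pvalues(obs_stat: np.ndarray, perm_stats: np.ndarray) -> np.ndarray:
    """Permutation p-values p = (1 + #{b: perm >= obs}) / (1 + B).

    Non-finite observed statistics are flagged and assigned p = 1.
    """
    obs = np.asarray(obs_stat, dtype=float)
    B = perm_stats.shape[1]
    bad = ~np.isfinite(obs)
    if bad.any():
        logger.warning("%d features with non-finite statistics; p set to 1",
                       int(bad.sum()))
        obs = np.where(bad, np.finfo(float).max / 4, obs)
    counts = count_exceedances(np.where(np.isfinite(perm_stats), perm_stats, -np.inf),
                               obs)
    p = (1.0 + counts) / (1.0 + B)
    return np.where(bad, 1.0, p)


def liptak_combine(partial_p: np.ndarray, weights: np.ndarray | None = None,
                   n_permutations: int | None = None) -> np.ndarray:
    """Liptak/Stouffer combination T = sum_d w_d * Phi^-1(1 - p_d).

    ``partial_p`` is features x D (or a 1-D vector for one dataset).  Before
    the normal quantile, p is clipped from above to 1 - 1/(2(B+1)) when the
    permutation count is known (else to 1 - 1e-12) so the quantile stays
    finite.  Larger T means more significant.
    """
    P = np.atleast_2d(np.asarray(partial_p, dtype=float))
    if P.ndim == 1:
        P = P[:, None]
    if (P <= 0).any() or (P > 1).any():
        raise ValueError("partial p-values must lie in (0, 1]")
    D = P.shape[1]
    if weights is None:
        w = np.ones(D)
    else:
        w = np.asarray(weights, dtype=float)
        if (w < 0).any():
            raise ValueError("Liptak weights must be non-negative")
        if w.shape != (D,):
            raise ValueError(f"expected {D} weights, got shape {w.shape}")
    ceiling = 1 - 1 / (2 * (n_permutations + 1)) if n_permutations else 1 - 1e-12
    Pc = np.minimum(P, ceiling)
    return stats.norm.ppf(1.0 - Pc) @ w


def bh_fdr(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# the global NPC procedure


@dataclass
class NPCResult:
    """Per-feature NPC output plus provenance."""

    table: pd.DataFrame            # indexed by feature_id
    dataset_ids: list[str]
    B: int
    seed: int | None = None
    dropped_features: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        t = self.table
        gp = t["global_p"].to_numpy()
        if ((gp <= 0) | (gp > 1)).any():
            raise ValueError("global p-values outside (0, 1]")
        if (t["q"].to_numpy() + 1e-12 < gp).any():
            raise ValueError("q-values below their p-values")


class _DatasetEngine:
    """Fast group-F evaluation for arbitrary label vectors on one dataset.

    Residualises the data on the covariate-only design once; for a label
    vector only the 2-column group block changes, so the partial F is
    obtained from the reduced-vs-full RSS difference

        F = (dRSS / q) / (RSS_full / df)

    at O(features x samples) per permutation.
    """

    def __init__(self, Y: np.ndarray, dm: DesignMatrix, moderate: bool = False):
        self.dm = dm
        n, p = dm.X.shape
        self.q = len(dm.group_cols)
        self.df = n - p
        if self.df <= 0:
            raise ValueError("non-positive residual degrees of freedom")
        cov_cols = [j for j in range(p) if j not in dm.group_cols]
        Xr = dm.X[:, cov_cols]
        self.Mr = np.eye(n) - Xr @ np.linalg.pinv(Xr)
        self.Yr = Y @ self.Mr
        self.rss_red = np.einsum("fi,fi->f", self.Yr, self.Yr)
        self.moderate = moderate and Y.shape[0] >= 50

    def f_stats(self, labels: np.ndarray) -> np.ndarray:
        G = _group_dummies(labels)
        Gt = self.Mr @ G
        S = G.T @ Gt
        A = self.Yr @ G          # == Yr @ Gt since Mr is idempotent
        try:
            Si = np.linalg.inv(S)
        except np.linalg.LinAlgError:  # a group emptied by the permutation
            Si = np.linalg.pinv(S)
        drss = np.einsum("fq,fq->f", A @ Si, A)
        rss_full = np.maximum(self.rss_red - drss, 0.0)
        s2 = rss_full / self.df
        if self.moderate:
            d0, s0_sq = _estimate_inv_chisq_prior(s2[s2 > 0], self.df)
            if np.isfinite(s0_sq):
                if np.isinf(d0):
                    s2 = np.full_like(s2, s0_sq)
                else:
                    s2 = (d0 * s0_sq + self.df * s2) / (d0 + self.df)
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (drss / self.q) / s2
        return np.where(drss <= 1e-20 * (1.0 + self.rss_red), 0.0, F)


def npc_global(datasets: list[OmicsDataset], design: StudyDesign,
               B: int = 1000, seed: int | None = None,
               moderate: bool = False, weights: np.ndarray | None = None,
               permutation_set: PermutationSet | None = None,
               exhaustive: bool = False) -> NPCResult:
    """Run the full NPC procedure on two or more datasets.

    Steps: observed per-dataset group F; ``B`` pairing-constrained label
    permutations recomputing F with covariates fixed; partial permutation
    p-values for the observed data *and* for every permutation (each
    permutation scored against the full permutation pool, itself included);
    Liptak combination of both; global p by comparing observed T against the
    permuted T null; BH q-values across features.
    """
    if len(datasets) < 1:
        raise ValueError("need at least one dataset")
    ids = [d.dataset_id for d in datasets]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate dataset ids")

    features = list(datasets[0].feature_ids)
    common = set(features)
    for d in datasets[1:]:
        common &= set(d.feature_ids)
    if not common:
        raise ValueError("datasets share no features")
    features = [f for f in features if f in common]
    dropped = {d.dataset_id: sorted(set(d.feature_ids) - common) for d in datasets}
    n_drop = sum(len(v) for v in dropped.values())
    if n_drop:
        logger.info("dropped %d features outside the common universe", n_drop)

    pset = permutation_set
    if pset is None:
        pset = constrained_permutations(design, ids, B=B, seed=seed,
                                        exhaustive=exhaustive)
    B_eff = pset.B

    nF = len(features)
    z_table = _liptak_z_table(B_eff)
    if weights is None:
        weights = np.ones(len(datasets))
    else:
        weights = np.asarray(weights, dtype=float)
        if (weights < 0).any():
            raise ValueError("Liptak weights must be non-negative")

    T_obs = np.zeros(nF)
    T_perm = np.zeros((nF, B_eff))
    stat_cols, partial_cols = {}, {}
    for w_d, data in zip(weights, datasets):
        ds = data.dataset_id
        rows = design.subset(ds).set_index("sample_id").loc[data.sample_ids].reset_index()
        dm = build_design_matrix(rows)
        if pset.sample_orders[ds] != list(data.sample_ids):
            # permutation set built from the design table order; remap
            pos = {s: i for i, s in enumerate(pset.sample_orders[ds])}
            remap = np.array([pos[s] for s in data.sample_ids])
        else:
            remap = None
        Y = data.values.loc[features].to_numpy(dtype=float)
        engine = _DatasetEngine(Y, dm, moderate=moderate)

        obs_labels = pset.observed_dataset_labels(ds)
        if remap is not None:
            obs_labels = obs_labels[remap]
        F_obs = engine.f_stats(obs_labels)
        F_perm = np.empty((nF, B_eff))
        for b in range(B_eff):
            lab = pset.dataset_labels(ds, b)
            if remap is not None:
                lab = lab[remap]
            F_perm[:, b] = engine.f_stats(lab)

        c_obs = 1 + count_exceedances(F_perm, F_obs)            # in 1..B+1
        c_perm = 1 + _self_inclusive_counts(F_perm)             # in 2..B+1
        T_obs += w_d * z_table[c_obs]
        T_perm += w_d * z_table[c_perm]
        stat_cols[ds] = F_obs
        partial_cols[ds] = c_obs / (1.0 + B_eff)

    g_counts = 1 + count_exceedances(T_perm, T_obs)
    global_p = g_counts / (1.0 + B_eff)
    q = bh_fdr(global_p)

    cols: dict[str, np.ndarray] = {}
    for ds in ids:
        cols[f"stat_{ds}"] = stat_cols[ds]
    for ds in ids:
        cols[f"partial_p_{ds}"] = partial_cols[ds]
    cols["T_obs"] = T_obs
    cols["global_p"] = global_p
    cols["q"] = q
    table = pd.DataFrame(cols, index=pd.Index(features, name="feature_id"))
    return NPCResult(table=table, dataset_ids=ids, B=B_eff, seed=seed,
                     dropped_features=dropped)


def _liptak_z_table(B: int) -> np.ndarray:
    """z_table[c] = Phi^-1(1 - c/(B+1)) with the top cell clipped finite."""
    c = np.arange(B + 2, dtype=float)
    p = np.minimum(c / (B + 1), 1 - 1 / (2 * (B + 1)))
    p[0] = 0.5  # index 0 unused
    return stats.norm.ppf(1.0 - p)


def select_features(result: NPCResult, p_max: float, q_max: float) -> list[str]:
    """Features with global p <= p_max and q <= q_max, sorted by (p, id)."""
    t = result.table
    keep = t[(t["global_p"] <= p_max) & (t["q"] <= q_max)].reset_index()
    keep = keep.sort_values(["global_p", "feature_id"])
    return list(keep["feature_id"])
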