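"""Per-feature linear models with covariates.

Each dataset is modelled with a single three-group linear model

    y_f = b0 + b_RR * I(RR) + b_SP * I(SP) + b_age * age_c + b_sex * I(M) + e

fitted by ordinary least squares, vectorised over features.  The group-factor
partial F statistic (2 numerator df) is the partial-test statistic fed to the
permutation NPC; per-contrast t statistics (HC-RR: the RR coefficient;
RR-SP: SP minus RR) supply direction.  Optional empirical-Bayes variance
moderation shrinks the residual variances toward a common prior, giving a
limma-like moderated statistic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import special, stats
from scipy.optimize import brentq

from .datatypes import OmicsDataset

logger = logging.getLogger(__name__)

CONTRASTS = ("HC-RR", "RR-SP")


class RankError(ValueError):
    """Design matrix is rank deficient; message names collinear columns."""


@dataclass
class DesignMatrix:
    """Fixed-effect design for one dataset: intercept, group dummies, covariates."""

    X: np.ndarray  # n_samples x n_columns
    columns: list[str]
    sample_ids: list[str]
    group_cols: list[int]  # indices of the group indicator columns (RR, SP)

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]


def _group_dummies(labels: np.ndarray) -> np.ndarray:
    out = np.empty((len(labels), 2))
    out[:, 0] = labels == "RR"
    out[:, 1] = labels == "SP"
    return out


def build_design_matrix(design_rows: pd.DataFrame, reference_group: str = "HC") -> DesignMatrix:
    """Treatment-coded design: intercept, RR, SP, centred age, sex indicator.

    ``design_rows`` is one dataset's slice of a :class:`StudyDesign` table.
    Age is mean-centred within the dataset; a zero-variance age column is
    dropped with a warning.  Raises :class:`RankError` when columns are
    collinear (e.g. a group perfectly confounded with sex).
    """
    groups_present = sorted(design_rows["group"].unique())
    if len(groups_present) < 2:
        raise ValueError(f"need >=2 groups, got {groups_present}")
    if reference_group != "HC":
        raise NotImplementedError("HC is the only supported reference group")

    labels = design_rows["group"].to_numpy()
    cols: list[np.ndarray] = [np.ones(len(design_rows))]
    names = ["intercept"]
    dummies = _group_dummies(labels)
    group_cols = []
    for j, g in enumerate(("RR", "SP")):
        if g in groups_present:
            group_cols.append(len(cols))
            cols.append(dummies[:, j])
            names.append(f"group{g}")

    age = design_rows["age"].to_numpy(dtype=float)
    if np.ptp(age) == 0:
        logger.warning("age has zero variance; dropping age column")
    else:
        cols.append(age - age.mean())
        names.append("age")
    sex = (design_rows["sex"].to_numpy() == "M").astype(float)
    if np.ptp(sex) == 0:
        logger.warning("sex has zero variance; dropping sex column")
    else:
        cols.append(sex)
        names.append("sexM")

    X = np.column_stack(cols)
    if X.shape[0] <= X.shape[1]:
        raise ValueError(
            f"{X.shape[0]} samples cannot identify {X.shape[1]} coefficients"
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify the offending columns by greedy removal
        bad = []
        keep = list(range(X.shape[1]))
        for j in range(X.shape[1] - 1, -1, -1):
            reduced = [k for k in keep if k != j]
            if np.linalg.matrix_rank(X[:, reduced]) == rank:
                bad.append(names[j])
                keep = reduced
                if len(keep) == rank:
                    break
        raise RankError(f"design matrix rank deficient; collinear columns: {bad}")
    return DesignMatrix(X=X, columns=names, sample_ids=list(design_rows["sample_id"]),
                        group_cols=group_cols)


@dataclass
class ModelFits:
    """OLS results for every feature of one dataset."""

    coef: np.ndarray          # n_features x p
    sigma2: np.ndarray        # residual variance, n_features
    df_resid: int
    xtx_inv: np.ndarray       # p x p, shared across features
    columns: list[str]
    feature_ids: list[str]
    sigma2_mod: np.ndarray | None = None  # moderated variance
    df_prior: float = 0.0

    @property
    def variance(self) -> np.ndarray:
        """Residual variance used for statistics (moderated when available)."""
        return self.sigma2 if self.sigma2_mod is None else self.sigma2_mod

    @property
    def df_total(self) -> float:
        return self.df_resid + (0.0 if self.sigma2_mod is None else self.df_prior)


def fit_feature_models(data: OmicsDataset, dm: DesignMatrix) -> ModelFits:
    """Vectorised per-feature OLS of the data matrix on the design."""
    if list(data.sample_ids) != dm.sample_ids:
        raise ValueError("sample order of data and design matrix disagree")
    Y = data.values.to_numpy(dtype=float)  # features x samples
    return fit_matrix(Y, dm, feature_ids=data.feature_ids)


def fit_matrix(Y: np.ndarray, dm: DesignMatrix, feature_ids: list[str] | None = None) -> ModelFits:
    n, p = dm.X.shape
    df = n - p
    if df <= 0:
        raise ValueError(f"non-positive residual df ({n} samples, {p} columns)")
    xtx = dm.X.T @ dm.X
    xtx_inv = np.linalg.inv(xtx)
    coef = Y @ dm.X @ xtx_inv  # features x p
    resid = Y - coef @ dm.X.T
    rss = np.einsum("fi,fi->f", resid, resid)
    sigma2 = rss / df
    ids = feature_ids if feature_ids is not None else [f"f{i}" for i in range(Y.shape[0])]
    return ModelFits(coef=coef, sigma2=sigma2, df_resid=df, xtx_inv=xtx_inv,
                     columns=dm.columns, feature_ids=list(ids))


def _estimate_inv_chisq_prior(sigma2: np.ndarray, df: int) -> tuple[float, float]:
    """Method-of-moments fit of a scaled-inverse-chi-square prior on log s2.

    If s2 ~ s0^2 * d0 / chi2(d0) * chi2(df)/df (the usual hierarchical model),
    then  var(log s2) = psi'(df/2) + psi'(d0/2)  and
          E(log s2)  = log s0^2 + [psi(df/2) - log(df/2)] - [psi(d0/2) - log(d0/2)].
    Solves the first equation for d0 by root finding, then the second for s0^2.
    """
    z = np.log(sigma2[sigma2 > 0])
    if z.var(ddof=1) < 1e-12:
        # degenerate: no dispersion to shrink, leave variances untouched
        return np.inf, float(np.exp(z.mean()))
    excess = z.var(ddof=1) - special.polygamma(1, df / 2)
    if not np.isfinite(excess) or excess <= 0:
        return np.inf, float(np.exp(z.mean() - special.digamma(df / 2) + np.log(df / 2)))
    f = lambda d0: special.polygamma(1, d0 / 2) - excess
    lo, hi = 1e-3, 1e6
    if f(lo) < 0 or f(hi) > 0:
        return np.inf, float(np.exp(z.mean()))
    d0 = brentq(f, lo, hi)
    log_s0 = (z.mean() - (special.digamma(df / 2) - np.log(df / 2))
              + (special.digamma(d0 / 2) - np.log(d0 / 2)))
    return float(d0), float(np.exp(log_s0))


def moderate_variances(fits: ModelFits, enabled: bool = True) -> ModelFits:
    """Empirical-Bayes shrinkage of residual variances toward a common prior.

    Posterior variance s~^2 = (d0*s0^2 + df*s^2) / (d0 + df).  With
    ``enabled=False`` the fits pass through unchanged.  Falls back to the
    identity (with a warning) when the moment estimates are non-finite.
    """
    if not enabled:
        return fits
    if len(fits.sigma2) < 50:
        raise ValueError("variance moderation needs >= 50 features")
    d0, s0_sq = _estimate_inv_chisq_prior(fits.sigma2, fits.df_resid)
    if not np.isfinite(s0_sq):
        logger.warning("variance moderation: non-finite moment estimates; skipped")
        return fits
    if np.isinf(d0):
        s2_mod = np.full_like(fits.sigma2, s0_sq)
        return replace(fits, sigma2_mod=s2_mod, df_prior=np.inf)
    s2_mod = (d0 * s0_sq + fits.df_resid * fits.sigma2) / (d0 + fits.df_resid)
    return replace(fits, sigma2_mod=s2_mod, df_prior=d0)


def group_f_statistics(fits: ModelFits, dm: DesignMatrix) -> np.ndarray:
    """Partial F for the group factor (joint nullity of RR and SP), 2 num. df.

    F = (C b)' [C (X'X)^-1 C']^-1 (C b) / (q * s2) with q = 2 and s2 the
    (possibly moderated) residual variance; zero-variance features yield
    F = 0 when the numerator is also zero, +inf otherwise.
    """
    q = len(dm.group_cols)
    C = np.zeros((q, fits.coef.shape[1]))
    for r, j in enumerate(dm.group_cols):
        C[r, j] = 1.0
    mid = np.linalg.inv(C @ fits.xtx_inv @ C.T)
    cb = fits.coef @ C.T  # features x q
    num = np.einsum("fq,qr,fr->f", cb, mid, cb) / q
    # numerically-zero numerators (noiseless null fits) count as exactly zero
    scale = 1.0 + np.einsum("fp,fp->f", fits.coef, fits.coef)
    with np.errstate(divide="ignore", invalid="ignore"):
        F = num / fits.variance
    F = np.where(num <= 1e-20 * scale, 0.0, F)
    return F


def f_pvalues(F: np.ndarray, fits: ModelFits, dm: DesignMatrix) -> np.ndarray:
    """Parametric p-values of the group F (used for diagnostics, not NPC)."""
    q = len(dm.group_cols)
    return stats.f.sf(F, q, fits.df_total)


def contrast_t_statistics(fits: ModelFits, dm: DesignMatrix, contrast: str) -> pd.DataFrame:
    """t statistic and effect size for one disease-stage contrast.

    ``HC-RR`` tests the RR coefficient; ``RR-SP`` tests SP minus RR.  The
    sign convention is positive = upregulated in the later stage.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    c = np.zeros(fits.coef.shape[1])
    needed = ["groupRR"] if contrast == "HC-RR" else ["groupRR", "groupSP"]
    missing = [g for g in needed if g not in dm.columns]
    if missing:
        raise ValueError(f"contrast {contrast} needs columns {missing}")
    j_rr = dm.columns.index("groupRR")
    if contrast == "HC-RR":
        c[j_rr] = 1.0
    else:
        c[dm.columns.index("groupSP")] = 1.0
        c[j_rr] = -1.0
    effect = fits.coef @ c
    var_c = float(c @ fits.xtx_inv @ c)
    scale = 1.0 + np.abs(fits.coef).max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = effect / np.sqrt(fits.variance * var_c)
    t = np.where(np.abs(effect) <= 1e-12 * scale, 0.0, t)
    return pd.DataFrame({"feature_id": fits.feature_ids, "t": t, "effect": effect})


def assign_expression_groups(t_stats: dict[str, dict[str, pd.DataFrame]],
                             feature_ids: list[str]) -> pd.Series:
    """Direction-pattern groups G1..G5 across two datasets and two contrasts.

    When the sign of t agrees between datasets for BOTH contrasts, the
    shared sign pair maps to G1 (+,+), G2 (+,-), G3 (-,+), G4 (-,-); any
    discordance — or an exactly-zero t — yields G5.
    """
    datasets = sorted(t_stats)
    if len(datasets) != 2:
        raise ValueError("direction groups need exactly two datasets")
    signs = {}
    for ds in datasets:
        for ct in CONTRASTS:
            tab = t_stats[ds][ct].set_index("feature_id")["t"]
            signs[(ds, ct)] = np.sign(tab.reindex(feature_ids).to_numpy())
    d1, d2 = datasets
    labels = []
    pattern = {(1, 1): "G1", (1, -1): "G2", (-1, 1): "G3", (-1, -1): "G4"}
    for i, f in enumerate(feature_ids):
        s1 = (signs[(d1, CONTRASTS[0])][i], signs[(d1, CONTRASTS[1])][i])
        s2 = (signs[(d2, CONTRASTS[0])][i], signs[(d2, CONTRASTS[1])][i])
        if 0 in s1 or 0 in s2:
            logger.info("feature %s has a zero t statistic; assigned G5", f)
            labels.append("G5")
        elif s1 == s2:
            labels.append(pattern[s1])
        else:
            labels.append("G5")
    return pd.Series(labels, index=feature_ids, name="direction_group")
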