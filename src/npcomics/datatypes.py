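"""Shared data containers for paired multi-omics studies.

A *study* consists of two (or more) datasets — e.g. CD4 and CD8 T cells —
whose sample sets overlap partially at the individual level.  All containers
are thin wrappers around pandas objects with validation of the invariants
the permutation machinery relies on (unique sample ids, consistent
per-individual metadata, in-range methylation values).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

GROUPS = ("HC", "RR", "SP")
SEXES = ("F", "M")

DESIGN_COLUMNS = ["sample_id", "individual_id", "dataset_id", "group", "age", "sex"]


class InvalidDesignError(ValueError):
    """Raised when a study design violates a structural invariant."""


@dataclass
class StudyDesign:
    """Sample-level metadata table defining groups, covariates and pairing.

    ``table`` has one row per sample with columns ``sample_id``,
    ``individual_id``, ``dataset_id``, ``group`` (HC/RR/SP), ``age`` and
    ``sex`` (F/M).  An individual contributes at most one sample per dataset;
    individuals present in several datasets ("paired") must carry identical
    group/age/sex everywhere — these are the units whose disease labels the
    constrained permutations shuffle.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        missing = [c for c in DESIGN_COLUMNS if c not in t.columns]
        if missing:
            raise InvalidDesignError(f"design table missing columns {missing}")
        self.table = t = t.reset_index(drop=True).copy()
        if t["sample_id"].duplicated().any():
            dupes = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise InvalidDesignError(f"duplicate sample ids: {dupes}")
        if t.duplicated(subset=["individual_id", "dataset_id"]).any():
            raise InvalidDesignError(
                "an individual contributes more than one sample to a dataset"
            )
        bad_group = set(t["group"]) - set(GROUPS)
        if bad_group:
            raise InvalidDesignError(f"unknown group labels: {sorted(bad_group)}")
        bad_sex = set(t["sex"]) - set(SEXES)
        if bad_sex:
            raise InvalidDesignError(f"unknown sex labels: {sorted(bad_sex)}")
        if (t["age"] <= 0).any():
            raise InvalidDesignError("ages must be positive")
        per_ind = t.groupby("individual_id")[["group", "age", "sex"]].nunique()
        inconsistent = per_ind.index[(per_ind > 1).any(axis=1)]
        if len(inconsistent):
            raise InvalidDesignError(
                f"individuals with inconsistent metadata across datasets: "
                f"{list(inconsistent)}"
            )
        for ds, sub in t.groupby("dataset_id"):
            counts = sub["group"].value_counts()
            if (counts >= 2).sum() < 2:
                # group F undefined for such a dataset; model fitting will
                # reject it, but the permutation structure is still usable
                logger.warning(
                    "dataset %r has <2 groups with >=2 samples (%s); "
                    "the group F statistic is undefined there", ds,
                    counts.to_dict())

    @property
    def dataset_ids(self) -> list[str]:
        return sorted(self.table["dataset_id"].unique())

    def subset(self, dataset_id: str) -> pd.DataFrame:
        """Rows of one dataset, in stored order."""
        return self.table[self.table["dataset_id"] == dataset_id].reset_index(drop=True)

    def individuals(self) -> pd.DataFrame:
        """One row per distinct individual with group and dataset membership."""
        t = self.table
        agg = t.groupby("individual_id").agg(
            group=("group", "first"),
            age=("age", "first"),
            sex=("sex", "first"),
            n_datasets=("dataset_id", "nunique"),
        )
        return agg.reset_index()

    def paired_individuals(self) -> list[str]:
        ind = self.individuals()
        return ind.loc[ind["n_datasets"] >= 2, "individual_id"].tolist()

    def paired_only(self) -> "StudyDesign":
        """Restrict to individuals present in every dataset (paired subset)."""
        n_ds = self.table["dataset_id"].nunique()
        ind = self.table.groupby("individual_id")["dataset_id"].nunique()
        keep = ind.index[ind == n_ds]
        return StudyDesign(self.table[self.table["individual_id"].isin(keep)])


@dataclass
class OmicsDataset:
    """One feature x sample matrix for a single dataset and modality.

    ``values`` is a DataFrame indexed by feature id with sample ids as
    columns.  Methylation values are beta fractions in [0, 1]; expression
    values are log2 CPM.  ``counts`` optionally carries the raw negative
    binomial counts expression was derived from.
    """

    dataset_id: str
    modality: str  # "expression" | "methylation"
    values: pd.DataFrame
    counts: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.modality not in ("expression", "methylation"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if self.values.isna().any().any():
            raise ValueError("omics matrix contains missing values")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate feature ids")
        if self.modality == "methylation":
            v = self.values.to_numpy()
            if (v < 0).any() or (v > 1).any():
                raise ValueError("methylation beta values must lie in [0, 1]")

    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def check_samples(self, design: StudyDesign) -> None:
        known = set(design.subset(self.dataset_id)["sample_id"])
        unknown = set(self.sample_ids) - known
        if unknown:
            raise ValueError(
                f"samples not in design for dataset {self.dataset_id!r}: "
                f"{sorted(unknown)}"
            )


@dataclass
class FeatureAnnotation:
    """Genomic coordinates for genes (intervals + strand) and probes (points).

    Coordinates are 0-based half-open internally.  Probes are single
    positions (start == end).
    """

    table: pd.DataFrame  # feature_id, feature_type, chrom, start, end, strand

    def __post_init__(self) -> None:
        t = self.table.reset_index(drop=True).copy()
        if (t["start"] < 0).any():
            raise ValueError("negative start coordinate")
        genes = t[t["feature_type"] == "gene"]
        if (genes["end"] <= genes["start"]).any():
            raise ValueError("gene end must exceed start")
        probes = t[t["feature_type"] == "probe"]
        if (probes["end"] != probes["start"]).any():
            raise ValueError("probes must have a single position (start == end)")
        self.table = t

    def genes(self) -> pd.DataFrame:
        return self.table[self.table["feature_type"] == "gene"].reset_index(drop=True)

    def probes(self) -> pd.DataFrame:
        return self.table[self.table["feature_type"] == "probe"].reset_index(drop=True)


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the generators, for recovery tests.

    ``effects``: per feature and dataset, the injected RR and SP coefficient
    shifts and flags (``is_de``, ``shared``).  ``cis_links``: injected
    gene-probe couplings with their target Spearman rho.  ``dropped``:
    feature ids removed by the expression abundance filter.
    """

    effects: pd.DataFrame = field(default_factory=pd.DataFrame)
    cis_links: pd.DataFrame = field(default_factory=pd.DataFrame)
    dropped: list[str] = field(default_factory=list)

    def de_features(self, dataset_id: str | None = None) -> list[str]:
        if self.effects.empty:
            return []
        eff = self.effects
        if dataset_id is not None:
            eff = eff[eff["dataset_id"] == dataset_id]
        return sorted(eff.loc[eff["is_de"], "feature_id"].unique())
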