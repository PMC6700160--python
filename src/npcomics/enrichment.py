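"""Rank-based gene-set enrichment over per-gene p-values.

Genes are ranked by ascending p-value (from a per-dataset differential
analysis or from the NPC global p-values — the test is invariant to any
strictly monotone transform of the scores) and each gene set is compared to
its complement with a one-sided rank-sum test asking whether the set sits
toward the top of the ranking.  Sets are size-filtered after intersection
with the analysis universe: effective sizes below ``min_size`` or above
``max_size`` are excluded.  BH q-values are reported across sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .npc import bh_fdr

logger = logging.getLogger(__name__)

MIN_SIZE = 20
MAX_SIZE = 200


@dataclass
class GeneSetCollection:
    """Named gene sets plus the universe of analysed genes."""

    sets: dict[str, set[str]]
    universe: set[str] = field(default_factory=set)

    def __len__(self) -> int:
        return len(self.sets)


def filter_sets(collection: GeneSetCollection, universe: set[str] | None = None,
                min_size: int = MIN_SIZE, max_size: int = MAX_SIZE) -> GeneSetCollection:
    """Intersect sets with the universe and drop out-of-range effective sizes.

    Boundaries are inclusive: sets of exactly ``min_size`` or ``max_size``
    universe members are retained.
    """
    uni = set(universe) if universe is not None else set(collection.universe)
    if not uni:
        raise ValueError("an analysis universe is required")
    kept = {}
    for name, members in collection.sets.items():
        eff = members & uni
        if min_size <= len(eff) <= max_size:
            kept[name] = eff
    logger.info("retained %d/%d gene sets (size %d-%d within universe of %d)",
                len(kept), len(collection.sets), min_size, max_size, len(uni))
    return GeneSetCollection(sets=kept, universe=uni)


def rank_set_test(gene_scores: pd.Series, collection: GeneSetCollection) -> pd.DataFrame:
    """One-sided rank-sum enrichment of each set toward small scores.

    ``gene_scores`` maps gene id -> p-value (smaller = more interesting) and
    must cover the universe.  Returns per set: effective size, the set's
    rank sum (ranks of members among all universe genes, average ranks for
    ties), the one-sided p (set scores smaller than complement) and BH q,
    sorted by p.
    """
    uni = sorted(collection.universe)
    missing = [g for g in uni if g not in gene_scores.index]
    if missing:
        raise ValueError(f"scores missing for {len(missing)} universe genes")
    scores = gene_scores.loc[uni]
    ranks = pd.Series(stats.rankdata(scores.to_numpy()), index=uni)

    rows = []
    for name, members in collection.sets.items():
        m = sorted(members)
        in_set = scores.loc[m].to_numpy()
        out_set = scores.drop(index=m).to_numpy()
        res = stats.mannwhitneyu(in_set, out_set, alternative="less")
        rows.append({"set": name, "size": len(m),
                     "rank_sum": float(ranks.loc[m].sum()),
                     "p": float(res.pvalue)})
    out = pd.DataFrame(rows, columns=["set", "size", "rank_sum", "p"])
    if len(out):
        out["q"] = bh_fdr(out["p"].to_numpy())
        out = out.sort_values(["p", "set"]).reset_index(drop=True)
    else:
        out["q"] = []
    return out
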