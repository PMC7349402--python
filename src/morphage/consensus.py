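"""Consensus feature sets across cross-validation rounds.

Two aggregation paths: robust rank aggregation (RRA), which scores each
feature by comparing its normalized ranks across rounds to the order
statistics of uniform null rankings via beta distributions (Bonferroni
corrected), and a frequency criterion that keeps features selected in at
least a fixed share of rounds (for sparse selectors such as the lasso).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import beta as beta_dist

from .schema import CATEGORIES, FeatureSchema


@dataclass
class ConsensusSet:
    """Aggregated feature set with per-feature scores.

    ``table`` (index feature_id) has columns ``score`` (rho for RRA,
    frequency for the frequency path) and ``p_adj`` (NaN for frequency);
    rows are the selected features in consensus order. ``full_table``
    keeps all candidate features for diagnostics.
    """

    table: pd.DataFrame = field(repr=False)
    method: str = "rra"
    full_table: pd.DataFrame | None = field(repr=False, default=None)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.table.index)

    def __len__(self) -> int:
        return len(self.table)

    def truncate(self, n: int) -> "ConsensusSet":
        return ConsensusSet(self.table.iloc[:n].copy(), self.method,
                            self.full_table)


def rra_scores(rank_lists: list[list[str]], universe: list[str]) -> pd.DataFrame:
    """Per-feature rho scores and Bonferroni p-values.

    Normalized ranks are position / |universe|. Features absent from a
    partial list contribute no order statistic there (they are treated as
    uniform beyond the truncation under the null); rho is the minimum over
    the observed order statistics j of BetaCDF(r_(j); j, L-j+1), and
    p = min(rho * L, 1).
    """
    if len(rank_lists) < 1:
        raise ValueError("need at least one rank list")
    universe = list(universe)
    pos = {f: i for i, f in enumerate(universe)}
    u = len(universe)
    n_lists = len(rank_lists)
    r = np.full((u, n_lists), np.nan)
    for j, lst in enumerate(rank_lists):
        for rank_pos, f in enumerate(lst, start=1):
            if f not in pos:
                raise ValueError(f"feature {f!r} outside the universe")
            r[pos[f], j] = rank_pos / u
    r_sorted = np.sort(r, axis=1)  # NaNs sort to the end
    rho = np.ones(u)
    for j in range(n_lists):
        col = r_sorted[:, j]
        observed = ~np.isnan(col)
        if not observed.any():
            continue
        cdf = beta_dist.cdf(col[observed], j + 1, n_lists - j)
        rho[observed] = np.minimum(rho[observed], cdf)
    p_adj = np.minimum(rho * n_lists, 1.0)
    return pd.DataFrame({"score": rho, "p_adj": p_adj},
                        index=pd.Index(universe, name="feature_id"))


def rra_aggregate(rank_lists: list[list[str]], universe: list[str],
                  top_k: int | None = None, alpha: float = 0.05,
                  truncate_to: int | None = None) -> ConsensusSet:
    """Aggregate (partial) rankings into a consensus set.

    ``top_k`` truncates every input list first; features with Bonferroni
    p <= alpha form the set, ordered by p then score; ``truncate_to``
    additionally caps the set size (e.g. at k_opt).
    """
    if len(rank_lists) == 1:
        # single list: consensus is the list itself
        table = pd.DataFrame(
            {"score": np.linspace(0, 1, len(rank_lists[0]), endpoint=False),
             "p_adj": np.ones(len(rank_lists[0]))},
            index=pd.Index(rank_lists[0], name="feature_id"))
        return ConsensusSet(table, "rra", table)
    lists = [list(lst)[:top_k] if top_k else list(lst) for lst in rank_lists]
    full = rra_scores(lists, universe)
    full = full.sort_values(["p_adj", "score"], kind="stable")
    selected = full[full["p_adj"] <= alpha]
    if truncate_to is not None:
        selected = selected.iloc[:truncate_to]
    return ConsensusSet(selected.copy(), "rra", full)


def frequency_select(selection_matrix: np.ndarray, threshold: float = 0.8,
                     feature_ids: list[str] | None = None,
                     truncate_to: int | None = None) -> ConsensusSet:
    """Features selected in at least ``threshold`` of the rounds."""
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    m = np.asarray(selection_matrix)
    freq = m.mean(axis=0)
    ids = feature_ids or [f"f{j}" for j in range(m.shape[1])]
    full = pd.DataFrame({"score": freq, "p_adj": np.nan},
                        index=pd.Index(ids, name="feature_id"))
    full = full.sort_values("score", ascending=False, kind="stable")
    selected = full[full["score"] >= threshold]
    if truncate_to is not None:
        selected = selected.iloc[:truncate_to]
    return ConsensusSet(selected.copy(), "frequency", full)


def category_frequency(consensus: ConsensusSet,
                       schema: FeatureSchema) -> pd.Series:
    """Relative frequency of each feature category in the consensus set."""
    if len(consensus) == 0:
        return pd.Series(0.0, index=pd.Index(CATEGORIES, name="category"))
    cats = [schema.category_of(f) for f in consensus.feature_ids]
    counts = pd.Series(cats).value_counts()
    freq = counts.reindex(CATEGORIES, fill_value=0) / len(consensus)
    freq.index.name = "category"
    return freq


def roi_frequency(consensus: ConsensusSet,
                  schema: FeatureSchema) -> pd.DataFrame:
    """Occurrence count and fraction of each region, descending."""
    if len(consensus) == 0:
        return pd.DataFrame(columns=["count", "fraction"],
                            index=pd.Index([], name="region"))
    regions = [schema.region_of(f) for f in consensus.feature_ids]
    counts = pd.Series(regions).value_counts()
    out = pd.DataFrame({"count": counts,
                        "fraction": counts / len(consensus)})
    out.index.name = "region"
    return out
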