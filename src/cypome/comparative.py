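"""Family-level comparative analysis across species and lifestyles.

Three views of the assigned CYPome are produced here:

* a species x family presence/absence matrix, encoded -3 (absent, green) /
  3 (present, red) for import into MeV-style heatmap viewers, with
  agglomerative clustering (Euclidean metric, average linkage) of both axes;
* the lifestyle Venn partition of family sets (shared vs unique families
  between saprotrophic and ectomycorrhizal species);
* summary statistics: per-group totals, half-away-rounded means, extremes
  with their species, and "bloom" families whose cohort-wide member count
  reaches the bloom threshold (>=30 by default).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list
from scipy.spatial.distance import pdist, squareform

from .config import DEFAULT_RULES, RulesConfig, round_half_away


def presence_matrix(families_by_species: Mapping[str, Sequence[str]],
                    all_species: Sequence[str],
                    all_families: Sequence[str],
                    rules: RulesConfig = DEFAULT_RULES) -> pd.DataFrame:
    """Species x family matrix of presence/absence codes.

    A cell holds ``rules.presence_code`` iff at least one member of that
    family was assigned in that species, else ``rules.absence_code``.
    """
    if not list(all_species) or not list(all_families):
        raise ValueError("species and family universes must be non-empty")
    unknown = set(families_by_species) - set(all_species)
    if unknown:
        raise ValueError(f"assignments reference unknown species: "
                         f"{sorted(unknown)}")
    mat = pd.DataFrame(
        rules.absence_code,
        index=pd.Index(all_species, name="species_id"),
        columns=pd.Index(all_families, name="family"),
        dtype=int,
    )
    for species, families in families_by_species.items():
        for fam in families:
            if fam not in mat.columns:
                raise ValueError(f"unknown family {fam!r} for {species!r}")
            mat.loc[species, fam] = rules.presence_code
    return mat


def conserved_families(pm: pd.DataFrame, k: int,
                       rules: RulesConfig = DEFAULT_RULES) -> set[str]:
    """Families present in at least ``k`` species (k = all rows gives strict
    conservation)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(pm.index):
        raise ValueError(f"k={k} exceeds species count {len(pm.index)}")
    counts = (pm == rules.presence_code).sum(axis=0)
    return set(counts.index[counts >= k])


def average_linkage(data: np.ndarray) -> np.ndarray:
    """Agglomerative average-linkage clustering with deterministic ties.

    Euclidean distances between rows; at each step the closest pair of
    clusters is merged, equal distances resolved by the smallest cluster-index
    pair (with rows pre-sorted by label this is label order).  Cluster-to-
    cluster distances follow the Lance-Williams update for average linkage.
    Returns a merge tree in scipy ``linkage`` format (cluster_a, cluster_b,
    height, size), so scipy's dendrogram utilities apply.
    """
    n = data.shape[0]
    if n < 2:
        raise ValueError("need at least two rows to cluster")
    dist = squareform(pdist(data, metric="euclidean"))
    sizes = {i: 1 for i in range(n)}
    active = list(range(n))
    d: dict[tuple[int, int], float] = {
        (i, j): dist[i, j] for i in range(n) for j in range(i + 1, n)
    }
    z = np.zeros((n - 1, 4))
    next_id = n
    for step in range(n - 1):
        best_pair, best_dist = None, None
        for ai in range(len(active)):
            for bi in range(ai + 1, len(active)):
                a, b = active[ai], active[bi]
                dd = d[(a, b)]
                if best_dist is None or dd < best_dist - 1e-12:
                    best_pair, best_dist = (a, b), dd
        a, b = best_pair
        z[step] = (a, b, best_dist, sizes[a] + sizes[b])
        for k in active:
            if k in (a, b):
                continue
            da = d[tuple(sorted((a, k)))]
            db = d[tuple(sorted((b, k)))]
            d[(k, next_id)] = (sizes[a] * da + sizes[b] * db) / (
                sizes[a] + sizes[b])
        sizes[next_id] = sizes[a] + sizes[b]
        active = [k for k in active if k not in (a, b)] + [next_id]
        next_id += 1
    return z


def cluster_rows_cols(pm: pd.DataFrame,
                      method: Optional[str] = None,
                      ) -> tuple[list[str], list[str],
                                 Optional[np.ndarray], Optional[np.ndarray]]:
    """Hierarchically cluster both axes of the presence matrix.

    Euclidean metric, average linkage.  Rows and columns are first sorted by
    label so equal-distance merges are resolved the same way on every run.
    Returns (row order, column order, row merge tree, column merge tree); a
    degenerate axis of length 1 keeps its identity ordering with a ``None``
    merge tree.
    """
    method = method or DEFAULT_RULES.linkage_method
    if method != "average":
        raise ValueError("only average linkage is implemented")

    def _axis(df: pd.DataFrame):
        labels = sorted(df.index)
        data = df.loc[labels].to_numpy(dtype=float)
        if len(labels) < 2:
            return list(labels), None
        z = average_linkage(data)
        order = [labels[i] for i in leaves_list(z)]
        return order, z

    row_order, row_z = _axis(pm)
    col_order, col_z = _axis(pm.T)
    return row_order, col_order, row_z, col_z


@dataclass
class VennPartition:
    shared_families: set[str]
    unique_to_group: dict[str, set[str]]
    group_totals: dict[str, int]

    @property
    def union_size(self) -> int:
        return len(self.shared_families) + sum(
            len(s) for s in self.unique_to_group.values())


def venn_partition(family_sets_by_group: Mapping[str, set]) -> VennPartition:
    """Partition family sets into shared vs group-unique families.

    For two groups this is the classic Venn split; for N groups "shared"
    means present in every group and "unique" means present in exactly one.
    """
    if not family_sets_by_group:
        raise ValueError("no groups supplied")
    groups = {g: set(s) for g, s in family_sets_by_group.items()}
    shared = set.intersection(*groups.values())
    unique = {
        g: s - set.union(set(), *(o for h, o in groups.items() if h != g))
        for g, s in groups.items()
    }
    return VennPartition(
        shared_families=shared,
        unique_to_group=unique,
        group_totals={g: len(s) for g, s in groups.items()},
    )


@dataclass
class GroupStats:
    total: int
    mean: int
    min_count: int
    max_count: int
    argmin_species: str
    argmax_species: str
    n_species: int


@dataclass
class SummaryStats:
    overall: GroupStats
    per_group: dict[str, GroupStats]
    bloom_families: list[str] = field(default_factory=list)


def _group_stats(df: pd.DataFrame, count_col: str) -> GroupStats:
    counts = df[count_col]
    imin = counts.idxmin()
    imax = counts.idxmax()
    return GroupStats(
        total=int(counts.sum()),
        mean=round_half_away(counts.mean()),
        min_count=int(counts.min()),
        max_count=int(counts.max()),
        argmin_species=str(df.loc[imin, "species_id"]),
        argmax_species=str(df.loc[imax, "species_id"]),
        n_species=len(df),
    )


def summary_stats(table: pd.DataFrame,
                  count_col: str = "p450s",
                  family_counts: Optional[pd.DataFrame] = None,
                  rules: RulesConfig = DEFAULT_RULES) -> SummaryStats:
    """Per-lifestyle and overall count statistics.

    ``table`` needs columns ``species_id``, ``lifestyle`` and ``count_col``.
    When a per-family member-count table (columns ``family``, ``members``) is
    supplied, families at or above the bloom threshold are listed, ordered by
    descending member count.
    """
    if table.empty:
        raise ValueError("empty species table")
    for col in ("species_id", "lifestyle", count_col):
        if col not in table.columns:
            raise ValueError(f"species table missing column {col!r}")
    if table["lifestyle"].isna().any():
        raise ValueError("species missing lifestyle label")
    per_group = {
        lifestyle: _group_stats(sub, count_col)
        for lifestyle, sub in table.groupby("lifestyle")
    }
    blooms: list[str] = []
    if family_counts is not None:
        hot = family_counts[
            family_counts["members"] >= rules.bloom_member_threshold]
        hot = hot.sort_values(["members", "family"],
                              ascending=[False, True])
        blooms = list(hot["family"])
    return SummaryStats(
        overall=_group_stats(table, count_col),
        per_group=per_group,
        bloom_families=blooms,
    )


def plot_presence_heatmap(pm: pd.DataFrame, path,
                          rules: RulesConfig = DEFAULT_RULES) -> None:
    """Optional heatmap figure of the clustered presence matrix (red present,
    green absent)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    row_order, col_order, _, _ = cluster_rows_cols(pm)
    data = pm.loc[row_order, col_order]
    fig, ax = plt.subplots(
        figsize=(max(6, 0.12 * len(col_order)), max(4, 0.3 * len(row_order))))
    cmap = ListedColormap(["green", "red"])
    ax.imshow((data == rules.presence_code).astype(int), cmap=cmap,
              aspect="auto", interpolation="nearest")
    ax.set_yticks(range(len(row_order)), labels=row_order, fontsize=6)
    ax.set_xticks(range(len(col_order)), labels=col_order, fontsize=4,
                  rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
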