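"""Community characterization: profiles, names, ANOVA, concordance, feature maps.

Communities found by partitioning the phenotype graphs are interpreted as
candidate clinical subtypes.  Each community is summarized by its per-feature
mean, named by the one or two features with the highest community means, and
features are screened for between-community differences with one-way ANOVA.
Agreement between two partitions (e.g., bipartite vs unipartite) is quantified
pairwise by the Jaccard index of community member sets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist, squareform

from .community import Partition

logger = logging.getLogger(__name__)


@dataclass
class CommunityProfile:
    """Mean feature vector, size and derived name of one community."""

    community_id: int
    size: int
    feature_means: pd.Series
    name: str


def _assignment(partition: Partition | Mapping[Hashable, int]) -> dict:
    return dict(partition.assignment if isinstance(partition, Partition) else partition)


def _subject_assignment(features: pd.DataFrame, partition) -> pd.Series:
    """Restrict a partition to the subjects present in ``features`` (feature
    nodes from a bipartite partition are excluded automatically)."""
    assignment = _assignment(partition)
    idx = [s for s in features.index if str(s) in {str(k) for k in assignment}]
    by_str = {str(k): v for k, v in assignment.items()}
    if not idx:
        raise ValueError("partition covers no subject present in the feature matrix")
    return pd.Series({s: by_str[str(s)] for s in idx})


def name_community(
    feature_means: pd.Series | Mapping[str, float],
    second_feature_ratio: float = 0.8,
) -> str:
    """Name a community by its one or two highest-mean features.

    The top feature always names the community; the runner-up is appended
    ("/"-joined) iff its mean is at least ``second_feature_ratio`` times the
    top mean.  Exact ties break lexicographically.  All-zero means yield
    ``"indeterminate"``.
    """
    means = pd.Series(feature_means, dtype=float)
    if means.empty:
        raise ValueError("feature_means must be non-empty")
    if (means == 0).all():
        return "indeterminate"
    ranked = means.sort_values(ascending=False, kind="stable")
    ranked = ranked.loc[sorted(ranked.index, key=lambda f: (-ranked[f], str(f)))]
    top, top_val = ranked.index[0], ranked.iloc[0]
    if len(ranked) > 1 and ranked.iloc[1] >= second_feature_ratio * top_val:
        return f"{top}/{ranked.index[1]}"
    return str(top)


def community_profiles(
    features: pd.DataFrame,
    partition: Partition | Mapping[Hashable, int],
    second_feature_ratio: float = 0.8,
) -> list[CommunityProfile]:
    """Per-community arithmetic means of the (normalized) features, with names.

    Sizes sum to the number of retained subjects; weighted-mean conservation
    holds: Σ_c size_c · mean_c equals the column sums over retained subjects.
    """
    assign = _subject_assignment(features, partition)
    sub = features.loc[assign.index].astype(float)
    profiles = []
    for cid, group in sub.groupby(assign, sort=True):
        means = group.mean(axis=0)
        profiles.append(
            CommunityProfile(
                community_id=int(cid),
                size=len(group),
                feature_means=means,
                name=name_community(means, second_feature_ratio),
            )
        )
    return profiles


def profiles_frame(profiles: list[CommunityProfile]) -> pd.DataFrame:
    """Tabular view: one row per community with size, name and feature means."""
    rows = []
    for p in profiles:
        row = {"community_id": p.community_id, "size": p.size, "name": p.name}
        row.update(p.feature_means.to_dict())
        rows.append(row)
    return pd.DataFrame(rows).set_index("community_id")


def anova_by_feature(
    features: pd.DataFrame,
    partition: Partition | Mapping[Hashable, int],
    holm: bool = False,
) -> pd.DataFrame:
    """One-way fixed-effects ANOVA of each feature across communities.

    F = [SSB/(K−1)] / [SSW/(N−K)] with the p-value from the F distribution on
    (K−1, N−K) degrees of freedom.  Zero within-group variance with nonzero
    between-group variance yields F = +inf with the smallest positive p.

    ``holm=True`` adds a Holm step-down adjusted p column (an extension; the
    default reports raw p-values across the 16 features).
    """
    assign = _subject_assignment(features, partition)
    sub = features.loc[assign.index].astype(float)
    groups = [g for _, g in sub.groupby(assign)]
    k = len(groups)
    n = len(sub)
    if k < 2:
        raise ValueError(f"ANOVA needs at least 2 communities, got {k}")
    if any(len(g) < 2 for g in groups):
        raise ValueError("ANOVA needs every community to have at least 2 members")
    dfb, dfw = k - 1, n - k
    rows = []
    for col in sub.columns:
        xs = [g[col].values for g in groups]
        grand = sub[col].mean()
        ssb = sum(len(x) * (x.mean() - grand) ** 2 for x in xs)
        ssw = sum(((x - x.mean()) ** 2).sum() for x in xs)
        if ssw == 0:
            if ssb == 0:
                f_stat, p = 0.0, 1.0
            else:
                f_stat, p = float("inf"), float(np.nextafter(0, 1))
                logger.warning("feature %r: zero within-community variance; F = inf", col)
        else:
            f_stat = (ssb / dfb) / (ssw / dfw)
            p = float(stats.f.sf(f_stat, dfb, dfw))
        rows.append({"superclass": col, "F": f_stat, "df_between": dfb,
                     "df_within": dfw, "p": max(p, float(np.nextafter(0, 1)))})
    out = pd.DataFrame(rows).set_index("superclass")
    if holm:
        from statsmodels.stats.multitest import multipletests

        out["p_holm"] = multipletests(out["p"].values, method="holm")[1]
    return out


def jaccard(A, B) -> float:
    """|A∩B| / |A∪B|.  Both sets empty is a hard error."""
    A, B = set(A), set(B)
    union = A | B
    if not union:
        raise ValueError("Jaccard index is undefined for two empty sets")
    return len(A & B) / len(union)


@dataclass
class ConcordanceTable:
    """Pairwise Jaccard indices between the communities of two partitions."""

    j: pd.DataFrame                    # rows: partition-1 communities, cols: partition-2
    best_match: list[tuple[int, int, float]]
    members_a: dict[int, set]
    members_b: dict[int, set]


def concordance_table(
    p1: Partition | Mapping[Hashable, int],
    p2: Partition | Mapping[Hashable, int],
) -> ConcordanceTable:
    """Jaccard index for every community pair of two partitions.

    The comparison is restricted to subjects retained in both partitions.
    ``best_match`` greedily pairs communities by descending J (ties: lower
    community ids first); the full matrix is always available for audit.
    """
    a1, a2 = _assignment(p1), _assignment(p2)
    common = {str(k) for k in a1} & {str(k) for k in a2}
    if not common:
        raise ValueError("partitions share no subjects")
    mem_a: dict[int, set] = {}
    for n, c in a1.items():
        if str(n) in common:
            mem_a.setdefault(int(c), set()).add(str(n))
    mem_b: dict[int, set] = {}
    for n, c in a2.items():
        if str(n) in common:
            mem_b.setdefault(int(c), set()).add(str(n))
    rows = sorted(mem_a)
    cols = sorted(mem_b)
    J = pd.DataFrame(
        [[jaccard(mem_a[r], mem_b[c]) for c in cols] for r in rows],
        index=rows,
        columns=cols,
    )
    pairs = sorted(
        ((r, c) for r in rows for c in cols),
        key=lambda rc: (-J.at[rc[0], rc[1]], rc[0], rc[1]),
    )
    used_r: set[int] = set()
    used_c: set[int] = set()
    best: list[tuple[int, int, float]] = []
    for r, c in pairs:
        if r not in used_r and c not in used_c:
            best.append((r, c, float(J.at[r, c])))
            used_r.add(r)
            used_c.add(c)
    return ConcordanceTable(j=J, best_match=best, members_a=mem_a, members_b=mem_b)


def feature_map_order(features: pd.DataFrame) -> tuple[list, list]:
    """Dendrogram leaf orders for a heat-map display of the feature matrix.

    Rows (subjects) cluster on Euclidean distance, columns (features) on
    correlation distance (1 − Pearson r), both with Ward linkage.  A
    zero-variance column has no defined correlation; it is assigned the
    maximal correlation distance (2.0) to every other column, with a warning.
    """
    X = pd.DataFrame(features).astype(float)
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("feature map ordering needs at least 2 rows and 2 columns")
    row_Z = linkage(pdist(X.values, metric="euclidean"), method="ward")
    row_order = [X.index[i] for i in leaves_list(row_Z)]

    col_vals = X.values.T
    var = col_vals.var(axis=1)
    dcol = squareform(pdist(col_vals, metric="correlation"), checks=False)
    if (var == 0).any():
        flat = np.flatnonzero(var == 0)
        logger.warning(
            "zero-variance column(s) %s assigned maximal correlation distance",
            [X.columns[i] for i in flat],
        )
        dcol[flat, :] = 2.0
        dcol[:, flat] = 2.0
    np.fill_diagonal(dcol, 0.0)
    col_Z = linkage(squareform(dcol, checks=False), method="ward")
    col_order = [X.columns[i] for i in leaves_list(col_Z)]
    return row_order, col_order


def plot_feature_map(features: pd.DataFrame, path=None):  # pragma: no cover - presentation extra
    """Render the reordered feature matrix as a heat map (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows, cols = feature_map_order(features)
    M = features.loc[rows, cols]
    fig, ax = plt.subplots(figsize=(0.4 * len(cols) + 2, 0.12 * len(rows) + 2))
    im = ax.imshow(M.values, aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(cols)), [str(c) for c in cols], rotation=90)
    ax.set_yticks([])
    fig.colorbar(im, ax=ax, label="normalized feature")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
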