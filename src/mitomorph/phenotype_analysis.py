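"""Clustering and condition comparison of morphometric feature tables.

The feature table (one row per image or per condition mean) is z-scored
column-wise, then summarized two ways: a two-dimensional clustergram
(UPGMA/average-linkage hierarchical clustering with Euclidean distance on
rows and columns) and a k-means partition. Individual metrics are compared
between conditions with Welch t-tests, falling back to Wilcoxon rank-sum
when a Shapiro-Wilk check rejects normality in either group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from sklearn.cluster import KMeans

from .morphometry import SHAPE_COLUMNS, TEXTURE_COLUMNS

DEFAULT_METRICS = SHAPE_COLUMNS + TEXTURE_COLUMNS


def clean_feature_table(df: pd.DataFrame, metrics: list[str] | None = None
                        ) -> tuple[pd.DataFrame, list]:
    """Drop rows unusable for clustering (no objects / missing metrics).

    Returns the cleaned table and the list of dropped row indices.
    """
    metrics = metrics or [c for c in DEFAULT_METRICS if c in df.columns]
    bad = df.index[df[metrics].isna().any(axis=1)]
    if "NObjects" in df.columns:
        bad = bad.union(df.index[df["NObjects"] == 0])
    return df.drop(index=bad), list(bad)


def standardize(table: pd.DataFrame | np.ndarray) -> pd.DataFrame | np.ndarray:
    """Column-wise z-scores: (x - mean) / sample SD (ddof=1).

    Raises on a constant column, naming it — a constant metric carries no
    clustering information and would divide by zero.
    """
    values = table.to_numpy(dtype=float) if isinstance(table, pd.DataFrame) \
        else np.asarray(table, dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    sd = values.std(axis=0, ddof=1)
    const = np.flatnonzero(sd == 0)
    if const.size:
        names = ([str(table.columns[i]) for i in const]
                 if isinstance(table, pd.DataFrame) else [str(i) for i in const])
        raise ValueError(f"constant column(s): {', '.join(names)}")
    z = (values - values.mean(axis=0)) / sd
    if isinstance(table, pd.DataFrame):
        return pd.DataFrame(z, index=table.index, columns=table.columns)
    return z


@dataclass
class Clustergram:
    """Two-dimensional clustergram: dendrograms + orders + z-matrix."""

    z_matrix: np.ndarray
    row_linkage: np.ndarray  # scipy linkage matrices (merge tree + heights)
    col_linkage: np.ndarray
    row_order: np.ndarray
    col_order: np.ndarray
    row_labels: list = field(default_factory=list)
    col_labels: list = field(default_factory=list)

    def top_split_rows(self) -> tuple[list, list]:
        """Row labels of the two branches under the root merge."""
        n = self.z_matrix.shape[0]
        tree = hierarchy.to_tree(self.row_linkage)
        left = tree.get_left().pre_order()
        right = tree.get_right().pre_order()
        lab = self.row_labels or list(range(n))
        return [lab[i] for i in left], [lab[i] for i in right]


def _to_newick(node, labels, parent_height: float) -> str:
    length = parent_height - node.dist
    if node.is_leaf():
        return f"{labels[node.id]}:{length:.6g}"
    left = _to_newick(node.get_left(), labels, node.dist)
    right = _to_newick(node.get_right(), labels, node.dist)
    return f"({left},{right}):{length:.6g}"


def linkage_to_newick(linkage: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage tree as Newick with branch lengths from merge heights."""
    tree = hierarchy.to_tree(linkage)
    return f"({_to_newick(tree.get_left(), labels, tree.dist)},"\
           f"{_to_newick(tree.get_right(), labels, tree.dist)});"


def clustergram(
    z: pd.DataFrame | np.ndarray,
    distance: str = "euclidean",
    linkage: str = "average",
) -> Clustergram:
    """Agglomerative clustering (default UPGMA) on rows and on columns.

    Merge heights are average inter-cluster Euclidean distances; leaf
    orders come from the standard recursive dendrogram ordering.
    """
    if isinstance(z, pd.DataFrame):
        row_labels = [str(i) for i in z.index]
        col_labels = [str(c) for c in z.columns]
        mat = z.to_numpy(dtype=float)
    else:
        mat = np.asarray(z, dtype=float)
        row_labels = [str(i) for i in range(mat.shape[0])]
        col_labels = [str(j) for j in range(mat.shape[1])]
    if mat.shape[0] < 2 or mat.shape[1] < 2:
        raise ValueError("need at least 2 rows and 2 columns")
    if np.isnan(mat).any():
        raise ValueError("NaN in matrix; clean the feature table first")
    row_link = hierarchy.linkage(mat, method=linkage, metric=distance)
    col_link = hierarchy.linkage(mat.T, method=linkage, metric=distance)
    return Clustergram(
        z_matrix=mat,
        row_linkage=row_link,
        col_linkage=col_link,
        row_order=hierarchy.leaves_list(row_link),
        col_order=hierarchy.leaves_list(col_link),
        row_labels=row_labels,
        col_labels=col_labels,
    )


def kmeans_cluster(
    z: np.ndarray | pd.DataFrame, k: int, n_init: int = 10, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Lloyd k-means, best of ``n_init`` seeded restarts by within-cluster SS."""
    mat = z.to_numpy(dtype=float) if isinstance(z, pd.DataFrame) \
        else np.asarray(z, dtype=float)
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > mat.shape[0]:
        raise ValueError("k cannot exceed the number of rows")
    km = KMeans(n_clusters=k, n_init=n_init, random_state=seed, algorithm="lloyd")
    labels = km.fit_predict(mat)
    return labels, km.cluster_centers_


@dataclass
class ComparisonResult:
    """One metric, one condition-vs-control comparison."""

    metric: str
    condition: str
    control: str
    test: str  # "t" (Welch) or "wilcoxon" (rank-sum)
    statistic: float
    p_value: float
    normal_group: bool
    normal_control: bool


def _is_normal(x: np.ndarray, alpha: float) -> bool:
    """Shapiro-Wilk gate; groups too small to test are not rejected."""
    if x.size < 3 or np.ptp(x) == 0:
        return True
    return stats.shapiro(x).pvalue >= alpha


def compare_conditions(
    table: pd.DataFrame,
    control_label: str,
    metrics: list[str] | None = None,
    alpha_normality: float = 0.05,
    holm: bool = False,
) -> pd.DataFrame:
    """Pairwise condition-vs-control tests per metric.

    Both groups normal by Shapiro-Wilk -> Welch (unequal-variance) t-test;
    otherwise two-sided Wilcoxon rank-sum. Holm correction across all
    comparisons is available behind ``holm`` (off by default).
    """
    metrics = metrics or [c for c in DEFAULT_METRICS if c in table.columns]
    conditions = [c for c in table["Condition"].unique() if c != control_label]
    if control_label not in set(table["Condition"]):
        raise ValueError(f"control label {control_label!r} not in table")
    results = []
    ctrl_rows = table[table["Condition"] == control_label]
    for cond in conditions:
        grp_rows = table[table["Condition"] == cond]
        for metric in metrics:
            g = grp_rows[metric].dropna().to_numpy(dtype=float)
            c = ctrl_rows[metric].dropna().to_numpy(dtype=float)
            if g.size < 2 or c.size < 2:
                raise ValueError(f"group size < 2 for {metric}/{cond}")
            ng, nc = _is_normal(g, alpha_normality), _is_normal(c, alpha_normality)
            if ng and nc:
                if np.ptp(g) == 0 and np.ptp(c) == 0 and g.mean() == c.mean():
                    stat, p = 0.0, 1.0
                else:
                    res = stats.ttest_ind(g, c, equal_var=False)
                    stat, p = float(res.statistic), float(res.pvalue)
                test = "t"
            else:
                res = stats.ranksums(g, c)
                stat, p = float(res.statistic), float(res.pvalue)
                test = "wilcoxon"
            results.append(ComparisonResult(metric, cond, control_label, test,
                                            stat, p, ng, nc))
    df = pd.DataFrame([r.__dict__ for r in results])
    if holm and len(df):
        order = np.argsort(df["p_value"].to_numpy())
        m = len(df)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * df["p_value"].iloc[idx])
            adj[idx] = min(1.0, running)
        df["p_holm"] = adj
    return df
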