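"""Statistical tail: ANOVA + Tukey letters, Mann–Whitney U, PCA, Ward trees.

These are the steps applied downstream of the trait tables: per-trait
significance testing between treatments/accessions, dimensionality
reduction of the fluorescence parameter set, and Ward clustering of
accessions by their salt-relative fluorescence traits together with the two
SIIT indices.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from sklearn.decomposition import PCA as _PCA


# ---------------------------------------------------------------------------
# ANOVA + Tukey HSD with compact letter display


@dataclass
class TukeyResult:
    f_stat: float
    p_value: float
    groups: list[str]
    means: dict[str, float]
    pairwise: pd.DataFrame  # columns: group1, group2, mean_diff, p_adj
    letters: dict[str, str]


def anova_tukey(values, labels, alpha: float = 0.05) -> TukeyResult:
    """One-way ANOVA with Tukey–Kramer post-hoc comparisons.

    Pairwise p-values come from the studentized-range distribution with the
    pooled within-group variance (Tukey–Kramer for unequal group sizes).
    The compact letter display assigns letters so that any two groups
    sharing a letter are *not* significantly different at ``alpha``.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    names = list(pd.unique(labels))
    if len(names) < 2:
        raise ValueError("need at least two groups")
    groups = {g: values[labels == g] for g in names}
    for g, v in groups.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 observations")

    n = len(values)
    k = len(names)
    grand = values.mean()
    ss_between = sum(len(v) * (v.mean() - grand) ** 2 for v in groups.values())
    ss_within = sum(((v - v.mean()) ** 2).sum() for v in groups.values())
    df_b, df_w = k - 1, n - k
    mse = ss_within / df_w
    if ss_between <= 1e-300:
        f_stat, p_value = 0.0, 1.0
    elif mse <= 1e-300:
        f_stat, p_value = float("inf"), 0.0
    else:
        f_stat = (ss_between / df_b) / mse
        p_value = float(sps.f.sf(f_stat, df_b, df_w))

    rows = []
    for g1, g2 in itertools.combinations(names, 2):
        v1, v2 = groups[g1], groups[g2]
        diff = v2.mean() - v1.mean()
        if mse <= 1e-300:
            p_adj = 1.0 if abs(diff) < 1e-300 else 0.0
        else:
            se = np.sqrt(mse / 2.0 * (1.0 / len(v1) + 1.0 / len(v2)))
            q = abs(diff) / se
            p_adj = float(sps.studentized_range.sf(q, k, df_w))
        rows.append({"group1": g1, "group2": g2, "mean_diff": diff, "p_adj": p_adj})
    pairwise = pd.DataFrame(rows)

    means = {g: float(v.mean()) for g, v in groups.items()}
    letters = compact_letter_display(names, pairwise, alpha, means)
    return TukeyResult(f_stat=float(f_stat), p_value=float(p_value), groups=names,
                       means=means, pairwise=pairwise, letters=letters)


def compact_letter_display(groups, pairwise: pd.DataFrame, alpha: float, means) -> dict[str, str]:
    """Letters from maximal cliques of the non-significance graph.

    Each maximal clique of "not significantly different" pairs receives one
    letter; a group's display is the sorted concatenation of its letters.
    """
    g = nx.Graph()
    g.add_nodes_from(groups)
    for row in pairwise.itertuples():
        if row.p_adj > alpha:
            g.add_edge(row.group1, row.group2)
    cliques = sorted(nx.find_cliques(g), key=lambda c: (-max(means[m] for m in c), sorted(str(x) for x in c)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {grp: "" for grp in groups}
    for i, clique in enumerate(cliques):
        letter = alphabet[i % len(alphabet)]
        for member in clique:
            out[member] += letter
    return {grp: "".join(sorted(s)) for grp, s in out.items()}


# ---------------------------------------------------------------------------
# Mann–Whitney U


def mann_whitney(a, b, *, continuity_correction: bool = True, method: str = "auto") -> tuple[float, float]:
    """Two-sided Mann–Whitney U test; returns (U of sample a, p).

    ``method``: "asymptotic" uses the tie-corrected normal approximation
    with a 0.5 continuity correction; "exact" enumerates every labelling of
    the pooled sample (intended for n <= 8 per group); "auto" picks exact
    for small samples without ties.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    if method == "auto":
        small = a.size <= 8 and b.size <= 8
        method = "exact" if small else "asymptotic"
    if method == "exact":
        return _mann_whitney_exact(a, b)
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic",
                           use_continuity=continuity_correction)
    return float(res.statistic), float(res.pvalue)


def _mann_whitney_exact(a, b) -> tuple[float, float]:
    """Exhaustive permutation distribution of U (handles ties exactly)."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    mu = n1 * len(b) / 2.0
    dev = abs(u_obs - mu)
    count = total = 0
    for idx in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(idx)].sum() - n1 * (n1 + 1) / 2.0
        count += abs(u - mu) >= dev - 1e-12
        total += 1
    return float(u_obs), count / total


# ---------------------------------------------------------------------------
# standardisation and PCA


def standardize_traits(matrix: pd.DataFrame) -> pd.DataFrame:
    """Per-column z-scores (sample SD, ddof=1): mean 0, SD 1 per trait."""
    X = matrix.astype(float)
    sd = X.std(ddof=1)
    bad = sd[~(sd > 0)].index.tolist()
    if bad:
        raise ValueError(f"zero-variance column(s): {bad}")
    return (X - X.mean()) / sd


@dataclass
class PCAResult:
    scores: pd.DataFrame
    loadings: pd.DataFrame
    explained_variance_ratio: np.ndarray
    dropped_columns: list[str] = field(default_factory=list)
    imputed: bool = False


def pca(matrix: pd.DataFrame, n_components: int | None = None) -> PCAResult:
    """PCA of the column-standardized trait matrix.

    Missing values are imputed by the column mean (flagged); zero-variance
    columns are dropped with a warning.  Scores are centred and
    explained-variance fractions are non-increasing.
    """
    X = matrix.astype(float).copy()
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError(f"need >= 2 rows and columns, got {X.shape}")
    imputed = bool(X.isna().any().any())
    if imputed:
        X = X.fillna(X.mean())
    sd = X.std(ddof=1)
    dropped = sd[~(sd > 0)].index.tolist()
    if dropped:
        warnings.warn(f"dropping zero-variance column(s) from PCA: {dropped}", stacklevel=2)
        X = X.drop(columns=dropped)
    Z = (X - X.mean()) / X.std(ddof=1)
    n_components = n_components or min(Z.shape)
    model = _PCA(n_components=n_components, svd_solver="full")
    scores = model.fit_transform(Z.to_numpy())
    pcs = [f"PC{i + 1}" for i in range(model.n_components_)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=Z.index, columns=pcs),
        loadings=pd.DataFrame(model.components_.T, index=Z.columns, columns=pcs),
        explained_variance_ratio=model.explained_variance_ratio_,
        dropped_columns=dropped,
        imputed=imputed,
    )


# ---------------------------------------------------------------------------
# Ward clustering


@dataclass
class ClusterResult:
    linkage: np.ndarray  # scipy (n-1, 4) merge list
    labels: dict[str, int]  # leaf name -> cluster id at the requested cut
    leaf_names: list[str]
    n_clusters: int

    @property
    def heights(self) -> np.ndarray:
        return self.linkage[:, 2]


def ward_cluster(matrix: pd.DataFrame, n_clusters: int = 3) -> ClusterResult:
    """Agglomerative Ward tree over rows (Euclidean distance).

    Expects a standardized matrix; deterministic given row order (scipy
    breaks distance ties by merge index).  ``n_clusters`` sets the cut.
    """
    X = matrix.to_numpy(float)
    if X.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    Z = hierarchy.linkage(X, method="ward")
    flat = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    names = [str(i) for i in matrix.index]
    return ClusterResult(linkage=Z, labels=dict(zip(names, (int(c) for c in flat))),
                         leaf_names=names, n_clusters=n_clusters)


@dataclass
class ClusterReport:
    matrix_std: pd.DataFrame
    rows: ClusterResult
    cols: ClusterResult


def early_late_cluster_report(
    trait_matrix: pd.DataFrame,
    *,
    row_clusters: int = 3,
    col_clusters: int = 2,
    impute_missing: bool = True,
) -> ClusterReport:
    """Cluster accessions (rows) and traits (columns) of a salt-response matrix.

    Input: accessions x traits, typically the eight fluorescence traits at
    the final-day high-irradiance state plus SIIT1 and SIIT2, as
    salt-relative-to-control values.  Columns are z-scored per trait, then
    Ward trees are built over rows and (independently) over columns; the
    default cuts are 3 row clusters and 2 column clusters.
    """
    X = trait_matrix.astype(float).copy()
    if X.isna().any().any():
        if impute_missing:
            X = X.fillna(X.mean())
        else:
            X = X.dropna()
    Z = standardize_traits(X)
    return ClusterReport(
        matrix_std=Z,
        rows=ward_cluster(Z, n_clusters=row_clusters),
        cols=ward_cluster(Z.T, n_clusters=col_clusters),
    )


def plot_heatmap(report: ClusterReport, path) -> None:
    """Dendrogram-ordered heatmap of the standardized matrix (PNG)."""
    from matplotlib.figure import Figure

    row_order = hierarchy.leaves_list(report.rows.linkage)
    col_order = hierarchy.leaves_list(report.cols.linkage)
    M = report.matrix_std.to_numpy()[np.ix_(row_order, col_order)]
    fig = Figure(figsize=(1.0 + 0.5 * M.shape[1], 1.0 + 0.4 * M.shape[0]))
    ax = fig.add_subplot(111)
    im = ax.imshow(M, cmap="RdBu_r", aspect="auto")
    ax.set_xticks(range(M.shape[1]))
    ax.set_xticklabels([report.matrix_std.columns[i] for i in col_order], rotation=90, fontsize=7)
    ax.set_yticks(range(M.shape[0]))
    ax.set_yticklabels([report.matrix_std.index[i] for i in row_order], fontsize=7)
    fig.colorbar(im, ax=ax, label="z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)


def benjamini_hochberg(pvalues) -> np.ndarray:
    """BH-adjusted p-values (optional multiple-testing control)."""
    p = np.asarray(pvalues, float)
    order = np.argsort(p)
    ranked = p[order] * len(p) / (np.arange(len(p)) + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty_like(adj)
    out[order] = np.minimum(adj, 1.0)
    return out
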