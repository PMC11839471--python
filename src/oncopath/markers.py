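"""Cancer-type-specific marker selection.

For each cancer type, features are screened by one-way ANOVA across all
cancer types (P < 0.05), then tested one-vs-rest with a pooled-variance
two-tailed Student's t test and BH-FDR corrected.  For transcripts, the FDR
cutoff is chosen from a nine-point grid (1e-10 .. 1e-2, tenfold steps): at
each cutoff the samples are clustered hierarchically (complete linkage,
Euclidean distance) on the surviving features, the tree is cut into two
clusters, and the clustering is scored with Gini purity against
target-vs-rest labels; the cutoff maximizing purity wins, ties broken toward
the more stringent cutoff.  For proteins, the selection rule is simply raw
t-test P < 0.05.

The same machinery is exposed as an sklearn-compatible feature selector,
:class:`OneVsRestMarkerSelector`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix

__all__ = [
    "DEFAULT_FDR_GRID",
    "CutoffEvaluation",
    "SignificantFeatureSet",
    "anova_screen",
    "one_vs_rest_ttest",
    "bh_adjust",
    "gini_purity",
    "cluster_samples",
    "select_transcripts",
    "select_proteins",
    "biotype_composition",
    "top_biotype_percent",
    "OneVsRestMarkerSelector",
]

#: FDR-adjusted P-value grid: 1e-10 .. 1e-2 with tenfold proportional increase.
DEFAULT_FDR_GRID: tuple[float, ...] = tuple(10.0 ** np.arange(-10, -1))


@dataclass
class CutoffEvaluation:
    """Result of evaluating one FDR-grid cutoff: how many features survive
    and how class-pure the induced sample clustering is."""

    fdr_cutoff: float
    subset_size: int
    gini_purity: float | None  # None when the subset is empty


@dataclass
class SignificantFeatureSet:
    """Significant features for one cancer type on one omics layer."""

    cancer_type: str
    omics_layer: str  # "transcript" | "protein"
    feature_ids: list[str]
    chosen_cutoff: float | None
    stats: pd.DataFrame  # per retained feature: anova_p, t_stat, p_raw, p_fdr, direction
    evaluations: list[CutoffEvaluation] = field(default_factory=list)

    def gene_symbols(self, matrix: ExpressionMatrix) -> set[str]:
        """Symbols of the selected features (symbol-less features excluded)."""
        if matrix.gene_symbols is None:
            return set()
        sym = matrix.gene_symbols.reindex(self.feature_ids).dropna()
        return set(sym)

    def to_frame(self, matrix: ExpressionMatrix | None = None) -> pd.DataFrame:
        out = self.stats.loc[self.feature_ids].copy()
        if matrix is not None:
            if matrix.gene_symbols is not None:
                out.insert(0, "gene_symbol", matrix.gene_symbols.reindex(out.index))
            if matrix.biotypes is not None:
                out.insert(1, "biotype", matrix.biotypes.reindex(out.index))
        return out


def _split_by_class(
    matrix: ExpressionMatrix, labels: dict[str, str]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Align samples with labels; return (values, label array, sample ids)."""
    samples = [s for s in matrix.sample_ids if s in labels]
    if len(samples) < len(matrix.sample_ids):
        missing = [s for s in matrix.sample_ids if s not in labels]
        warnings.warn(f"{len(missing)} samples lack annotations and are excluded: {missing[:5]}")
    values = matrix.values[samples].to_numpy(dtype=float)
    y = np.array([labels[s] for s in samples])
    return values, y, samples


def anova_screen(
    matrix: ExpressionMatrix, labels: dict[str, str], alpha: float = 0.05
) -> pd.DataFrame:
    """One-way ANOVA of each feature across cancer types.

    Returns a DataFrame indexed by feature id with columns ``anova_p`` and
    ``retained`` (anova_p < alpha).  Features with zero total variance (or
    too few usable values) get ``anova_p = 1`` and are dropped.
    """
    values, y, _ = _split_by_class(matrix, labels)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("ANOVA needs at least 2 cancer types")
    for cls in classes:
        if np.sum(y == cls) < 2:
            raise ValueError(f"cancer type {cls!r} has fewer than 2 samples")
    groups = [values[:, y == cls] for cls in classes]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows produce harmless warnings
        _, p = stats.f_oneway(*groups, axis=1, nan_policy="omit")
    p = np.asarray(p, dtype=float)
    total_var = np.nanvar(values, axis=1)
    p[~np.isfinite(p) | (total_var == 0)] = 1.0
    out = pd.DataFrame({"anova_p": p}, index=matrix.feature_ids)
    out["retained"] = out["anova_p"] < alpha
    return out


def one_vs_rest_ttest(
    matrix: ExpressionMatrix, labels: dict[str, str], target: str
) -> pd.DataFrame:
    """Pooled-variance two-tailed Student's t test, target class vs the rest.

    Returns a DataFrame indexed by feature id with ``t_stat``, ``p_raw``,
    ``direction`` ('up' when the target mean exceeds the rest mean),
    ``n_target`` and ``n_rest``.  Features with fewer than 2 usable values on
    either side get NaN statistics (marked missing).
    """
    values, y, _ = _split_by_class(matrix, labels)
    if target not in set(y):
        raise ValueError(f"target cancer type {target!r} not present in labels")
    in_target = y == target
    a = values[:, in_target]
    b = values[:, ~in_target]
    n_a = np.sum(~np.isnan(a), axis=1)
    n_b = np.sum(~np.isnan(b), axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        t, p = stats.ttest_ind(a, b, axis=1, equal_var=True, nan_policy="omit")
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    usable = (n_a >= 2) & (n_b >= 2)
    t[~usable] = np.nan
    p[~usable] = np.nan
    mean_a = np.nanmean(np.where(np.isnan(a), np.nan, a), axis=1)
    mean_b = np.nanmean(np.where(np.isnan(b), np.nan, b), axis=1)
    direction = np.where(mean_a > mean_b, "up", "down")
    return pd.DataFrame(
        {
            "t_stat": t,
            "p_raw": p,
            "direction": direction,
            "n_target": n_a,
            "n_rest": n_b,
        },
        index=matrix.feature_ids,
    )


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted P values, clipped to 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def gini_purity(cluster_assignment, class_labels) -> float:
    """Cluster-size-weighted Gini purity of a clustering against labels.

    ``sum_c (n_c / N) * sum_j p_cj^2`` where ``p_cj`` is the fraction of
    cluster ``c`` carrying label ``j`` — one minus the weighted Gini
    impurity.  1 means every cluster is label-pure; invariant to cluster
    relabelling and sample order.
    """
    clusters = np.asarray(cluster_assignment)
    y = np.asarray(class_labels)
    if clusters.size == 0:
        raise ValueError("empty clustering")
    if clusters.shape != y.shape:
        raise ValueError("cluster assignment and labels must align")
    total = clusters.size
    purity = 0.0
    for c in np.unique(clusters):
        members = y[clusters == c]
        n_c = members.size
        _, counts = np.unique(members, return_counts=True)
        purity += (n_c / total) * float(np.sum((counts / n_c) ** 2))
    return purity


def cluster_samples(values: np.ndarray, k: int = 2) -> np.ndarray:
    """Complete-linkage Euclidean hierarchical clustering of samples.

    ``values`` is features x samples; the tree is cut into ``k`` clusters.
    """
    obs = np.asarray(values, dtype=float).T  # samples in rows
    if obs.shape[0] < 2:
        raise ValueError("clustering needs at least 2 samples")
    # linkage cannot digest NaN; impute per-feature means (protein layer only)
    if np.isnan(obs).any():
        col_means = np.nanmean(obs, axis=0)
        col_means = np.where(np.isfinite(col_means), col_means, 0.0)
        obs = np.where(np.isnan(obs), col_means[None, :], obs)
    tree = linkage(obs, method="complete", metric="euclidean")
    return fcluster(tree, t=k, criterion="maxclust")


def _binary_labels(y: np.ndarray, target: str) -> np.ndarray:
    return np.where(y == target, "target", "rest")


def select_transcripts(
    matrix: ExpressionMatrix,
    labels: dict[str, str],
    target: str,
    grid: tuple[float, ...] = DEFAULT_FDR_GRID,
    anova_alpha: float = 0.05,
    k_clusters: int = 2,
    purity_scheme: str = "binary",
) -> SignificantFeatureSet:
    """Select significant transcripts for one cancer type via the FDR grid.

    Parameters
    ----------
    purity_scheme
        ``"binary"`` (default) scores clusterings against target-vs-rest
        labels; ``"multiclass"`` scores against the full cancer-type labels.
    """
    if purity_scheme not in ("binary", "multiclass"):
        raise ValueError("purity_scheme must be 'binary' or 'multiclass'")
    screen = anova_screen(matrix, labels, alpha=anova_alpha)
    retained = screen.index[screen["retained"]]
    tt = one_vs_rest_ttest(matrix, labels, target).loc[retained]
    usable = tt.index[tt["p_raw"].notna()]
    tt = tt.loc[usable]
    stats_df = tt.copy()
    stats_df.insert(0, "anova_p", screen.loc[usable, "anova_p"])
    stats_df["p_fdr"] = bh_adjust(stats_df["p_raw"].to_numpy())

    values, y, samples = _split_by_class(matrix, labels)
    feature_pos = pd.Index(matrix.feature_ids).get_indexer(stats_df.index)
    score_labels = _binary_labels(y, target) if purity_scheme == "binary" else y

    evaluations: list[CutoffEvaluation] = []
    for cutoff in sorted(grid):
        mask = stats_df["p_fdr"].to_numpy() < cutoff
        size = int(mask.sum())
        if size == 0:
            evaluations.append(CutoffEvaluation(cutoff, 0, None))
            continue
        sub = values[feature_pos[mask], :]
        assignment = cluster_samples(sub, k=k_clusters)
        evaluations.append(
            CutoffEvaluation(cutoff, size, gini_purity(assignment, score_labels))
        )

    scored = [e for e in evaluations if e.gini_purity is not None]
    if not scored:
        warnings.warn(f"no transcript passes any FDR cutoff for {target!r}")
        return SignificantFeatureSet(target, "transcript", [], None, stats_df, evaluations)
    best_purity = max(e.gini_purity for e in scored)
    # ties broken toward the smaller (more stringent) cutoff
    chosen = min(e.fdr_cutoff for e in scored if e.gini_purity == best_purity)
    selected = stats_df.index[stats_df["p_fdr"] < chosen].tolist()
    return SignificantFeatureSet(target, "transcript", selected, chosen, stats_df, evaluations)


def select_proteins(
    matrix: ExpressionMatrix,
    labels: dict[str, str],
    target: str,
    alpha: float = 0.05,
    anova_alpha: float = 0.05,
) -> SignificantFeatureSet:
    """Select significant proteins: ANOVA screen then raw t-test P < alpha.

    Unlike transcripts, proteins use the raw (not FDR-adjusted) one-vs-rest
    P value with a fixed 0.05 threshold.
    """
    screen = anova_screen(matrix, labels, alpha=anova_alpha)
    retained = screen.index[screen["retained"]]
    tt = one_vs_rest_ttest(matrix, labels, target).loc[retained]
    usable = tt.index[tt["p_raw"].notna()]
    tt = tt.loc[usable]
    stats_df = tt.copy()
    stats_df.insert(0, "anova_p", screen.loc[usable, "anova_p"])
    stats_df["p_fdr"] = bh_adjust(stats_df["p_raw"].to_numpy()) if len(stats_df) else np.nan
    selected = stats_df.index[stats_df["p_raw"] < alpha].tolist()
    return SignificantFeatureSet(target, "protein", selected, alpha, stats_df, [])


def biotype_composition(biotypes) -> pd.Series:
    """Count features per biotype, descending (alphabetical among ties)."""
    counts = pd.Series(biotypes).dropna().value_counts()
    return counts.sort_index().sort_values(ascending=False, kind="stable")


def top_biotype_percent(counts: pd.Series, n_top: int = 10, total: int | None = None) -> float:
    """Percentage of all features accounted for by the ``n_top`` largest
    biotype categories."""
    counts = pd.Series(counts).sort_values(ascending=False, kind="stable")
    if total is None:
        total = int(counts.sum())
    if total <= 0:
        raise ValueError("total must be positive")
    return 100.0 * float(counts.iloc[:n_top].sum()) / total


class OneVsRestMarkerSelector(BaseEstimator, SelectorMixin):
    """Sklearn feature selector wrapping the one-vs-rest marker machinery.

    Operates on ``(n_samples, n_features)`` arrays with class labels ``y``.
    ``layer="transcript"`` runs the FDR-grid/Gini-purity selection;
    ``layer="protein"`` the raw ``p < alpha`` rule.

    Attributes
    ----------
    stats_ : pd.DataFrame
        Per-feature test statistics for retained features.
    chosen_cutoff_ : float or None
    evaluations_ : list of CutoffEvaluation
    support_mask_ : np.ndarray of bool, shape (n_features,)
    """

    def __init__(
        self,
        target: str = "",
        layer: str = "transcript",
        alpha: float = 0.05,
        anova_alpha: float = 0.05,
        grid: tuple[float, ...] = DEFAULT_FDR_GRID,
        k_clusters: int = 2,
        purity_scheme: str = "binary",
    ):
        self.target = target
        self.layer = layer
        self.alpha = alpha
        self.anova_alpha = anova_alpha
        self.grid = grid
        self.k_clusters = k_clusters
        self.purity_scheme = purity_scheme

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, n_features) aligned with y")
        self.n_features_in_ = X.shape[1]
        feature_ids = [f"f{i}" for i in range(X.shape[1])]
        sample_ids = [f"s{i}" for i in range(X.shape[0])]
        matrix = ExpressionMatrix(
            values=pd.DataFrame(X.T, index=feature_ids, columns=sample_ids),
            scale="log2",
        )
        labels = dict(zip(sample_ids, map(str, y)))
        if self.layer == "transcript":
            result = select_transcripts(
                matrix,
                labels,
                str(self.target),
                grid=self.grid,
                anova_alpha=self.anova_alpha,
                k_clusters=self.k_clusters,
                purity_scheme=self.purity_scheme,
            )
        elif self.layer == "protein":
            result = select_proteins(
                matrix, labels, str(self.target), alpha=self.alpha, anova_alpha=self.anova_alpha
            )
        else:
            raise ValueError("layer must be 'transcript' or 'protein'")
        self.stats_ = result.stats
        self.chosen_cutoff_ = result.chosen_cutoff
        self.evaluations_ = result.evaluations
        mask = np.zeros(X.shape[1], dtype=bool)
        mask[[int(f[1:]) for f in result.feature_ids]] = True
        self.support_mask_ = mask
        return self

    def _get_support_mask(self):
        check_is_fitted(self, "support_mask_")
        return self.support_mask_
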