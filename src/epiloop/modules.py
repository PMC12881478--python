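"""Error-aware transcript filtering and SHAP-profile clustering.

Transcripts whose expression change the promoter model predicts well
(|RNA log2FC| > 0.5 and |prediction error| < 0.5, strict) are kept for
module discovery; variably expressed transcripts the model fails on
(|error| > 0.5) form the "unexplained" set, interpreted as enhancer-
driven regulation invisible to promoter features. Kept transcripts are
clustered on their per-feature Shapley profiles, within each prediction
direction, by agglomerative clustering; each cluster's dominant feature
(largest mean |phi|) names its regulatory module.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist
from sklearn.metrics import adjusted_rand_score

from .shapley import ShapMatrix


@dataclass
class FilterCriteria:
    """Thresholds of the error-aware transcript filter (log2 units)."""

    min_abs_lfc: float = 0.5
    max_abs_error: float = 0.5

    def __post_init__(self):
        if self.min_abs_lfc <= 0 or self.max_abs_error <= 0:
            raise ValueError("filter thresholds must be positive")


def filter_transcripts(observed_lfc, error,
                       criteria: FilterCriteria | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Boolean masks (kept, unexplained).

    kept: |lfc| > min_abs_lfc and |error| < max_abs_error;
    unexplained: |lfc| > min_abs_lfc and |error| > max_abs_error.
    All inequalities strict, so exact-boundary rows fall in neither set.
    """
    criteria = criteria or FilterCriteria()
    lfc = np.asarray(observed_lfc, dtype=float)
    err = np.asarray(error, dtype=float)
    if lfc.shape != err.shape:
        raise ValueError("lfc and error vectors differ in length")
    variable = np.abs(lfc) > criteria.min_abs_lfc
    kept = variable & (np.abs(err) < criteria.max_abs_error)
    unexplained = variable & (np.abs(err) > criteria.max_abs_error)
    return kept, unexplained


@dataclass
class ModuleAssignment:
    """Cluster labels for filtered transcripts, with per-cluster stats.

    ``df`` columns: transcript_id, stratum (up/down), cluster (labels
    like "up_1"); ``feature_ranking`` maps cluster → features ordered by
    mean |phi| descending.
    """

    df: pd.DataFrame
    feature_ranking: dict[str, list[str]]
    linkage: dict[str, np.ndarray]

    def module_labels(self) -> pd.Series:
        """Per-transcript dominant-feature label (the cluster's top
        feature), the package's notion of a regulatory module."""
        top = {c: r[0] for c, r in self.feature_ranking.items()}
        return self.df["cluster"].map(top).rename("module")


def cluster_shap(shap: ShapMatrix, k_up: int = 4, k_down: int = 3,
                 metric: str = "euclidean", method: str = "ward",
                 zscore: bool = True) -> ModuleAssignment:
    """Hierarchical clustering of SHAP profiles within direction strata.

    Direction is the sign of prediction − base_value. Profiles are
    z-scored per feature within each stratum by default (mirroring
    scaled heatmaps); pass ``zscore=False`` for raw values. Deterministic
    and invariant to row order (up to label renaming).
    """
    delta = shap.predictions - shap.df["base_value"].to_numpy()
    stratum = np.where(delta >= 0, "up", "down")
    phi = shap.phi()
    records = []
    rankings: dict[str, list[str]] = {}
    linkages: dict[str, np.ndarray] = {}
    for name, k in (("up", k_up), ("down", k_down)):
        mask = stratum == name
        n = int(mask.sum())
        if n == 0:
            continue
        if n < 2:
            raise ValueError(f"stratum '{name}' has fewer than 2 rows")
        if k > n:
            raise ValueError(f"k={k} exceeds {n} rows in stratum '{name}'")
        block = phi[mask]
        if zscore:
            sd = block.std(axis=0, ddof=0)
            sd[sd == 0] = 1.0
            block = (block - block.mean(axis=0)) / sd
        # sort rows so the partition is invariant to input order
        order = np.lexsort(block.T[::-1])
        Z = hierarchy.linkage(pdist(block[order], metric=metric),
                              method=method)
        labels_sorted = hierarchy.fcluster(Z, t=k, criterion="maxclust")
        labels = np.empty(n, dtype=int)
        labels[order] = labels_sorted
        linkages[name] = Z
        idx = shap.df.loc[mask, "transcript_id"].to_numpy()
        for tid, lab in zip(idx, labels):
            records.append({"transcript_id": tid, "stratum": name,
                            "cluster": f"{name}_{lab}"})
        for lab in np.unique(labels):
            sub = np.abs(phi[mask][labels == lab]).mean(axis=0)
            order_f = sorted(range(len(sub)), key=lambda j: (-sub[j], j))
            rankings[f"{name}_{lab}"] = [shap.feature_names[j]
                                         for j in order_f]
    return ModuleAssignment(df=pd.DataFrame(records),
                            feature_ranking=rankings, linkage=linkages)


def rank_cluster_features(assignment: ModuleAssignment, shap: ShapMatrix
                          ) -> pd.DataFrame:
    """Per-cluster features ordered by mean |phi| (descending).

    Recomputed from the SHAP matrix; ties keep feature-contract order.
    """
    merged = assignment.df.merge(shap.df, on="transcript_id")
    rows = []
    for cluster, sub in merged.groupby("cluster", sort=True):
        means = sub[shap.feature_names].abs().mean()
        order = sorted(shap.feature_names,
                       key=lambda f: (-means[f],
                                      shap.feature_names.index(f)))
        for rank, feat in enumerate(order, start=1):
            rows.append({"cluster": cluster, "rank": rank, "feature": feat,
                         "mean_abs_phi": float(means[feat]),
                         "n": len(sub)})
    return pd.DataFrame(rows)


def recovery_score(labels_a, labels_b) -> float:
    """Adjusted Rand index between two labelings of the same transcripts."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if a.shape != b.shape:
        raise ValueError("labelings differ in length")
    return float(adjusted_rand_score(a, b))


def dendrogram_newick(Z: np.ndarray, labels: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string for inspection."""
    tree = hierarchy.to_tree(Z)

    def walk(node):
        if node.is_leaf():
            return labels[node.id]
        return (f"({walk(node.left)}:{node.dist / 2:.6g},"
                f"{walk(node.right)}:{node.dist / 2:.6g})")

    return walk(tree) + ";"
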