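"""Patient phenotyping from medication-cluster distributions.

Each patient is summarised by how their distinct medications distribute
over the medication clusters (residual cluster included), normalized by the
total number of distinct medications they received.  Patients are then
clustered by hierarchical agglomeration (default Ward linkage on Euclidean
distances) and the number of phenotypes is chosen by silhouette analysis:
prefer the k maximising the mean silhouette among those k for which every
cluster's mean silhouette is at or above the overall mean ("all clusters
above average width"); fall back to the global argmax when no k qualifies.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from sklearn.metrics import silhouette_samples

from .preprocess import BinaryMedicationMatrix
from .rbm import MedicationClusterAssignment

logger = logging.getLogger(__name__)

__all__ = [
    "PatientFeatureMatrix",
    "PhenotypeModel",
    "PhenotypeResults",
    "compute_cluster_distribution",
    "hierarchical_cluster",
    "silhouette_profile",
    "select_k",
]


@dataclass
class PatientFeatureMatrix:
    """Patients x (n_hidden + 1) nonnegative feature matrix.

    With single-membership assignments and "by_total_meds" normalization
    each row sums to exactly 1; with overlapping memberships row sums can
    exceed 1, which "simplex" normalization repairs by dividing counts by
    their own sum.
    """

    values: pd.DataFrame
    normalization: str = "by_total_meds"

    def __post_init__(self) -> None:
        if self.normalization not in ("by_total_meds", "simplex"):
            raise ValueError(f"unknown normalization {self.normalization!r}")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("feature entries must be nonnegative")

    @property
    def patient_ids(self) -> list:
        return list(self.values.index)

    def to_numpy(self) -> np.ndarray:
        return self.values.to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", index_label="patient_id")


def compute_cluster_distribution(
    matrix: BinaryMedicationMatrix,
    assignment: MedicationClusterAssignment,
    normalization: str = "by_total_meds",
) -> PatientFeatureMatrix:
    """Per-patient normalized medication-cluster distribution.

    count_k(p) = number of distinct received medications of patient p that
    are members of cluster k (residual included).  "by_total_meds" divides
    by the patient's total distinct medications; "simplex" divides counts by
    their own sum so rows always lie on the probability simplex.
    """
    missing = set(matrix.medication_names) - set(assignment.membership)
    if missing:
        raise ValueError(f"medications without cluster assignment: {sorted(missing)[:5]}")
    X = matrix.values.to_numpy(dtype=float)
    totals = X.sum(axis=1)
    if (totals == 0).any():
        bad = [p for p, t in zip(matrix.patient_ids, totals) if t == 0]
        raise ValueError(f"patients with zero medications: {bad[:5]}")
    M = assignment.indicator(matrix.medication_names).to_numpy()
    counts = X @ M  # [patients x clusters]
    if normalization == "by_total_meds":
        feats = counts / totals[:, None]
    elif normalization == "simplex":
        feats = counts / counts.sum(axis=1, keepdims=True)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    cols = [f"cluster_{k}" for k in range(1, assignment.n_clusters + 1)]
    values = pd.DataFrame(feats, index=pd.Index(matrix.patient_ids, name="patient_id"), columns=cols)
    return PatientFeatureMatrix(values, normalization=normalization)


def _as_array(features) -> tuple[np.ndarray, list]:
    if isinstance(features, PatientFeatureMatrix):
        return features.to_numpy(), features.patient_ids
    if isinstance(features, pd.DataFrame):
        return features.to_numpy(dtype=float), list(features.index)
    arr = np.asarray(features, dtype=float)
    return arr, list(range(arr.shape[0]))


def _cut(Z: np.ndarray, k: int) -> np.ndarray:
    return hierarchy.fcluster(Z, t=k, criterion="maxclust")


def silhouette_profile(features, k_range, linkage_method: str = "ward") -> dict[int, dict]:
    """Mean and per-cluster silhouette scores for each candidate k.

    Labels come from cutting the agglomerative tree; silhouettes use
    Euclidean distance on the raw features, with s(i) = 0 for points in
    singleton clusters.
    """
    X, _ = _as_array(features)
    n = X.shape[0]
    k_range = sorted(set(int(k) for k in k_range))
    if any(k < 2 or k > n - 1 for k in k_range):
        raise ValueError(f"k_range must lie within [2, {n - 1}]")
    Z = hierarchy.linkage(X, method=linkage_method)
    out: dict[int, dict] = {}
    for k in k_range:
        labels = _cut(Z, k)
        if len(np.unique(labels)) < 2:
            # degenerate cut (duplicated points); silhouette undefined
            out[k] = {"mean": float("nan"), "per_cluster": {}, "labels": labels}
            continue
        s = silhouette_samples(X, labels)
        per = {int(c): float(s[labels == c].mean()) for c in np.unique(labels)}
        out[k] = {"mean": float(s.mean()), "per_cluster": per, "labels": labels}
    return out


def select_k(silhouette_by_k: dict[int, dict]) -> tuple[int, str]:
    """Choose k by the "all clusters above average" silhouette rule.

    Among k whose every per-cluster mean silhouette is >= the overall mean
    silhouette at that k, return the one with maximal mean silhouette
    (ties -> smallest k).  If none qualifies, fall back to the global
    argmax of the mean silhouette.  Returns (k, rule applied).
    """
    if not silhouette_by_k:
        raise ValueError("silhouette_by_k is empty")
    usable = {k: v for k, v in silhouette_by_k.items() if np.isfinite(v["mean"])}
    if not usable:
        k = min(silhouette_by_k)
        return k, "degenerate: no finite silhouette, smallest k returned"
    qualifying = [
        k for k, v in usable.items()
        if v["per_cluster"] and min(v["per_cluster"].values()) >= v["mean"] - 1e-12
    ]
    if qualifying:
        best = max(usable[k]["mean"] for k in qualifying)
        k = min(k for k in qualifying if usable[k]["mean"] >= best - 1e-12)
        rule = "all-clusters-above-average rule"
    else:
        best = max(v["mean"] for v in usable.values())
        k = min(k for k, v in usable.items() if v["mean"] >= best - 1e-12)
        rule = "no qualifying k; global mean-silhouette argmax"
    logger.info("select_k: k=%d via %s", k, rule)
    return k, rule


class PhenotypeModel:
    """Model object: hierarchical patient clustering on phenotype features.

    Parameters
    ----------
    features : PatientFeatureMatrix, DataFrame or array
        Per-patient feature rows (normalized cluster distributions).
    linkage_method : str
        "ward" (default), "complete" or "average"; distances are Euclidean
        on the raw features, which already share a [0, 1] scale.
    """

    def __init__(self, features, linkage_method: str = "ward"):
        self.features = features
        self.X, self.patient_ids = _as_array(features)
        if self.X.shape[0] < 2:
            raise ValueError("need at least 2 patients to cluster")
        self.linkage_method = linkage_method

    def fit(self, k: int | None = None, k_range=range(2, 9)) -> "PhenotypeResults":
        """Build the merge tree; cut at ``k`` or select k by silhouette."""
        n = self.X.shape[0]
        Z = hierarchy.linkage(self.X, method=self.linkage_method)
        silhouettes: dict[int, dict] = {}
        rule = f"k={k} fixed by caller"
        if k is None:
            k_range = [kk for kk in k_range if 2 <= kk <= n - 1]
            if not k_range:
                raise ValueError("empty usable k_range")
            silhouettes = silhouette_profile(self.features, k_range, self.linkage_method)
            k, rule = select_k(silhouettes)
        if not 1 <= k <= n:
            raise ValueError(f"k={k} outside [1, n_patients={n}]")
        labels = _cut(Z, int(k)) if k > 1 else np.ones(n, dtype=int)
        return PhenotypeResults(
            labels=pd.Series(labels, index=pd.Index(self.patient_ids, name="patient_id"), name="cluster"),
            k=int(k),
            linkage_method=self.linkage_method,
            merge_tree=Z,
            silhouette_by_k=silhouettes,
            selection_rule=rule,
        )


@dataclass
class PhenotypeResults:
    """Fitted phenotype solution: labels, merge tree, silhouettes."""

    labels: pd.Series
    k: int
    linkage_method: str
    merge_tree: np.ndarray
    silhouette_by_k: dict[int, dict] = field(default_factory=dict)
    selection_rule: str = ""

    def centroids(self, features=None) -> pd.DataFrame:
        """Per-cluster mean feature vectors (rows indexed by cluster label)."""
        if features is None:
            raise ValueError("pass the feature matrix used for fitting")
        X, ids = _as_array(features)
        df = pd.DataFrame(X, index=ids)
        return df.groupby(self.labels.values).mean().rename_axis("cluster")

    def merge_tree_frame(self) -> pd.DataFrame:
        Z = self.merge_tree
        return pd.DataFrame(
            {
                "child1": Z[:, 0].astype(int),
                "child2": Z[:, 1].astype(int),
                "height": Z[:, 2],
                "size": Z[:, 3].astype(int),
            }
        )

    def silhouette_frame(self) -> pd.DataFrame:
        rows = []
        for k in sorted(self.silhouette_by_k):
            v = self.silhouette_by_k[k]
            per = ";".join(f"{c}:{s:.4f}" for c, s in sorted(v["per_cluster"].items()))
            rows.append((k, v["mean"], per))
        return pd.DataFrame(rows, columns=["k", "mean_silhouette", "per_cluster_silhouette"])

    def summary(self) -> str:
        counts = self.labels.value_counts().sort_index()
        lines = [
            "Patient phenotype solution",
            "=" * 40,
            f"patients: {len(self.labels)}   clusters: {self.k}   linkage: {self.linkage_method}",
            f"selection: {self.selection_rule}",
            "cluster sizes: " + ", ".join(f"{c}: {n}" for c, n in counts.items()),
        ]
        if self.silhouette_by_k:
            prof = ", ".join(
                f"k={k}: {v['mean']:.3f}" for k, v in sorted(self.silhouette_by_k.items())
            )
            lines.append("mean silhouette by k: " + prof)
        return "\n".join(lines)


def hierarchical_cluster(features, linkage_method: str = "ward", k: int = 2) -> PhenotypeResults:
    """Cluster patients into exactly ``k`` groups (functional surface)."""
    return PhenotypeModel(features, linkage_method=linkage_method).fit(k=k)
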