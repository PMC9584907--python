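"""Sample stratification from the TF PageRank matrix.

TFs are filtered to those expressed in at least one sample, ranked by
cross-sample variance of their raw PageRank scores, and the top set's
z-scored profiles feed hierarchical clustering (Euclidean distance,
complete linkage).  Cluster labels are ordered by size (CL1 = largest).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform

from .io_formats import ExpressionMatrix, ValidationError
from .pagerank import PPRMatrix


@dataclass
class ClusterAssignment:
    labels: dict[str, str]        # sample -> "CL1", "CL2", ...
    linkage_matrix: np.ndarray    # scipy linkage over sorted sample order
    samples: list[str]            # sorted sample order used for clustering
    selected_tfs: list[str]
    params: dict

    @property
    def k(self) -> int:
        return len(set(self.labels.values()))

    def members(self, cluster: str) -> list[str]:
        return [s for s in self.samples if self.labels[s] == cluster]

    @property
    def clusters(self) -> list[str]:
        return sorted(set(self.labels.values()))


def select_variable_tfs(ppr: PPRMatrix, expression: ExpressionMatrix,
                        n_top: int = 350,
                        expressed_min_tpm: float = 1.0) -> list[str]:
    """Top TFs by cross-sample variance of raw PageRank, restricted to TFs
    with TPM >= threshold in at least one sample.  Ties break
    lexicographically by TF name."""
    if n_top < 2:
        raise ValidationError("n_top must be >= 2")
    expressed = set()
    tpm = expression.tpm
    for tf in ppr.tf_names:
        if tf in tpm.index and (tpm.loc[tf] >= expressed_min_tpm).any():
            expressed.add(tf)
    candidates = [t for t in ppr.tf_names if t in expressed]
    if len(candidates) < 2:
        raise ValidationError(
            f"only {len(candidates)} expressed TFs; need >= 2")
    variances = ppr.tf_scores.loc[candidates].var(axis=1, ddof=1)
    order = sorted(candidates, key=lambda t: (-variances[t], t))
    return order[:n_top]


def cluster_samples(tf_z: pd.DataFrame, k: int = 2,
                    selected_tfs: list[str] | None = None,
                    params: dict | None = None) -> ClusterAssignment:
    """Agglomerative clustering of samples (columns of ``tf_z``).

    Euclidean distance on per-TF z-score profiles, complete linkage, tree
    cut into ``k`` clusters.  Labels are assigned by cluster size descending
    (ties: cluster containing the lexicographically smallest sample first).
    Sample and TF order do not affect the result: rows and columns are
    sorted internally before distances are computed.
    """
    samples = sorted(tf_z.columns)
    if k > len(samples):
        raise ValidationError(f"k={k} exceeds number of samples {len(samples)}")
    if k < 1:
        raise ValidationError("k must be >= 1")
    if tf_z.isna().any().any():
        raise ValidationError("missing values in the clustering matrix")
    X = tf_z.sort_index().loc[:, samples].to_numpy(dtype=float).T
    Z = linkage(X, method="complete", metric="euclidean")
    raw = fcluster(Z, t=k, criterion="maxclust")
    groups: dict[int, list[str]] = {}
    for sample, g in zip(samples, raw):
        groups.setdefault(int(g), []).append(sample)
    ordered = sorted(groups.values(), key=lambda ms: (-len(ms), min(ms)))
    labels = {}
    for i, members in enumerate(ordered, start=1):
        for s in members:
            labels[s] = f"CL{i}"
    return ClusterAssignment(
        labels=labels, linkage_matrix=Z, samples=samples,
        selected_tfs=list(selected_tfs or tf_z.index),
        params={"k": k, "distance": "euclidean", "linkage": "complete",
                **(params or {})})


def linkage_to_newick(Z: np.ndarray, leaf_names: list[str]) -> str:
    """Render a scipy linkage matrix as a Newick string with branch
    lengths derived from merge heights."""
    n = len(leaf_names)
    heights = {i: 0.0 for i in range(n)}

    def render(node: int) -> str:
        if node < n:
            return leaf_names[node]
        a, b, h, _ = Z[node - n]
        a, b = int(a), int(b)
        la = h - heights[a]
        lb = h - heights[b]
        return f"({render(a)}:{la:g},{render(b)}:{lb:g})"

    for j in range(Z.shape[0]):
        heights[n + j] = Z[j, 2]
    return render(n + Z.shape[0] - 1) + ";"


def silhouette_report(assignment: ClusterAssignment,
                      matrix: pd.DataFrame) -> pd.Series:
    """Per-sample silhouette values (Euclidean).

    Conventions: members of singleton clusters get 0; if every cluster is a
    singleton (k = n) all values are 0; identical points give 0.
    """
    samples = assignment.samples
    labels = np.array([assignment.labels[s] for s in samples])
    if len(set(labels)) < 2:
        raise ValidationError("silhouette requires k >= 2")
    X = matrix.sort_index().loc[:, samples].to_numpy(dtype=float).T
    D = squareform(pdist(X, metric="euclidean"))
    values = np.zeros(len(samples))
    for i in range(len(samples)):
        own = labels == labels[i]
        n_own = own.sum()
        if n_own == 1:
            values[i] = 0.0  # singleton convention
            continue
        a = D[i, own].sum() / (n_own - 1)
        b = np.inf
        for other in set(labels) - {labels[i]}:
            mask = labels == other
            b = min(b, D[i, mask].mean())
        denom = max(a, b)
        values[i] = 0.0 if denom == 0 else (b - a) / denom
    return pd.Series(values, index=samples)
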