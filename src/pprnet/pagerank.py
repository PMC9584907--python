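"""Node/edge weighting and Personalized PageRank.

Node weights are exp(z_i) of the node's cross-sample expression z-score; the
normalized node weights form the restart (seed) vector.  Raw edge weights
multiply parent expression, relative peak intensity and relative motif
strength; each node's outgoing weights are normalized to sum to 1 so the
walk operator is stochastic.  Dangling-node mass is redistributed according
to the seed vector, which keeps the iterate a probability distribution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io_formats import ExpressionMatrix, PeakSet, ValidationError, zscore_rows
from .network import RegulatoryNetwork

logger = logging.getLogger(__name__)

WEIGHT_CLIP = 1e-6  # lower clip applied to each raw edge-weight factor


@dataclass
class PPRConfig:
    damping: float = 0.85
    tolerance: float = 1e-8     # L1 change per iteration
    max_iterations: int = 1000

    def __post_init__(self):
        if not 0.0 <= self.damping < 1.0:
            raise ValidationError(f"damping must be in [0, 1), got {self.damping}")
        if self.tolerance <= 0:
            raise ValidationError("tolerance must be positive")
        if self.max_iterations < 1:
            raise ValidationError("max_iterations must be >= 1")


class ConvergenceError(RuntimeError):
    def __init__(self, residual: float, iterations: int):
        self.residual = residual
        self.iterations = iterations
        super().__init__(
            f"PageRank did not converge in {iterations} iterations "
            f"(last L1 residual {residual:.3g})")


@dataclass
class WeightedNetwork:
    """Stochastic walk operator derived from a regulatory network."""

    sample_id: str
    nodes: list[str]
    seed: np.ndarray          # restart distribution, sums to 1
    matrix: sp.csr_matrix     # matrix[child, parent] = normalized out-weight
    dangling: np.ndarray      # bool mask of nodes with no outgoing edges

    def index_of(self, node: str) -> int:
        return self.nodes.index(node)


def node_weights(z: pd.Series) -> tuple[pd.Series, pd.Series]:
    """exp(z) node weights and the normalized seed vector."""
    if len(z) == 0:
        raise ValidationError("empty network: no nodes to weight")
    if not np.isfinite(z.to_numpy()).all():
        raise ValidationError("non-finite expression z-scores")
    w = np.exp(z.astype(float))
    return w, w / w.sum()


def edge_weights(net: RegulatoryNetwork,
                 expression: ExpressionMatrix | None = None,
                 peaks: PeakSet | None = None, *,
                 log_expression: bool = True,
                 clip: float = WEIGHT_CLIP) -> WeightedNetwork:
    """Weight edges and build the stochastic operator for one sample.

    Raw weight of edge (parent -> child) =
        exp(z_parent) * (peak intensity / max intensity in sample)
                      * (motif score / max achievable PWM score),
    each factor clipped to >= ``clip``; outgoing weights are then normalized
    per parent node.  The normalized weight is written back onto each edge.
    If ``expression`` is None the z-scores annotated on the network nodes
    are used.
    """
    if expression is not None:
        z_all = expression.zscores(log=log_expression)
        if net.sample_id not in z_all.columns:
            raise ValidationError(
                f"sample {net.sample_id} absent from expression matrix")
        node_z = pd.Series(0.0, index=net.node_z.index)
        present = [n for n in node_z.index if n in z_all.index]
        node_z.loc[present] = z_all.loc[present, net.sample_id]
    else:
        node_z = net.node_z
    if len(node_z) == 0:
        raise ValidationError("network has no nodes")

    nodes = list(node_z.index)
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    _, seed = node_weights(node_z)
    seed_vec = seed.to_numpy()

    intensities = {}
    max_intensity = 1.0
    if peaks is not None:
        intensities = {p.peak_id: p.intensity for p in peaks}
        max_intensity = max(peaks.max_intensity, 0.0) or 1.0

    rows, cols, raw = [], [], []
    for e in net.edges:
        if e.parent not in idx or e.child not in idx:
            raise ValidationError(
                f"edge {e.parent}->{e.child} references unknown node")
        f_expr = max(float(np.exp(node_z[e.parent])), clip)
        inten = intensities.get(e.peak_id, max_intensity)
        if inten < 0:
            raise ValidationError(f"negative intensity for peak {e.peak_id}")
        f_peak = max(inten / max_intensity, clip)
        f_motif = max(e.motif_score, clip)
        rows.append(idx[e.child])
        cols.append(idx[e.parent])
        raw.append(f_expr * f_peak * f_motif)

    mat = sp.csc_matrix((raw, (rows, cols)), shape=(n, n))
    out_sums = np.asarray(mat.sum(axis=0)).ravel()
    dangling = out_sums == 0
    scale = np.where(dangling, 1.0, out_sums)
    mat = mat @ sp.diags(1.0 / scale)
    mat = mat.tocsr()

    # write normalized weights back onto the edges
    for e, w in zip(net.edges, raw):
        e.weight = w / out_sums[idx[e.parent]]

    return WeightedNetwork(sample_id=net.sample_id, nodes=nodes,
                           seed=seed_vec, matrix=mat, dangling=dangling)


def personalized_pagerank(wnet: WeightedNetwork,
                          cfg: PPRConfig | None = None) -> pd.Series:
    """Iterate v_{t+1} = (1-d) s + d (W v_t + dangling_mass * s) from v_0 = s
    until the L1 change drops below tolerance."""
    cfg = cfg or PPRConfig()
    d = cfg.damping
    s = wnet.seed
    v = s.copy()
    for it in range(1, cfg.max_iterations + 1):
        dangling_mass = v[wnet.dangling].sum()
        v_new = (1.0 - d) * s + d * (wnet.matrix @ v + dangling_mass * s)
        residual = np.abs(v_new - v).sum()
        v = v_new
        if residual < cfg.tolerance:
            logger.debug("sample %s: PPR converged in %d iterations "
                         "(residual %.3g)", wnet.sample_id, it, residual)
            return pd.Series(v, index=wnet.nodes)
    raise ConvergenceError(residual, cfg.max_iterations)


@dataclass
class PPRMatrix:
    """Node x sample PageRank scores plus TF-restricted views."""

    scores: pd.DataFrame        # all nodes x samples
    tf_names: list[str]

    def __post_init__(self):
        if self.scores.shape[1] < 2:
            raise ValidationError(
                "need >= 2 samples for cross-sample z-scores")
        self.tf_names = [t for t in self.tf_names if t in self.scores.index]

    @property
    def samples(self) -> list[str]:
        return list(self.scores.columns)

    @property
    def tf_scores(self) -> pd.DataFrame:
        return self.scores.loc[self.tf_names]

    def zscores(self) -> pd.DataFrame:
        """Per-node z-scores across samples (sample SD, ddof=1)."""
        return zscore_rows(self.scores)

    def tf_zscores(self) -> pd.DataFrame:
        return self.zscores().loc[self.tf_names]


def ppr_matrix(scores_by_sample: Mapping[str, pd.Series],
               tf_names: list[str]) -> PPRMatrix:
    """Assemble per-sample score vectors into a node x sample matrix.

    The node universe is the union across samples; nodes missing from a
    sample get score 0.
    """
    if len(scores_by_sample) < 2:
        raise ValidationError("need >= 2 samples to build a PPR matrix")
    nodes = sorted(set().union(*(set(v.index) for v in scores_by_sample.values())))
    df = pd.DataFrame(0.0, index=nodes, columns=sorted(scores_by_sample))
    for sample, vec in scores_by_sample.items():
        df.loc[vec.index, sample] = vec
    return PPRMatrix(scores=df, tf_names=sorted(set(tf_names) & set(nodes)))
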