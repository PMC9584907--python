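"""Cluster-specific TF identification and downstream comparisons.

TFs are ranked by the absolute difference of their mean PageRank z-scores
between the two clusters.  For each candidate, the z-scores of its
regulatee union are reduced by PCA to the components covering 90% of the
variance and tested with a two-sample Hotelling T-squared statistic using
the pooled covariance; the F transform is

    F = (n1 + n2 - k - 1) / (k (n1 + n2 - 2)) * T^2  ~  F(k, n1 + n2 - k - 1).

Also provided: cluster DEG calling, regulatee/DEG coverage, TF-TF
subnetwork extraction and hypergeometric gene-set enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import ExpressionMatrix, ValidationError
from .network import RegulatoryNetwork
from .pagerank import PPRMatrix
from .stratify import ClusterAssignment

logger = logging.getLogger(__name__)

RIDGE = 1e-6  # shrinkage factor for singular pooled covariance


@dataclass
class HotellingResult:
    tf_name: str
    delta_mean_z: float
    n1: int
    n2: int
    k: int
    t2: float
    f_stat: float
    p_value: float
    q_value: float = float("nan")
    n_regulatees: int = 0
    selected: bool = False


def benjamini_hochberg(pvalues: np.ndarray) -> np.ndarray:
    """BH step-up q-values (monotone non-decreasing in p-rank)."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def regulatee_union(tf: str, networks: list[RegulatoryNetwork]) -> set[str]:
    """Union of the TF's child nodes over all sample networks."""
    out: set[str] = set()
    for net in networks:
        out |= net.children_of(tf)
    return out


def _split_groups(df: pd.DataFrame, assignment: ClusterAssignment
                  ) -> tuple[list[str], list[str]]:
    clusters = assignment.clusters
    if len(clusters) != 2:
        raise ValidationError(
            f"two clusters required, got {len(clusters)}")
    g1 = assignment.members(clusters[0])
    g2 = assignment.members(clusters[1])
    missing = (set(g1) | set(g2)) - set(df.columns)
    if missing:
        raise ValidationError(f"samples missing from matrix: {sorted(missing)}")
    return g1, g2


def regulatee_hotelling(tf: str, reg_z: pd.DataFrame,
                        assignment: ClusterAssignment,
                        variance_kept: float = 0.90,
                        ridge: float = RIDGE) -> HotellingResult:
    """Two-sample Hotelling T-squared on PCA-reduced regulatee z-scores.

    ``reg_z`` is regulatees x samples.  PCA is fit on all samples pooled
    (column-centered); k is the smallest component count whose cumulative
    explained variance reaches ``variance_kept``, capped at n1 + n2 - 2.
    A singular pooled covariance is shrunk with lambda = ridge * trace / k.
    """
    g1, g2 = _split_groups(reg_z, assignment)
    n1, n2 = len(g1), len(g2)
    if n1 < 2 or n2 < 2:
        raise ValidationError("each cluster needs >= 2 samples")
    if n1 + n2 < 4:
        raise ValidationError("n1 + n2 must be >= 4")

    skipped = HotellingResult(tf_name=tf, delta_mean_z=float("nan"),
                              n1=n1, n2=n2, k=0, t2=0.0, f_stat=0.0,
                              p_value=1.0, n_regulatees=reg_z.shape[0])
    if reg_z.shape[0] == 0:
        logger.info("TF %s has no regulatees; test skipped (p=1)", tf)
        return skipped

    X = reg_z.loc[:, g1 + g2].to_numpy(dtype=float).T  # samples x regulatees
    Xc = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    total_var = (s ** 2).sum()
    if total_var <= 0:
        return skipped
    explained = (s ** 2) / total_var
    cum = np.cumsum(explained)
    k = int(np.searchsorted(cum, variance_kept - 1e-12) + 1)
    k = min(k, n1 + n2 - 2, int((s > s[0] * 1e-12).sum()))
    scores = U[:, :k] * s[:k]  # PC projections, samples x k

    x1, x2 = scores[:n1], scores[n1:]
    diff = x1.mean(axis=0) - x2.mean(axis=0)
    s1 = np.cov(x1, rowvar=False, ddof=1).reshape(k, k)
    s2 = np.cov(x2, rowvar=False, ddof=1).reshape(k, k)
    sp = ((n1 - 1) * s1 + (n2 - 1) * s2) / (n1 + n2 - 2)
    m = sp * (1.0 / n1 + 1.0 / n2)
    t2 = None
    try:
        sol = np.linalg.solve(m, diff)
        t2 = float(diff @ sol)
    except np.linalg.LinAlgError:
        pass
    if t2 is None or not np.isfinite(t2) or t2 < 0:
        lam = ridge * np.trace(sp) / k
        m = (sp + lam * np.eye(k)) * (1.0 / n1 + 1.0 / n2)
        t2 = float(diff @ np.linalg.solve(m, diff))
    df1, df2 = k, n1 + n2 - k - 1
    f_stat = t2 * df2 / (k * (n1 + n2 - 2))
    p = float(stats.f.sf(f_stat, df1, df2))
    p = min(max(p, np.nextafter(0, 1)), 1.0)
    return HotellingResult(tf_name=tf, delta_mean_z=float("nan"),
                           n1=n1, n2=n2, k=k, t2=t2, f_stat=f_stat,
                           p_value=p, n_regulatees=reg_z.shape[0])


def rank_cluster_tfs(ppr: PPRMatrix, assignment: ClusterAssignment,
                     networks: list[RegulatoryNetwork],
                     n_candidates: int = 200, n_shortlist: int = 100,
                     alpha: float = 0.05, q_alpha: float = 0.05,
                     variance_kept: float = 0.90
                     ) -> tuple[list[HotellingResult], set[str]]:
    """Rank TFs by |mean z(PPR) difference| between clusters, test the top
    candidates' regulatees with the Hotelling procedure, and select TFs.

    BH q-values are computed over all tested candidates.  The shortlist is
    the top ``n_shortlist`` by delta among candidates with p < alpha; the
    final selection keeps shortlist members with q < q_alpha.
    """
    tf_z = ppr.tf_zscores()
    g1, g2 = _split_groups(tf_z, assignment)
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("each cluster needs >= 2 samples")
    delta = (tf_z[g1].mean(axis=1) - tf_z[g2].mean(axis=1)).abs()
    ranked_tfs = sorted(delta.index, key=lambda t: (-delta[t], t))
    candidates = ranked_tfs[:n_candidates]

    all_z = ppr.zscores()
    results: list[HotellingResult] = []
    for tf in candidates:
        regs = sorted(regulatee_union(tf, networks) & set(all_z.index))
        res = regulatee_hotelling(tf, all_z.loc[regs], assignment,
                                  variance_kept=variance_kept)
        res.delta_mean_z = float(delta[tf])
        results.append(res)

    qvals = benjamini_hochberg(np.array([r.p_value for r in results]))
    for r, q in zip(results, qvals):
        r.q_value = float(q)

    shortlist = [r for r in results if r.p_value < alpha][:n_shortlist]
    selected = {r.tf_name for r in shortlist if r.q_value < q_alpha}
    for r in results:
        r.selected = r.tf_name in selected
    return results, selected


# ---------------------------------------------------------------------------
# DEGs and regulatee coverage
# ---------------------------------------------------------------------------

def compute_degs(expression: ExpressionMatrix,
                 assignment: ClusterAssignment,
                 fold_min: float = 2.0, alpha: float = 0.05,
                 pseudocount: float = 0.01) -> pd.DataFrame:
    """Per-gene fold change (cluster-1 vs cluster-2 mean TPM, pseudocount
    both sides), two-sided Student t-test on log2(TPM+1), and a DEG flag
    (fold strictly > ``fold_min`` in either direction AND p strictly <
    ``alpha``)."""
    g1, g2 = _split_groups(expression.tpm, assignment)
    if len(g1) < 2 or len(g2) < 2:
        raise ValidationError("each cluster needs >= 2 samples")
    tpm = expression.tpm
    m1 = tpm[g1].mean(axis=1)
    m2 = tpm[g2].mean(axis=1)
    fold = (m1 + pseudocount) / (m2 + pseudocount)

    log_expr = np.log2(tpm + 1.0)
    x1 = log_expr[g1].to_numpy()
    x2 = log_expr[g2].to_numpy()
    import warnings

    with np.errstate(invalid="ignore", divide="ignore"), \
            warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(x1, x2, axis=1, equal_var=True)
    # zero variance in both groups: p = 1 if means equal, else effectively 0
    nan_mask = ~np.isfinite(p)
    if nan_mask.any():
        equal = np.isclose(x1.mean(axis=1), x2.mean(axis=1))
        p = np.where(nan_mask, np.where(equal, 1.0, 0.0), p)
    p = pd.Series(p, index=tpm.index)

    deg = ((fold > fold_min) | (fold < 1.0 / fold_min)) & (p < alpha)
    return pd.DataFrame({"fold_change": fold, "p_value": p, "is_deg": deg})


def regulated_fraction(tf_set: set[str], degs: pd.DataFrame,
                       networks: list[RegulatoryNetwork]
                       ) -> tuple[float, int, int]:
    """Fraction of DEGs regulated by at least one TF in ``tf_set`` across
    the sample networks.  Returns (fraction, n_regulated, n_degs)."""
    deg_genes = set(degs.index[degs["is_deg"]])
    if not deg_genes:
        raise ValidationError("no DEGs to intersect")
    regulated: set[str] = set()
    for tf in tf_set:
        regulated |= regulatee_union(tf, networks)
    covered = regulated & deg_genes
    return len(covered) / len(deg_genes), len(covered), len(deg_genes)


# ---------------------------------------------------------------------------
# TF-TF subnetworks
# ---------------------------------------------------------------------------

@dataclass
class SubnetworkEdge:
    parent: str
    child: str
    cluster: str
    presence_fraction: float
    mean_weight_cluster: float
    mean_weight_other: float
    weight_ratio: float
    parent_out_degree: int = 0


def tf_tf_subnetwork(networks: list[RegulatoryNetwork],
                     assignment: ClusterAssignment, cluster: str,
                     tf_names: set[str] | list[str],
                     presence_min: float = 0.75,
                     weight_ratio_min: float = 1.5,
                     eps: float = 1e-12) -> list[SubnetworkEdge]:
    """Cluster-specific TF-TF edges.

    Keep edges between TFs present in strictly more than ``presence_min``
    of the cluster's networks whose mean weight (absent edges counted as 0)
    is strictly more than ``weight_ratio_min`` times the other cluster's
    mean (+eps)."""
    tf_names = set(tf_names)
    members = set(assignment.members(cluster))
    others = [c for c in assignment.clusters if c != cluster]
    other_members = {s for c in others for s in assignment.members(c)}
    in_cluster = [n for n in networks if n.sample_id in members]
    out_cluster = [n for n in networks if n.sample_id in other_members]
    if not in_cluster:
        raise ValidationError(f"no networks for cluster {cluster}")

    def weights_of(nets: list[RegulatoryNetwork]
                   ) -> dict[tuple[str, str], list[float]]:
        table: dict[tuple[str, str], list[float]] = {}
        for net in nets:
            for e in net.edges:
                if e.parent in tf_names and e.child in tf_names:
                    table.setdefault((e.parent, e.child), []).append(e.weight)
        return table

    w_in = weights_of(in_cluster)
    w_out = weights_of(out_cluster)
    n_in = len(in_cluster)
    n_out = max(len(out_cluster), 1)

    kept: list[SubnetworkEdge] = []
    for key in sorted(w_in):
        presence = len(w_in[key]) / n_in
        if not presence > presence_min:
            continue
        mean_in = sum(w_in[key]) / n_in  # absent edges count as 0
        mean_out = sum(w_out.get(key, [])) / n_out
        ratio = mean_in / (mean_out + eps)
        if not ratio > weight_ratio_min:
            continue
        kept.append(SubnetworkEdge(
            parent=key[0], child=key[1], cluster=cluster,
            presence_fraction=presence, mean_weight_cluster=mean_in,
            mean_weight_other=mean_out, weight_ratio=ratio))
    out_deg: dict[str, int] = {}
    for e in kept:
        out_deg[e.parent] = out_deg.get(e.parent, 0) + 1
    for e in kept:
        e.parent_out_degree = out_deg[e.parent]
    return kept


# ---------------------------------------------------------------------------
# Hypergeometric enrichment
# ---------------------------------------------------------------------------

def hypergeom_enrichment(query: set[str], collection: dict[str, set[str]],
                         universe: set[str]) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation p-value per gene set,
    with BH q-values across sets."""
    if not universe:
        raise ValidationError("empty universe")
    if not query:
        raise ValidationError("empty query")
    if not query <= universe:
        raise ValidationError("query must be a subset of the universe")
    names, pvals, overlaps, sizes = [], [], [], []
    M = len(universe)
    N = len(query)
    for name in sorted(collection):
        members = collection[name] & universe
        K = len(members)
        k = len(members & query)
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        names.append(name)
        pvals.append(min(p, 1.0))
        overlaps.append(k)
        sizes.append(K)
    q = benjamini_hochberg(np.array(pvals)) if names else np.array([])
    return pd.DataFrame({
        "set_size": sizes, "overlap": overlaps,
        "p_value": pvals, "q_value": q,
    }, index=pd.Index(names, name="gene_set"))
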