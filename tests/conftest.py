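import numpy as np
import pandas as pd
import pytest

from pprnet import network as nm
from pprnet import pagerank as pr
from pprnet import synthetic as syn
from pprnet.stratify import ClusterAssignment

SMALL_CONFIG = dict(seed=1, n_samples=11, cluster_sizes=(7, 4), n_tfs=20,
                    n_genes=150, n_driver_tfs=3, effect_size=4.0,
                    edge_density=0.08)


@pytest.fixture(scope="session")
def dataset():
    """Small planted-structure dataset shared across the suite."""
    return syn.simulate_dataset(syn.SimulationConfig(**SMALL_CONFIG))


@pytest.fixture(scope="session")
def built(dataset):
    """Networks, weighted networks and PPR scores for every sample."""
    ds = dataset
    first = ds.samples[0]
    hits = nm.scan_all_peaks(ds.peaks[first], ds.sequences, ds.motifs)
    nets, scores = {}, {}
    for s in ds.samples:
        net, _ = nm.build_network(s, ds.peaks[s], ds.annotation, ds.motifs,
                                  ds.links, ds.expression, hits=hits)
        wnet = pr.edge_weights(net, peaks=ds.peaks[s])
        scores[s] = pr.personalized_pagerank(wnet)
        nets[s] = net
    return nets, scores


@pytest.fixture(scope="session")
def ppr_mat(dataset, built):
    _, scores = built
    return pr.ppr_matrix(scores, dataset.annotation.tf_names)


def make_assignment(n1: int, n2: int) -> ClusterAssignment:
    samples = [f"S{i + 1:02d}" for i in range(n1 + n2)]
    labels = {s: ("CL1" if i < n1 else "CL2") for i, s in enumerate(samples)}
    return ClusterAssignment(labels=labels, linkage_matrix=np.empty((0, 4)),
                             samples=samples, selected_tfs=[], params={})


def toy_network(sample_id, pairs, nodes=None, weights=None):
    """RegulatoryNetwork from bare (parent, child) pairs."""
    edges = []
    for i, (tf, g) in enumerate(pairs):
        w = weights[i] if weights is not None else 0.0
        edges.append(nm.Edge(parent=tf, child=g, evidence="promoter",
                             peak_id=f"pk{i}", motif_score=1.0, weight=w))
    if nodes is None:
        nodes = sorted({n for p in pairs for n in p})
    return nm.RegulatoryNetwork(sample_id=sample_id, edges=edges,
                                node_z=pd.Series(0.0, index=list(nodes)))
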