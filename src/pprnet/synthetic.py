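"""Coupled synthetic inputs with planted two-cluster structure.

Generates peak sequences, per-sample peak sets, a TPM expression matrix,
gene annotation, a motif library, an enhancer link table and the ground
truth used to score recovery.  True TF->gene edges are realized by planting
the TF's consensus sequence inside the 150 bp window around the target
peak's summit; driver-TF expression is shifted between the two planted
clusters and regulatee expression follows its driver linearly plus noise.
All randomness flows from the config seed, so identical configs produce
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io_formats as iof
from .io_formats import (
    BASES,
    EnhancerLinkTable,
    ExpressionMatrix,
    GeneAnnotation,
    Motif,
    MotifLibrary,
    Peak,
    PeakSet,
    ValidationError,
)
from .network import SCAN_WINDOW, RegulatoryNetwork


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 11
    n_tfs: int = 30
    n_genes: int = 300              # non-TF genes; TFs are genes too
    n_driver_tfs: int = 3           # planted drivers per cluster
    cluster_sizes: tuple[int, int] = (7, 4)
    effect_size: float = 2.0        # standardized driver mean shift
    noise_sd: float = 0.5           # additive log2-expression noise
    edge_density: float = 0.05      # P(TF regulates a given gene)
    motif_length: int = 10
    motif_info: float = 0.97        # consensus-base probability
    peak_intensity_lognorm: tuple[float, float] = (1.0, 0.5)
    enhancer_fraction: float = 0.2  # true edges mediated by enhancers
    beta: float = 0.8               # regulatee response to driver deviation
    baseline_log_mean: float = 5.0
    baseline_log_sd: float = 1.0
    peak_width: int = 400
    seed: int = 0

    def __post_init__(self):
        if sum(self.cluster_sizes) != self.n_samples:
            raise ConfigurationError(
                f"cluster sizes {self.cluster_sizes} do not sum to "
                f"n_samples {self.n_samples}")
        if self.effect_size < 0:
            raise ConfigurationError("effect_size must be >= 0")
        if not 0 < self.edge_density <= 1:
            raise ConfigurationError("edge_density must be in (0, 1]")
        if not 0.25 <= self.motif_info <= 1:
            raise ConfigurationError("motif_info must be in [0.25, 1]")
        if not 0 <= self.enhancer_fraction <= 1:
            raise ConfigurationError("enhancer_fraction must be in [0, 1]")
        if 2 * self.n_driver_tfs > self.n_tfs:
            raise ConfigurationError("too many driver TFs for n_tfs")
        if self.peak_width < SCAN_WINDOW:
            raise ConfigurationError(
                f"peak_width must be >= scan window ({SCAN_WINDOW})")


@dataclass
class GroundTruth:
    true_edges: set[tuple[str, str, str]]       # (tf, gene, sample)
    true_clusters: dict[str, str]               # sample -> cluster
    true_drivers: dict[str, set[str]]           # cluster -> TF set
    planted_motif_positions: dict[str, list[tuple[str, int]]]
    # peak_id -> [(tf, offset within the scan window)]

    def edges_for_sample(self, sample: str) -> set[tuple[str, str]]:
        if sample not in self.true_clusters:
            raise KeyError(f"sample {sample} not in ground truth")
        return {(tf, g) for tf, g, s in self.true_edges if s == sample}

    def to_json(self) -> dict:
        return {
            "true_edges": sorted(list(e) for e in self.true_edges),
            "true_clusters": self.true_clusters,
            "true_drivers": {c: sorted(v) for c, v in self.true_drivers.items()},
            "planted_motif_positions": {
                pid: [[tf, off] for tf, off in offs]
                for pid, offs in self.planted_motif_positions.items()},
        }

    @classmethod
    def from_json(cls, obj: dict) -> "GroundTruth":
        return cls(
            true_edges={tuple(e) for e in obj["true_edges"]},
            true_clusters=dict(obj["true_clusters"]),
            true_drivers={c: set(v) for c, v in obj["true_drivers"].items()},
            planted_motif_positions={
                pid: [(tf, int(off)) for tf, off in offs]
                for pid, offs in obj["planted_motif_positions"].items()},
        )


@dataclass
class SyntheticDataset:
    config: SimulationConfig
    sequences: dict[str, str]           # peak_id -> peak sequence
    peaks: dict[str, PeakSet]           # sample -> PeakSet
    expression: ExpressionMatrix
    annotation: GeneAnnotation
    motifs: MotifLibrary
    links: EnhancerLinkTable
    truth: GroundTruth

    @property
    def samples(self) -> list[str]:
        return sorted(self.peaks)


def _consensus_pwm(consensus: str, info: float) -> np.ndarray:
    pwm = np.full((len(consensus), 4), (1.0 - info) / 3.0)
    for i, base in enumerate(consensus):
        pwm[i, BASES.index(base)] = info
    return pwm


def simulate_dataset(config: SimulationConfig) -> SyntheticDataset:
    rng = np.random.default_rng(config.seed)
    c1, c2 = config.cluster_sizes
    samples = [f"S{i + 1:02d}" for i in range(config.n_samples)]
    clusters = {s: ("CL1" if i < c1 else "CL2")
                for i, s in enumerate(samples)}

    tf_names = [f"TF{i + 1:03d}" for i in range(config.n_tfs)]
    gene_names = [f"G{i + 1:04d}" for i in range(config.n_genes)]
    all_genes = tf_names + gene_names

    d = config.n_driver_tfs
    drivers = {"CL1": set(tf_names[:d]), "CL2": set(tf_names[d:2 * d])}
    driver_cluster = {tf: c for c, tfs in drivers.items() for tf in tfs}

    # motifs: random consensus per TF
    consensi = {}
    motifs = []
    for tf in tf_names:
        consensus = "".join(rng.choice(list(BASES), size=config.motif_length))
        consensi[tf] = consensus
        motifs.append(Motif(tf, _consensus_pwm(consensus, config.motif_info)))
    library = MotifLibrary(motifs, np.full(4, 0.25))

    # regulatory topology: TF -> gene (genes include other TFs, no self)
    edges: list[tuple[str, str]] = []
    for tf in tf_names:
        targets = [g for g in all_genes
                   if g != tf and rng.random() < config.edge_density]
        edges.extend((tf, g) for g in targets)
    # every driver must regulate something
    existing_parents = {tf for tf, _ in edges}
    for tf in sorted(driver_cluster):
        if tf not in existing_parents:
            g = gene_names[int(rng.integers(len(gene_names)))]
            edges.append((tf, g))

    parents: dict[str, list[str]] = {}
    for tf, g in edges:
        parents.setdefault(g, []).append(tf)

    # genome layout: one promoter peak per gene, enhancer peaks beyond
    spacing = 12000
    half_w = config.peak_width // 2
    ann_rows = []
    peak_defs: list[tuple[str, int, int, int]] = []  # (peak_id, start, end, summit)
    promoter_peak: dict[str, str] = {}
    for i, g in enumerate(all_genes):
        tss = 6000 + i * spacing
        strand = "+" if rng.random() < 0.5 else "-"
        ann_rows.append((g, "chr1", tss, strand, g in set(tf_names)))
        pid = f"peak{i + 1:05d}"
        promoter_peak[g] = pid
        peak_defs.append((pid, tss - half_w, tss + half_w, tss))
    annotation = GeneAnnotation(pd.DataFrame(
        [r[1:] for r in ann_rows], index=[r[0] for r in ann_rows],
        columns=["chrom", "tss", "strand", "is_tf"]))

    # assign each true edge to a promoter or enhancer peak
    enhancer_region_start = 6000 + len(all_genes) * spacing + 100000
    link_rows: list[tuple[str, str]] = []
    edge_peak: dict[tuple[str, str], str] = {}
    n_enh = 0
    for tf, g in sorted(edges):
        if rng.random() < config.enhancer_fraction:
            start = enhancer_region_start + n_enh * (config.peak_width + 2000)
            pid = f"epeak{n_enh + 1:05d}"
            peak_defs.append((pid, start, start + config.peak_width,
                              start + half_w))
            link_rows.append((pid, g))
            edge_peak[(tf, g)] = pid
            n_enh += 1
        else:
            edge_peak[(tf, g)] = promoter_peak[g]
    links = EnhancerLinkTable(pd.DataFrame(link_rows or [],
                                           columns=["peak_id", "gene_id"]))

    # peak sequences with planted consensus motifs inside the scan window
    half_scan = SCAN_WINDOW // 2
    sequences: dict[str, str] = {}
    planted: dict[str, list[tuple[str, int]]] = {}
    seq_arrays: dict[str, np.ndarray] = {}
    for pid, start, end, summit in peak_defs:
        seq_arrays[pid] = rng.integers(0, 4, size=end - start)
    occupied: dict[str, list[tuple[int, int]]] = {pid: [] for pid in seq_arrays}
    realized: set[tuple[str, str]] = set()
    L = config.motif_length
    for (tf, g), pid in sorted(edge_peak.items()):
        spans = occupied[pid]
        placed = None
        for _ in range(50):
            off = int(rng.integers(0, SCAN_WINDOW - L + 1))
            if all(off + L <= lo or off >= hi for lo, hi in spans):
                placed = off
                break
        if placed is None:
            continue  # window full; edge not realized
        spans.append((placed, placed + L))
        realized.add((tf, g))
        planted.setdefault(pid, []).append((tf, placed))
        # window start relative to peak start
        peak_start = next(s for p, s, e, sm in peak_defs if p == pid)
        summit = next(sm for p, s, e, sm in peak_defs if p == pid)
        win_lo = (summit - peak_start) - half_scan
        arr = seq_arrays[pid]
        for j, base in enumerate(consensi[tf]):
            arr[win_lo + placed + j] = BASES.index(base)
    for pid, arr in seq_arrays.items():
        sequences[pid] = "".join(BASES[b] for b in arr)
    for pid in planted:
        planted[pid].sort()

    # per-sample peak sets with log-normal intensities
    mu, sigma = config.peak_intensity_lognorm
    peaksets: dict[str, PeakSet] = {}
    for s in samples:
        intens = rng.lognormal(mu, sigma, size=len(peak_defs))
        peaksets[s] = PeakSet(s, [
            Peak("chr1", start, end, pid, float(val), ".", summit)
            for (pid, start, end, summit), val in zip(peak_defs, intens)])

    # expression: log-normal baseline; drivers shifted between clusters;
    # regulatees of drivers follow the driver deviation linearly
    baseline = rng.normal(config.baseline_log_mean, config.baseline_log_sd,
                          size=len(all_genes))
    shift = config.effect_size * config.noise_sd
    in_cluster = {c: np.array([clusters[s] == c for s in samples])
                  for c in ("CL1", "CL2")}
    log_expr = np.tile(baseline[:, None], (1, len(samples)))
    gene_index = {g: i for i, g in enumerate(all_genes)}
    for tf, c in driver_cluster.items():
        log_expr[gene_index[tf]] += shift * in_cluster[c]
    for g, ps in parents.items():
        for tf in ps:
            c = driver_cluster.get(tf)
            if c is not None and (tf, g) in realized:
                log_expr[gene_index[g]] += (
                    config.beta * shift * in_cluster[c])
    log_expr += rng.normal(0.0, config.noise_sd, size=log_expr.shape)
    raw = np.power(2.0, log_expr)
    tpm = raw / raw.sum(axis=0, keepdims=True) * 1e6
    expression = ExpressionMatrix(pd.DataFrame(tpm, index=all_genes,
                                               columns=samples))

    true_edges = {(tf, g, s) for (tf, g) in realized for s in samples}
    truth = GroundTruth(true_edges=true_edges, true_clusters=clusters,
                        true_drivers=drivers,
                        planted_motif_positions=planted)
    return SyntheticDataset(config=config, sequences=sequences,
                            peaks=peaksets, expression=expression,
                            annotation=annotation, motifs=library,
                            links=links, truth=truth)


def write_dataset(ds: SyntheticDataset, outdir: str | Path) -> dict[str, str]:
    """Write every component to plain-text files; returns the path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    iof.write_fasta(ds.sequences, outdir / "peaks.fa")
    paths["sequences"] = str(outdir / "peaks.fa")
    for sample in ds.samples:
        p = outdir / f"{sample}.peaks.bed"
        iof.write_peaks(ds.peaks[sample], p)
        paths[f"peaks:{sample}"] = str(p)
    iof.write_expression(ds.expression, outdir / "expression.tsv")
    paths["expression"] = str(outdir / "expression.tsv")
    iof.write_annotation(ds.annotation, outdir / "annotation.tsv")
    paths["annotation"] = str(outdir / "annotation.tsv")
    iof.write_motifs(ds.motifs, outdir / "motifs.meme")
    paths["motifs"] = str(outdir / "motifs.meme")
    iof.write_links(ds.links, outdir / "links.tsv")
    paths["links"] = str(outdir / "links.tsv")
    iof.write_json(ds.truth.to_json(), outdir / "truth.json")
    paths["truth"] = str(outdir / "truth.json")
    iof.write_json(dataclasses.asdict(ds.config), outdir / "config.json")
    paths["config"] = str(outdir / "config.json")
    return paths


def realized_edge_recall(truth: GroundTruth, net: RegulatoryNetwork) -> float:
    """Fraction of the sample's true edges recovered by the network."""
    true_pairs = truth.edges_for_sample(net.sample_id)
    if not true_pairs:
        return float("nan")
    recovered = net.edge_set() & true_pairs
    return len(recovered) / len(true_pairs)


def edge_precision(truth: GroundTruth, net: RegulatoryNetwork) -> float:
    """Fraction of predicted edges that are true (diagnostic)."""
    predicted = net.edge_set()
    if not predicted:
        return float("nan")
    true_pairs = truth.edges_for_sample(net.sample_id)
    return len(predicted & true_pairs) / len(predicted)
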