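"""Per-sample TF->gene network construction.

Peaks are classified as promoter peaks (>=1 bp overlap with a strand-aware
promoter window) or enhancer peaks (via a precomputed link table); motif
occurrences are called in fixed-width windows centered on peak summits with
log-odds scores and exact p-values from a dynamic program over the PWM score
distribution; edges connect a TF to a gene whenever the TF has a significant
hit in one of the gene's promoter or linked-enhancer peaks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

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

logger = logging.getLogger(__name__)

SCAN_WINDOW = 150          # bp centered on the peak summit
MOTIF_PVALUE = 1e-4        # significance threshold for a motif hit
PROMOTER_UPSTREAM = 5000   # bp upstream of the TSS
PROMOTER_DOWNSTREAM = 1000  # bp downstream of the TSS

# log-odds scores are quantized to integer milli-bits so that the exact
# score-distribution DP and a brute-force enumeration agree bit-for-bit
SCORE_SCALE = 1000

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = np.array([3, 2, 1, 0])  # A<->T, C<->G in ACGT order


@dataclass(frozen=True)
class MotifHit:
    tf_name: str
    peak_id: str
    offset: int        # position of the match start within the scan window
    strand: str
    score_bits: float  # log-odds score in bits
    score_frac: float  # score / maximum achievable score for the PWM
    p_value: float     # P(score >= observed) for one position under background


@dataclass
class Edge:
    parent: str
    child: str
    evidence: str      # "promoter" | "enhancer"
    peak_id: str
    motif_score: float  # fraction of the PWM's maximum score
    weight: float = 0.0  # normalized edge weight, set by the pagerank module


@dataclass
class RegulatoryNetwork:
    """Directed, weighted TF->gene network for one sample."""

    sample_id: str
    edges: list[Edge]
    node_z: pd.Series  # expression z-score per node (all genes + TFs)

    def __post_init__(self):
        keys = [(e.parent, e.child) for e in self.edges]
        if len(keys) != len(set(keys)):
            raise ValidationError(
                f"sample {self.sample_id}: duplicate (parent, child) edges")

    @property
    def nodes(self) -> list[str]:
        return list(self.node_z.index)

    def edge_set(self) -> set[tuple[str, str]]:
        return {(e.parent, e.child) for e in self.edges}

    def children_of(self, tf: str) -> set[str]:
        return {e.child for e in self.edges if e.parent == tf}


# ---------------------------------------------------------------------------
# Promoter windows and peak classification
# ---------------------------------------------------------------------------

def promoter_window(tss: int, strand: str,
                    upstream: int = PROMOTER_UPSTREAM,
                    downstream: int = PROMOTER_DOWNSTREAM) -> tuple[int, int]:
    """Strand-aware promoter interval around a TSS, 0-based half-open,
    clipped at the chromosome origin."""
    if strand == "+":
        lo, hi = tss - upstream, tss + downstream
    elif strand == "-":
        lo, hi = tss - downstream, tss + upstream
    else:
        raise ValidationError(f"invalid strand {strand!r}")
    return max(0, lo), hi


@dataclass
class PeakClassification:
    promoter: dict[str, list[str]]  # peak_id -> gene ids
    enhancer: dict[str, list[str]]
    dropped: list[str]
    ignored_links: int = 0


def classify_peaks(peaks: PeakSet, annotation: GeneAnnotation,
                   links: EnhancerLinkTable,
                   upstream: int = PROMOTER_UPSTREAM,
                   downstream: int = PROMOTER_DOWNSTREAM) -> PeakClassification:
    """Partition peaks into promoter / enhancer / dropped.

    A peak overlapping >=1 promoter window by >=1 bp is a promoter peak,
    assigned to every overlapped gene.  Remaining peaks with link-table
    entries are enhancer peaks for the linked genes.  Links that point at
    promoter-classified peaks are ignored (logged).  Everything else is
    dropped.
    """
    ann = annotation.table
    windows = {}
    by_chrom: dict[str, list[tuple[int, int, str]]] = {}
    for gid, row in ann.iterrows():
        lo, hi = promoter_window(int(row["tss"]), row["strand"],
                                 upstream, downstream)
        windows[gid] = (lo, hi)
        by_chrom.setdefault(row["chrom"], []).append((lo, hi, gid))

    peak_ids = {p.peak_id for p in peaks}
    link_map = links.by_peak()
    for pid, gids in link_map.items():
        if pid not in peak_ids:
            raise ValidationError(f"link references unknown peak {pid}")
        for gid in gids:
            if gid not in annotation:
                raise ValidationError(f"link references unknown gene {gid}")

    promoter: dict[str, list[str]] = {}
    enhancer: dict[str, list[str]] = {}
    dropped: list[str] = []
    ignored = 0
    for p in peaks:
        hits = [gid for lo, hi, gid in by_chrom.get(p.chrom, ())
                if p.start < hi and lo < p.end]
        if hits:
            promoter[p.peak_id] = sorted(hits)
            if p.peak_id in link_map:
                ignored += len(link_map[p.peak_id])
                logger.info("ignoring %d link(s) to promoter peak %s",
                            len(link_map[p.peak_id]), p.peak_id)
        elif p.peak_id in link_map:
            enhancer[p.peak_id] = sorted(set(link_map[p.peak_id]))
        else:
            dropped.append(p.peak_id)
    return PeakClassification(promoter, enhancer, dropped, ignored)


# ---------------------------------------------------------------------------
# Motif scanning
# ---------------------------------------------------------------------------

def encode_sequence(seq: str) -> np.ndarray:
    """Map ACGT to 0..3; any other character to -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, idx in _BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out


def log_odds_matrix(pwm: np.ndarray, background: np.ndarray,
                    pseudo: float = 1e-6) -> np.ndarray:
    """Per-position log2 odds in bits, with a background-proportional
    pseudocount so zero PWM entries stay finite."""
    p = (pwm + pseudo * background[None, :]) / (1.0 + pseudo)
    return np.log2(p / background[None, :])


def quantize_lom(lom: np.ndarray) -> np.ndarray:
    return np.rint(lom * SCORE_SCALE).astype(np.int64)


def score_survival(qlom: np.ndarray, background: np.ndarray) -> tuple[
        np.ndarray, np.ndarray]:
    """Exact null distribution of the quantized PWM score.

    Dynamic program convolving per-position score distributions under the
    0-order background.  Returns (sorted unique scores ascending,
    survival[i] = P(score >= scores[i])).
    """
    dist: dict[int, float] = {0: 1.0}
    for row in qlom:
        new: dict[int, float] = {}
        for s, prob in dist.items():
            for b in range(4):
                key = s + int(row[b])
                new[key] = new.get(key, 0.0) + prob * background[b]
        dist = new
    scores = np.array(sorted(dist), dtype=np.int64)
    probs = np.array([dist[int(s)] for s in scores])
    # survival from the top down
    surv = probs[::-1].cumsum()[::-1]
    return scores, surv


class MotifScanner:
    """Scans sequences against a motif library on both strands.

    Score p-values are exact under the 0-order background via the score
    distribution DP; hits are positions with p-value strictly below the
    threshold.
    """

    def __init__(self, motifs: MotifLibrary,
                 background: np.ndarray | None = None,
                 pvalue_threshold: float = MOTIF_PVALUE):
        self.motifs = motifs
        self.background = (np.asarray(background, dtype=float)
                           if background is not None else motifs.background)
        if abs(self.background.sum() - 1.0) > 1e-6:
            raise ValidationError("background probabilities must sum to 1")
        self.pvalue_threshold = pvalue_threshold
        self._tables = {}
        for m in motifs:
            lom = log_odds_matrix(m.pwm, self.background)
            qlom = quantize_lom(lom)
            scores, surv = score_survival(qlom, self.background)
            max_score = int(qlom.max(axis=1).sum())
            self._tables[m.tf_name] = (qlom, scores, surv, max_score)

    def max_score_bits(self, tf_name: str) -> float:
        return self._tables[tf_name][3] / SCORE_SCALE

    def _pvalue(self, tf_name: str, qscore: int) -> float:
        _, scores, surv, _ = self._tables[tf_name]
        i = np.searchsorted(scores, qscore, side="left")
        if i >= len(scores):
            return float(surv[-1]) if qscore <= scores[-1] else 0.0
        return float(surv[i])

    def scan(self, seq: str, peak_id: str = "") -> list[MotifHit]:
        """All significant hits of every motif in ``seq``, both strands.

        Offsets are match start positions on the forward strand of ``seq``.
        """
        enc = encode_sequence(seq)
        hits: list[MotifHit] = []
        for m in self.motifs:
            hits.extend(self._scan_one(enc, m, peak_id))
        return hits

    def _scan_one(self, enc: np.ndarray, motif: Motif,
                  peak_id: str) -> list[MotifHit]:
        qlom, scores, surv, max_score = self._tables[motif.tf_name]
        L = qlom.shape[0]
        n = enc.shape[0]
        if L > n:
            logger.info("motif %s (%d bp) longer than window (%d bp); skipped",
                        motif.tf_name, L, n)
            return []
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        valid = (windows >= 0).all(axis=1)
        hits: list[MotifHit] = []
        safe = np.where(windows >= 0, windows, 0)
        for strand in "+-":
            mat = qlom if strand == "+" else qlom[::-1, _COMPLEMENT]
            pos_scores = mat[np.arange(L), safe].sum(axis=1)
            idx = np.searchsorted(scores, pos_scores, side="left")
            pvals = surv[np.minimum(idx, len(scores) - 1)]
            pvals = np.where(idx >= len(scores), 0.0, pvals)
            sig = valid & (pvals < self.pvalue_threshold)
            for off in np.nonzero(sig)[0]:
                q = int(pos_scores[off])
                frac = q / max_score if max_score > 0 else 0.0
                hits.append(MotifHit(
                    tf_name=motif.tf_name, peak_id=peak_id,
                    offset=int(off), strand=strand,
                    score_bits=q / SCORE_SCALE, score_frac=frac,
                    p_value=float(pvals[off])))
        return hits


def summit_window(peak: Peak, seq: str, scan_bp: int = SCAN_WINDOW
                  ) -> tuple[str, int]:
    """Sequence of the scan window centered on the summit, clipped to the
    peak; returns (window sequence, window start offset within the peak)."""
    half = scan_bp // 2
    rel = peak.summit - peak.start
    lo = max(0, rel - half)
    hi = min(len(seq), rel + (scan_bp - half))
    return seq[lo:hi], lo


def estimate_background(sequences: list[str]) -> np.ndarray:
    """0-order background from base counts over all scanned windows
    (with +1 smoothing so no probability is zero)."""
    counts = np.ones(4, dtype=float)
    for seq in sequences:
        enc = encode_sequence(seq)
        enc = enc[enc >= 0]
        counts += np.bincount(enc, minlength=4)
    return counts / counts.sum()


def scan_all_peaks(peaks: PeakSet, sequences: dict[str, str],
                   motifs: MotifLibrary, *,
                   scan_bp: int = SCAN_WINDOW,
                   pvalue_threshold: float = MOTIF_PVALUE,
                   background: np.ndarray | None = None
                   ) -> dict[str, list[MotifHit]]:
    """Motif hits for every peak's summit window.

    Peak sequences are shared across samples that call the same peaks, so
    multi-sample pipelines can scan once and pass the result to
    :func:`build_network`.
    """
    windows = {}
    for p in peaks:
        if p.peak_id not in sequences:
            raise ValidationError(f"no sequence for peak {p.peak_id}")
        windows[p.peak_id] = summit_window(p, sequences[p.peak_id], scan_bp)[0]
    if background is None:
        background = estimate_background(list(windows.values()))
    scanner = MotifScanner(motifs, background, pvalue_threshold)
    return {pid: scanner.scan(seq, pid) for pid, seq in windows.items()}


# ---------------------------------------------------------------------------
# Network assembly
# ---------------------------------------------------------------------------

def build_network(sample_id: str, peaks: PeakSet, annotation: GeneAnnotation,
                  motifs: MotifLibrary, links: EnhancerLinkTable,
                  expression: ExpressionMatrix,
                  sequences: dict[str, str] | None = None, *,
                  scan_bp: int = SCAN_WINDOW,
                  pvalue_threshold: float = MOTIF_PVALUE,
                  background: np.ndarray | None = None,
                  log_expression: bool = True,
                  upstream: int = PROMOTER_UPSTREAM,
                  downstream: int = PROMOTER_DOWNSTREAM,
                  hits: dict[str, list[MotifHit]] | None = None
                  ) -> tuple[RegulatoryNetwork, dict]:
    """Assemble the TF->gene network for one sample.

    An edge TF->gene exists iff the TF has >=1 significant motif hit in a
    promoter peak of the gene or in an enhancer peak linked to it.  Multiple
    supporting hits collapse to one edge keeping the best-scoring hit
    (ties: higher peak intensity, then lexicographic peak id).
    Returns the network and a build report.
    """
    if hits is None:
        if sequences is None:
            raise ValueError("either sequences or precomputed hits required")
        hits = scan_all_peaks(peaks, sequences, motifs, scan_bp=scan_bp,
                              pvalue_threshold=pvalue_threshold,
                              background=background)
    cls = classify_peaks(peaks, annotation, links, upstream, downstream)
    peak_by_id = peaks.by_id()

    tf_names = set(annotation.tf_names)
    for tf in motifs.tf_names:
        if tf not in tf_names:
            logger.warning("motif TF %s absent from annotation; node added "
                           "with zero expression", tf)
            tf_names.add(tf)

    # gene -> [(peak, evidence)]
    gene_peaks: dict[str, list[tuple[Peak, str]]] = {}
    for pid, gids in cls.promoter.items():
        for gid in gids:
            gene_peaks.setdefault(gid, []).append((peak_by_id[pid], "promoter"))
    for pid, gids in cls.enhancer.items():
        for gid in gids:
            gene_peaks.setdefault(gid, []).append((peak_by_id[pid], "enhancer"))

    best: dict[tuple[str, str], tuple] = {}
    n_hits = 0
    for gid, plist in gene_peaks.items():
        for peak, evidence in plist:
            for h in hits.get(peak.peak_id, ()):  # hits are per peak
                if h.tf_name == gid:
                    continue  # no self-loops
                n_hits += 1
                key = (h.tf_name, gid)
                cand = (h.score_frac, peak.intensity, peak.peak_id, evidence)
                prev = best.get(key)
                if (prev is None or cand[0] > prev[0]
                        or (cand[0] == prev[0] and cand[1] > prev[1])
                        or (cand[0] == prev[0] and cand[1] == prev[1]
                            and cand[2] < prev[2])):
                    best[key] = cand
    edges = [Edge(parent=tf, child=gid, evidence=ev, peak_id=pid,
                  motif_score=frac)
             for (tf, gid), (frac, _inten, pid, ev) in sorted(best.items())]

    nodes = sorted(set(annotation.gene_ids) | tf_names)
    z_all = expression.zscores(log=log_expression)
    if sample_id not in z_all.columns:
        raise ValidationError(f"sample {sample_id} absent from expression matrix")
    node_z = pd.Series(0.0, index=nodes)
    present = [n for n in nodes if n in z_all.index]
    node_z.loc[present] = z_all.loc[present, sample_id]

    net = RegulatoryNetwork(sample_id=sample_id, edges=edges, node_z=node_z)
    report = {
        "sample_id": sample_id,
        "n_peaks": len(peaks),
        "n_promoter_peaks": len(cls.promoter),
        "n_enhancer_peaks": len(cls.enhancer),
        "n_dropped_peaks": len(cls.dropped),
        "n_ignored_links": cls.ignored_links,
        "n_motif_hits": n_hits,
        "n_edges": len(edges),
        "n_nodes": len(nodes),
    }
    return net, report
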