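"""Readers and writers for every on-disk format the pipeline touches.

All genomic coordinates are 0-based, half-open.  Every reader validates its
input strictly and raises :class:`FormatError` (malformed syntax) or
:class:`ValidationError` (well-formed but semantically invalid) rather than
silently coercing.  Writers are deterministic: the same in-memory object
always produces byte-identical files.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "Peak",
    "PeakSet",
    "GeneAnnotation",
    "ExpressionMatrix",
    "Motif",
    "MotifLibrary",
    "EnhancerLinkTable",
    "read_peaks",
    "write_peaks",
    "read_expression",
    "write_expression",
    "read_annotation",
    "write_annotation",
    "read_motifs",
    "write_motifs",
    "read_links",
    "write_links",
    "read_network",
    "write_network",
    "read_fasta",
    "write_fasta",
    "read_gmt",
    "zscore_rows",
]

BASES = "ACGT"
EVIDENCE_TAGS = ("promoter", "enhancer")


class FormatError(ValueError):
    """A file does not conform to its expected syntax."""


class ValidationError(ValueError):
    """A parsed object violates a semantic invariant."""


def _fmt(x: float) -> str:
    """Shortest decimal string that round-trips through float()."""
    return repr(float(x))


# ---------------------------------------------------------------------------
# Peaks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    peak_id: str
    intensity: float
    strand: str
    summit: int  # absolute coordinate

    def __post_init__(self):
        if self.start >= self.end:
            raise ValidationError(
                f"peak {self.peak_id}: start {self.start} >= end {self.end}")
        if not (self.start <= self.summit < self.end):
            raise ValidationError(
                f"peak {self.peak_id}: summit {self.summit} outside "
                f"[{self.start}, {self.end})")
        if self.intensity < 0 or not math.isfinite(self.intensity):
            raise ValidationError(
                f"peak {self.peak_id}: invalid intensity {self.intensity}")


@dataclass
class PeakSet:
    """All peaks called for one sample."""

    sample_id: str
    peaks: list[Peak]

    def __post_init__(self):
        ids = [p.peak_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValidationError(
                f"sample {self.sample_id}: duplicate peak ids {dup[:5]}")

    def __len__(self) -> int:
        return len(self.peaks)

    def __iter__(self):
        return iter(self.peaks)

    def by_id(self) -> dict[str, Peak]:
        return {p.peak_id: p for p in self.peaks}

    @property
    def max_intensity(self) -> float:
        if not self.peaks:
            return 0.0
        return max(p.intensity for p in self.peaks)


def read_peaks(path: str | Path, sample_id: str) -> PeakSet:
    """Read a BED6+summit (7-column) or narrowPeak (10-column) file.

    7 columns: chrom start end name intensity strand summit_offset
    10 columns (narrowPeak): intensity taken from signalValue (col 7),
    summit = start + col-10 offset.
    """
    peaks: list[Peak] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated input
                fields = line.split()
            try:
                if len(fields) == 7:
                    chrom, start, end, name, inten, strand, off = fields
                    intensity = float(inten)
                elif len(fields) == 10:
                    chrom, start, end, name = fields[:4]
                    strand = fields[5]
                    intensity = float(fields[6])
                    off = fields[9]
                else:
                    raise FormatError(
                        f"{path}: line {lineno}: expected 7 or 10 columns, "
                        f"got {len(fields)}")
                start_i, end_i, off_i = int(start), int(end), int(off)
            except FormatError:
                raise
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if off_i < 0:
                raise FormatError(
                    f"{path}: line {lineno}: negative summit offset {off_i}")
            peaks.append(Peak(chrom, start_i, end_i, name, intensity, strand,
                              start_i + off_i))
    return PeakSet(sample_id=sample_id, peaks=peaks)


def write_peaks(peakset: PeakSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        for p in peakset:
            fh.write("\t".join([
                p.chrom, str(p.start), str(p.end), p.peak_id,
                _fmt(p.intensity), p.strand, str(p.summit - p.start),
            ]) + "\n")


# ---------------------------------------------------------------------------
# Gene annotation
# ---------------------------------------------------------------------------

@dataclass
class GeneAnnotation:
    """TSS-level annotation for all genes, with a TF flag per gene."""

    table: pd.DataFrame  # index gene_id; columns chrom, tss, strand, is_tf

    def __post_init__(self):
        t = self.table
        required = {"chrom", "tss", "strand", "is_tf"}
        missing = required - set(t.columns)
        if missing:
            raise ValidationError(f"annotation missing columns {sorted(missing)}")
        if t.index.duplicated().any():
            dup = sorted(t.index[t.index.duplicated()].unique())
            raise ValidationError(f"duplicate gene ids {dup[:5]}")
        bad = set(t["strand"]) - {"+", "-"}
        if bad:
            raise ValidationError(f"invalid strand values {sorted(bad)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def tf_names(self) -> list[str]:
        return list(self.table.index[self.table["is_tf"].astype(bool)])

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index

    def __len__(self) -> int:
        return len(self.table)


def read_annotation(path: str | Path) -> GeneAnnotation:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str,
                                            "strand": str})
    required = {"gene_id", "chrom", "tss", "strand", "is_tf"}
    if not required <= set(df.columns):
        raise FormatError(
            f"{path}: expected columns {sorted(required)}, got {list(df.columns)}")
    if df["gene_id"].duplicated().any():
        raise ValidationError(f"{path}: duplicated gene_id")
    df = df.set_index("gene_id")
    df["tss"] = df["tss"].astype(int)
    df["is_tf"] = df["is_tf"].astype(bool)
    return GeneAnnotation(df)


def write_annotation(ann: GeneAnnotation, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("gene_id\tchrom\ttss\tstrand\tis_tf\n")
        for gid, row in ann.table.iterrows():
            fh.write(f"{gid}\t{row['chrom']}\t{int(row['tss'])}\t"
                     f"{row['strand']}\t{bool(row['is_tf'])}\n")


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def zscore_rows(df: pd.DataFrame, ddof: int = 1) -> pd.DataFrame:
    """Per-row z-scores across columns; zero-variance rows get all-zero z."""
    values = df.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=ddof, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (values - mean) / sd
    z[np.broadcast_to(sd == 0, z.shape)] = 0.0
    z[~np.isfinite(z)] = 0.0
    return pd.DataFrame(z, index=df.index, columns=df.columns)


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM matrix.

    ``zscores`` gives per-gene cross-sample z-scores, by default on
    log2(TPM+1); pass ``log=False`` for raw-TPM z-scores.
    """

    tpm: pd.DataFrame

    def __post_init__(self):
        df = self.tpm
        if df.index.duplicated().any():
            raise ValidationError("duplicate gene ids in expression matrix")
        if df.columns.duplicated().any():
            raise ValidationError("duplicate sample ids in expression matrix")
        values = df.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValidationError("non-numeric expression values")
        if np.isnan(values).any():
            raise ValidationError("NaN expression values")
        if (values < 0).any():
            raise ValidationError("negative TPM values")

    @property
    def genes(self) -> list[str]:
        return list(self.tpm.index)

    @property
    def samples(self) -> list[str]:
        return list(self.tpm.columns)

    def zscores(self, log: bool = True) -> pd.DataFrame:
        mat = np.log2(self.tpm + 1.0) if log else self.tpm
        return zscore_rows(mat)


def read_expression(path: str | Path) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0,
                     float_precision="round_trip")
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ValidationError(f"{path}: non-numeric expression value: {exc}")
    df.index.name = None
    return ExpressionMatrix(df)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = expr.tpm
    with open(path, "w") as fh:
        fh.write("gene_id\t" + "\t".join(df.columns) + "\n")
        for gid, row in df.iterrows():
            fh.write(gid + "\t" + "\t".join(_fmt(v) for v in row) + "\n")


# ---------------------------------------------------------------------------
# Motifs (MEME minimal format)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Motif:
    tf_name: str
    pwm: np.ndarray  # L x 4 probabilities over ACGT

    def __post_init__(self):
        pwm = np.asarray(self.pwm, dtype=float)
        object.__setattr__(self, "pwm", pwm)
        if pwm.ndim != 2 or pwm.shape[1] != 4:
            raise ValidationError(f"motif {self.tf_name}: PWM must be Lx4")
        if pwm.shape[0] < 4:
            raise ValidationError(
                f"motif {self.tf_name}: length {pwm.shape[0]} < 4")
        if (pwm < 0).any():
            raise ValidationError(f"motif {self.tf_name}: negative probability")
        sums = pwm.sum(axis=1)
        if np.abs(sums - 1.0).max() > 1e-6:
            raise ValidationError(
                f"motif {self.tf_name}: PWM rows do not sum to 1 "
                f"(max deviation {np.abs(sums - 1.0).max():.3g})")

    def __len__(self) -> int:
        return self.pwm.shape[0]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.pwm.argmax(axis=1))


@dataclass
class MotifLibrary:
    motifs: list[Motif]
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self):
        names = [m.tf_name for m in self.motifs]
        if len(names) != len(set(names)):
            raise ValidationError("duplicate motif names")
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-6 or (bg <= 0).any():
            raise ValidationError("background must be 4 positive probs summing to 1")
        self.background = bg

    def __iter__(self):
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    def __getitem__(self, name: str) -> Motif:
        for m in self.motifs:
            if m.tf_name == name:
                return m
        raise KeyError(name)

    @property
    def tf_names(self) -> list[str]:
        return [m.tf_name for m in self.motifs]


def read_motifs(path: str | Path) -> MotifLibrary:
    """Parse a MEME minimal motif file (DNA alphabet)."""
    motifs: list[Motif] = []
    background = np.full(4, 0.25)
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            i += 1
            toks = lines[i].split()
            freqs = {toks[j]: float(toks[j + 1]) for j in range(0, len(toks), 2)}
            background = np.array([freqs.get(b, 0.25) for b in BASES])
        elif line.startswith("MOTIF"):
            toks = line.split()
            if len(toks) < 2:
                raise FormatError(f"{path}: MOTIF line without a name")
            name = toks[1]
            # seek letter-probability header
            i += 1
            while i < len(lines) and not lines[i].strip().startswith(
                    "letter-probability matrix"):
                if lines[i].strip().startswith("MOTIF"):
                    raise FormatError(f"{path}: motif {name} has no matrix")
                i += 1
            if i >= len(lines):
                raise FormatError(f"{path}: motif {name} has no matrix")
            header = lines[i]
            width = None
            toks = header.split()
            for j, tok in enumerate(toks):
                if tok.startswith("w="):
                    width = int(tok[2:] or toks[j + 1])
                elif tok == "w=":
                    width = int(toks[j + 1])
                elif tok == "w" and j + 2 < len(toks) and toks[j + 1] == "=":
                    width = int(toks[j + 2])
            rows = []
            i += 1
            while i < len(lines):
                s = lines[i].strip()
                if not s or s.startswith(("MOTIF", "URL")):
                    break
                vals = s.split()
                if len(vals) != 4:
                    raise FormatError(
                        f"{path}: motif {name}: expected 4 columns, got {len(vals)}")
                try:
                    rows.append([float(v) for v in vals])
                except ValueError as exc:
                    raise FormatError(f"{path}: motif {name}: {exc}") from exc
                i += 1
            if width is not None and width != len(rows):
                raise FormatError(
                    f"{path}: motif {name}: declared width {width} != "
                    f"{len(rows)} rows")
            motifs.append(Motif(name, np.array(rows)))
            continue
        i += 1
    return MotifLibrary(motifs, background)


def write_motifs(library: MotifLibrary, path: str | Path) -> None:
    bg = library.background
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\n")
        fh.write(" ".join(f"{b} {_fmt(f)}" for b, f in zip(BASES, bg)) + "\n\n")
        for m in library:
            fh.write(f"MOTIF {m.tf_name}\n")
            fh.write(f"letter-probability matrix: alength= 4 w= {len(m)}\n")
            for row in m.pwm:
                fh.write(" " + " ".join(_fmt(v) for v in row) + "\n")
            fh.write("\n")


# ---------------------------------------------------------------------------
# Enhancer links
# ---------------------------------------------------------------------------

@dataclass
class EnhancerLinkTable:
    """(peak_id, gene_id) pairs linking distal peaks to target genes."""

    links: pd.DataFrame  # columns peak_id, gene_id

    def __post_init__(self):
        if not {"peak_id", "gene_id"} <= set(self.links.columns):
            raise ValidationError("link table needs peak_id and gene_id columns")
        self.links = self.links[["peak_id", "gene_id"]].drop_duplicates()
        self.links = self.links.reset_index(drop=True)

    def genes_for_peak(self, peak_id: str) -> list[str]:
        sel = self.links[self.links["peak_id"] == peak_id]
        return list(sel["gene_id"])

    def by_peak(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for pid, gid in self.links.itertuples(index=False):
            out.setdefault(pid, []).append(gid)
        return out

    def __len__(self) -> int:
        return len(self.links)


def read_links(path: str | Path) -> EnhancerLinkTable:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return EnhancerLinkTable(df)


def write_links(table: EnhancerLinkTable, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("peak_id\tgene_id\n")
        for pid, gid in table.links.itertuples(index=False):
            fh.write(f"{pid}\t{gid}\n")


# ---------------------------------------------------------------------------
# Regulatory network TSV
# ---------------------------------------------------------------------------

def write_network(net, path: str | Path) -> None:
    """Write a network as a TSV edge list.

    Columns: sample, parent_tf, child_gene, weight, evidence, peak_id,
    motif_score (motif score as fraction of the PWM's maximum).
    """
    edges = sorted(net.edges, key=lambda e: (e.parent, e.child))
    with open(path, "w") as fh:
        fh.write("sample\tparent_tf\tchild_gene\tweight\tevidence\t"
                 "peak_id\tmotif_score\n")
        for e in edges:
            if e.evidence not in EVIDENCE_TAGS:
                raise ValidationError(f"unknown evidence tag {e.evidence!r}")
            fh.write("\t".join([
                net.sample_id, e.parent, e.child, _fmt(e.weight),
                e.evidence, e.peak_id, _fmt(e.motif_score),
            ]) + "\n")


def read_network(path: str | Path):
    from .network import Edge, RegulatoryNetwork

    df = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={
        "sample": str, "parent_tf": str, "child_gene": str,
        "evidence": str, "peak_id": str})
    expected = ["sample", "parent_tf", "child_gene", "weight", "evidence",
                "peak_id", "motif_score"]
    if list(df.columns) != expected:
        raise FormatError(f"{path}: expected columns {expected}")
    if len(df) == 0:
        return RegulatoryNetwork(sample_id="", edges=[],
                                 node_z=pd.Series(dtype=float))
    samples = df["sample"].unique()
    if len(samples) != 1:
        raise ValidationError(f"{path}: multiple sample ids {list(samples)}")
    bad = set(df["evidence"]) - set(EVIDENCE_TAGS)
    if bad:
        raise ValidationError(f"{path}: unknown evidence tags {sorted(bad)}")
    for col in ("weight", "motif_score"):
        vals = df[col].to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise ValidationError(f"{path}: NaN in column {col}")
    edges = [Edge(parent=r.parent_tf, child=r.child_gene,
                  evidence=r.evidence, peak_id=r.peak_id,
                  motif_score=float(r.motif_score), weight=float(r.weight))
             for r in df.itertuples(index=False)]
    return RegulatoryNetwork(sample_id=str(samples[0]), edges=edges,
                             node_z=pd.Series(dtype=float))


# ---------------------------------------------------------------------------
# FASTA, GMT, JSON helpers
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio import SeqIO

    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValidationError(f"{path}: duplicate sequence id {rec.id}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path,
                width: int = 70) -> None:
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i:i + width] + "\n")


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    sets: dict[str, set[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT needs name, description, "
                    "and at least one gene")
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}: duplicate gene set {name}")
            sets[name] = {g for g in fields[2:] if g}
    return sets


def write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path) as fh:
        return json.load(fh)
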