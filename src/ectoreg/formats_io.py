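"""Readers and writers for the external formats the pipeline touches.

Everything is converted at the boundary to a single internal convention:
0-based, half-open coordinates (the BED/bedGraph convention).  GFF3, which is
1-based and closed, is shifted on the way in and restored on the way out.
Chromosome names are matched by exact string equality; no "chr" aliasing is
attempted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import scipy.io
import scipy.sparse

from .errors import FormatError, ParseError

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "SignalTrack",
    "CellMatrix",
    "PeakSet",
    "read_bed",
    "write_bed",
    "read_gff3_genes",
    "write_gff3_genes",
    "read_bedgraph",
    "write_bedgraph",
    "read_cell_matrix",
    "write_cell_matrix",
]

_STRANDS = {"+", "-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded half-open interval on a named sequence.

    ``start`` is 0-based inclusive, ``end`` exclusive.  This is the unit of
    all overlap algebra in the package; every "peak" or "bound region" is one
    of these.
    """

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float = 0.0
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"require 0 <= start < end, got [{self.start}, {self.end})"
            )
        if self.strand not in _STRANDS:
            raise ValueError(f"strand must be one of {_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


# A peak set is an ordered list of intervals; input order is preserved.
PeakSet = list


@dataclass(frozen=True)
class GeneModel:
    """A gene body with a strand-aware 5' end.

    The transcription start site is the first transcribed base: ``start`` on
    the + strand (and for unstranded records), ``end - 1`` on the - strand.
    """

    gene_id: str
    interval: GenomicInterval

    @property
    def tss(self) -> int:
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start

    @property
    def chrom(self) -> str:
        return self.interval.chrom


class SignalTrack:
    """Per-base signal stored as non-overlapping runs per chromosome.

    Runs are ``(start, end, value)`` with value >= 0 (normalized coverage).
    Positions not covered by any run implicitly carry signal 0.
    """

    def __init__(self, runs: Iterable[tuple[str, int, int, float]] = ()):
        per_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, start, end, value in runs:
            if start >= end:
                raise FormatError(f"empty run [{start}, {end}) on {chrom}")
            if value < 0:
                raise FormatError(f"negative signal value {value} on {chrom}")
            per_chrom.setdefault(chrom, []).append((start, end, value))
        self._starts: dict[str, np.ndarray] = {}
        self._ends: dict[str, np.ndarray] = {}
        self._values: dict[str, np.ndarray] = {}
        for chrom, triples in per_chrom.items():
            triples.sort()
            starts = np.array([t[0] for t in triples], dtype=np.int64)
            ends = np.array([t[1] for t in triples], dtype=np.int64)
            values = np.array([t[2] for t in triples], dtype=float)
            if np.any(starts[1:] < ends[:-1]):
                raise FormatError(f"overlapping runs on {chrom} (ambiguous signal)")
            self._starts[chrom] = starts
            self._ends[chrom] = ends
            self._values[chrom] = values

    @property
    def chroms(self) -> list[str]:
        return sorted(self._starts)

    def runs(self, chrom: str) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(starts, ends, values) arrays for one chromosome (empty if absent)."""
        empty = np.array([], dtype=np.int64)
        return (
            self._starts.get(chrom, empty),
            self._ends.get(chrom, empty),
            self._values.get(chrom, np.array([], dtype=float)),
        )

    def iter_runs(self):
        for chrom in self.chroms:
            s, e, v = self.runs(chrom)
            for i in range(len(s)):
                yield chrom, int(s[i]), int(e[i]), float(v[i])

    def total_signal(self) -> float:
        """Sum of value x run-length over the whole track."""
        total = 0.0
        for chrom in self.chroms:
            s, e, v = self.runs(chrom)
            total += float(np.sum((e - s) * v))
        return total


@dataclass
class CellMatrix:
    """A genes x cells non-negative count matrix with optional cluster labels."""

    matrix: scipy.sparse.spmatrix | np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    clusters: list[str] | None = field(default=None)

    def __post_init__(self) -> None:
        n_genes, n_cells = self.matrix.shape
        if n_genes != len(self.gene_ids):
            raise FormatError(
                f"{len(self.gene_ids)} gene ids for {n_genes} matrix rows"
            )
        if n_cells != len(self.cell_ids):
            raise FormatError(
                f"{len(self.cell_ids)} cell ids for {n_cells} matrix columns"
            )
        if self.clusters is not None and len(self.clusters) != n_cells:
            raise FormatError(
                f"{len(self.clusters)} cluster labels for {n_cells} cells"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape

    def dense(self) -> np.ndarray:
        if scipy.sparse.issparse(self.matrix):
            return np.asarray(self.matrix.todense())
        return np.asarray(self.matrix)


# ---------------------------------------------------------------------------
# BED


def _format_score(score: float) -> str:
    if float(score).is_integer():
        return str(int(score))
    return format(score, "g")


def read_bed(path: str | Path) -> PeakSet:
    """Read a BED3/BED6 file into a list of :class:`GenomicInterval`.

    Track/browser/comment header lines are skipped; input order is preserved.
    Malformed lines raise :class:`ParseError` naming the line number.
    """
    peaks: PeakSet = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith(("track", "browser", "#")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: fewer than 3 columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-integer coordinates"
                ) from exc
            name = fields[3] if len(fields) > 3 else None
            score = 0.0
            if len(fields) > 4 and fields[4] not in ("", "."):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: bad score field") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                peaks.append(
                    GenomicInterval(chrom, start, end, name=name, score=score,
                                    strand=strand)
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return peaks


def write_bed(peaks: Sequence[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED (6 columns when a name is present, else 3)."""
    with open(path, "w") as fh:
        for p in peaks:
            if p.name is None:
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\n")
            else:
                fh.write(
                    f"{p.chrom}\t{p.start}\t{p.end}\t{p.name}"
                    f"\t{_format_score(p.score)}\t{p.strand}\n"
                )


# ---------------------------------------------------------------------------
# GFF3


def _gff3_attributes(attr_field: str) -> dict[str, str]:
    attrs = {}
    for part in attr_field.rstrip(";").split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        attrs[key.strip()] = value.strip()
    return attrs


def read_gff3_genes(path: str | Path) -> list[GeneModel]:
    """Read records of type ``gene`` from a GFF3 file.

    GFF3 coordinates are 1-based and closed; they come back 0-based and
    half-open.  Records missing an ``ID`` attribute raise :class:`ParseError`.
    """
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 9:
                raise ParseError(f"{path}:{lineno}: fewer than 9 columns")
            if fields[2] != "gene":
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
            attrs = _gff3_attributes(fields[8])
            if "ID" not in attrs:
                raise ParseError(f"{path}:{lineno}: gene record missing ID attribute")
            strand = fields[6] if fields[6] in _STRANDS else "."
            try:
                interval = GenomicInterval(
                    fields[0], start1 - 1, end1, name=attrs["ID"], strand=strand
                )
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
            genes.append(GeneModel(gene_id=attrs["ID"], interval=interval))
    return genes


def write_gff3_genes(genes: Sequence[GeneModel], path: str | Path) -> None:
    """Write gene models back as GFF3 ``gene`` records (1-based, closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tectoreg\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )


# ---------------------------------------------------------------------------
# bedGraph


def read_bedgraph(path: str | Path) -> SignalTrack:
    """Read a 4-column bedGraph (0-based half-open) into a :class:`SignalTrack`.

    Overlapping runs are rejected (ambiguous signal), as are negative values.
    """
    runs: list[tuple[str, int, int, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            fields = line.split()
            if len(fields) < 4:
                raise ParseError(f"{path}:{lineno}: fewer than 4 columns")
            try:
                start, end = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: bad numeric field") from exc
            if not math.isfinite(value):
                raise ParseError(f"{path}:{lineno}: non-finite value")
            if value < 0:
                raise ParseError(f"{path}:{lineno}: negative value {value}")
            if start >= end:
                raise ParseError(f"{path}:{lineno}: empty interval")
            runs.append((fields[0], start, end, value))
    return SignalTrack(runs)


def write_bedgraph(track: SignalTrack, path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, start, end, value in track.iter_runs():
            fh.write(f"{chrom}\t{start}\t{end}\t{format(value, 'g')}\n")


# ---------------------------------------------------------------------------
# MatrixMarket single-cell matrices


def _read_id_list(path: str | Path) -> list[str]:
    with open(path) as fh:
        return [line.split("\t")[0].strip() for line in fh if line.strip()]


def read_cell_matrix(
    mtx: str | Path,
    features: str | Path,
    barcodes: str | Path,
    clusters: str | Path | None = None,
    genes_in_rows: bool = True,
) -> CellMatrix:
    """Read a MatrixMarket count matrix plus feature/barcode lists.

    The returned matrix is always oriented genes x cells; set
    ``genes_in_rows=False`` when the file stores cells in rows.
    """
    matrix = scipy.sparse.csr_matrix(scipy.io.mmread(str(mtx)))
    if not genes_in_rows:
        matrix = matrix.T.tocsr()
    gene_ids = _read_id_list(features)
    cell_ids = _read_id_list(barcodes)
    cluster_labels = _read_id_list(clusters) if clusters is not None else None
    if matrix.shape != (len(gene_ids), len(cell_ids)):
        raise FormatError(
            f"matrix shape {matrix.shape} does not match "
            f"{len(gene_ids)} features x {len(cell_ids)} barcodes"
        )
    return CellMatrix(matrix, gene_ids, cell_ids, cluster_labels)


def write_cell_matrix(m: CellMatrix, mtx: str | Path, features: str | Path,
                      barcodes: str | Path,
                      clusters: str | Path | None = None) -> None:
    mat = m.matrix
    if not scipy.sparse.issparse(mat):
        mat = scipy.sparse.coo_matrix(mat)
    scipy.io.mmwrite(str(mtx), mat)
    Path(features).write_text("".join(f"{g}\n" for g in m.gene_ids))
    Path(barcodes).write_text("".join(f"{c}\n" for c in m.cell_ids))
    if clusters is not None:
        if m.clusters is None:
            raise FormatError("matrix carries no cluster labels to write")
        Path(clusters).write_text("".join(f"{c}\n" for c in m.clusters))
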