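"""Core genomic data model and flat-file I/O.

Coordinates are 0-based half-open (BED convention) everywhere internally.
Fragments and annotation elements are plain intervals; read collections are
stored columnar (numpy arrays) because downstream window/bin counting is
vectorised, but iterate as :class:`GenomicInterval` records.
"""
from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger("hetmig")

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open span on a named chromosome.

    ``strand`` is ``"+"``, ``"-"`` or ``"."`` (unstranded); ``score`` is an
    optional real used when round-tripping BED6.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"empty or inverted interval [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


class GenomeTable:
    """Ordered chromosome name -> length table (a chrom.sizes stand-in)."""

    def __init__(self, sizes: Sequence[tuple[str, int]]):
        names = [n for n, _ in sizes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for name, length in sizes:
            if length <= 0:
                raise ValueError(f"chromosome {name} has non-positive length {length}")
        self._names: list[str] = list(names)
        self._lengths: dict[str, int] = {n: int(l) for n, l in sizes}

    @property
    def names(self) -> list[str]:
        return list(self._names)

    def length(self, chrom: str) -> int:
        try:
            return self._lengths[chrom]
        except KeyError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._lengths

    def __iter__(self) -> Iterator[tuple[str, int]]:
        for n in self._names:
            yield n, self._lengths[n]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, GenomeTable) and list(self) == list(other)

    @property
    def total_bp(self) -> int:
        return sum(self._lengths.values())

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for n, l in self:
                fh.write(f"{n}\t{l}\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "GenomeTable":
        rows = []
        for line in open(path):
            if line.strip():
                name, length = line.split()[:2]
                rows.append((name, int(length)))
        return cls(rows)


@dataclass
class ReadSet:
    """A labelled collection of sequencing fragments on one genome.

    Fragments are stored columnar: ``chrom_idx`` indexes into
    ``genome.names``; ``start``/``end`` are the fragment spans after
    extension to the library fragment length.
    """

    label: str
    genome: GenomeTable
    chrom_idx: np.ndarray
    start: np.ndarray
    end: np.ndarray
    strand: np.ndarray | None = None
    fragment_size: int | None = None

    def __post_init__(self) -> None:
        self.chrom_idx = np.asarray(self.chrom_idx, dtype=np.int32)
        self.start = np.asarray(self.start, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        if not (len(self.chrom_idx) == len(self.start) == len(self.end)):
            raise ValueError("fragment column lengths differ")

    @property
    def total_count(self) -> int:
        return int(len(self.start))

    @property
    def midpoints(self) -> np.ndarray:
        return (self.start + self.end) // 2

    def chrom_mask(self, chrom: str) -> np.ndarray:
        return self.chrom_idx == self.genome.names.index(chrom)

    @property
    def fragments(self) -> list[GenomicInterval]:
        names = self.genome.names
        strands = self.strand if self.strand is not None else ["."] * self.total_count
        return [
            GenomicInterval(names[c], int(s), int(e), str(st))
            for c, s, e, st in zip(self.chrom_idx, self.start, self.end, strands)
        ]

    @classmethod
    def from_intervals(
        cls,
        label: str,
        intervals: Iterable[GenomicInterval],
        genome: GenomeTable,
        fragment_size: int | None = None,
    ) -> "ReadSet":
        ivs = list(intervals)
        names = {n: i for i, n in enumerate(genome.names)}
        cidx = np.array([names[iv.chrom] for iv in ivs], dtype=np.int32)
        start = np.array([iv.start for iv in ivs], dtype=np.int64)
        end = np.array([iv.end for iv in ivs], dtype=np.int64)
        strand = np.array([iv.strand for iv in ivs], dtype="U1") if ivs else np.array([], dtype="U1")
        return cls(label, genome, cidx, start, end, strand, fragment_size)

    def coverage(self, chrom: str, scale: float = 1.0) -> np.ndarray:
        """Per-bp fragment pileup on one chromosome, optionally scaled."""
        L = self.genome.length(chrom)
        diff = np.zeros(L + 1, dtype=np.float64)
        m = self.chrom_mask(chrom)
        np.add.at(diff, self.start[m], 1.0)
        np.add.at(diff, self.end[m], -1.0)
        cov = np.cumsum(diff[:-1])
        if scale != 1.0:
            cov *= scale
        return cov

    def digest(self) -> str:
        """Stable content hash used for run manifests."""
        h = hashlib.sha256()
        h.update(self.label.encode())
        for arr in (self.chrom_idx, self.start, self.end):
            h.update(np.ascontiguousarray(arr).tobytes())
        return h.hexdigest()[:16]


class BedFormatError(ValueError):
    pass


def read_bed(path: str | Path, genome: GenomeTable) -> list[GenomicInterval]:
    """Read BED3/BED6 into sorted, validated intervals.

    Malformed lines, unknown chromosomes and out-of-bounds coordinates are
    hard errors naming the offending line number.
    """
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedFormatError(f"{path}:{lineno}: expected >=3 tab-separated fields")
            chrom = fields[0]
            if chrom not in genome:
                raise BedFormatError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if end > genome.length(chrom):
                raise BedFormatError(
                    f"{path}:{lineno}: interval end {end} beyond {chrom} length {genome.length(chrom)}"
                )
            strand = fields[5] if len(fields) >= 6 and fields[5] in VALID_STRANDS else "."
            score = None
            if len(fields) >= 5 and fields[4] not in (".", ""):
                score = float(fields[4])
            try:
                out.append(GenomicInterval(chrom, start, end, strand, score))
            except ValueError as exc:
                raise BedFormatError(f"{path}:{lineno}: {exc}") from exc
    order = genome.names
    out.sort(key=lambda iv: (order.index(iv.chrom), iv.start, iv.end))
    return out


def write_bed(path: str | Path, intervals: Iterable[GenomicInterval], name_prefix: str = "iv") -> None:
    """Write BED6 (score column '.' when absent); round-trips read_bed coordinates."""
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            score = "." if iv.score is None else f"{iv.score:g}"
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name_prefix}{i}\t{score}\t{iv.strand}\n")


def extend_reads(
    raw: Sequence[GenomicInterval],
    fragment_size: int,
    genome: GenomeTable,
    label: str = "reads",
) -> ReadSet:
    """Extend each read to the library fragment length from its 5' end.

    Plus-strand (and unstranded) reads grow rightward from ``start``;
    minus-strand reads grow leftward from ``end``. Fragments are clipped to
    chromosome bounds; the read count is preserved.
    """
    if fragment_size <= 0:
        raise ValueError("fragment_size must be positive")
    names = {n: i for i, n in enumerate(genome.names)}
    n = len(raw)
    cidx = np.empty(n, dtype=np.int32)
    start = np.empty(n, dtype=np.int64)
    end = np.empty(n, dtype=np.int64)
    strand = np.empty(n, dtype="U1")
    for i, iv in enumerate(raw):
        cidx[i] = names[iv.chrom]
        L = genome.length(iv.chrom)
        if iv.strand == "-":
            s, e = iv.end - fragment_size, iv.end
        else:
            s, e = iv.start, iv.start + fragment_size
        start[i] = max(0, s)
        end[i] = min(L, e)
        strand[i] = iv.strand
    return ReadSet(label, genome, cidx, start, end, strand, fragment_size)


def read_gene_table(path: str | Path) -> pd.DataFrame:
    """Read the gene-model TSV: gene_id, chrom, start, end, strand, biotype."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "strand": str})
    required = {"gene_id", "chrom", "start", "end", "strand", "biotype"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"gene table missing columns: {sorted(missing)}")
    return df


def write_gene_table(path: str | Path, genes: pd.DataFrame) -> None:
    genes.to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    """Gene x sample integer count matrix with a header row; index = gene_id."""
    return pd.read_csv(path, sep="\t", index_col=0)
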