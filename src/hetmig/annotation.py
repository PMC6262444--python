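"""Annotation catalog and the exclusive, priority-resolved genomic partition.

Every base pair of the genome is assigned to exactly one class by the fixed
priority order coding genes > noncoding genes > promoters > enhancers >
repetitive elements; whatever no element claims falls into ``other``. Repeat
subtypes (LINE/SINE/LTR/DNA) share one priority tier but keep their subtype
tag for per-subtype signal profiling.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeTable, GenomicInterval, write_bed

REPEAT_SUBTYPES = ("LINE", "SINE", "LTR", "DNA")

# priority order, highest first; "other" is the explicit residual class
PARTITION_CLASSES = ("coding_gene", "noncoding_gene", "promoter", "enhancer", "repeat", "other")


@dataclass
class AnnotationCatalog:
    """Raw (possibly overlapping) element lists.

    ``genes``: DataFrame with gene_id, chrom, start, end, strand, biotype
    (biotype in {coding, noncoding}); ``enhancers``: chrom/start/end;
    ``repeats``: chrom/start/end/subtype.
    """

    genes: pd.DataFrame
    enhancers: pd.DataFrame
    repeats: pd.DataFrame

    def __post_init__(self) -> None:
        bad = set(self.repeats["subtype"].unique()) - set(REPEAT_SUBTYPES)
        if bad:
            raise ValueError(f"unknown repeat subtypes: {sorted(bad)}")
        bad_bt = set(self.genes["biotype"].unique()) - {"coding", "noncoding"}
        if bad_bt:
            raise ValueError(f"unknown gene biotypes: {sorted(bad_bt)}")

    def coding_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["biotype"] == "coding"]

    def noncoding_genes(self) -> pd.DataFrame:
        return self.genes[self.genes["biotype"] == "noncoding"]


def tss(genes: pd.DataFrame) -> pd.Series:
    """Transcription start site: start on '+', end on '-' (half-open end)."""
    plus = genes["strand"] == "+"
    return genes["start"].where(plus, genes["end"])


def merge_intervals(raw: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping and bookended intervals into disjoint sorted spans.

    The union of covered base pairs is preserved exactly.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    for iv in raw:
        if iv.chrom not in by_chrom:
            by_chrom[iv.chrom] = []
            order.append(iv.chrom)
        by_chrom[iv.chrom].append((iv.start, iv.end))
    out: list[GenomicInterval] = []
    for chrom in sorted(order):
        spans = sorted(by_chrom[chrom])
        cur_s, cur_e = spans[0]
        for s, e in spans[1:]:
            if s <= cur_e:  # overlap or bookend
                cur_e = max(cur_e, e)
            else:
                out.append(GenomicInterval(chrom, cur_s, cur_e))
                cur_s, cur_e = s, e
        out.append(GenomicInterval(chrom, cur_s, cur_e))
    return out


def define_promoters(
    genes: pd.DataFrame,
    genome: GenomeTable,
    length: int = 1000,
    include_noncoding: bool = True,
) -> list[GenomicInterval]:
    """Strand-aware promoter windows: the ``length`` bp upstream of each TSS.

    '+' gene with TSS t -> [t-length, t); '-' gene with TSS t -> [t, t+length),
    clipped at chromosome bounds. Genes whose clipped window is empty (TSS at
    a chromosome edge) are dropped.
    """
    recs = genes if include_noncoding else genes[genes["biotype"] == "coding"]
    if (~recs["strand"].isin(["+", "-"])).any():
        raise ValueError("every gene needs a '+' or '-' strand to define its promoter")
    out: list[GenomicInterval] = []
    t = tss(recs)
    for chrom, strand, pos in zip(recs["chrom"], recs["strand"], t):
        L = genome.length(chrom)
        if strand == "+":
            s, e = max(0, pos - length), pos
        else:
            s, e = pos, min(L, pos + length)
        if e > s:
            out.append(GenomicInterval(chrom, int(s), int(e), strand))
    return out


class ExclusivePartition:
    """Disjoint per-class territories covering the genome exactly.

    Stored per chromosome as breakpoints ``b[0..n]`` (b0 = 0, bn = length)
    plus a class code for each elementary segment ``[b[i], b[i+1])``; this
    makes point-to-class lookup a single ``searchsorted``.
    """

    def __init__(self, genome: GenomeTable, boundaries: dict[str, np.ndarray], codes: dict[str, np.ndarray]):
        self.genome = genome
        self.boundaries = boundaries
        self.codes = codes
        self.classes = PARTITION_CLASSES
        self._check()

    def _check(self) -> None:
        for chrom, L in self.genome:
            b = self.boundaries[chrom]
            c = self.codes[chrom]
            assert b[0] == 0 and b[-1] == L, f"{chrom}: partition does not span chromosome"
            assert np.all(np.diff(b) > 0), f"{chrom}: non-increasing breakpoints"
            assert len(c) == len(b) - 1
        assert sum(self.class_bp.values()) == self.genome.total_bp

    @property
    def class_bp(self) -> dict[str, int]:
        bp = {cls: 0 for cls in self.classes}
        for chrom, _ in self.genome:
            seg = np.diff(self.boundaries[chrom])
            for k, cls in enumerate(self.classes):
                bp[cls] += int(seg[self.codes[chrom] == k].sum())
        return bp

    def class_of_positions(self, chrom: str, pos: np.ndarray) -> np.ndarray:
        """Class code for each position (0-based bp) on one chromosome."""
        b = self.boundaries[chrom]
        idx = np.searchsorted(b, pos, side="right") - 1
        return self.codes[chrom][idx]

    def intervals_of(self, cls: str) -> list[GenomicInterval]:
        k = self.classes.index(cls)
        out = []
        for chrom, _ in self.genome:
            b, c = self.boundaries[chrom], self.codes[chrom]
            for i in np.nonzero(c == k)[0]:
                out.append(GenomicInterval(chrom, int(b[i]), int(b[i + 1])))
        return out

    def overlap_bp(self, cls: str, starts: np.ndarray, ends: np.ndarray, chrom: str) -> np.ndarray:
        """bp of each query interval lying in ``cls`` territory (vectorised)."""
        k = self.classes.index(cls)
        b, c = self.boundaries[chrom], self.codes[chrom]
        seg_s, seg_e = b[:-1][c == k], b[1:][c == k]
        out = np.zeros(len(starts), dtype=np.int64)
        if len(seg_s) == 0:
            return out
        # for each query, sum clipped overlaps with the (few) class segments
        lo = np.searchsorted(seg_e, starts, side="right")
        hi = np.searchsorted(seg_s, ends, side="left")
        for i, (s, e, a, z) in enumerate(zip(starts, ends, lo, hi)):
            if z > a:
                out[i] = np.sum(np.minimum(seg_e[a:z], e) - np.maximum(seg_s[a:z], s))
        return out

    def write_beds(self, outdir: str | Path, prefix: str = "partition") -> list[Path]:
        outdir = Path(outdir)
        paths = []
        for cls in self.classes:
            p = outdir / f"{prefix}_{cls}.bed"
            write_bed(p, self.intervals_of(cls), name_prefix=cls)
            paths.append(p)
        return paths


def build_exclusive_partition(
    catalog: AnnotationCatalog,
    promoters: Sequence[GenomicInterval],
    genome: GenomeTable,
) -> ExclusivePartition:
    """Resolve overlaps by strict priority; every bp gets exactly one class.

    Each class list is first merged within itself; then, scanning elementary
    segments between all breakpoints, the highest-priority covering class
    wins. Uncovered bp become ``other``.
    """
    class_ivs: dict[str, list[GenomicInterval]] = {
        "coding_gene": _df_ivs(catalog.coding_genes()),
        "noncoding_gene": _df_ivs(catalog.noncoding_genes()),
        "promoter": list(promoters),
        "enhancer": _df_ivs(catalog.enhancers),
        "repeat": _df_ivs(catalog.repeats),
    }
    merged = {cls: merge_intervals(ivs) if ivs else [] for cls, ivs in class_ivs.items()}

    boundaries: dict[str, np.ndarray] = {}
    codes: dict[str, np.ndarray] = {}
    other_code = PARTITION_CLASSES.index("other")
    for chrom, L in genome:
        pts = {0, L}
        per_class: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for cls, ivs in merged.items():
            s = np.array([iv.start for iv in ivs if iv.chrom == chrom], dtype=np.int64)
            e = np.array([iv.end for iv in ivs if iv.chrom == chrom], dtype=np.int64)
            e = np.minimum(e, L)
            s = np.minimum(s, L)
            per_class[cls] = (s, e)
            pts.update(s.tolist())
            pts.update(e.tolist())
        b = np.array(sorted(pts), dtype=np.int64)
        seg_code = np.full(len(b) - 1, other_code, dtype=np.int8)
        seg_start = b[:-1]
        unassigned = np.ones(len(seg_start), dtype=bool)
        for k, cls in enumerate(PARTITION_CLASSES[:-1]):
            s, e = per_class[cls]
            if len(s) == 0 or not unassigned.any():
                continue
            # segment covered iff its start falls inside a merged class span
            idx = np.searchsorted(s, seg_start, side="right") - 1
            covered = (idx >= 0) & (seg_start < e[np.clip(idx, 0, None)])
            take = covered & unassigned
            seg_code[take] = k
            unassigned &= ~take
        # compress runs of equal codes
        keep = np.concatenate(([True], seg_code[1:] != seg_code[:-1]))
        boundaries[chrom] = np.concatenate((b[:-1][keep], [L]))
        codes[chrom] = seg_code[keep]
    return ExclusivePartition(genome, boundaries, codes)


def _df_ivs(df: pd.DataFrame) -> list[GenomicInterval]:
    return [
        GenomicInterval(c, int(s), int(e))
        for c, s, e in zip(df["chrom"], df["start"], df["end"])
    ]
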