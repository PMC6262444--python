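"""Redistribution accounting and average-signal (metagene) profiles.

Two deliberately different denominators mirror the two published summaries:
read fractions assign each fragment (by midpoint) to the partition class it
falls in, as a percentage of all mapped fragments; differential-peak
fractions intersect island bp with class territories, as a percentage of
total island bp. Metagene profiles average fragments-per-million coverage
over fixed-width flanks and a length-rescaled body.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import ExclusivePartition
from .genome import ReadSet
from .peaks import IslandSet

log = logging.getLogger("hetmig")


def coverage_fractions(reads: ReadSet, partition: ExclusivePartition) -> pd.Series:
    """Percent of fragments whose midpoint lies in each partition class.

    Sums to 100 (the partition covers the genome exactly).
    """
    mids = reads.midpoints
    counts = np.zeros(len(partition.classes), dtype=np.int64)
    for ci, (chrom, _) in enumerate(reads.genome):
        m = reads.chrom_idx == ci
        if not m.any():
            continue
        codes = partition.class_of_positions(chrom, mids[m])
        counts += np.bincount(codes, minlength=len(partition.classes))
    pct = counts / max(reads.total_count, 1) * 100.0
    return pd.Series(pct, index=list(partition.classes), name=reads.label)


def diffpeak_bp_fractions(islands: IslandSet, partition: ExclusivePartition) -> pd.Series:
    """Percent of differential-island bp intersecting each class territory."""
    classes = list(partition.classes)
    if len(islands.df) == 0:
        log.warning("diffpeak_bp_fractions: empty island set, returning zeros")
        return pd.Series(np.zeros(len(classes)), index=classes)
    bp = np.zeros(len(classes))
    total = islands.total_bp()
    for chrom in {c for c in islands.df["chrom"]}:
        sub = islands.df[islands.df["chrom"] == chrom]
        s = sub["start"].to_numpy()
        e = sub["end"].to_numpy()
        for k, cls in enumerate(classes):
            bp[k] += partition.overlap_bp(cls, s, e, chrom).sum()
    return pd.Series(bp / total * 100.0, index=classes)


@dataclass
class MetaProfile:
    """Mean normalised coverage over [upstream flank | scaled body | downstream flank]."""

    n_regions: int
    flank_bp: int
    n_flank_bins: int
    n_body_bins: int
    values: np.ndarray

    @property
    def body_mean(self) -> float:
        a = self.n_flank_bins
        return float(self.values[a:a + self.n_body_bins].mean())


def _bin_means(v: np.ndarray, n_bins: int) -> np.ndarray:
    """Mean of v over n_bins equal slices; interpolates when len(v) < n_bins."""
    if len(v) == 0:
        return np.zeros(n_bins)
    if len(v) < n_bins:
        x = np.linspace(0, 1, len(v))
        return np.interp(np.linspace(0, 1, n_bins), x, v)
    edges = np.linspace(0, len(v), n_bins + 1).astype(np.int64)
    cs = np.concatenate(([0.0], np.cumsum(v)))
    widths = np.maximum(edges[1:] - edges[:-1], 1)
    return (cs[edges[1:]] - cs[edges[:-1]]) / widths


def meta_profile(
    signal: ReadSet,
    regions: pd.DataFrame,
    flank_bp: int = 2000,
    n_body_bins: int = 100,
    n_flank_bins: int = 50,
) -> MetaProfile:
    """Average fragments-per-million coverage across scaled regions.

    Flanks are sampled at native resolution and binned without length
    scaling; bodies are rescaled to ``n_body_bins``. Minus-strand regions
    are reversed before averaging. ``regions`` needs chrom/start/end and
    optionally strand.
    """
    if len(regions) == 0:
        raise ValueError("meta_profile needs at least one region")
    scale = 1e6 / max(signal.total_count, 1)
    strands = regions["strand"] if "strand" in regions else pd.Series(["+"] * len(regions))
    total = np.zeros(2 * n_flank_bins + n_body_bins)
    short_seen = False
    cov_cache: dict[str, np.ndarray] = {}
    for chrom, start, end, strand in zip(regions["chrom"], regions["start"], regions["end"], strands):
        if chrom not in cov_cache:
            cov_cache[chrom] = signal.coverage(chrom, scale=scale)
        cov = cov_cache[chrom]
        L = len(cov)
        up = cov[max(0, start - flank_bp):start]
        body = cov[start:end]
        down = cov[end:min(L, end + flank_bp)]
        if len(up) < flank_bp:
            up = np.concatenate((np.zeros(flank_bp - len(up)), up))
        if len(down) < flank_bp:
            down = np.concatenate((down, np.zeros(flank_bp - len(down))))
        if end - start < n_body_bins:
            short_seen = True
        prof = np.concatenate(
            (_bin_means(up, n_flank_bins), _bin_means(body, n_body_bins), _bin_means(down, n_flank_bins))
        )
        if strand == "-":
            prof = prof[::-1]
        total += prof
    if short_seen:
        log.warning("meta_profile: some regions shorter than n_body_bins were interpolated")
    return MetaProfile(len(regions), flank_bp, n_flank_bins, n_body_bins, total / len(regions))


def cpm(counts: pd.DataFrame) -> pd.DataFrame:
    """Counts per million using per-sample library sizes of this matrix."""
    lib = counts.sum(axis=0)
    return counts / lib * 1e6


def expression_ranked_regions(
    counts: pd.DataFrame,
    genes: pd.DataFrame,
    samples: list[str] | None = None,
    k: int = 500,
    min_cpm: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k and bottom-k expressed gene intervals for metagene profiling.

    Mean cpm is taken across ``samples`` (default: all columns); genes below
    ``min_cpm`` are excluded; survivors are ranked descending. ``k`` shrinks
    with a warning when fewer than 2k genes survive.
    """
    sub = counts[samples] if samples is not None else counts
    mean_cpm = cpm(sub).mean(axis=1)
    kept = mean_cpm[mean_cpm >= min_cpm]
    kept = kept[kept.index.isin(genes["gene_id"])]
    if len(kept) == 0:
        log.warning("expression_ranked_regions: no gene passes the cpm filter")
        empty = genes.iloc[0:0]
        return empty, empty
    if len(kept) < 2 * k:
        k = len(kept) // 2
        log.warning("expression_ranked_regions: fewer than 2k survivors, shrinking k to %d", k)
    ranked = kept.sort_values(ascending=False)
    gi = genes.set_index("gene_id")
    top = gi.loc[ranked.index[:k]].reset_index()
    bottom = gi.loc[ranked.index[-k:]].reset_index()
    return top, bottom
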