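"""Genome-binned inter-mark correlation, optionally restricted to a class.

The genome is tiled into non-overlapping fixed-width bins (10 kb default);
fragments are assigned to the bin containing their midpoint; Spearman
correlations use average ranks for ties.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import ExclusivePartition
from .genome import GenomeTable, ReadSet


@dataclass
class BinnedSignalMatrix:
    """Fixed-width genome-tiling bins x one count column per track."""

    bins: pd.DataFrame  # chrom, start, end
    counts: pd.DataFrame  # one column per track label, aligned with bins

    def __len__(self) -> int:
        return len(self.bins)


def bin_signal(tracks: list[ReadSet], genome: GenomeTable, bin_bp: int = 10_000) -> BinnedSignalMatrix:
    """Count fragment midpoints per bin; column sums equal track totals.

    The last bin of each chromosome may be short.
    """
    rows = []
    for chrom, L in genome:
        edges = np.arange(0, L, bin_bp)
        for s in edges:
            rows.append((chrom, int(s), int(min(s + bin_bp, L))))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    cols = {}
    for t in tracks:
        if t.genome != genome:
            raise ValueError(f"track {t.label} is on a different genome")
        mids = t.midpoints
        col = []
        for ci, (chrom, L) in enumerate(genome):
            n_bins = -(-L // bin_bp)
            m = t.chrom_idx == ci
            col.append(np.bincount((mids[m] // bin_bp).astype(np.int64), minlength=n_bins))
        cols[t.label] = np.concatenate(col)
    return BinnedSignalMatrix(bins, pd.DataFrame(cols))


def bin_class_overlap(bins: pd.DataFrame, partition: ExclusivePartition, cls: str) -> np.ndarray:
    """Fraction of each bin's bp lying in ``cls`` territory."""
    frac = np.zeros(len(bins))
    for chrom in partition.genome.names:
        m = (bins["chrom"] == chrom).to_numpy()
        if not m.any():
            continue
        s = bins.loc[m, "start"].to_numpy()
        e = bins.loc[m, "end"].to_numpy()
        frac[m] = partition.overlap_bp(cls, s, e, chrom) / (e - s)
    return frac


def spearman_matrix(
    m: BinnedSignalMatrix,
    restrict_to: str | None = None,
    partition: ExclusivePartition | None = None,
    min_overlap: float = 0.5,
) -> pd.DataFrame:
    """Pairwise Spearman rho between tracks over bins.

    With ``restrict_to``, only bins whose overlap with that partition class
    is >= ``min_overlap`` of the bin length are kept.
    """
    X = m.counts
    if X.shape[1] < 2:
        raise ValueError("need at least two tracks")
    if restrict_to is not None:
        if partition is None:
            raise ValueError("restriction needs a partition")
        keep = bin_class_overlap(m.bins, partition, restrict_to) >= min_overlap
        X = X.loc[keep]
    if len(X) < 3:
        raise ValueError(f"only {len(X)} bins retained; need >= 3")
    return pd.DataFrame(_spearman_full(X.to_numpy()), index=X.columns, columns=X.columns)


def _spearman_full(arr: np.ndarray) -> np.ndarray:
    r = stats.spearmanr(arr).statistic
    if np.ndim(r) == 0:  # scipy collapses the 2-column case to a scalar
        r = np.array([[1.0, r], [r, 1.0]])
    return np.asarray(r)


def correlate_over_features(
    tracks: list[ReadSet],
    features: pd.DataFrame,
) -> pd.DataFrame:
    """Alternative mode: Spearman over per-feature fragment counts directly."""
    from .peaks import _count_in_regions

    cols = {t.label: _count_in_regions(t, features) for t in tracks}
    X = pd.DataFrame(cols)
    if len(X) < 3:
        raise ValueError("need >= 3 features")
    return pd.DataFrame(_spearman_full(X.to_numpy()), index=X.columns, columns=X.columns)
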