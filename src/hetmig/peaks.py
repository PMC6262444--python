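"""Broad-domain (island) calling, differential islands and diffuseness stats.

The caller follows the spatial-clustering recipe for broad marks: the genome
is tiled into small windows, windows are flagged eligible when their
fragment count beats a Poisson background, and runs of eligible windows
tolerant of short ineligible gaps are joined into islands. Islands are then
tested for enrichment of immunoprecipitation over the input library with a
library-size-scaled Poisson test and Benjamini-Hochberg control.
"""
from __future__ import annotations

from dataclasses import dataclass, field
import logging

import numpy as np
import pandas as pd
from scipy import stats

from .genome import GenomeTable, GenomicInterval, ReadSet
from .stats_util import bh_adjust

log = logging.getLogger("hetmig")


@dataclass(frozen=True)
class IslandCallerParams:
    window_size: int = 200
    gap: int = 600
    fragment_size: int = 350
    genome_fraction: float = 0.8   # effective genome fraction f
    window_p0: float = 0.2         # window eligibility p-value
    fdr: float = 0.05

    def __post_init__(self) -> None:
        if not (0 < self.genome_fraction <= 1):
            raise ValueError("genome_fraction must be in (0, 1]")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")
        if self.gap % self.window_size != 0:
            raise ValueError("gap must be a multiple of window_size")

    @property
    def gap_windows(self) -> int:
        return self.gap // self.window_size


@dataclass
class WindowScores:
    """Per-window fragment counts (midpoint membership) and eligibility."""

    genome: GenomeTable
    params: IslandCallerParams
    counts: dict[str, np.ndarray]
    eligible: dict[str, np.ndarray]
    lam: float
    total_count: int


def score_windows(reads: ReadSet, params: IslandCallerParams, genome: GenomeTable) -> WindowScores:
    """Tile the genome into windows; a window is eligible iff the Poisson
    upper tail of its count under the background rate is below ``window_p0``.

    Background rate per window: lambda = N * W / (G * f) with N mapped
    fragments, G the genome length and f the effective genome fraction.
    """
    W = params.window_size
    total = reads.total_count
    lam = total * W / (genome.total_bp * params.genome_fraction)
    counts: dict[str, np.ndarray] = {}
    eligible: dict[str, np.ndarray] = {}
    if total == 0:
        log.warning("score_windows: empty read set, all windows ineligible")
    mids = reads.midpoints
    for ci, (chrom, L) in enumerate(genome):
        n_win = -(-L // W)
        m = reads.chrom_idx == ci
        c = np.bincount((mids[m] // W).astype(np.int64), minlength=n_win)
        counts[chrom] = c
        if total == 0:
            eligible[chrom] = np.zeros(n_win, dtype=bool)
        else:
            eligible[chrom] = stats.poisson.sf(c - 1, lam) < params.window_p0
    return WindowScores(genome, params, counts, eligible, lam, total)


@dataclass
class IslandSet:
    """Called islands with counts, scores and significance."""

    df: pd.DataFrame  # chrom, start, end, length, treat_count, control_count, score, p_value, q_value, intensity
    treat_total: int
    control_total: int
    params: IslandCallerParams

    @property
    def intervals(self) -> list[GenomicInterval]:
        return [
            GenomicInterval(r.chrom, int(r.start), int(r.end), score=float(r.score))
            for r in self.df.itertuples()
        ]

    def total_bp(self) -> int:
        return int(self.df["length"].sum()) if len(self.df) else 0

    def write_bed(self, path) -> None:
        with open(path, "w") as fh:
            for i, r in enumerate(self.df.itertuples()):
                fh.write(f"{r.chrom}\t{r.start}\t{r.end}\tisland{i}\t{r.score:.4f}\t.\n")


def _join_eligible_runs(eligible: np.ndarray, max_gap_windows: int) -> list[tuple[int, int]]:
    """Maximal runs of eligible windows whose internal ineligible gaps are
    <= max_gap_windows; returns [first_window, last_window] index pairs."""
    idx = np.nonzero(eligible)[0]
    if len(idx) == 0:
        return []
    breaks = np.nonzero(np.diff(idx) - 1 > max_gap_windows)[0]
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [len(idx) - 1]))
    return [(int(idx[a]), int(idx[z])) for a, z in zip(starts, ends)]


def call_islands(scored: WindowScores, control: ReadSet, params: IslandCallerParams) -> IslandSet:
    """Join eligible windows into islands and test them against the input.

    Island score: sum over eligible windows of -ln P(X = count; lambda).
    Island p-value: Poisson upper tail of the island fragment count with
    mean max(control_count, 1) scaled by the library-size ratio; BH across
    all candidate islands, keep q < fdr.
    """
    if control is None:
        raise ValueError("an input/control read set is required for island calling")
    W = params.window_size
    genome = scored.genome
    lam = scored.lam
    treat_total = scored.total_count
    control_total = control.total_count
    ratio = treat_total / max(control_total, 1)

    rows = []
    cmids = control.midpoints
    for ci, (chrom, L) in enumerate(genome):
        elig = scored.eligible[chrom]
        counts = scored.counts[chrom]
        cm = np.sort(cmids[control.chrom_idx == ci])
        for w0, w1 in _join_eligible_runs(elig, params.gap_windows):
            start, end = w0 * W, min((w1 + 1) * W, L)
            win_slice = slice(w0, w1 + 1)
            e = elig[win_slice]
            c = counts[win_slice]
            with np.errstate(divide="ignore"):
                score = float(-np.sum(np.log(stats.poisson.pmf(c[e], lam))))
            treat_count = int(c.sum())
            control_count = int(np.searchsorted(cm, end) - np.searchsorted(cm, start))
            rows.append((chrom, start, end, end - start, treat_count, control_count, score))
    df = pd.DataFrame(
        rows, columns=["chrom", "start", "end", "length", "treat_count", "control_count", "score"]
    )
    if len(df):
        mean = np.maximum(df["control_count"].to_numpy(), 1) * ratio
        df["p_value"] = stats.poisson.sf(df["treat_count"].to_numpy() - 1, mean)
        df["q_value"] = bh_adjust(df["p_value"].to_numpy())
        df["intensity"] = df["treat_count"] / df["length"] * 1e6 / max(treat_total, 1)
        df = df[df["q_value"] < params.fdr].reset_index(drop=True)
    else:
        df = df.assign(p_value=[], q_value=[], intensity=[])
    return IslandSet(df, treat_total, control_total, params)


def _count_in_regions(reads: ReadSet, regions: pd.DataFrame) -> np.ndarray:
    """Fragments (by midpoint) inside each region; regions need chrom/start/end."""
    mids = reads.midpoints
    out = np.zeros(len(regions), dtype=np.int64)
    for ci, (chrom, _) in enumerate(reads.genome):
        m = regions["chrom"] == chrom
        if not m.any():
            continue
        rm = np.sort(mids[reads.chrom_idx == ci])
        s = regions.loc[m, "start"].to_numpy()
        e = regions.loc[m, "end"].to_numpy()
        out[np.nonzero(m.to_numpy())[0]] = np.searchsorted(rm, e) - np.searchsorted(rm, s)
    return out


def differential_islands(
    a: ReadSet,
    b: ReadSet,
    islands_a: IslandSet,
    islands_b: IslandSet,
    params: IslandCallerParams,
) -> tuple[IslandSet, IslandSet]:
    """Condition-vs-condition differential islands over the merged candidates.

    Candidate regions are the merged union of both island sets; each is
    tested in both directions with the library-size-scaled Poisson test and
    BH across candidates.
    """
    from .annotation import merge_intervals

    merged = merge_intervals(islands_a.intervals + islands_b.intervals)
    cand = pd.DataFrame(
        [(iv.chrom, iv.start, iv.end) for iv in merged], columns=["chrom", "start", "end"]
    )
    if len(cand) == 0:
        empty = cand.assign(length=[], treat_count=[], control_count=[], score=[], p_value=[], q_value=[], intensity=[])
        return (
            IslandSet(empty.copy(), a.total_count, b.total_count, params),
            IslandSet(empty.copy(), b.total_count, a.total_count, params),
        )
    count_a = _count_in_regions(a, cand)
    count_b = _count_in_regions(b, cand)
    out = []
    for treat_counts, ctrl_counts, treat, ctrl in (
        (count_a, count_b, a, b),
        (count_b, count_a, b, a),
    ):
        ratio = treat.total_count / max(ctrl.total_count, 1)
        mean = np.maximum(ctrl_counts, 1) * ratio
        p = stats.poisson.sf(treat_counts - 1, mean)
        q = bh_adjust(p)
        df = cand.copy()
        df["length"] = df["end"] - df["start"]
        df["treat_count"] = treat_counts
        df["control_count"] = ctrl_counts
        df["score"] = -np.log10(np.maximum(p, 1e-300))
        df["p_value"] = p
        df["q_value"] = q
        df["intensity"] = df["treat_count"] / df["length"] * 1e6 / max(treat.total_count, 1)
        out.append(
            IslandSet(df[q < params.fdr].reset_index(drop=True), treat.total_count, ctrl.total_count, params)
        )
    return out[0], out[1]


@dataclass
class PeakStats:
    """Diffuseness summary of one island set."""

    n_islands: int
    mean_length: float
    se_length: float
    mean_intensity: float  # fragments per bp per million mapped
    se_intensity: float
    fraction_reads_in_peaks: float


def peak_statistics(islands: IslandSet, reads: ReadSet) -> PeakStats:
    df = islands.df
    if len(df) == 0:
        return PeakStats(0, float("nan"), float("nan"), float("nan"), float("nan"), 0.0)
    inside = int(_count_in_regions(reads, df).sum())
    frac = inside / max(reads.total_count, 1)
    L = df["length"].to_numpy(dtype=float)
    I = df["intensity"].to_numpy(dtype=float)
    n = len(df)
    sem = lambda x: float(np.std(x, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return PeakStats(n, float(L.mean()), sem(L), float(I.mean()), sem(I), frac)


def compare_peak_stats(islands1: IslandSet, islands2: IslandSet) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum p-values for per-island length and
    intensity between two island populations (exact for small n)."""
    out = {}
    for key in ("length", "intensity"):
        x = islands1.df[key].to_numpy(dtype=float)
        y = islands2.df[key].to_numpy(dtype=float)
        if len(x) == 0 or len(y) == 0:
            out[key] = float("nan")
            continue
        method = "exact" if max(len(x), len(y)) <= 25 else "asymptotic"
        out[key] = float(stats.mannwhitneyu(x, y, alternative="two-sided", method=method).pvalue)
    return out
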