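"""Island caller vs brute-force oracles, differential islands, rank-sum stats."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hetmig.genome import GenomeTable, GenomicInterval, ReadSet
from hetmig.peaks import (
    IslandCallerParams,
    _join_eligible_runs,
    call_islands,
    compare_peak_stats,
    differential_islands,
    peak_statistics,
    score_windows,
)


def poisson_sf_oracle(k, lam):
    """Upper tail P(X >= k) by direct summation."""
    if k <= 0:
        return 1.0
    total = 0.0
    term = math.exp(-lam)
    for i in range(k):
        total += term * lam**i / math.factorial(i)
    return 1.0 - total


def reads_at(midpoints, genome, label="t"):
    mids = np.asarray(midpoints, dtype=np.int64)
    return ReadSet(label, genome, np.zeros(len(mids), dtype=np.int32), mids - 5, mids + 5)


class TestScoreWindows:
    def test_zero_count_never_eligible(self):
        genome = GenomeTable([("chr1", 2000)])
        rs = reads_at([], genome)
        scored = score_windows(rs, IslandCallerParams(), genome)
        assert not scored.eligible["chr1"].any()

    def test_eligibility_matches_tail_oracle(self):
        """lambda = 1, count = 4 has upper tail ~= 0.019 < 0.2 -> eligible."""
        genome = GenomeTable([("chr1", 4000)])  # 20 windows of 200
        params = IslandCallerParams(genome_fraction=1.0, window_p0=0.2)
        # 20 fragments -> lambda = 20*200/4000 = 1; put 4 in window 0
        mids = [50, 60, 70, 80] + list(np.arange(16) * 200 + 900)
        scored = score_windows(reads_at(mids, genome), params, genome)
        assert scored.lam == pytest.approx(1.0)
        assert poisson_sf_oracle(4, 1.0) == pytest.approx(0.01899, abs=1e-4)
        assert scored.eligible["chr1"][0]

    def test_lambda_recomputed_on_doubling(self):
        genome = GenomeTable([("chr1", 4000)])
        params = IslandCallerParams(genome_fraction=1.0)
        mids = [50, 60, 70, 80] + list(np.arange(16) * 200 + 900)
        s1 = score_windows(reads_at(mids), params, genome) if False else score_windows(reads_at(mids, genome), params, genome)
        s2 = score_windows(reads_at(mids + [m + 1 for m in mids], genome), params, genome)
        assert s2.lam == pytest.approx(2 * s1.lam)
        # eligibility governed by the recomputed lambda, matching the oracle
        for w in range(20):
            c = s2.counts["chr1"][w]
            assert s2.eligible["chr1"][w] == (poisson_sf_oracle(int(c), s2.lam) < params.window_p0)


def brute_force_islands(eligible, max_gap):
    """Enumerative gap-joining oracle over a window eligibility vector."""
    islands = []
    cur = None
    gap = 0
    for i, e in enumerate(eligible):
        if e:
            if cur is None:
                cur = [i, i]
            elif gap <= max_gap:
                cur[1] = i
            else:
                islands.append(tuple(cur))
                cur = [i, i]
            gap = 0
        else:
            gap += 1
    if cur is not None:
        islands.append(tuple(cur))
    return islands


class TestGapJoining:
    def test_three_windows_one_gap_each(self):
        """Eligible at 0, 2, 4 with gap tolerance 3 windows -> one island."""
        elig = np.array([1, 0, 1, 0, 1], dtype=bool)
        assert _join_eligible_runs(elig, 3) == [(0, 4)]

    @pytest.mark.parametrize("max_gap", [0, 1, 3])
    def test_matches_brute_force_on_all_short_vectors(self, max_gap):
        for bits in itertools.product([0, 1], repeat=10):
            elig = np.array(bits, dtype=bool)
            assert _join_eligible_runs(elig, max_gap) == brute_force_islands(bits, max_gap)

    def test_random_long_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            elig = rng.random(50) < 0.4
            assert _join_eligible_runs(elig, 2) == brute_force_islands(elig, 2)


class TestCallIslands:
    genome = GenomeTable([("chr1", 10_000)])

    def _call(self, treat_mids, control_mids, **kw):
        params = IslandCallerParams(genome_fraction=1.0, **kw)
        treat = reads_at(treat_mids, self.genome)
        control = reads_at(control_mids, self.genome, "input")
        scored = score_windows(treat, params, self.genome)
        return call_islands(scored, control, params)

    def test_no_eligible_windows_empty_set(self):
        isl = self._call(list(np.arange(50) * 200 + 10), list(np.arange(50) * 200 + 10))
        assert len(isl.df) == 0

    def test_missing_control_rejected(self):
        params = IslandCallerParams()
        treat = reads_at([100], self.genome)
        scored = score_windows(treat, params, self.genome)
        with pytest.raises(ValueError, match="control"):
            call_islands(scored, None, params)

    def test_enriched_island_significant_against_control(self):
        """treat 20 vs scaled control 5: upper tail ~2.6e-7, kept at q<0.05."""
        treat_mids = list(np.linspace(10, 190, 20).astype(int)) + list(np.arange(30) * 200 + 2010)
        ctrl_mids = list(np.linspace(10, 190, 5).astype(int)) + list(np.arange(45) * 200 + 2010)
        isl = self._call(treat_mids, ctrl_mids)
        assert len(isl.df) == 1
        row = isl.df.iloc[0]
        assert row["treat_count"] == 20 and row["control_count"] == 5
        assert row["p_value"] == pytest.approx(poisson_sf_oracle(20, 5.0), rel=1e-9)
        assert row["p_value"] < 1e-6 and row["q_value"] < 0.05

    def test_island_boundaries_are_window_multiples(self, called_islands):
        W = IslandCallerParams().window_size
        for isl in called_islands.values():
            assert (isl.df["start"] % W == 0).all()
            ends_ok = (isl.df["end"] % W == 0) | (isl.df["end"] == 5_000_000)
            assert ends_ok.all()

    def test_monotonicity_in_fdr_and_p0(self):
        rng = np.random.default_rng(5)
        mids = np.concatenate([rng.integers(0, 10_000, 300), rng.integers(2000, 3000, 120)])
        params_loose = IslandCallerParams(genome_fraction=1.0, fdr=0.2)
        params_tight = IslandCallerParams(genome_fraction=1.0, fdr=0.01)
        treat = reads_at(mids, self.genome)
        ctrl = reads_at(rng.integers(0, 10_000, 420), self.genome, "input")
        scored = score_windows(treat, params_loose, self.genome)
        n_loose = len(call_islands(scored, ctrl, params_loose).df)
        n_tight = len(call_islands(scored, ctrl, params_tight).df)
        assert n_loose >= n_tight
        s_loose = score_windows(treat, IslandCallerParams(genome_fraction=1.0, window_p0=0.3), self.genome)
        s_tight = score_windows(treat, IslandCallerParams(genome_fraction=1.0, window_p0=0.05), self.genome)
        assert s_loose.eligible["chr1"].sum() >= s_tight.eligible["chr1"].sum()


class TestDifferentialIslands:
    genome = GenomeTable([("chr1", 10_000)])

    def _islands_at(self, span, reads):
        df = pd.DataFrame(
            [("chr1", span[0], span[1], span[1] - span[0], 0, 0, 1.0, 0.0, 0.0, 0.0)],
            columns=["chrom", "start", "end", "length", "treat_count", "control_count", "score", "p_value", "q_value", "intensity"],
        )
        return __import__("hetmig.peaks", fromlist=["IslandSet"]).IslandSet(
            df, reads.total_count, reads.total_count, IslandCallerParams()
        )

    def test_identical_libraries_yield_nothing(self):
        mids = list(np.arange(40) * 10 + 1000)
        a = reads_at(mids, self.genome, "a")
        b = reads_at(mids, self.genome, "b")
        ia = self._islands_at((1000, 1400), a)
        enr_a, enr_b = differential_islands(a, b, ia, ia, IslandCallerParams())
        assert len(enr_a.df) == 0 and len(enr_b.df) == 0

    def test_count_excess_detected(self):
        """30 vs 10 at equal totals is enriched (sole candidate)."""
        a = reads_at(list(np.linspace(1000, 1390, 30).astype(int)) + list(np.arange(70) * 10 + 5000), self.genome, "a")
        b = reads_at(list(np.linspace(1000, 1390, 10).astype(int)) + list(np.arange(90) * 10 + 5000), self.genome, "b")
        ia = self._islands_at((1000, 1400), a)
        enr_a, enr_b = differential_islands(a, b, ia, ia, IslandCallerParams())
        got = enr_a.df[(enr_a.df.start == 1000)]
        assert len(got) == 1
        assert got.iloc[0]["p_value"] == pytest.approx(poisson_sf_oracle(30, 10.0), rel=1e-9)

    def test_presence_without_excess_not_differential(self):
        mids = list(np.linspace(1000, 1390, 20).astype(int))
        a = reads_at(mids, self.genome, "a")
        b = reads_at(mids, self.genome, "b")
        ia = self._islands_at((1000, 1400), a)
        ib_empty = self._islands_at((5000, 5200), b)
        enr_a, _ = differential_islands(a, b, ia, ib_empty, IslandCallerParams())
        assert not (enr_a.df["start"] == 1000).any()


class TestPeakStatistics:
    genome = GenomeTable([("chr1", 10_000)])

    def test_fraction_of_midpoints(self):
        from tests.test_peaks import reads_at as _ra

        mids = list(np.linspace(1000, 1390, 50).astype(int)) + list(np.linspace(5000, 9000, 150).astype(int))
        reads = _ra(mids, self.genome)
        df = pd.DataFrame(
            [("chr1", 1000, 1400, 400, 50, 0, 1.0, 0.0, 0.0, 50 / 400 * 1e6 / 200)],
            columns=["chrom", "start", "end", "length", "treat_count", "control_count", "score", "p_value", "q_value", "intensity"],
        )
        from hetmig.peaks import IslandSet

        isl = IslandSet(df, 200, 200, IslandCallerParams())
        ps = peak_statistics(isl, reads)
        assert ps.fraction_reads_in_peaks == pytest.approx(0.25)

    def test_identical_populations_ranksum_p_one(self):
        from hetmig.peaks import IslandSet

        df = pd.DataFrame(
            {"chrom": "chr1", "start": [0, 1000], "end": [400, 1400], "length": [400, 400],
             "treat_count": [10, 10], "control_count": [0, 0], "score": 1.0,
             "p_value": 0.0, "q_value": 0.0, "intensity": [1.0, 1.0]}
        )
        isl = IslandSet(df, 20, 20, IslandCallerParams())
        p = compare_peak_stats(isl, isl)
        assert p["length"] == pytest.approx(1.0)
        assert p["intensity"] == pytest.approx(1.0)

    def test_ranksum_matches_exhaustive_enumeration(self):
        """{100,100,200} vs {400,400,800}: p equals enumeration over all
        C(6,3)=20 rank assignments."""
        x, y = [100.0, 100.0, 200.0], [400.0, 400.0, 800.0]
        obs_u = sum(1 for a in x for b in y if a > b) + 0.5 * sum(1 for a in x for b in y if a == b)
        pooled = x + y
        us = []
        for idx in itertools.combinations(range(6), 3):
            xx = [pooled[i] for i in idx]
            yy = [pooled[i] for i in range(6) if i not in idx]
            us.append(sum(1 for a in xx for b in yy if a > b) + 0.5 * sum(1 for a in xx for b in yy if a == b))
        mean_u = np.mean(us)
        p_exact = np.mean([abs(u - mean_u) >= abs(obs_u - mean_u) - 1e-12 for u in us])
        got = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert got == pytest.approx(p_exact, abs=1e-12)

    def test_empty_island_set(self):
        from hetmig.peaks import IslandSet

        empty = pd.DataFrame(columns=["chrom", "start", "end", "length", "treat_count", "control_count", "score", "p_value", "q_value", "intensity"])
        ps = peak_statistics(IslandSet(empty, 10, 10, IslandCallerParams()), reads_at([100], self.genome))
        assert ps.n_islands == 0 and ps.fraction_reads_in_peaks == 0.0
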