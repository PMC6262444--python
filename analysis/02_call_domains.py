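#!/usr/bin/env python
"""Call broad islands against input for every mark/condition, measure the
diffuseness statistics (island count, mean length, intensity, fraction of
reads in peaks), and call condition-vs-condition differential islands.

Finding on the default scenario: induced migration yields fewer reads in
peaks and longer, weaker islands — the diffuse-spreading signature.
"""
import argparse
import dataclasses
from pathlib import Path

import pandas as pd

from hetmig.peaks import IslandCallerParams, call_islands, compare_peak_stats, differential_islands, peak_statistics, score_windows
from hetmig.synthetic import MARKS, SyntheticScenario, generate_annotation, simulate_chip_reads


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/domains"))
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    scenario = SyntheticScenario(seed=args.seed)
    genome = scenario.genome()
    catalog, _ = generate_annotation(scenario)
    params = IslandCallerParams()

    rows = []
    islands, tracks = {}, {}
    for cond in ("control", "migrating"):
        inp, _ = simulate_chip_reads(scenario, "input", cond, catalog=catalog)
        for mark in MARKS:
            reads, _ = simulate_chip_reads(scenario, mark, cond, catalog=catalog)
            tracks[(mark, cond)] = reads
            isl = call_islands(score_windows(reads, params, genome), inp, params)
            islands[(mark, cond)] = isl
            isl.write_bed(out / f"islands_{mark}_{cond}.bed")
            ps = peak_statistics(isl, reads)
            rows.append({"mark": mark, "condition": cond, **dataclasses.asdict(ps)})
    stats = pd.DataFrame(rows)
    stats.to_csv(out / "peak_stats.tsv", sep="\t", index=False)

    print("diffuseness statistics (per mark, control vs migrating):")
    for mark in MARKS:
        c = stats[(stats["mark"] == mark) & (stats.condition == "control")].iloc[0]
        m = stats[(stats["mark"] == mark) & (stats.condition == "migrating")].iloc[0]
        p = compare_peak_stats(islands[(mark, "control")], islands[(mark, "migrating")])
        print(f"  {mark:9s}: reads-in-peaks {c.fraction_reads_in_peaks:.1%} -> {m.fraction_reads_in_peaks:.1%}; "
              f"mean length {c.mean_length:.0f} -> {m.mean_length:.0f} bp "
              f"(rank-sum p = {p['length']:.2e}); intensity {c.mean_intensity:.3f} -> {m.mean_intensity:.3f}")

    for mark in MARKS:
        mig, ctl = differential_islands(
            tracks[(mark, "migrating")], tracks[(mark, "control")],
            islands[(mark, "migrating")], islands[(mark, "control")], params,
        )
        mig.write_bed(out / f"diffpeaks_{mark}_migrating_enriched.bed")
        ctl.write_bed(out / f"diffpeaks_{mark}_control_enriched.bed")
        print(f"  {mark:9s}: {len(mig.df)} migrating-enriched, {len(ctl.df)} control-enriched differential islands")


if __name__ == "__main__":
    main()
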