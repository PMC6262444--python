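#!/usr/bin/env python
"""Generate the toy study: genome, annotation, ChIP fragment sets per
mark/condition, and the five-arm RNA-seq count matrix with planted truth.

Writes annotation tables, planted-domain BEDs, counts and the sample sheet
under results/data/, and prints a summary of what was planted.
"""
import argparse
from pathlib import Path

from hetmig.genome import write_bed
from hetmig.pipeline import write_reads_bed
from hetmig.synthetic import CONDITIONS, MARKS, SyntheticScenario, generate_annotation, simulate_chip_reads, simulate_counts


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--outdir", type=Path, default=Path("results/data"))
    ap.add_argument("--write-reads", action="store_true", help="also write fragment BEDs (large)")
    args = ap.parse_args()
    out = args.outdir
    out.mkdir(parents=True, exist_ok=True)

    scenario = SyntheticScenario(seed=args.seed)
    catalog, truth = generate_annotation(scenario)
    catalog.genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    catalog.enhancers.to_csv(out / "enhancers.tsv", sep="\t", index=False)
    catalog.repeats.to_csv(out / "repeats.tsv", sep="\t", index=False)
    print(f"annotation: {len(catalog.genes)} genes, {len(catalog.repeats)} repeats, "
          f"{len(catalog.enhancers)} enhancers on {scenario.n_chroms} x {scenario.chrom_length/1e6:.0f} Mb")

    for cond in CONDITIONS:
        for mark in MARKS + ("input",):
            reads, tr = simulate_chip_reads(scenario, mark, cond, catalog=catalog)
            if args.write_reads:
                write_reads_bed(out / f"reads_{mark}_{cond}.bed", reads)
            if mark != "input":
                doms = tr.domains[(mark, cond)]
                write_bed(out / f"truth_domains_{mark}_{cond}.bed", doms, name_prefix="dom")
                mean_len = sum(len(d) for d in doms) / len(doms)
                print(f"  {mark:9s} {cond:9s}: {reads.total_count:7d} fragments, "
                      f"{len(doms)} planted domains, mean {mean_len:.0f} bp")

    counts, samples, ct = simulate_counts(scenario)
    counts.to_csv(out / "counts.tsv", sep="\t")
    samples.to_csv(out / "samples.tsv", sep="\t")
    ct.gene_classes.to_csv(out / "truth_gene_classes.tsv", sep="\t")
    vc = ct.gene_classes["class"].value_counts()
    print(f"counts: {counts.shape[0]} genes x {counts.shape[1]} samples; planted classes: "
          + ", ".join(f"{k}={v}" for k, v in vc.items() if k != "unchanged"))


if __name__ == "__main__":
    main()
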