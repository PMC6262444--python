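"""End-to-end orchestration: simulate -> annotate -> peaks -> coverage ->
correlation -> states -> differential expression -> classification ->
profiles, with a manifest recording every parameter and output digest.

Stages are pure functions of (inputs, parameters, seed); the run directory
is the only shared state, so stages can be re-run individually.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import annotation as ann
from . import classify as cl
from . import correlation as corr
from . import coverage as cov
from . import diffexpr as de
from . import states as st
from .genome import GenomeTable, ReadSet, write_bed
from .peaks import IslandCallerParams, IslandSet, call_islands, differential_islands, peak_statistics, score_windows
from .synthetic import CONDITIONS, MARKS, SyntheticScenario, generate_annotation, simulate_chip_reads, simulate_counts

log = logging.getLogger("hetmig")


@dataclass
class RunConfig:
    """Every stage's parameters; defaults are the study's printed values
    where the study prints one (fragment 350, effective genome fraction
    0.8, FDR 0.05, promoter 1000 bp, correlation bins 10 kb, K = 5 states,
    1 cpm in 3 samples, fold change 1.3, 2000 bp flanks, top/bottom 500)."""

    scenario: SyntheticScenario = field(default_factory=SyntheticScenario)
    islands: IslandCallerParams = field(default_factory=IslandCallerParams)
    promoter_bp: int = 1000
    corr_bin_bp: int = 10_000
    state_bin_bp: int = 200
    n_states: int = 5
    hmm_max_iter: int = 200
    fdr: float = 0.05
    fc_min: float = 1.3
    cpm_min: float = 1.0
    cpm_min_samples: int = 3
    flank_bp: int = 2000
    rank_k: int = 500
    outdir: Path = Path("results/run")
    seed: int = 0
    write_reads: bool = False

    def replace_seed(self, seed: int) -> "RunConfig":
        return dataclasses.replace(
            self, seed=seed, scenario=dataclasses.replace(self.scenario, seed=seed)
        )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def write_reads_bed(path: Path, reads: ReadSet) -> None:
    names = reads.genome.names
    df = pd.DataFrame(
        {"chrom": [names[c] for c in reads.chrom_idx], "start": reads.start, "end": reads.end}
    )
    df.to_csv(path, sep="\t", header=False, index=False)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


def run_all(config: RunConfig) -> dict:
    """Execute every stage; returns the manifest (also written as JSON)."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}
    ctx: dict = {}
    stages = [
        ("simulate", _stage_simulate),
        ("annotate", _stage_annotate),
        ("callpeaks", _stage_callpeaks),
        ("diffpeaks", _stage_diffpeaks),
        ("coverage", _stage_coverage),
        ("correlate", _stage_correlate),
        ("states", _stage_states),
        ("de", _stage_de),
        ("classify", _stage_classify),
        ("profile", _stage_profile),
    ]
    for name, fn in stages:
        log.info("stage %s starting", name)
        try:
            params, outputs = fn(config, ctx, out)
        except Exception as exc:  # noqa: BLE001 - halt with stage named
            raise PipelineError(name, exc) from exc
        manifest["stages"][name] = {
            "params": params,
            "outputs": {str(p.relative_to(out)): _digest(p) for p in outputs},
        }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def _stage_simulate(config: RunConfig, ctx: dict, out: Path):
    sc = config.scenario
    catalog, truth = generate_annotation(sc)
    ctx["catalog"] = catalog
    ctx["genome"] = sc.genome()
    ctx["tracks"] = {}
    ctx["truth_domains"] = {}
    outputs = []
    for cond in CONDITIONS:
        for mark in MARKS + ("input",):
            reads, tr = simulate_chip_reads(sc, mark, cond, catalog=catalog)
            ctx["tracks"][(mark, cond)] = reads
            ctx["truth_domains"][(mark, cond)] = tr.domains[(mark, cond)]
            if config.write_reads:
                p = out / f"reads_{mark}_{cond}.bed"
                write_reads_bed(p, reads)
                outputs.append(p)
            if mark != "input":
                p = out / f"truth_domains_{mark}_{cond}.bed"
                write_bed(p, tr.domains[(mark, cond)], name_prefix="dom")
                outputs.append(p)
    counts, samples, ct = simulate_counts(sc)
    ctx["counts"], ctx["samples"], ctx["gene_truth"] = counts, samples, ct.gene_classes
    for name, df in (
        ("counts.tsv", counts),
        ("samples.tsv", samples),
        ("truth_gene_classes.tsv", ct.gene_classes),
    ):
        df.to_csv(out / name, sep="\t")
        outputs.append(out / name)
    (out / "genes.tsv").write_text(catalog.genes.to_csv(sep="\t", index=False))
    outputs.append(out / "genes.tsv")
    return dataclasses.asdict(sc), outputs


def _stage_annotate(config: RunConfig, ctx: dict, out: Path):
    genome, catalog = ctx["genome"], ctx["catalog"]
    promoters = ann.define_promoters(catalog.genes, genome, length=config.promoter_bp)
    partition = ann.build_exclusive_partition(catalog, promoters, genome)
    ctx["partition"] = partition
    outputs = partition.write_beds(out)
    bp = partition.class_bp
    pd.Series(bp).to_csv(out / "partition_class_bp.tsv", sep="\t", header=["bp"])
    outputs.append(out / "partition_class_bp.tsv")
    return {"promoter_bp": config.promoter_bp}, outputs


def _stage_callpeaks(config: RunConfig, ctx: dict, out: Path):
    genome = ctx["genome"]
    islands: dict[tuple[str, str], IslandSet] = {}
    stats_rows = []
    outputs = []
    for cond in CONDITIONS:
        control = ctx["tracks"][("input", cond)]
        for mark in MARKS:
            reads = ctx["tracks"][(mark, cond)]
            scored = score_windows(reads, config.islands, genome)
            isl = call_islands(scored, control, config.islands)
            islands[(mark, cond)] = isl
            p = out / f"islands_{mark}_{cond}.bed"
            isl.write_bed(p)
            outputs.append(p)
            ps = peak_statistics(isl, reads)
            stats_rows.append({"mark": mark, "condition": cond, **dataclasses.asdict(ps)})
    ctx["islands"] = islands
    df = pd.DataFrame(stats_rows)
    df.to_csv(out / "peak_stats.tsv", sep="\t", index=False)
    outputs.append(out / "peak_stats.tsv")
    ctx["peak_stats"] = df
    return dataclasses.asdict(config.islands), outputs


def _stage_diffpeaks(config: RunConfig, ctx: dict, out: Path):
    outputs = []
    diff = {}
    for mark in MARKS:
        a = ctx["tracks"][(mark, "migrating")]
        b = ctx["tracks"][(mark, "control")]
        mig_enr, ctrl_enr = differential_islands(
            a, b, ctx["islands"][(mark, "migrating")], ctx["islands"][(mark, "control")], config.islands
        )
        diff[mark] = {"migrating": mig_enr, "control": ctrl_enr}
        for cond, isl in (("migrating", mig_enr), ("control", ctrl_enr)):
            p = out / f"diffpeaks_{mark}_{cond}_enriched.bed"
            isl.write_bed(p)
            outputs.append(p)
    ctx["diffpeaks"] = diff
    return {"fdr": config.islands.fdr}, outputs


def _stage_coverage(config: RunConfig, ctx: dict, out: Path):
    partition = ctx["partition"]
    rows = {}
    for (mark, cond), reads in ctx["tracks"].items():
        rows[f"{mark}_{cond}"] = cov.coverage_fractions(reads, partition)
    reads_pct = pd.DataFrame(rows).T
    reads_pct.to_csv(out / "coverage_read_percent.tsv", sep="\t")
    drows = {}
    for mark, d in ctx["diffpeaks"].items():
        for cond, isl in d.items():
            drows[f"{mark}_{cond}_enriched"] = cov.diffpeak_bp_fractions(isl, partition)
    diff_pct = pd.DataFrame(drows).T
    diff_pct.to_csv(out / "coverage_diffpeak_bp_percent.tsv", sep="\t")
    ctx["reads_pct"], ctx["diff_pct"] = reads_pct, diff_pct
    return {}, [out / "coverage_read_percent.tsv", out / "coverage_diffpeak_bp_percent.tsv"]


def _stage_correlate(config: RunConfig, ctx: dict, out: Path):
    genome, partition = ctx["genome"], ctx["partition"]
    outputs = []
    ctx["spearman"] = {}
    for cond in CONDITIONS:
        tracks = [ctx["tracks"][(m, cond)] for m in MARKS]
        m = corr.bin_signal(tracks, genome, config.corr_bin_bp)
        for label, restrict in (("genome", None), ("promoter", "promoter"), ("repeat", "repeat")):
            try:
                rho = corr.spearman_matrix(m, restrict_to=restrict, partition=partition)
            except ValueError:
                # toy-scale features rarely dominate a 10 kb bin; correlate
                # over the feature intervals themselves instead
                feats = pd.DataFrame(
                    [(iv.chrom, iv.start, iv.end) for iv in partition.intervals_of(restrict)],
                    columns=["chrom", "start", "end"],
                )
                rho = corr.correlate_over_features(tracks, feats)
            p = out / f"spearman_{cond}_{label}.tsv"
            rho.to_csv(p, sep="\t")
            outputs.append(p)
            ctx["spearman"][(cond, label)] = rho
    return {"bin_bp": config.corr_bin_bp}, outputs


def _stage_states(config: RunConfig, ctx: dict, out: Path):
    genome, partition = ctx["genome"], ctx["partition"]
    outputs = []
    ctx["segmentations"] = {}
    for cond in CONDITIONS:
        tracks = [ctx["tracks"][(m, cond)] for m in MARKS]
        b = st.binarize(tracks, ctx["tracks"][("input", cond)], genome, config.state_bin_bp)
        model = st.fit_state_model(b, K=config.n_states, seed=config.seed, max_iter=config.hmm_max_iter)
        seg = st.segment_and_enrich(model, b, partition)
        ctx["segmentations"][cond] = seg
        model.to_tsv(out / f"state_model_{cond}.tsv")
        seg.enrichment.to_csv(out / f"state_enrichment_{cond}.tsv", sep="\t")
        pd.Series(seg.state_shares, index=[f"state{k+1}" for k in range(model.K)]).to_csv(
            out / f"state_shares_{cond}.tsv", sep="\t", header=["share"]
        )
        outputs += [
            out / f"state_model_{cond}.tsv",
            out / f"state_enrichment_{cond}.tsv",
            out / f"state_shares_{cond}.tsv",
        ]
    return {"K": config.n_states, "bin_bp": config.state_bin_bp}, outputs


def _stage_de(config: RunConfig, ctx: dict, out: Path):
    res = de.run_de(
        ctx["counts"], ctx["samples"], fdr=config.fdr, fc_min=config.fc_min,
        cpm_min=config.cpm_min, min_samples=config.cpm_min_samples,
    )
    ctx["de"] = res
    outputs = []
    for name, r in res.items():
        p = out / f"de_{name}.tsv"
        r.table.to_csv(p, sep="\t")
        outputs.append(p)
    return {"fdr": config.fdr, "fc_min": config.fc_min}, outputs


def _stage_classify(config: RunConfig, ctx: dict, out: Path):
    res = ctx["de"]
    dep = cl.classify_dependency(res["mig_vs_ctrl"], res["ezh2i_vs_ctrl"])
    stab = cl.classify_stability(res["drb_mig_vs_drb_ctrl"])
    table, frac = cl.cross_tabulate(dep, stab)
    ctx["dependency"], ctx["stability"] = dep, stab
    ctx["crosstab"], ctx["stability_fractions"] = table, frac
    dep.to_csv(out / "dependency_classes.tsv", sep="\t")
    stab.to_csv(out / "stability_classes.tsv", sep="\t")
    table.to_csv(out / "crosstab.tsv", sep="\t")
    frac.to_csv(out / "stability_fractions.tsv", sep="\t", header=["fraction"])
    tracks = {c: ctx["tracks"][("H3K27me3", c)] for c in CONDITIONS}
    sig = cl.promoter_signal_by_class(dep, tracks, ctx["catalog"].genes, ctx["genome"])
    sig.to_csv(out / "promoter_signal_by_class.tsv", sep="\t", index=False)
    ctx["promoter_signal"] = sig
    return {}, [
        out / "dependency_classes.tsv", out / "stability_classes.tsv", out / "crosstab.tsv",
        out / "stability_fractions.tsv", out / "promoter_signal_by_class.tsv",
    ]


def _stage_profile(config: RunConfig, ctx: dict, out: Path):
    genes = ctx["catalog"].genes
    untreated = ctx["samples"].index[ctx["samples"]["treatment"] == "none"].tolist()
    top, bottom = cov.expression_ranked_regions(
        ctx["counts"], genes, samples=untreated, k=config.rank_k
    )
    outputs = []
    profs = {}
    for name, regions in (("genes", genes), ("top_expressed", top), ("bottom_expressed", bottom)):
        if len(regions) == 0:
            continue
        for (mark, cond), reads in ctx["tracks"].items():
            if mark == "input":
                continue
            prof = cov.meta_profile(reads, regions, flank_bp=config.flank_bp)
            profs[f"{name}_{mark}_{cond}"] = prof.values
    df = pd.DataFrame(profs)
    df.to_csv(out / "meta_profiles.tsv", sep="\t", index_label="bin")
    outputs.append(out / "meta_profiles.tsv")
    ctx["profiles"] = df
    return {"flank_bp": config.flank_bp, "rank_k": config.rank_k}, outputs
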