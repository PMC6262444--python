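"""Synthetic toy genome, annotation, ChIP fragment sets and RNA-seq counts.

The generator emulates the structure of the real study: three repressive
histone marks (H3K9me3, H3K27me3, H4K20me1) whose enrichment is peaked in
resting cells and diffuse — longer, weaker domains — after induction of
migration; mark-specific redistribution (H3K9me3/H4K20me1 domains drift to
repetitive elements, H3K27me3 to genes); an increased shared spatial
component between marks in the migrating state; and a count matrix with
planted H3K27me-dependent / -independent / -buffered and RNA-stability gene
classes over the five-arm design (control, migrating, migrating+EZH2
inhibitor, and both RNA-Pol-II-inhibited arms; 5/5/3/3/3 replicates).

All outputs are deterministic functions of the scenario seed; each stage
draws from its own derived stream so stages can be re-run independently.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import AnnotationCatalog, merge_intervals, tss
from .genome import GenomeTable, GenomicInterval, ReadSet

MARKS = ("H3K9me3", "H3K27me3", "H4K20me1")
CONDITIONS = ("control", "migrating")
GENE_CLASSES = ("dependent", "independent", "buffered", "stability_up", "stability_down", "unchanged")

# repeat-seeking marks vs gene-seeking mark (redistribution in migrating cells)
_REPEAT_SEEKING = {"H3K9me3", "H4K20me1"}

_STREAM = {"annotation": 1, "gene_params": 2, "counts": 3, "shared_domains": 4, "chip": 5}


@dataclass(frozen=True)
class SyntheticScenario:
    """All knobs of the toy study; defaults are the standard conditions."""

    seed: int = 0
    # genome
    n_chroms: int = 2
    chrom_length: int = 5_000_000
    # annotation densities (elements per Mb) and typical lengths (bp)
    coding_per_mb: float = 15.0
    coding_len: int = 20_000
    noncoding_per_mb: float = 10.0
    noncoding_len: int = 2_000
    enhancer_per_mb: float = 20.0
    enhancer_len: int = 1_000
    enhancer_in_gene_frac: float = 0.2
    line_per_mb: float = 60.0
    line_len: int = 1_000
    sine_per_mb: float = 80.0
    sine_len: int = 200
    ltr_per_mb: float = 40.0
    ltr_len: int = 500
    dna_per_mb: float = 20.0
    dna_len: int = 300
    # ChIP enrichment model
    background_rate: float = 0.05          # fragments per bp outside domains
    fragment_size: int = 350
    control_n_domains: int = 250
    control_domain_len: float = 4_000.0    # mean; peaked, strong
    control_multiplier: float = 6.0
    migrating_n_domains: int = 250
    migrating_domain_len: float = 8_000.0  # mean; diffuse, weak
    migrating_multiplier: float = 2.2
    shared_domain_fraction: float = 0.4    # migrating marks share these domains
    placement_escape_prob: float = 0.1     # rejection-sampling leak for biased placement
    buffered_promoter_gain: bool = True    # extra H3K27me3 domains at buffered-gene TSSs (migrating)
    # count model
    n_genes: int = 2_000
    replicates: tuple[int, int, int, int, int] = (5, 5, 3, 3, 3)
    lib_size: float = 1e6
    lib_size_spread: float = 0.15
    mean_log2_cpm: float = 5.0
    sd_log2_cpm: float = 2.0
    dispersion_low: float = 0.05
    dispersion_high: float = 0.2
    effect_log2fc: float = 2.0
    prop_dependent: float = 0.03
    prop_independent: float = 0.06
    prop_buffered: float = 0.05
    prop_stability_up: float = 0.03
    prop_stability_down: float = 0.05
    min_effect_cpm: float = 16.0           # planted effects only on expressed genes
    batch_sd: float = 0.3

    def __post_init__(self) -> None:
        props = (
            self.prop_dependent + self.prop_independent + self.prop_buffered
            + self.prop_stability_up + self.prop_stability_down
        )
        if props > 1.0:
            raise ValueError(f"class proportions sum to {props:.3f} > 1")
        for name in ("background_rate", "control_multiplier", "migrating_multiplier"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    def genome(self) -> GenomeTable:
        return GenomeTable([(f"chr{i + 1}", self.chrom_length) for i in range(self.n_chroms)])


@dataclass
class GroundTruth:
    """Planted truth: domain intervals per (mark, condition) and gene classes."""

    domains: dict[tuple[str, str], list[GenomicInterval]] = field(default_factory=dict)
    gene_classes: pd.DataFrame | None = None


def _rng(scenario: SyntheticScenario, stage: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng([scenario.seed, _STREAM[stage], *extra])


def _spread_nonoverlapping(rng, L: int, n: int, length: int) -> np.ndarray:
    """n non-overlapping starts for fixed-length elements, uniform gaps."""
    slack = L - n * length
    if slack < 0:
        raise ValueError(f"infeasible density: {n} elements x {length} bp exceed chromosome ({L} bp)")
    gaps = rng.dirichlet(np.ones(n + 1)) * slack
    starts = np.floor(np.cumsum(gaps[:-1]) + np.arange(n) * length).astype(np.int64)
    return starts


def gene_parameters(scenario: SyntheticScenario) -> pd.DataFrame:
    """Per-gene baseline expression, dispersion, planted class and signs.

    Shared deterministic stream so the ChIP and count generators agree on
    which genes carry which class label.
    """
    rng = _rng(scenario, "gene_params")
    n = scenario.n_genes
    gene_id = [f"gene{i + 1:04d}" for i in range(n)]
    base = rng.normal(scenario.mean_log2_cpm, scenario.sd_log2_cpm, size=n)
    disp = rng.uniform(scenario.dispersion_low, scenario.dispersion_high, size=n)
    cls = np.array(["unchanged"] * n, dtype=object)
    sign = np.zeros(n)
    eligible = np.nonzero(base >= np.log2(scenario.min_effect_cpm))[0]
    counts = {
        "dependent": round(scenario.prop_dependent * n),
        "independent": round(scenario.prop_independent * n),
        "buffered": round(scenario.prop_buffered * n),
        "stability_up": round(scenario.prop_stability_up * n),
        "stability_down": round(scenario.prop_stability_down * n),
    }
    need = sum(counts.values())
    if need > len(eligible):
        raise ValueError(
            f"only {len(eligible)} genes clear the {scenario.min_effect_cpm} cpm floor "
            f"but {need} planted-class genes requested"
        )
    chosen = rng.choice(eligible, size=need, replace=False)
    pos = 0
    for name, k in counts.items():
        idx = chosen[pos:pos + k]
        pos += k
        cls[idx] = name
        if name == "stability_up":
            sign[idx] = 1.0
        elif name == "stability_down":
            sign[idx] = -1.0
        else:
            sign[idx] = rng.choice([-1.0, 1.0], size=k)
    d = scenario.effect_log2fc
    lfc_a = np.where(np.isin(cls, ["dependent", "independent"]), sign * d, 0.0)
    lfc_b = np.where(np.isin(cls, ["independent", "buffered"]), sign * d, 0.0)
    lfc_c = np.where(np.isin(cls, ["stability_up", "stability_down"]), sign * d, 0.0)
    return pd.DataFrame(
        {
            "gene_id": gene_id,
            "base_log2_cpm": base,
            "dispersion": disp,
            "class": cls,
            "true_lfc_mig_vs_ctrl": lfc_a,
            "true_lfc_ezh2i_vs_ctrl": lfc_b,
            "true_lfc_drb": lfc_c,
        }
    ).set_index("gene_id")


def generate_annotation(scenario: SyntheticScenario) -> tuple[AnnotationCatalog, GroundTruth]:
    """Toy annotation catalog with deliberate cross-class overlaps.

    Genes are non-overlapping within their class; repeats land anywhere (so
    they overlap genes); a fixed fraction of enhancers is dropped inside
    gene bodies so the priority resolution is actually exercised. The first
    catalog genes share ids with the count-matrix universe.
    """
    rng = _rng(scenario, "annotation")
    genome = scenario.genome()
    mb = scenario.chrom_length / 1e6

    gene_rows, enh_rows, rep_rows = [], [], []
    gid = 0
    for chrom, L in genome:
        n_cod = int(round(scenario.coding_per_mb * mb))
        n_nc = int(round(scenario.noncoding_per_mb * mb))
        for starts, length, biotype in (
            (_spread_nonoverlapping(rng, L, n_cod, scenario.coding_len), scenario.coding_len, "coding"),
            (_spread_nonoverlapping(rng, L, n_nc, scenario.noncoding_len), scenario.noncoding_len, "noncoding"),
        ):
            for s in starts:
                gid += 1
                gene_rows.append(
                    {
                        "gene_id": f"gene{gid:04d}",
                        "chrom": chrom,
                        "start": int(s),
                        "end": int(s + length),
                        "strand": str(rng.choice(["+", "-"])),
                        "biotype": biotype,
                    }
                )
        for subtype, per_mb, length in (
            ("LINE", scenario.line_per_mb, scenario.line_len),
            ("SINE", scenario.sine_per_mb, scenario.sine_len),
            ("LTR", scenario.ltr_per_mb, scenario.ltr_len),
            ("DNA", scenario.dna_per_mb, scenario.dna_len),
        ):
            n = int(round(per_mb * mb))
            starts = rng.integers(0, max(1, L - length), size=n)
            for s in np.sort(starts):
                rep_rows.append({"chrom": chrom, "start": int(s), "end": int(s + length), "subtype": subtype})

    genes = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end", "strand", "biotype"])
    coding = genes[genes["biotype"] == "coding"]
    n_enh = int(round(scenario.enhancer_per_mb * mb * scenario.n_chroms))
    n_inside = int(round(scenario.enhancer_in_gene_frac * n_enh))
    for i in range(n_enh):
        if i < n_inside and len(coding):
            g = coding.iloc[int(rng.integers(0, len(coding)))]
            lo = int(g["start"])
            hi = max(lo + 1, int(g["end"]) - scenario.enhancer_len)
            chrom, s = g["chrom"], int(rng.integers(lo, hi))
        else:
            chrom = f"chr{int(rng.integers(0, scenario.n_chroms)) + 1}"
            s = int(rng.integers(0, scenario.chrom_length - scenario.enhancer_len))
        enh_rows.append({"chrom": chrom, "start": s, "end": s + scenario.enhancer_len})
    enhancers = pd.DataFrame(enh_rows, columns=["chrom", "start", "end"]).sort_values(
        ["chrom", "start"], ignore_index=True
    )
    repeats = pd.DataFrame(rep_rows, columns=["chrom", "start", "end", "subtype"])
    catalog = AnnotationCatalog(genes=genes, enhancers=enhancers, repeats=repeats)
    return catalog, GroundTruth(gene_classes=gene_parameters(scenario))


def _territory(ivs: list[GenomicInterval], genome: GenomeTable) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    merged = merge_intervals(ivs) if ivs else []
    out = {}
    for chrom, _ in genome:
        s = np.array([iv.start for iv in merged if iv.chrom == chrom], dtype=np.int64)
        e = np.array([iv.end for iv in merged if iv.chrom == chrom], dtype=np.int64)
        out[chrom] = (s, e)
    return out


def _in_territory(pos: np.ndarray, terr: tuple[np.ndarray, np.ndarray]) -> np.ndarray:
    s, e = terr
    if len(s) == 0:
        return np.zeros(len(pos), dtype=bool)
    idx = np.searchsorted(s, pos, side="right") - 1
    return (idx >= 0) & (pos < e[np.clip(idx, 0, None)])


def _shared_domain_pool(scenario: SyntheticScenario, genome: GenomeTable) -> list[GenomicInterval]:
    rng = _rng(scenario, "shared_domains")
    lens = rng.gamma(4.0, scenario.migrating_domain_len / 4.0, size=scenario.migrating_n_domains)
    out = []
    for length in lens:
        ci = int(rng.integers(0, scenario.n_chroms))
        chrom = genome.names[ci]
        L = genome.length(chrom)
        mid = int(rng.integers(0, L))
        s = max(0, mid - int(length) // 2)
        e = min(L, s + max(1, int(length)))
        out.append(GenomicInterval(chrom, s, e))
    return out


def simulate_chip_reads(
    scenario: SyntheticScenario,
    mark: str,
    condition: str,
    catalog: AnnotationCatalog | None = None,
) -> tuple[ReadSet, GroundTruth]:
    """Fragments from a uniform background plus enriched domains.

    Control domains are short and strong and placed uniformly; migrating
    domains are long and weak, partly drawn from a pool shared between the
    three marks (raising inter-mark correlation) and otherwise biased
    towards repeats (H3K9me3/H4K20me1) or genes (H3K27me3) by rejection
    sampling. The input track is background only.
    """
    if mark not in MARKS + ("input",):
        raise ValueError(f"unknown mark {mark!r}")
    if condition not in CONDITIONS:
        raise ValueError(f"unknown condition {condition!r}")
    genome = scenario.genome()
    rng = _rng(scenario, "chip", (MARKS + ("input",)).index(mark), CONDITIONS.index(condition))
    label = f"{mark}_{condition}"

    if mark == "input":
        reads = _sample_fragments(rng, scenario, genome, domains=[], multiplier=1.0)
        reads.label = label
        return reads, GroundTruth(domains={(mark, condition): []})

    if catalog is None:
        catalog, _ = generate_annotation(scenario)

    if condition == "control":
        n, mean_len, mult = scenario.control_n_domains, scenario.control_domain_len, scenario.control_multiplier
        bias_terr = None
        shared: list[GenomicInterval] = []
    else:
        n, mean_len, mult = scenario.migrating_n_domains, scenario.migrating_domain_len, scenario.migrating_multiplier
        if mark in _REPEAT_SEEKING:
            bias_ivs = [
                GenomicInterval(c, int(s), int(e))
                for c, s, e in zip(catalog.repeats["chrom"], catalog.repeats["start"], catalog.repeats["end"])
            ]
        else:
            bias_ivs = [
                GenomicInterval(c, int(s), int(e))
                for c, s, e in zip(catalog.genes["chrom"], catalog.genes["start"], catalog.genes["end"])
            ]
        bias_terr = _territory(bias_ivs, genome)
        pool = _shared_domain_pool(scenario, genome)
        shared = pool[: int(round(scenario.shared_domain_fraction * n))]

    domains = list(shared)
    lens = rng.gamma(4.0, mean_len / 4.0, size=n - len(shared))
    for length in lens:
        ci = int(rng.integers(0, scenario.n_chroms))
        chrom = genome.names[ci]
        L = genome.length(chrom)
        for _ in range(1000):
            mid = int(rng.integers(0, L))
            if bias_terr is None or _in_territory(np.array([mid]), bias_terr[chrom])[0]:
                break
            if rng.random() < scenario.placement_escape_prob:
                break
        s = max(0, mid - int(length) // 2)
        e = min(L, s + max(1, int(length)))
        domains.append(GenomicInterval(chrom, s, e))

    if mark == "H3K27me3" and condition == "migrating" and scenario.buffered_promoter_gain:
        truth = gene_parameters(scenario)
        buffered_ids = set(truth.index[truth["class"] == "buffered"])
        g = catalog.genes[catalog.genes["gene_id"].isin(buffered_ids)]
        t = tss(g)
        for chrom, pos in zip(g["chrom"], t):
            L = genome.length(chrom)
            domains.append(GenomicInterval(chrom, max(0, int(pos) - 1000), min(L, int(pos) + 1000)))

    merged = merge_intervals(domains)
    reads = _sample_fragments(rng, scenario, genome, merged, mult)
    reads.label = label
    return reads, GroundTruth(domains={(mark, condition): merged})


def _sample_fragments(
    rng: np.random.Generator,
    scenario: SyntheticScenario,
    genome: GenomeTable,
    domains: list[GenomicInterval],
    multiplier: float,
) -> ReadSet:
    """Poisson fragment counts at background_rate outside domains and
    background_rate x multiplier inside; midpoints uniform within territory."""
    frag = scenario.fragment_size
    cidx_parts, start_parts, end_parts = [], [], []
    for ci, (chrom, L) in enumerate(genome):
        dom_s = np.array([d.start for d in domains if d.chrom == chrom], dtype=np.int64)
        dom_e = np.array([d.end for d in domains if d.chrom == chrom], dtype=np.int64)
        comp_s, comp_e = _complement(dom_s, dom_e, L)
        for (seg_s, seg_e), rate in (
            ((dom_s, dom_e), scenario.background_rate * multiplier),
            ((comp_s, comp_e), scenario.background_rate),
        ):
            bp = int((seg_e - seg_s).sum())
            if bp == 0:
                continue
            k = rng.poisson(rate * bp)
            mids = _uniform_in_segments(rng, seg_s, seg_e, k)
            s = np.clip(mids - frag // 2, 0, L)
            e = np.clip(s + frag, 0, L)
            s = np.maximum(e - frag, 0)
            cidx_parts.append(np.full(k, ci, dtype=np.int32))
            start_parts.append(s)
            end_parts.append(e)
    cidx = np.concatenate(cidx_parts) if cidx_parts else np.array([], dtype=np.int32)
    start = np.concatenate(start_parts) if start_parts else np.array([], dtype=np.int64)
    end = np.concatenate(end_parts) if end_parts else np.array([], dtype=np.int64)
    order = np.lexsort((start, cidx))
    return ReadSet("reads", genome, cidx[order], start[order], end[order], fragment_size=frag)


def _complement(s: np.ndarray, e: np.ndarray, L: int) -> tuple[np.ndarray, np.ndarray]:
    if len(s) == 0:
        return np.array([0], dtype=np.int64), np.array([L], dtype=np.int64)
    cs = np.concatenate(([0], e))
    ce = np.concatenate((s, [L]))
    keep = ce > cs
    return cs[keep], ce[keep]


def _uniform_in_segments(rng, seg_s: np.ndarray, seg_e: np.ndarray, k: int) -> np.ndarray:
    lens = (seg_e - seg_s).astype(np.float64)
    cum = np.concatenate(([0.0], np.cumsum(lens)))
    u = rng.uniform(0, cum[-1], size=k)
    idx = np.searchsorted(cum, u, side="right") - 1
    idx = np.clip(idx, 0, len(seg_s) - 1)
    return (seg_s[idx] + (u - cum[idx])).astype(np.int64)


def sample_table(scenario: SyntheticScenario) -> pd.DataFrame:
    """Sample sheet for the five-arm design with alternating batch labels."""
    groups = [
        ("control", "none"),
        ("migrating", "none"),
        ("migrating", "EZH2i"),
        ("control", "DRB"),
        ("migrating", "DRB"),
    ]
    rows = []
    for (cond, treat), r in zip(groups, scenario.replicates):
        for i in range(r):
            rows.append(
                {
                    "sample": f"{cond}_{treat}_r{i + 1}",
                    "condition": cond,
                    "treatment": treat,
                    "batch": "b1" if i % 2 == 0 else "b2",
                }
            )
    return pd.DataFrame(rows).set_index("sample")


def simulate_counts(scenario: SyntheticScenario) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Negative-binomial gene x sample counts with planted class structure.

    Returns (counts, sample sheet, truth). Dependent genes shift only in
    untreated migrating samples (the shift is erased by the EZH2 inhibitor);
    independent genes shift in both; buffered genes shift only under the
    inhibitor; stability classes shift only in the Pol-II-inhibited
    migrating arm. A per-gene batch offset is applied to batch-b2 samples.
    """
    params = gene_parameters(scenario)
    samples = sample_table(scenario)
    rng = _rng(scenario, "counts")
    n_genes, n_samples = len(params), len(samples)

    lib = scenario.lib_size * rng.uniform(
        1 - scenario.lib_size_spread, 1 + scenario.lib_size_spread, size=n_samples
    )
    batch_shift = rng.normal(0.0, scenario.batch_sd, size=n_genes)

    base = params["base_log2_cpm"].to_numpy()
    cls = params["class"].to_numpy()
    lfc_a = params["true_lfc_mig_vs_ctrl"].to_numpy()
    lfc_b = params["true_lfc_ezh2i_vs_ctrl"].to_numpy()
    lfc_c = params["true_lfc_drb"].to_numpy()

    log2cpm = np.tile(base[:, None], (1, n_samples))
    for j, (_, s) in enumerate(samples.iterrows()):
        cond, treat = s["condition"], s["treatment"]
        if cond == "migrating" and treat == "none":
            log2cpm[:, j] += lfc_a
        elif cond == "migrating" and treat == "EZH2i":
            log2cpm[:, j] += lfc_b
        elif cond == "migrating" and treat == "DRB":
            log2cpm[:, j] += lfc_c
        if s["batch"] == "b2":
            log2cpm[:, j] += batch_shift

    mu = (2.0 ** log2cpm) * (lib[None, :] / 1e6)
    alpha = params["dispersion"].to_numpy()[:, None]
    r = 1.0 / alpha
    p = r / (r + mu)
    counts = rng.negative_binomial(np.broadcast_to(r, mu.shape), p)
    counts = pd.DataFrame(counts, index=params.index, columns=samples.index)
    return counts, samples, GroundTruth(gene_classes=params)
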