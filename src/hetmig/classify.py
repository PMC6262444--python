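"""H3K27me-dependency and RNA-stability gene classification.

The headline set algebra: genes altered on induction of migration
(contrast A) whose alteration disappears when H3K27 methylation is
inhibited (absent from contrast B) are H3K27me-dependent; genes altered in
both contrasts are independent; genes altered only under the inhibitor are
buffered. Genes altered between the two RNA-Pol-II-inhibited arms
(contrast C) changed their RNA stability.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .annotation import tss
from .coverage import MetaProfile, meta_profile
from .diffexpr import DEResult
from .genome import GenomeTable, ReadSet

log = logging.getLogger("hetmig")

DEPENDENCY_CLASSES = ("dependent", "independent", "buffered", "unchanged")
STABILITY_CLASSES = ("stability_up", "stability_down", "unchanged")


def classify_dependency(deA: DEResult, deB: DEResult) -> pd.DataFrame:
    """Partition the gene universe by membership in the two called sets.

    dependent = A only; independent = A and B; buffered = B only;
    unchanged = neither. Directions from each contrast are retained, and
    direction discordance of independent genes is flagged rather than
    reclassified (class membership is purely set-based).
    """
    if not deA.table.index.equals(deB.table.index):
        raise ValueError("contrasts were called on different gene universes")
    in_a = deA.table["called"].to_numpy()
    in_b = deB.table["called"].to_numpy()
    cls = np.where(
        in_a & in_b, "independent", np.where(in_a, "dependent", np.where(in_b, "buffered", "unchanged"))
    )
    dir_a = np.where(in_a, np.where(deA.table["log2fc"] > 0, "up", "down"), "")
    dir_b = np.where(in_b, np.where(deB.table["log2fc"] > 0, "up", "down"), "")
    discordant = in_a & in_b & (dir_a != dir_b)
    return pd.DataFrame(
        {
            "class": cls,
            "in_mig_vs_ctrl": in_a,
            "dir_mig_vs_ctrl": dir_a,
            "in_ezh2i_vs_ctrl": in_b,
            "dir_ezh2i_vs_ctrl": dir_b,
            "direction_discordant": discordant,
        },
        index=deA.table.index,
    )


def classify_stability(deC: DEResult) -> pd.DataFrame:
    """Stability classes from the Pol-II-inhibited contrast: up-called ->
    stability_up, down-called -> stability_down, else unchanged."""
    called = deC.table["called"].to_numpy()
    up = deC.table["log2fc"].to_numpy() > 0
    cls = np.where(called & up, "stability_up", np.where(called, "stability_down", "unchanged"))
    return pd.DataFrame({"class": cls, "in_drb": called}, index=deC.table.index)


def cross_tabulate(dep: pd.DataFrame, stab: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """4x3 dependency x stability contingency table and per-class stability
    fractions ((stability_up + stability_down) / class size)."""
    if not dep.index.equals(stab.index):
        raise ValueError("dependency and stability tables cover different genes")
    table = pd.crosstab(dep["class"], stab["class"]).reindex(
        index=list(DEPENDENCY_CLASSES), columns=list(STABILITY_CLASSES), fill_value=0
    )
    frac = {}
    for cls in DEPENDENCY_CLASSES:
        n = int(table.loc[cls].sum())
        if n == 0:
            frac[cls] = np.nan
            log.warning("cross_tabulate: dependency class %r is empty", cls)
        else:
            frac[cls] = float(table.loc[cls, ["stability_up", "stability_down"]].sum()) / n
    return table, pd.Series(frac, name="stability_fraction")


def promoter_signal_by_class(
    dep: pd.DataFrame,
    tracks: dict[str, ReadSet],
    genes: pd.DataFrame,
    genome: GenomeTable,
    window: int = 2000,
    n_bins: int = 50,
) -> pd.DataFrame:
    """Mean H3K27me3 signal in TSS-centred windows per dependency class.

    ``tracks`` maps condition -> ReadSet. Returns one row per (class,
    condition) with the mean fragments-per-million window signal, plus the
    migrating-minus-control difference per class. Empty classes are skipped.
    """
    gi = genes.set_index("gene_id")
    rows = []
    profiles: dict[tuple[str, str], MetaProfile] = {}
    for cls in DEPENDENCY_CLASSES:
        ids = dep.index[dep["class"] == cls].intersection(gi.index)
        if len(ids) == 0:
            log.warning("promoter_signal_by_class: no profiled genes in class %r", cls)
            continue
        g = gi.loc[ids]
        t = tss(g)
        regions = pd.DataFrame(
            {
                "chrom": g["chrom"].to_numpy(),
                "start": np.maximum(0, t.to_numpy() - window),
                "end": [
                    min(genome.length(c), int(pos) + window)
                    for c, pos in zip(g["chrom"], t)
                ],
                "strand": g["strand"].to_numpy(),
            }
        )
        means = {}
        for cond, track in tracks.items():
            prof = meta_profile(track, regions, flank_bp=0, n_body_bins=n_bins, n_flank_bins=0)
            profiles[(cls, cond)] = prof
            means[cond] = prof.body_mean
        rows.append(
            {
                "class": cls,
                "n_genes": len(ids),
                **{f"mean_{c}": v for c, v in means.items()},
                "difference": means.get("migrating", np.nan) - means.get("control", np.nan),
            }
        )
    return pd.DataFrame(rows)
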