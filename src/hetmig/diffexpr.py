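"""Count filtering, TMM normalisation, precision-weighted linear models.

The modelling chain is the standard bulk RNA-seq one for this design:
genes below 1 cpm in fewer than 3 samples are dropped; library sizes are
rescaled by trimmed-mean-of-M-values factors; counts are transformed to
log2-cpm with observation-level precision weights from the fitted
mean-variance trend; per-gene weighted least squares with a batch term and
empirical-Bayes variance moderation yield moderated t statistics, BH
q-values, and calls at FDR < 0.05 with linear fold change >= 1.3.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.nonparametric.smoothers_lowess import lowess

from .stats_util import bh_adjust

log = logging.getLogger("hetmig")


def cpm(counts: pd.DataFrame, lib: pd.Series | None = None) -> pd.DataFrame:
    if lib is None:
        lib = counts.sum(axis=0)
    return counts / lib * 1e6


def filter_low_counts(counts: pd.DataFrame, cpm_min: float = 1.0, min_samples: int = 3) -> pd.DataFrame:
    """Keep genes reaching ``cpm_min`` cpm in at least ``min_samples`` samples."""
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("non-positive library size")
    keep = (cpm(counts, lib) >= cpm_min).sum(axis=1) >= min_samples
    if not keep.any():
        raise ValueError("no gene passes the low-count filter")
    return counts.loc[keep]


def tmm_factors(
    counts: pd.DataFrame,
    logratio_trim: float = 0.3,
    sum_trim: float = 0.05,
) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, geometric mean 1.

    The reference sample is the one whose upper-quartile cpm is closest to
    the mean upper quartile. Per sample, M (log ratio) and A (average log
    abundance) are computed against the reference over genes expressed in
    both; the upper/lower ``logratio_trim`` of M and ``sum_trim`` of A are
    discarded and the remaining M are averaged with inverse asymptotic
    variance weights.
    """
    X = counts.to_numpy(dtype=float)
    N = X.sum(axis=0)
    n_samples = X.shape[1]
    if n_samples < 2:
        log.warning("tmm_factors: single sample, factors set to 1")
        return pd.Series(np.ones(n_samples), index=counts.columns)
    uq = np.array([np.quantile(X[:, j] / N[j], 0.75) for j in range(n_samples)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    yr, Nr = X[:, ref], N[ref]

    factors = np.ones(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        yj, Nj = X[:, j], N[j]
        ok = (yj > 0) & (yr > 0)
        pj, pr = yj[ok] / Nj, yr[ok] / Nr
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        w = (Nj - yj[ok]) / (Nj * yj[ok]) + (Nr - yr[ok]) / (Nr * yr[ok])
        n = len(M)
        if n == 0:
            continue
        loM = np.floor(n * logratio_trim) + 1
        hiM = n + 1 - loM
        loA = np.floor(n * sum_trim) + 1
        hiA = n + 1 - loA
        rM = stats.rankdata(M)
        rA = stats.rankdata(A)
        keep = (rM >= loM) & (rM <= hiM) & (rA >= loA) & (rA <= hiA)
        if keep.sum() == 0 or np.allclose(M, 0):
            f = 0.0
        else:
            f = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
        factors[j] = 2.0 ** f
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.columns)


@dataclass
class WeightedValues:
    """log2-cpm values with observation-level precision weights."""

    values: pd.DataFrame
    weights: pd.DataFrame


def precision_weighted_transform(
    counts: pd.DataFrame,
    factors: pd.Series,
    design: np.ndarray | None = None,
    lowess_frac: float = 0.5,
) -> WeightedValues:
    """Mean-variance-trend precision weights for log2-cpm values.

    value = log2((count + 0.5) / (effective libsize + 1) * 1e6) with
    effective libsize = libsize x factor. The sqrt-standard-deviation of
    each gene's residuals (under ``design``; intercept-only if omitted) is
    regressed on mean log-count by lowess, and each observation's weight is
    the inverse fourth power of the trend value at its fitted log-count.
    """
    if len(counts) < 10:
        raise ValueError("too few genes to fit a mean-variance trend")
    y_counts = counts.to_numpy(dtype=float)
    lib = y_counts.sum(axis=0) * factors.to_numpy()
    y = np.log2((y_counts + 0.5) / (lib + 1) * 1e6)
    n_genes, n_samples = y.shape
    X = design if design is not None else np.ones((n_samples, 1))
    p = X.shape[1]

    beta, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    fitted = (X @ beta).T
    resid = y - fitted
    df_resid = n_samples - p
    sd = np.sqrt(np.sum(resid**2, axis=1) / df_resid)

    sx = y.mean(axis=1) + np.mean(np.log2(lib + 1)) - np.log2(1e6)
    sy = np.sqrt(sd)
    trend = lowess(sy, sx, frac=lowess_frac, return_sorted=True)
    tx, ty = trend[:, 0], np.maximum(trend[:, 1], 1e-6)

    fitted_cpm = 2.0 ** fitted
    fitted_count = fitted_cpm * (lib + 1)[None, :] / 1e6
    fitted_logcount = np.log2(np.maximum(fitted_count, 1e-12))
    pred = np.interp(fitted_logcount, tx, ty)
    w = 1.0 / pred**4
    return WeightedValues(
        pd.DataFrame(y, index=counts.index, columns=counts.columns),
        pd.DataFrame(w, index=counts.index, columns=counts.columns),
    )


def build_design(samples: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
    """Cell-means design: one column per condition_treatment group plus
    dummy columns for batches beyond the first."""
    group = samples["condition"].astype(str) + "_" + samples["treatment"].astype(str)
    groups = sorted(group.unique())
    batches = sorted(samples["batch"].astype(str).unique())
    cols = []
    names = []
    for g in groups:
        cols.append((group == g).to_numpy(dtype=float))
        names.append(g)
    for b in batches[1:]:
        cols.append((samples["batch"].astype(str) == b).to_numpy(dtype=float))
        names.append(f"batch_{b}")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"rank-deficient design; check confounding among columns {names}")
    return X, names


def contrast_vector(names: list[str], plus: str, minus: str) -> np.ndarray:
    c = np.zeros(len(names))
    c[names.index(plus)] = 1.0
    c[names.index(minus)] = -1.0
    return c


def _trigamma_inverse(y: float) -> float:
    if y <= 0:
        return np.inf
    x = 0.5 + 1.0 / y
    for _ in range(75):
        tri = special.polygamma(1, x)
        dif = tri * (1.0 - tri / y) / special.polygamma(2, x)
        x += dif
        if abs(dif) < 1e-10 * x:
            break
    return float(x)


def squeeze_var(s2: np.ndarray, df: float, fallback_df0: float = 4.0) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of gene variances toward a common prior.

    Prior df and variance are estimated by moment matching on log s^2 (the
    scaled-F model); falls back to prior df 4 when the moment estimate is
    non-positive. Returns (posterior variances, prior df, prior variance).
    """
    ok = s2 > 0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + np.log(df / 2)
    emean = e.mean()
    n = len(e)
    evar = np.sum((e - emean) ** 2) / (n - 1) - special.polygamma(1, df / 2)
    if evar > 0:
        df0 = 2 * _trigamma_inverse(evar)
    else:
        df0 = np.inf
    if not np.isfinite(df0) or df0 <= 0:
        df0 = np.inf if evar <= 0 else fallback_df0
    if np.isfinite(df0):
        s02 = np.exp(emean + special.digamma(df0 / 2) - np.log(df0 / 2))
        post = (df0 * s02 + df * s2) / (df0 + df)
    else:
        s02 = np.exp(emean)
        post = np.full_like(s2, s02)
    return post, float(df0), float(s02)


@dataclass
class DEResult:
    """Per-gene moderated-test outcomes for one contrast."""

    table: pd.DataFrame  # log2fc, t, p_value, q_value, called
    contrast: str
    df_prior: float
    df_residual: float

    @property
    def called(self) -> pd.Index:
        return self.table.index[self.table["called"]]

    def called_with_direction(self) -> pd.Series:
        t = self.table[self.table["called"]]
        return pd.Series(np.where(t["log2fc"] > 0, "up", "down"), index=t.index)


def fit_and_call(
    wv: WeightedValues,
    design: np.ndarray,
    contrast: np.ndarray,
    contrast_name: str = "contrast",
    fdr: float = 0.05,
    fc_min: float = 1.3,
) -> DEResult:
    """Weighted least squares per gene, moderated t, BH, and FC+FDR calls.

    ``fc_min`` applies to the linear fold change: a gene is called iff
    q < ``fdr`` and the absolute log2 fold change is >= log2(fc_min).
    """
    y = wv.values.to_numpy()
    w = wv.weights.to_numpy()
    X = design
    n_genes, n_samples = y.shape
    p = X.shape[1]
    if np.linalg.matrix_rank(X) < p:
        raise ValueError("rank-deficient design matrix")
    df_resid = n_samples - p

    # batched WLS: A_g = X' W_g X, b_g = X' W_g y_g
    A = np.einsum("np,gn,nq->gpq", X, w, X)
    rhs = np.einsum("np,gn->gp", X, w * y)
    beta = np.linalg.solve(A, rhs[..., None])[..., 0]
    resid = y - beta @ X.T
    s2 = np.einsum("gn,gn->g", w, resid**2) / df_resid

    cvec = np.asarray(contrast, dtype=float)
    Ainv_c = np.linalg.solve(A, np.broadcast_to(cvec, (n_genes, p))[..., None])[..., 0]
    var_unscaled = Ainv_c @ cvec
    lfc = beta @ cvec

    s2_post, df0, _ = squeeze_var(s2, df_resid)
    t = lfc / np.sqrt(s2_post * var_unscaled)
    df_total = df_resid + (df0 if np.isfinite(df0) else 1e6)
    pvals = 2 * stats.t.sf(np.abs(t), df_total)
    q = bh_adjust(pvals)
    called = (q < fdr) & (np.abs(lfc) >= np.log2(fc_min))
    table = pd.DataFrame(
        {"log2fc": lfc, "t": t, "p_value": pvals, "q_value": q, "called": called},
        index=wv.values.index,
    )
    return DEResult(table, contrast_name, float(df0), float(df_resid))


STANDARD_CONTRASTS = {
    "mig_vs_ctrl": ("migrating_none", "control_none"),
    "ezh2i_vs_ctrl": ("migrating_EZH2i", "control_none"),
    "drb_mig_vs_drb_ctrl": ("migrating_DRB", "control_DRB"),
}


def run_de(
    counts: pd.DataFrame,
    samples: pd.DataFrame,
    fdr: float = 0.05,
    fc_min: float = 1.3,
    cpm_min: float = 1.0,
    min_samples: int = 3,
) -> dict[str, DEResult]:
    """Filter, normalise, transform and test the three standard contrasts.

    Contrast A: untreated migrating vs control; contrast B: EZH2-inhibited
    migrating vs untreated control; contrast C: Pol-II-inhibited migrating
    vs Pol-II-inhibited control.
    """
    filt = filter_low_counts(counts, cpm_min, min_samples)
    factors = tmm_factors(filt)
    X, names = build_design(samples)
    wv = precision_weighted_transform(filt, factors, design=X)
    out = {}
    for cname, (plus, minus) in STANDARD_CONTRASTS.items():
        c = contrast_vector(names, plus, minus)
        out[cname] = fit_and_call(wv, X, c, cname, fdr=fdr, fc_min=fc_min)
    return out
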