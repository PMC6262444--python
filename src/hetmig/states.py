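"""Combinatorial chromatin-state segmentation of binarised mark tracks.

A K-state hidden Markov model with independent Bernoulli emissions per mark
(the ChromHMM model family) is fit by Baum-Welch EM with scaled
forward-backward recursions. Tracks are first binarised per 200 bp bin with
a Poisson test against an input-scaled local expectation. Five states is
the default segmentation granularity.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import ExclusivePartition
from .genome import GenomeTable, ReadSet

log = logging.getLogger("hetmig")

_EPS = 1e-10


@dataclass
class BinarizedTracks:
    """Per-bin binary presence call per mark on a shared bin grid."""

    bins: pd.DataFrame          # chrom, start, end
    X: np.ndarray               # (n_bins, n_marks) uint8
    marks: list[str]
    bin_bp: int
    seq_slices: list[slice]     # one contiguous slice per chromosome

    def __len__(self) -> int:
        return len(self.X)


def binarize(
    tracks: list[ReadSet],
    input_track: ReadSet,
    genome: GenomeTable,
    bin_bp: int = 200,
    p_threshold: float = 1e-4,
) -> BinarizedTracks:
    """Poisson presence call per bin against an input-scaled expectation.

    Bin expectation = global mark rate x (input bin count / mean input bin
    count); bins where the input count is zero fall back to the global
    rate. A call is 1 iff the Poisson upper tail of the mark count is below
    ``p_threshold``.
    """
    rows, slices = [], []
    offset = 0
    for chrom, L in genome:
        n_bins = -(-L // bin_bp)
        for i in range(n_bins):
            rows.append((chrom, i * bin_bp, min((i + 1) * bin_bp, L)))
        slices.append(slice(offset, offset + n_bins))
        offset += n_bins
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])

    def bin_counts(t: ReadSet) -> np.ndarray:
        mids = t.midpoints
        parts = []
        for ci, (chrom, L) in enumerate(genome):
            n_bins = -(-L // bin_bp)
            m = t.chrom_idx == ci
            parts.append(np.bincount((mids[m] // bin_bp).astype(np.int64), minlength=n_bins))
        return np.concatenate(parts)

    inp = bin_counts(input_track).astype(float)
    inp_scale = inp / max(inp.mean(), _EPS)
    X = np.zeros((len(bins), len(tracks)), dtype=np.uint8)
    for j, t in enumerate(tracks):
        c = bin_counts(t)
        global_rate = t.total_count / len(bins)
        mu = np.where(inp > 0, global_rate * inp_scale, global_rate)
        X[:, j] = (stats.poisson.sf(c - 1, mu) < p_threshold).astype(np.uint8)
    return BinarizedTracks(bins, X, [t.label for t in tracks], bin_bp, slices)


@dataclass
class StateModel:
    """HMM parameters: initial pi, transitions A, Bernoulli emissions E."""

    pi: np.ndarray              # (K,)
    A: np.ndarray               # (K, K)
    E: np.ndarray               # (K, M)
    loglik_trace: list[float] = field(default_factory=list)

    @property
    def K(self) -> int:
        return len(self.pi)

    def validate(self, tol: float = 1e-8) -> None:
        assert abs(self.pi.sum() - 1) < tol
        assert np.allclose(self.A.sum(axis=1), 1, atol=tol)
        assert ((self.E >= 0) & (self.E <= 1)).all()

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("# pi\n" + "\t".join(f"{v:.10g}" for v in self.pi) + "\n# A\n")
            for row in self.A:
                fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")
            fh.write("# E\n")
            for row in self.E:
                fh.write("\t".join(f"{v:.10g}" for v in row) + "\n")


def _emission_probs(E: np.ndarray, X: np.ndarray) -> np.ndarray:
    """(n_obs, K) likelihood of each observation under each state."""
    Ec = np.clip(E, _EPS, 1 - _EPS)
    logB = X @ np.log(Ec).T + (1 - X) @ np.log(1 - Ec).T
    return np.exp(logB)


def _forward_backward(pi, A, B):
    """Scaled forward-backward; returns gamma, xi_sum, loglik."""
    T, K = B.shape
    alpha = np.zeros((T, K))
    c = np.zeros(T)
    alpha[0] = pi * B[0]
    c[0] = alpha[0].sum() + _EPS
    alpha[0] /= c[0]
    for t in range(1, T):
        alpha[t] = (alpha[t - 1] @ A) * B[t]
        c[t] = alpha[t].sum() + _EPS
        alpha[t] /= c[t]
    beta = np.zeros((T, K))
    beta[-1] = 1.0
    for t in range(T - 2, -1, -1):
        beta[t] = (A @ (B[t + 1] * beta[t + 1])) / c[t + 1]
    gamma = alpha * beta
    gamma /= np.maximum(gamma.sum(axis=1, keepdims=True), _EPS)
    # xi_t(i,j) = alpha_t(i) A(i,j) B_{t+1}(j) beta_{t+1}(j) / c_{t+1}, summed over t
    Y = B[1:] * beta[1:] / c[1:, None]
    xi_sum = (alpha[:-1].T @ Y) * A
    return gamma, xi_sum, float(np.log(c).sum())


def sequence_loglik(model: StateModel, X: np.ndarray) -> float:
    """Forward-algorithm log-likelihood of one observation sequence."""
    B = _emission_probs(model.E, np.asarray(X))
    T, K = B.shape
    alpha = model.pi * B[0]
    ll = 0.0
    c = alpha.sum()
    ll += np.log(c)
    alpha /= c
    for t in range(1, T):
        alpha = (alpha @ model.A) * B[t]
        c = alpha.sum()
        ll += np.log(c)
        alpha /= c
    return float(ll)


def fit_state_model(
    b: BinarizedTracks,
    K: int = 5,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-4,
) -> StateModel:
    """Baum-Welch EM over the per-chromosome sequences.

    The log-likelihood is asserted non-decreasing at every iteration;
    convergence is relative change below ``tol``. States are reported in a
    canonical order (total emission probability, descending) so fits are
    comparable across seeds up to the usual label permutation.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    M = b.X.shape[1]
    pi = rng.dirichlet(np.ones(K))
    A = rng.dirichlet(np.ones(K) * 5, size=K)
    E = rng.uniform(0.2, 0.8, size=(K, M))
    trace: list[float] = []
    X = b.X.astype(np.float64)
    seqs = [sl for sl in b.seq_slices if sl.stop > sl.start]
    for it in range(max_iter):
        B = _emission_probs(E, X)
        pi_new = np.zeros(K)
        xi_tot = np.zeros((K, K))
        gamma_tot = np.zeros(K)
        gamma_x = np.zeros((K, M))
        ll = 0.0
        for sl in seqs:
            gamma, xi, l = _forward_backward(pi, A, B[sl])
            ll += l
            pi_new += gamma[0]
            xi_tot += xi
            gamma_tot += gamma.sum(axis=0)
            gamma_x += gamma.T @ X[sl]
        if trace:
            assert ll >= trace[-1] - 1e-6 * abs(trace[-1]) - 1e-8, (
                f"EM log-likelihood decreased at iteration {it}: {trace[-1]} -> {ll}"
            )
        converged = bool(trace) and abs(ll - trace[-1]) <= tol * abs(trace[-1])
        trace.append(ll)
        if converged:
            break
        pi = pi_new / pi_new.sum()
        if K == 1:
            A = np.ones((1, 1))
        else:
            A = xi_tot / np.maximum(xi_tot.sum(axis=1, keepdims=True), _EPS)
        E = gamma_x / np.maximum(gamma_tot[:, None], _EPS)
    order = np.argsort(-E.sum(axis=1), kind="stable")
    model = StateModel(pi[order], A[np.ix_(order, order)], np.clip(E[order], 0, 1), trace)
    model.validate()
    return model


def posterior_states(model: StateModel, b: BinarizedTracks) -> tuple[np.ndarray, np.ndarray]:
    """Posterior marginals and per-bin most-probable state."""
    B = _emission_probs(model.E, b.X.astype(np.float64))
    post = np.zeros((len(b), model.K))
    for sl in b.seq_slices:
        if sl.stop > sl.start:
            gamma, _, _ = _forward_backward(model.pi, model.A, B[sl])
            post[sl] = gamma
    return post, post.argmax(axis=1)


def viterbi_states(model: StateModel, b: BinarizedTracks) -> np.ndarray:
    """Most-probable state path (log-space Viterbi), per chromosome."""
    logA = np.log(np.clip(model.A, _EPS, None))
    logpi = np.log(np.clip(model.pi, _EPS, None))
    Ec = np.clip(model.E, _EPS, 1 - _EPS)
    X = b.X.astype(np.float64)
    logB = X @ np.log(Ec).T + (1 - X) @ np.log(1 - Ec).T
    path = np.zeros(len(b), dtype=np.int64)
    for sl in b.seq_slices:
        lb = logB[sl]
        T = len(lb)
        if T == 0:
            continue
        delta = logpi + lb[0]
        back = np.zeros((T, model.K), dtype=np.int64)
        for t in range(1, T):
            cand = delta[:, None] + logA
            back[t] = cand.argmax(axis=0)
            delta = cand.max(axis=0) + lb[t]
        p = np.zeros(T, dtype=np.int64)
        p[-1] = delta.argmax()
        for t in range(T - 2, -1, -1):
            p[t] = back[t + 1, p[t + 1]]
        path[sl] = p
    return path


@dataclass
class StateSegmentation:
    """Per-bin state map plus per-class fold enrichments."""

    bins: pd.DataFrame
    states: np.ndarray
    posterior: np.ndarray
    state_shares: np.ndarray            # genome bp share per state
    enrichment: pd.DataFrame            # classes x states fold enrichment
    model: StateModel


def segment_and_enrich(
    model: StateModel,
    b: BinarizedTracks,
    partition: ExclusivePartition,
    decode: str = "posterior",
) -> StateSegmentation:
    """Decode states and compute per-(class, state) fold enrichment.

    Enrichment = (class bp in state / class bp) / (genome bp in state /
    genome bp); classes with zero bp report NaN.
    """
    post, states = posterior_states(model, b)
    if decode == "viterbi":
        states = viterbi_states(model, b)
    elif decode != "posterior":
        raise ValueError("decode must be 'posterior' or 'viterbi'")
    bp = (b.bins["end"] - b.bins["start"]).to_numpy()
    total_bp = bp.sum()
    state_bp = np.array([bp[states == k].sum() for k in range(model.K)], dtype=float)
    shares = state_bp / total_bp

    mid = ((b.bins["start"] + b.bins["end"]) // 2).to_numpy()
    cls_codes = np.zeros(len(b), dtype=np.int64)
    for chrom in partition.genome.names:
        m = (b.bins["chrom"] == chrom).to_numpy()
        cls_codes[m] = partition.class_of_positions(chrom, mid[m])
    rows = {}
    for ci, cls in enumerate(partition.classes):
        in_cls = cls_codes == ci
        cls_bp = bp[in_cls].sum()
        if cls_bp == 0:
            rows[cls] = [np.nan] * model.K
            continue
        vals = []
        for k in range(model.K):
            num = bp[in_cls & (states == k)].sum() / cls_bp
            den = shares[k]
            vals.append(num / den if den > 0 else np.nan)
        rows[cls] = vals
    enrich = pd.DataFrame.from_dict(
        rows, orient="index", columns=[f"state{k + 1}" for k in range(model.K)]
    )
    return StateSegmentation(b.bins, states, post, shares, enrich, model)


def match_states(E1: np.ndarray, E2: np.ndarray) -> tuple[np.ndarray, float]:
    """Optimal state matching between two emission matrices.

    Returns the permutation of model-2 states best matching model 1 and the
    mean absolute emission disagreement under it (Hungarian assignment).
    """
    from scipy.optimize import linear_sum_assignment

    cost = np.abs(E1[:, None, :] - E2[None, :, :]).mean(axis=2)
    ri, ci = linear_sum_assignment(cost)
    return ci, float(cost[ri, ci].mean())
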