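"""Multiple-class homozygosity-by-descent (HBD) hidden Markov model.

The genome of an inbred individual is a mosaic of HBD segments (both
chromosome copies inherited from one ancestral copy) and non-HBD segments.
The model has K HBD classes plus one non-HBD class; class k has a rate
``R_k`` per Morgan, so its segment lengths are exponential with mean
``1/R_k`` — small rates correspond to long segments from recent ancestors,
large rates to short, ancient ones.  The non-HBD class shares the largest
rate.  Between two markers separated by ``d`` Morgans the chain stays in
its class with probability ``exp(-R_k d)``; on leaving, it re-enters class
k' with the individual's mixing weight ``pi_k'`` (possibly returning to the
same class).

Emissions: the non-HBD class emits Hardy-Weinberg genotype probabilities
given the reference allele frequency p; an HBD class emits homozygotes with
probabilities (1-p, 0, p) for second-allele counts (0, 1, 2), contaminated
by a genotyping-error rate ``eps`` toward Hardy-Weinberg; missing genotypes
are uninformative.

The per-individual mixing weights are estimated by expectation-maximisation
with the rates held fixed; F_HBD is the genome-length-weighted mean
posterior probability of being in any HBD class.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_core import MISSING, GenotypeMatrix
from .marker_estimators import AlleleFrequencies

MORGAN_PER_BP = 1e-8   # 1 Mb = 1 cM, the standard cattle-scale approximation


@dataclass
class HBDModel:
    """K HBD classes + 1 non-HBD class (last index).

    ``rates``: per-class rates per Morgan, strictly increasing over HBD
    classes, non-HBD sharing the largest; ``pi``: mixing weights over all
    K+1 classes; ``eps``: genotyping-error rate.
    """

    rates: np.ndarray
    pi: np.ndarray
    eps: float = 0.001

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.pi = np.asarray(self.pi, dtype=float)
        k = self.n_hbd_classes
        if k < 1:
            raise ValueError("need at least one HBD class")
        if np.any(np.diff(self.rates[:k]) <= 0):
            raise ValueError("HBD class rates must be strictly increasing")
        if self.rates[-1] != self.rates[k - 1]:
            raise ValueError("non-HBD class must share the largest HBD rate")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("mixing weights must be non-negative and sum to 1")
        if not 0 <= self.eps <= 0.1:
            raise ValueError("eps must be in [0, 0.1]")

    @property
    def n_states(self) -> int:
        return len(self.rates)

    @property
    def n_hbd_classes(self) -> int:
        return len(self.rates) - 1


def default_model(K: int = 10, eps: float = 0.001) -> HBDModel:
    """Doubling-rate layout: R_k = 2^k for k = 1..K, non-HBD tied to 2^K,
    uniform initial mixing weights."""
    if K < 1:
        raise ValueError("K must be >= 1")
    rates = np.concatenate([2.0 ** np.arange(1, K + 1), [2.0 ** K]])
    pi = np.full(K + 1, 1.0 / (K + 1))
    return HBDModel(rates=rates, pi=pi, eps=eps)


def _emissions(x: np.ndarray, p: np.ndarray, model: HBDModel) -> np.ndarray:
    """(T x S) emission probabilities; missing genotypes emit 1 everywhere."""
    T = x.size
    S = model.n_states
    hw = np.empty((T, 3))
    hw[:, 0] = (1 - p) ** 2
    hw[:, 1] = 2 * p * (1 - p)
    hw[:, 2] = p ** 2
    ibd = np.empty((T, 3))
    ibd[:, 0] = 1 - p
    ibd[:, 1] = 0.0
    ibd[:, 2] = p
    out = np.ones((T, S))
    obs = x != MISSING
    xi = x[obs].astype(int)
    rows = np.nonzero(obs)[0]
    hbd_em = (1 - model.eps) * ibd[rows, xi] + model.eps * hw[rows, xi]
    out[rows, : S - 1] = hbd_em[:, None]
    out[rows, S - 1] = hw[rows, xi]
    return out


try:
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*a, **k):
        def wrap(f):
            return f
        return wrap if not (len(a) == 1 and callable(a[0])) else a[0]


@njit(cache=True)
def _fb_inplace(emis, stay, pi, alpha, c, gamma, jumps, beta_next, beta_cur, eb):
    """Scaled forward-backward into caller-provided buffers.

    ``stay``: (T-1 x S) stay probabilities exp(-r_s * d_t).  Fills
    per-marker posteriors ``gamma`` and expected EM jump-entry counts
    ``jumps`` (not including the first-marker draw, available as
    ``gamma[0]``); returns the log-likelihood.
    """
    T, S = emis.shape
    ct = 0.0
    for s in range(S):
        v = pi[s] * emis[0, s]
        alpha[0, s] = v
        ct += v
    c[0] = ct
    for s in range(S):
        alpha[0, s] /= ct
    for t in range(1, T):
        jump_mass = 0.0
        for s in range(S):
            jump_mass += alpha[t - 1, s] * (1.0 - stay[t - 1, s])
        ct = 0.0
        for s in range(S):
            v = (alpha[t - 1, s] * stay[t - 1, s] + jump_mass * pi[s]) * emis[t, s]
            alpha[t, s] = v
            ct += v
        c[t] = ct
        for s in range(S):
            alpha[t, s] /= ct
    for s in range(S):
        beta_next[s] = 1.0
        gamma[T - 1, s] = alpha[T - 1, s]
        jumps[s] = 0.0
    for t in range(T - 2, -1, -1):
        pi_eb = 0.0
        for s in range(S):
            eb[s] = emis[t + 1, s] * beta_next[s] / c[t + 1]
            pi_eb += pi[s] * eb[s]
        leave = 0.0
        for s in range(S):
            beta_cur[s] = stay[t, s] * eb[s] + (1.0 - stay[t, s]) * pi_eb
            leave += alpha[t, s] * (1.0 - stay[t, s])
        for s in range(S):
            jumps[s] += leave * pi[s] * eb[s]
            gamma[t, s] = alpha[t, s] * beta_cur[s]
            beta_next[s] = beta_cur[s]
    loglik = 0.0
    for t in range(T):
        loglik += np.log(c[t])
    return loglik


@njit(cache=True)
def _fb_core(emis, stay, pi):
    """Scaled forward-backward; returns (gamma, loglik, jumps, gamma[0])."""
    T, S = emis.shape
    alpha = np.empty((T, S))
    c = np.empty(T)
    gamma = np.empty((T, S))
    jumps = np.zeros(S)
    beta_next = np.empty(S)
    beta_cur = np.empty(S)
    eb = np.empty(S)
    ll = _fb_inplace(emis, stay, pi, alpha, c, gamma, jumps, beta_next, beta_cur, eb)
    return gamma, ll, jumps, gamma[0].copy()


def forward_backward(
    x: np.ndarray,
    p: np.ndarray,
    positions_morgans: np.ndarray,
    model: HBDModel,
) -> tuple[np.ndarray, float]:
    """Posterior class probabilities and log-likelihood for one animal on
    one chromosome.

    ``x``: genotype codes (0/1/2/-1); ``p``: second-allele frequencies;
    ``positions_morgans``: strictly increasing marker positions.
    """
    x = np.asarray(x)
    p = np.asarray(p, dtype=float)
    pos = np.asarray(positions_morgans, dtype=float)
    if np.any(np.diff(pos) <= 0):
        raise ValueError("marker positions must be strictly increasing")
    emis = _emissions(x, p, model)
    d = np.diff(pos)
    stay = np.exp(-np.outer(d, model.rates))
    gamma, loglik, _, _ = _fb_core(emis, stay, model.pi)
    return gamma, float(loglik)


@njit(cache=True)
def _em_core(emis, stay, pi0, tol, max_iter):
    """Full EM on the mixing weights for one animal's concatenated chain.

    Chromosome boundaries are rows of ``stay`` equal to 0, which make the
    chain re-enter from the mixing weights — exactly a fresh start.
    Returns (pi, loglik trace, number of iterations).
    """
    T, S = emis.shape
    pi = pi0.copy()
    trace = np.empty(max_iter)
    alpha = np.empty((T, S))
    c = np.empty(T)
    gamma = np.empty((T, S))
    jumps = np.zeros(S)
    beta_next = np.empty(S)
    beta_cur = np.empty(S)
    eb = np.empty(S)
    n_it = 0
    for it in range(max_iter):
        ll = _fb_inplace(emis, stay, pi, alpha, c, gamma, jumps,
                         beta_next, beta_cur, eb)
        trace[it] = ll
        n_it = it + 1
        if it > 0 and ll - trace[it - 1] < tol:
            break
        tot = 0.0
        for s in range(S):
            pi[s] = jumps[s] + gamma[0, s]
            tot += pi[s]
        for s in range(S):
            pi[s] /= tot
    return pi, trace[:n_it], n_it


def _chromosome_arrays(
    g: GenotypeMatrix, freqs: AlleleFrequencies
) -> list[tuple[int, np.ndarray, np.ndarray, np.ndarray]]:
    """Per-chromosome (chrom, marker-index, p, positions-in-Morgans) using
    only markers usable in the reference."""
    out = []
    chroms = g.markers["chrom"].to_numpy()
    pos = g.markers["pos"].to_numpy()
    for chrom in g.chromosomes():
        sl = g.chrom_slice(int(chrom))
        idx = np.arange(sl.start, sl.stop)[freqs.usable[sl]]
        if idx.size < 2:
            continue
        out.append(
            (int(chrom), idx, freqs.p[idx], pos[idx] * MORGAN_PER_BP)
        )
    return out


def _concatenated_chain(
    g: GenotypeMatrix,
    freqs: AlleleFrequencies,
    sample_index: int,
    model: HBDModel,
    chrom_data,
) -> tuple[np.ndarray, np.ndarray, list[tuple[int, int, int]]]:
    """Stack per-chromosome emissions into one chain.

    Chromosome boundaries get stay probability 0 (re-entry from the mixing
    weights — equivalent to starting a fresh chain).  Returns (emissions,
    stay, spans) with spans = (chrom, row offset, length).
    """
    emis_l, stay_l, spans = [], [], []
    off = 0
    for chrom, idx, p, pos_m in chrom_data:
        x = g.codes[sample_index, idx]
        emis_l.append(_emissions(x, p, model))
        if off > 0:
            stay_l.append(np.zeros((1, model.n_states)))
        stay_l.append(np.exp(-np.outer(np.diff(pos_m), model.rates)))
        spans.append((chrom, off, pos_m.size))
        off += pos_m.size
    emis = np.vstack(emis_l)
    stay = np.vstack(stay_l) if stay_l else np.zeros((0, model.n_states))
    return emis, stay, spans


def fit_mixing(
    g: GenotypeMatrix,
    freqs: AlleleFrequencies,
    animal: str,
    model: HBDModel | None = None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> tuple[HBDModel, float, list[float]]:
    """EM estimate of one animal's mixing weights (rates held fixed).

    Returns the fitted model, the converged log-likelihood, and the full
    log-likelihood trace (non-decreasing by the EM property).
    """
    model = model or default_model()
    i = g.sample_ids.index(animal)
    chrom_data = _chromosome_arrays(g, freqs)
    if not chrom_data:
        raise ValueError("no polymorphic markers available")
    emis, stay, _ = _concatenated_chain(g, freqs, i, model, chrom_data)
    pi, trace, _ = _em_core(emis, stay, model.pi, tol, max_iter)
    fitted = replace(model, pi=pi)
    return fitted, float(trace[-1]), [float(v) for v in trace]


@dataclass
class HBDPosteriors:
    """Per-animal HBD summaries.

    ``total_hbd``: dict animal -> dict chrom -> per-marker total-HBD
    posterior; ``weights``: dict chrom -> per-marker genome-length weights
    (midpoint rule, Morgans).
    """

    total_hbd: dict
    weights: dict
    sample_ids: list[str]


def _interval_weights(pos_m: np.ndarray) -> np.ndarray:
    """Midpoint-rule marker weights: each marker represents half the
    distance to each neighbour; chromosome-end markers get half the single
    flanking interval."""
    w = np.zeros(pos_m.size)
    d = np.diff(pos_m)
    w[:-1] += d / 2
    w[1:] += d / 2
    return w


def compute_posteriors(
    g: GenotypeMatrix,
    freqs: AlleleFrequencies,
    model: HBDModel | None = None,
    fit: bool = True,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> HBDPosteriors:
    """Total-HBD posteriors for every animal (optionally EM-fitting the
    mixing weights per animal first)."""
    model = model or default_model()
    chrom_data = _chromosome_arrays(g, freqs)
    if not chrom_data:
        raise ValueError("no polymorphic markers available")
    weights = {chrom: _interval_weights(pos_m) for chrom, _, _, pos_m in chrom_data}
    total: dict = {}
    for i, animal in enumerate(g.sample_ids):
        emis, stay, spans = _concatenated_chain(g, freqs, i, model, chrom_data)
        pi = model.pi
        if fit:
            pi, _, _ = _em_core(emis, stay, model.pi, tol, max_iter)
        gamma, _, _, _ = _fb_core(emis, stay, pi)
        hbd_marg = 1.0 - gamma[:, -1]
        total[animal] = {chrom: hbd_marg[off:off + ln] for chrom, off, ln in spans}
    return HBDPosteriors(total_hbd=total, weights=weights, sample_ids=list(g.sample_ids))


def f_hbd(post: HBDPosteriors, per_chromosome: bool = False):
    """Genome (or chromosomal) F_HBD: length-weighted mean total-HBD posterior."""
    chroms = sorted(post.weights)
    rows = {}
    for animal in post.sample_ids:
        per = post.total_hbd[animal]
        rows[animal] = {
            c: float(np.average(per[c], weights=post.weights[c])) for c in chroms
        }
    df = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=chroms)
    if per_chromosome:
        return df
    w = np.array([post.weights[c].sum() for c in chroms])
    genome = (df.to_numpy() * w).sum(axis=1) / w.sum()
    return pd.Series(genome, index=df.index, name="F_HBD")
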