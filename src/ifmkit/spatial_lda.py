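"""Spatial neighborhood topics via grid binning and collapsed-Gibbs LDA.

Cells are binned into square tiles (200 um side by default); each tile
becomes a "document" whose tokens are the marker-positive calls of its
cells (a cell positive for m markers contributes m tokens). A standard
collapsed Gibbs sampler fits the topic model; the topic number is chosen by
held-out perplexity over a scanned range, and cells inherit the argmax
topic of their tile.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numba import njit

__all__ = [
    "GridCorpus",
    "TopicModelFit",
    "grid_binning",
    "fit_lda",
    "heldout_perplexity",
    "select_K",
    "assign_cells",
]


@dataclass
class GridCorpus:
    counts: np.ndarray           # (n_docs, n_markers) token counts
    doc_meta: pd.DataFrame       # specimen_id, gx, gy, n_cells per document
    markers: list
    cell_doc: np.ndarray         # per-cell document index, -1 if unbinned
    grid_um: float


@dataclass
class TopicModelFit:
    K: int
    phi: np.ndarray              # (K, V) topic-marker distributions
    per_grid_theta: np.ndarray   # (n_docs, K)
    alpha: float
    beta: float
    markers: list
    grid_um: float
    seed: int
    n_iter: int
    burn_in: int
    perplexity_curve: dict | None = None
    per_cell_topic: np.ndarray | None = None
    per_specimen_topic_fraction: pd.DataFrame | None = None


def grid_binning(df: pd.DataFrame, markers, grid_um: float = 200.0,
                 min_cells: int = 5, call_suffix: str = "_pos") -> GridCorpus:
    """Bin marker-positive calls into square-tile documents."""
    for m in markers:
        if f"{m}{call_suffix}" not in df.columns:
            raise KeyError(f"missing call column for marker {m!r}")
    gx = np.floor(df["x_um"].values / grid_um).astype(np.int64)
    gy = np.floor(df["y_um"].values / grid_um).astype(np.int64)
    keys = pd.DataFrame({
        "specimen_id": df["specimen_id"].values, "gx": gx, "gy": gy,
    })
    grp = keys.groupby(["specimen_id", "gx", "gy"], sort=True)
    doc_of_cell = grp.ngroup().values
    sizes = grp.size().values
    meta = grp.size().reset_index(name="n_cells")

    calls = df[[f"{m}{call_suffix}" for m in markers]].values.astype(np.int64)
    n_docs = len(meta)
    counts = np.zeros((n_docs, len(markers)), dtype=np.int64)
    np.add.at(counts, doc_of_cell, calls)

    keep = sizes >= min_cells
    if not keep.any():
        raise ValueError("no grid tiles with enough cells")
    remap = np.full(n_docs, -1, dtype=np.int64)
    remap[np.nonzero(keep)[0]] = np.arange(int(keep.sum()))
    cell_doc = remap[doc_of_cell]
    return GridCorpus(
        counts=counts[keep],
        doc_meta=meta.loc[keep].reset_index(drop=True),
        markers=list(markers),
        cell_doc=cell_doc,
        grid_um=grid_um,
    )


def _tokens_from_counts(counts):
    docs, words = np.nonzero(counts)
    reps = counts[docs, words]
    doc_ids = np.repeat(docs, reps).astype(np.int64)
    word_ids = np.repeat(words, reps).astype(np.int64)
    return doc_ids, word_ids


@njit(cache=True)
def _gibbs_kernel(doc_ids, word_ids, z, ndk, nkw, nk, alpha, beta,
                  n_iter, burn_in, sample_every, phi_acc, theta_acc, seed):
    np.random.seed(seed)
    K, V = nkw.shape
    cum = np.empty(K)
    n_samples = 0
    for it in range(n_iter):
        for i in range(doc_ids.size):
            d = doc_ids[i]
            w = word_ids[i]
            k = z[i]
            ndk[d, k] -= 1
            nkw[k, w] -= 1
            nk[k] -= 1
            tot = 0.0
            for kk in range(K):
                tot += (ndk[d, kk] + alpha) * (nkw[kk, w] + beta) / (nk[kk] + V * beta)
                cum[kk] = tot
            u = np.random.random() * tot
            k = 0
            while cum[k] < u and k < K - 1:
                k += 1
            ndk[d, k] += 1
            nkw[k, w] += 1
            nk[k] += 1
            z[i] = k
        if it >= burn_in and (it - burn_in) % sample_every == 0:
            n_samples += 1
            for kk in range(K):
                denom = nk[kk] + V * beta
                for w in range(V):
                    phi_acc[kk, w] += (nkw[kk, w] + beta) / denom
            for d in range(ndk.shape[0]):
                nd = 0.0
                for kk in range(K):
                    nd += ndk[d, kk]
                denom = nd + K * alpha
                for kk in range(K):
                    theta_acc[d, kk] += (ndk[d, kk] + alpha) / denom
    return n_samples


@njit(cache=True)
def _foldin_kernel(doc_ids, word_ids, z, ndk, phi, alpha, n_iter, seed):
    np.random.seed(seed)
    K = phi.shape[0]
    cum = np.empty(K)
    for it in range(n_iter):
        for i in range(doc_ids.size):
            d = doc_ids[i]
            w = word_ids[i]
            k = z[i]
            ndk[d, k] -= 1
            tot = 0.0
            for kk in range(K):
                tot += (ndk[d, kk] + alpha) * phi[kk, w]
                cum[kk] = tot
            u = np.random.random() * tot
            k = 0
            while cum[k] < u and k < K - 1:
                k += 1
            ndk[d, k] += 1
            z[i] = k


def fit_lda(counts, K: int, alpha: float | None = None, beta: float = 0.01,
            n_iter: int = 1000, burn_in: int = 500, sample_every: int = 10,
            seed: int = 0, markers=None, grid_um: float = 200.0) -> TopicModelFit:
    """Fit LDA by collapsed Gibbs sampling; deterministic given the seed.

    ``phi``/``theta`` are posterior means over the post-burn-in samples.
    Defaults: ``alpha = 50/K``, ``beta = 0.01``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n_docs, V = counts.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n_docs:
        raise ValueError(f"K={K} exceeds document count {n_docs}")
    if counts.sum() == 0:
        raise ValueError("empty corpus")
    if alpha is None:
        alpha = 50.0 / K
    doc_ids, word_ids = _tokens_from_counts(counts)
    rng = np.random.default_rng(seed)
    z = rng.integers(0, K, size=doc_ids.size).astype(np.int64)
    ndk = np.zeros((n_docs, K), dtype=np.int64)
    nkw = np.zeros((K, V), dtype=np.int64)
    nk = np.zeros(K, dtype=np.int64)
    np.add.at(ndk, (doc_ids, z), 1)
    np.add.at(nkw, (z, word_ids), 1)
    np.add.at(nk, z, 1)
    phi_acc = np.zeros((K, V))
    theta_acc = np.zeros((n_docs, K))
    n_samples = _gibbs_kernel(
        doc_ids, word_ids, z, ndk, nkw, nk, float(alpha), float(beta),
        int(n_iter), int(burn_in), int(sample_every),
        phi_acc, theta_acc, int(seed) % (2**31 - 1),
    )
    if n_samples == 0:
        raise ValueError("no posterior samples collected; check n_iter > burn_in")
    phi = phi_acc / n_samples
    theta = theta_acc / n_samples
    markers = list(markers) if markers is not None else [
        f"m{v}" for v in range(V)
    ]
    return TopicModelFit(K=K, phi=phi, per_grid_theta=theta,
                         alpha=float(alpha), beta=float(beta),
                         markers=markers, grid_um=grid_um, seed=seed,
                         n_iter=n_iter, burn_in=burn_in)


def heldout_perplexity(phi, counts, alpha: float, n_iter: int = 50,
                       seed: int = 0, n_restarts: int = 3) -> float:
    """Perplexity of held-out documents under fixed topics.

    Per-document topic weights are estimated by folding in (Gibbs with phi
    frozen); perplexity = exp(-mean per-token predictive log-likelihood),
    averaged over ``n_restarts`` fold-in chains for stability.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n_docs, V = counts.shape
    K = phi.shape[0]
    phi = np.ascontiguousarray(phi)
    doc_ids, word_ids = _tokens_from_counts(counts)
    if doc_ids.size == 0:
        raise ValueError("empty held-out set")
    vals = []
    for r in range(n_restarts):
        rng = np.random.default_rng([seed, r])
        z = rng.integers(0, K, size=doc_ids.size).astype(np.int64)
        ndk = np.zeros((n_docs, K), dtype=np.int64)
        np.add.at(ndk, (doc_ids, z), 1)
        _foldin_kernel(doc_ids, word_ids, z, ndk, phi, float(alpha),
                       int(n_iter), (int(seed) + 7919 * r) % (2**31 - 1))
        theta = (ndk + alpha) / (ndk.sum(axis=1, keepdims=True) + K * alpha)
        probs = theta @ phi                   # (n_docs, V)
        ll = float(np.sum(counts * np.log(np.maximum(probs, 1e-300))))
        vals.append(-ll / counts.sum())
    return float(np.exp(np.mean(vals)))


def select_K(counts, k_range=range(8, 17), heldout_fraction: float = 0.1,
             alpha: float | None = None, beta: float = 0.01,
             n_iter: int = 300, burn_in: int = 150, seed: int = 0,
             markers=None, grid_um: float = 200.0):
    """Choose the topic count minimizing held-out perplexity.

    Ties go to the smaller K. Returns ``(chosen_K, perplexity_curve)``.
    """
    counts = np.asarray(counts, dtype=np.int64)
    n_docs = counts.shape[0]
    rng = np.random.default_rng(seed)
    n_test = max(int(round(heldout_fraction * n_docs)), 1)
    if n_test >= n_docs:
        raise ValueError("held-out fraction leaves no training documents")
    perm = rng.permutation(n_docs)
    test_idx, train_idx = perm[:n_test], perm[n_test:]
    curve = {}
    for K in k_range:
        fit = fit_lda(counts[train_idx], K, alpha=alpha, beta=beta,
                      n_iter=n_iter, burn_in=burn_in, seed=seed,
                      markers=markers, grid_um=grid_um)
        curve[K] = heldout_perplexity(fit.phi, counts[test_idx], fit.alpha,
                                      seed=seed)
    best = min(curve, key=lambda k: (curve[k], k))
    return best, curve


def assign_cells(fit: TopicModelFit, corpus: GridCorpus,
                 df: pd.DataFrame) -> TopicModelFit:
    """Propagate grid topics to cells and compute per-specimen fractions.

    Each cell inherits the argmax topic of its tile's theta; cells outside
    any retained tile get topic -1 and are excluded from the fractions
    (which renormalize over assigned cells).
    """
    doc_topic = np.argmax(fit.per_grid_theta, axis=1)
    cell_topic = np.where(corpus.cell_doc >= 0,
                          doc_topic[np.maximum(corpus.cell_doc, 0)], -1)
    assigned = cell_topic >= 0
    frac = (
        pd.crosstab(df["specimen_id"].values[assigned],
                    cell_topic[assigned], normalize="index")
        .reindex(columns=range(fit.K), fill_value=0.0)
    )
    frac.index.name = "specimen_id"
    frac.columns = [f"topic_{k}" for k in range(fit.K)]
    fit.per_cell_topic = cell_topic
    fit.per_specimen_topic_fraction = frac
    return fit
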