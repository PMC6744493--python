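"""Spectral consensus clustering of the DEG co-regulation network.

The pipeline follows the normalized spectral clustering of Ng–Jordan–Weiss,
preceded by two network-specific transforms:

1. edge weights (co-regulation frequencies) are inverted into a
   pseudo-distance, ``D_ij = 1 / W_ij`` (absent edges → ∞);
2. the pseudo-distances are passed through a Gaussian kernel,
   ``A_ij = exp(−D_ij² / 2σ²)``, so that frequently co-regulated pairs get
   affinities near 1 and rarely co-regulated pairs are suppressed.

The bandwidth σ is taken from the pseudo-distance distribution (a quantile,
median by default) unless overridden.  From the kernelised affinity the
degree-normalized operator ``D^{-1/2} A D^{-1/2}`` is built, its k leading
eigenvectors row-normalized to the unit sphere, and k-means with random,
seedable centre initialization produces a partition.  Because single k-means
runs are initialization-dependent, the partition used downstream comes from
a 100-run consensus; the number of modules is selected from consensus
stability (1 − PAC, the proportion of ambiguous co-clustering entries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


@dataclass
class ModulePartition:
    """Node → module labels (1..k); isolated nodes go to a sink module k+1."""

    labels: pd.Series  # index: node name, values: int module id
    k: int
    seed: int | None = None

    def modules(self) -> dict[int, list[str]]:
        return {int(m): sorted(idx)
                for m, idx in self.labels.groupby(self.labels).groups.items()}


@dataclass
class Consensus:
    """Co-clustering frequency matrix over repeated runs."""

    matrix: np.ndarray
    items: list[str]
    runs: int


def to_pseudo_distance(W: np.ndarray) -> np.ndarray:
    """Elementwise inverse of the weight matrix; ∞ off-edges, 0 diagonal."""
    W = np.asarray(W, dtype=float)
    D = np.full_like(W, np.inf)
    nz = W > 0
    D[nz] = 1.0 / W[nz]
    np.fill_diagonal(D, 0.0)
    return D


def gaussian_kernel(D: np.ndarray, sigma: float) -> np.ndarray:
    """``A_ij = exp(−D_ij²/2σ²)`` with A=0 where D=∞ and zero diagonal."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    D = np.asarray(D, dtype=float)
    A = np.zeros_like(D)
    finite = np.isfinite(D)
    A[finite] = np.exp(-(D[finite] ** 2) / (2.0 * sigma ** 2))
    np.fill_diagonal(A, 0.0)
    return A


def select_sigma(D: np.ndarray, quantile: float = 0.5) -> float:
    """Kernel bandwidth as a quantile of finite off-diagonal pseudo-distances."""
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    mask = np.isfinite(D) & ~np.eye(n, dtype=bool)
    values = D[mask]
    if values.size == 0:
        raise ValueError("edgeless graph: no finite pseudo-distances")
    return float(np.quantile(values, quantile))


def _embedding(A: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Row-normalized k-leading-eigenvector embedding of D^{-1/2}AD^{-1/2}.

    Returns (embedding of non-isolated nodes, boolean isolate mask).
    Eigenvector signs are fixed deterministically (first component of
    magnitude > 1e-12 made positive) so repeated calls agree bitwise.
    """
    A = np.asarray(A, dtype=float)
    degrees = A.sum(axis=1)
    isolated = degrees <= 0
    if isolated.any():
        logger.warning("%d isolated node(s) routed to sink module",
                       int(isolated.sum()))
    core = ~isolated
    Ac = A[np.ix_(core, core)]
    d = degrees[core]
    if Ac.shape[0] == 0:
        return np.zeros((0, k)), isolated
    inv_sqrt = 1.0 / np.sqrt(d)
    L = inv_sqrt[:, None] * Ac * inv_sqrt[None, :]
    n = L.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds number of non-isolated nodes {n}")
    vals, vecs = scipy.linalg.eigh(L)
    order = np.argsort(vals)[::-1][:k]
    V = vecs[:, order]
    for j in range(V.shape[1]):
        col = V[:, j]
        nz = np.flatnonzero(np.abs(col) > 1e-12)
        if nz.size and col[nz[0]] < 0:
            V[:, j] = -col
    norms = np.linalg.norm(V, axis=1)
    norms[norms == 0] = 1.0
    return V / norms[:, None], isolated


def _kmeans_labels(embedding: np.ndarray, k: int, seed: int) -> np.ndarray:
    km = KMeans(n_clusters=k, init="random", n_init=1, max_iter=300,
                tol=1e-6, random_state=int(seed) % (2 ** 31))
    return km.fit_predict(embedding)


def _assemble_labels(core_labels: np.ndarray, isolated: np.ndarray,
                     k: int) -> np.ndarray:
    """Merge core labels (0-based) and isolates into 1-based labels.

    Isolated nodes share a single sink module labelled k+1.
    """
    labels = np.empty(isolated.shape[0], dtype=int)
    labels[~isolated] = core_labels + 1
    labels[isolated] = k + 1
    return labels


def spectral_cluster(A: np.ndarray, k: int, seed: int,
                     nodes: list[str] | None = None) -> ModulePartition:
    """One spectral clustering run: embedding + seeded random-init k-means."""
    if k < 2:
        raise ValueError("k must be >= 2")
    V, isolated = _embedding(A, k)
    core_labels = _kmeans_labels(V, k, seed)
    labels = _assemble_labels(core_labels, isolated, k)
    if nodes is None:
        nodes = [str(i) for i in range(A.shape[0])]
    return ModulePartition(labels=pd.Series(labels, index=nodes), k=k, seed=seed)


def _run_seeds(base_seed: int, runs: int) -> np.ndarray:
    ss = np.random.SeedSequence(int(base_seed))
    return ss.generate_state(runs) % (2 ** 31)


def consensus_modules(A: np.ndarray, k: int, runs: int = 100,
                      base_seed: int = 0,
                      nodes: list[str] | None = None) -> Consensus:
    """Co-clustering frequency over ``runs`` k-means repetitions.

    All runs use all nodes (no resampling); the embedding depends only on
    (A, k) and is computed once, so runs differ only in k-means centre
    initialization.
    """
    if runs < 2:
        raise ValueError("runs must be >= 2")
    V, isolated = _embedding(A, k)
    n = A.shape[0]
    counts = np.zeros((n, n))
    for seed in _run_seeds(base_seed, runs):
        labels = _assemble_labels(_kmeans_labels(V, k, seed), isolated, k)
        same = labels[:, None] == labels[None, :]
        counts += same
    C = counts / runs
    np.fill_diagonal(C, 1.0)
    if nodes is None:
        nodes = [str(i) for i in range(n)]
    return Consensus(matrix=C, items=list(nodes), runs=runs)


def pac(consensus: np.ndarray, band: tuple[float, float] = (0.1, 0.9)) -> float:
    """Proportion of ambiguous clustering: off-diagonal entries inside the band."""
    n = consensus.shape[0]
    if n < 2:
        return 0.0
    iu = np.triu_indices(n, k=1)
    values = consensus[iu]
    lo, hi = band
    return float(np.mean((values > lo) & (values < hi)))


def stability_score(consensus: np.ndarray,
                    band: tuple[float, float] = (0.1, 0.9)) -> float:
    """1 − PAC: fraction of unambiguous co-clustering entries."""
    return 1.0 - pac(consensus, band)


def select_k(A: np.ndarray, candidate_ks: list[int], runs: int = 100,
             base_seed: int = 0, stability_floor: float = 0.75,
             band: tuple[float, float] = (0.1, 0.9),
             drop_tolerance: float = 0.005,
             ) -> tuple[int, pd.DataFrame]:
    """Choose the number of modules from consensus stability.

    For each candidate k a consensus matrix is computed and scored by
    1 − PAC.  Scanning k upward, the scan stops where the score first
    *drops* (falls more than ``drop_tolerance`` below the running maximum —
    the point where further increasing k makes modules unstable).  Among
    the pre-drop candidates meeting ``stability_floor`` the chosen k is the
    smallest member of the trailing stability plateau (scores within
    ``drop_tolerance`` of the pre-drop maximum): over-splitting a clean
    partition can be exactly as stable as the partition itself, and the
    plateau's first k is where stability saturates.  If no candidate
    qualifies, the best-scoring k (smallest on ties) is returned.  The full
    score table is returned for audit.
    """
    if not candidate_ks:
        raise ValueError("candidate_ks must be non-empty")
    ks = sorted(set(int(k) for k in candidate_ks))
    if any(k < 2 for k in ks):
        raise ValueError("all candidate ks must be >= 2")
    rows = []
    for k in ks:
        cons = consensus_modules(A, k, runs=runs, base_seed=base_seed)
        score = stability_score(cons.matrix, band)
        rows.append({"k": k, "stability": score, "pac": 1.0 - score})
    table = pd.DataFrame(rows)
    scores = table["stability"].to_numpy()
    running_max = -np.inf
    cut = len(ks)  # index of the first drop
    for i, s in enumerate(scores):
        if s < running_max - drop_tolerance:
            cut = i
            break
        running_max = max(running_max, s)
    chosen = None
    if cut > 0:
        smax = float(np.max(scores[:cut]))
        if smax >= stability_floor:
            # smallest k of the trailing plateau at the pre-drop maximum
            i = cut - 1
            while i > 0 and scores[i - 1] >= smax - drop_tolerance:
                i -= 1
            chosen = ks[i]
    if chosen is None:
        chosen = ks[int(np.argmax(scores))]
        logger.warning("no candidate k met stability floor %.2f before the "
                       "score dropped; falling back to best-scoring k=%d",
                       stability_floor, chosen)
    return chosen, table


def select_k_coarse_fine(A: np.ndarray, coarse_ks: tuple[int, ...] = (5, 10, 15, 20),
                         runs: int = 100, base_seed: int = 0,
                         stability_floor: float = 0.75,
                         band: tuple[float, float] = (0.1, 0.9),
                         ) -> tuple[int, pd.DataFrame]:
    """Coarse-then-fine scan: score a coarse grid, then every k in the
    bracket around the most stable coarse value."""
    n = A.shape[0]
    coarse = sorted({k for k in coarse_ks if 2 <= k <= n})
    if not coarse:
        raise ValueError("no feasible coarse k")
    _, coarse_table = select_k(A, coarse, runs=runs, base_seed=base_seed,
                               stability_floor=stability_floor, band=band)
    best = int(coarse_table.loc[coarse_table["stability"].idxmax(), "k"])
    idx = coarse.index(best)
    lo = coarse[idx - 1] if idx > 0 else 2
    hi = coarse[idx + 1] if idx + 1 < len(coarse) else min(best + 5, n)
    fine = list(range(lo, hi + 1))
    return select_k(A, fine, runs=runs, base_seed=base_seed,
                    stability_floor=stability_floor, band=band)


def consensus_labels(consensus: Consensus, k: int) -> ModulePartition:
    """Majority partition from a consensus matrix.

    Average-linkage hierarchical clustering on 1 − consensus, cut at k
    groups.  More robust than any single k-means run because it pools the
    co-clustering evidence of all runs.
    """
    C = np.clip(consensus.matrix, 0.0, 1.0)
    dist = 1.0 - C
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0
    Z = linkage(squareform(dist, checks=False), method="average")
    labels = fcluster(Z, t=k, criterion="maxclust")
    return ModulePartition(labels=pd.Series(labels, index=consensus.items), k=k)


def final_partition(A: np.ndarray, k_selected: int, seed: int,
                    nodes: list[str] | None = None) -> ModulePartition:
    """One additional seeded clustering run at the selected k."""
    return spectral_cluster(A, k_selected, seed, nodes=nodes)
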