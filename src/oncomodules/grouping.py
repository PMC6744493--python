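"""Patient subgrouping: PAM consensus clustering with AUCDFC model selection.

Patients (rows of the normalized feature table) are clustered with
Partitioning Around Medoids (k-medoids) under Euclidean dissimilarity.
Robustness comes from consensus over repeated subsampled runs: the
consensus entry for a patient pair is the fraction of co-sampled resamples
in which they landed in the same cluster.  The number of groups is chosen
from the area under the consensus CDF curve (AUCDFC): k grows while the
relative AUCDFC gain is material and the consensus matrix stays crisp
(low proportion of ambiguous entries).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .spectral import Consensus, stability_score

logger = logging.getLogger(__name__)


def _pam_build(D: np.ndarray, k: int) -> list[int]:
    """Greedy BUILD phase: medoids chosen to maximally reduce total cost."""
    n = D.shape[0]
    first = int(np.argmin(D.sum(axis=1)))
    medoids = [first]
    nearest = D[:, first].copy()
    while len(medoids) < k:
        # gain[h] = total reduction in nearest-medoid distance if h is added
        gains = np.maximum(nearest[:, None] - D, 0.0).sum(axis=0)
        gains[medoids] = -np.inf
        h = int(np.argmax(gains))  # argmax takes the lowest index on ties
        medoids.append(h)
        nearest = np.minimum(nearest, D[:, h])
    return medoids


def _nearest_two(D: np.ndarray, medoids: list[int]
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sub = D[:, medoids]
    order = np.argsort(sub, axis=1, kind="stable")
    nearest_idx = order[:, 0]
    d1 = sub[np.arange(sub.shape[0]), nearest_idx]
    if len(medoids) > 1:
        d2 = sub[np.arange(sub.shape[0]), order[:, 1]]
    else:
        d2 = np.full(sub.shape[0], np.inf)
    return nearest_idx, d1, d2


def pam(D: np.ndarray, k: int, seed: int | None = None,
        max_iter: int = 100) -> tuple[list[int], np.ndarray]:
    """PAM (k-medoids): BUILD + SWAP to a local optimum.

    ``D`` is a square symmetric dissimilarity matrix with zero diagonal.
    Returns (medoid indices, labels in 1..k).  The algorithm is
    deterministic — ties are broken by lowest index — so ``seed`` only
    documents the caller's seed stream.
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("D must be symmetric")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} must be < n={n}")
    medoids = _pam_build(D, k)
    for _ in range(max_iter):
        nearest_idx, d1, d2 = _nearest_two(D, medoids)
        best_delta, best_swap = -1e-12, None
        for mi in range(len(medoids)):
            mask = nearest_idx == mi
            # cost change of swapping medoid mi for each candidate h:
            # points served by mi fall back to min(d(.,h), second-nearest);
            # other points may switch to h if it is closer than their nearest.
            served = (np.minimum(D[mask, :], d2[mask, None]).sum(axis=0)
                      - d1[mask].sum())
            others = np.minimum(D[~mask, :] - d1[~mask, None], 0.0).sum(axis=0)
            delta = served + others
            delta[medoids] = np.inf
            h = int(np.argmin(delta))
            if delta[h] < best_delta:
                best_delta, best_swap = float(delta[h]), (mi, h)
        if best_swap is None:
            break
        mi, h = best_swap
        medoids[mi] = h
    nearest_idx, _, _ = _nearest_two(D, medoids)
    # relabel so medoids (and hence labels) are in ascending index order
    order = np.argsort(medoids, kind="stable")
    medoids_sorted = [medoids[i] for i in order]
    remap = {int(old): new for new, old in enumerate(order)}
    labels = np.array([remap[int(i)] for i in nearest_idx]) + 1
    return medoids_sorted, labels


def pam_cost(D: np.ndarray, medoids: list[int]) -> float:
    """Total dissimilarity of every point to its nearest medoid."""
    return float(np.asarray(D)[:, medoids].min(axis=1).sum())


def consensus_cluster_patients(features: pd.DataFrame, k: int,
                               resamples: int = 100,
                               subsample_fraction: float = 0.8,
                               seed: int = 0) -> Consensus:
    """PAM consensus over subsampled resamples.

    Per resample, a fraction of patients is drawn without replacement, PAM
    is run on their Euclidean dissimilarities, and co-clustering is tallied.
    Consensus entry = co-cluster count / co-sample count.  Pairs never
    co-sampled get 0 with a warning.
    """
    if resamples < 2:
        raise ValueError("resamples must be >= 2")
    if not 0.0 < subsample_fraction <= 1.0:
        raise ValueError("subsample_fraction must lie in (0, 1]")
    X = features.to_numpy(dtype=float)
    n = X.shape[0]
    m = max(k + 1, int(round(subsample_fraction * n)))
    if m > n:
        raise ValueError("subsample larger than cohort")
    D_full = squareform(pdist(X, metric="euclidean"))
    rng = np.random.default_rng(int(seed))
    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(resamples):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        _, labels = pam(D_full[np.ix_(idx, idx)], k)
        same = labels[:, None] == labels[None, :]
        co_sample[np.ix_(idx, idx)] += 1
        co_cluster[np.ix_(idx, idx)] += same
    never = (co_sample == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        logger.warning("%d patient pair(s) never co-sampled; consensus "
                       "entries set to 0", int(never.sum() // 2))
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
    np.fill_diagonal(C, 1.0)
    C = (C + C.T) / 2.0
    return Consensus(matrix=C, items=list(features.index), runs=resamples)


def auc_cdf(consensus: Consensus | np.ndarray) -> float:
    """Area under the empirical CDF of upper-triangle consensus entries.

    Step-function integral on [0, 1]: two crisp clusters of two patients
    (entries {1,1,0,0,0,0}) give CDF 2/3 on [0,1) and area 2/3; all-ones
    give 0; all-zeros give 1.
    """
    M = consensus.matrix if isinstance(consensus, Consensus) else np.asarray(consensus)
    n = M.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items")
    values = M[np.triu_indices(n, k=1)]
    xs = np.unique(values)
    total = values.size
    area = 0.0
    for i, x in enumerate(xs):
        cdf = np.count_nonzero(values <= x) / total
        upper = xs[i + 1] if i + 1 < len(xs) else 1.0
        area += cdf * (upper - x)
    return float(area)


@dataclass
class GroupSelection:
    k: int
    table: pd.DataFrame
    consensus: dict[int, Consensus]


def select_group_count(features: pd.DataFrame,
                       k_range: range | list[int] = range(2, 16),
                       resamples: int = 100,
                       subsample_fraction: float = 0.8,
                       seed: int = 0,
                       delta_threshold: float = 0.03,
                       stability_floor: float = 0.8,
                       stability_slack: float = 0.05,
                       band: tuple[float, float] = (0.1, 0.9),
                       ) -> GroupSelection:
    """Pick the number of patient groups from AUCDFC gains and crispness.

    The relative AUCDFC increase Δ(k) = (A(k) − A(k−1)) / A(k−1) (Δ(2) =
    A(2)) is computed for every candidate; the chosen k is the largest
    candidate satisfying all of: Δ(k) ≥ ``delta_threshold``; consensus
    stability (1 − PAC) ≥ ``stability_floor``; and stability within
    ``stability_slack`` of the best stability over the candidates — the
    relative condition is what rejects over-split solutions when a crisper
    partition exists, while the absolute floor rejects grouping of
    structureless data.  Falls back to the smallest candidate when nothing
    qualifies.  The full decision table is returned.
    """
    ks = sorted(set(int(k) for k in k_range))
    if len(ks) < 2:
        raise ValueError("need at least 2 candidate group counts")
    consensus: dict[int, Consensus] = {}
    rows = []
    prev_auc = None
    for k in ks:
        cons = consensus_cluster_patients(
            features, k, resamples=resamples,
            subsample_fraction=subsample_fraction, seed=seed)
        consensus[k] = cons
        auc = auc_cdf(cons)
        if prev_auc is None:
            delta = auc
        elif prev_auc <= 0:
            delta = np.inf if auc > 0 else 0.0
        else:
            delta = (auc - prev_auc) / prev_auc
        stability = stability_score(cons.matrix, band)
        rows.append({"k": k, "aucdfc": auc, "delta": delta,
                     "stability": stability})
        prev_auc = auc
    table = pd.DataFrame(rows)
    best_stability = table["stability"].max()
    qualified = table[(table["delta"] >= delta_threshold)
                      & (table["stability"] >= stability_floor)
                      & (table["stability"] >= best_stability - stability_slack)]
    if len(qualified):
        chosen = int(qualified["k"].max())
    else:
        chosen = ks[0]
        logger.warning("no k qualified on AUCDFC gain + stability; "
                       "falling back to k=%d", chosen)
    return GroupSelection(k=chosen, table=table, consensus=consensus)


def assign_groups(features: pd.DataFrame, k_selected: int,
                  seed: int = 0) -> tuple[pd.Series, list[str]]:
    """Final full-data PAM run at the chosen k.

    Returns (labels indexed by patient id, medoid patient ids).
    """
    X = features.to_numpy(dtype=float)
    D = squareform(pdist(X, metric="euclidean"))
    medoids, labels = pam(D, k_selected, seed=seed)
    ids = list(features.index)
    return (pd.Series(labels, index=ids, name="group"),
            [ids[i] for i in medoids])
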