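"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops over rows/pairs, deliberately
sharing no code with the package.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np


def brute_filter(rows: list[tuple], observations: list[tuple],
                 floor: float = 0.5, min_degs: int = 5, min_tumours: int = 30,
                 min_frac: float = 0.25, rel_tumours: int = 50,
                 rel_frac: float = 0.20):
    """Four filtering standards by exhaustive scanning.

    ``rows`` are (tumour, sga, deg, posterior); ``observations`` are
    (tumour, sga).  Returns (valid rows, tumour-driver set, significant
    driver set, significant relationship set).
    """
    valid = [r for r in rows if r[3] > floor]

    drivers = set()
    tumours = {r[0] for r in valid}
    sgas = {r[1] for r in valid}
    for t in tumours:
        for s in sgas:
            degs = {r[2] for r in valid if r[0] == t and r[1] == s}
            if len(degs) >= min_degs:
                drivers.add((t, s))

    significant = set()
    for s in sgas:
        n_driver = sum(1 for (t, s2) in drivers if s2 == s)
        n_obs = len({t for (t, s2) in observations if s2 == s})
        if n_driver == 0:
            continue
        if n_driver >= min_tumours and n_driver / n_obs >= min_frac:
            significant.add(s)

    relationships = set()
    for s in significant:
        n_driver = sum(1 for (t, s2) in drivers if s2 == s)
        degs = {r[2] for r in valid if r[1] == s}
        for d in degs:
            n_pair = len({r[0] for r in valid if r[1] == s and r[2] == d})
            if n_pair >= rel_tumours or (n_driver > 0
                                         and n_pair / n_driver >= rel_frac):
                relationships.add((s, d))
    return valid, drivers, significant, relationships


def brute_node_counts(rows: list[tuple]) -> dict[str, int]:
    """DEG -> number of distinct tumours in which it is a target."""
    counts: dict[str, set] = {}
    for t, _s, d, _p in rows:
        counts.setdefault(d, set()).add(t)
    return {d: len(ts) for d, ts in counts.items()}


def brute_coreg_instances(rows: list[tuple], kept: set[str]) -> set[tuple]:
    """(tumour, sga, deg_a, deg_b) triples by pairwise enumeration."""
    per_ts: dict[tuple, set] = {}
    for t, s, d, _p in rows:
        if d in kept:
            per_ts.setdefault((t, s), set()).add(d)
    out = set()
    for (t, s), degs in per_ts.items():
        for a, b in combinations(sorted(degs), 2):
            out.add((t, s, a, b))
    return out


def brute_edge_weights(instances: set[tuple]) -> dict[tuple, int]:
    """Pair -> distinct-tumour count."""
    tumours: dict[tuple, set] = {}
    for t, _s, a, b in instances:
        tumours.setdefault((a, b), set()).add(t)
    return {pair: len(ts) for pair, ts in tumours.items()}


def exact_hypergeom_upper_tail(M: int, n: int, N: int, observed: int) -> float:
    """P(X >= observed) by exhaustive combinatorial enumeration."""
    from math import comb
    total = comb(M, N)
    hits = sum(comb(n, x) * comb(M - n, N - x)
               for x in range(observed, min(n, N) + 1))
    return hits / total


def brute_pam_best(D: np.ndarray, k: int) -> tuple[float, frozenset]:
    """Globally optimal medoid set by exhaustive search (tiny n only)."""
    n = D.shape[0]
    best_cost, best = np.inf, None
    for medoids in combinations(range(n), k):
        cost = sum(min(D[j, m] for m in medoids) for j in range(n))
        if cost < best_cost:
            best_cost, best = cost, frozenset(medoids)
    return float(best_cost), best


def brute_concordance(risk: np.ndarray, times: np.ndarray,
                      events: np.ndarray) -> float:
    """Harrell's C by exhaustive pair enumeration.

    A pair is comparable when the earlier time is an event; concordant when
    the earlier subject has the higher risk; ties in risk credit 0.5.
    """
    num, den = 0.0, 0
    n = len(risk)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            if times[i] < times[j] and events[i] == 1:
                den += 1
                if risk[i] > risk[j]:
                    num += 1.0
                elif risk[i] == risk[j]:
                    num += 0.5
            elif times[i] == times[j] and i < j and events[i] + events[j] >= 1:
                # tied times: comparable only if exactly one is an event
                if events[i] != events[j]:
                    den += 1
                    ev, other = (i, j) if events[i] else (j, i)
                    if risk[ev] > risk[other]:
                        num += 1.0
                    elif risk[ev] == risk[other]:
                        num += 0.5
    if den == 0:
        raise ZeroDivisionError("no comparable pairs")
    return num / den


def random_assignment_instance(rng: np.random.Generator, n_tumours: int = 20,
                               n_sgas: int = 15, n_degs: int = 25,
                               density: float = 0.3):
    """Random assignment + observation tables obeying the one-cause rule."""
    tumours = [f"t{i}" for i in range(n_tumours)]
    sgas = [f"s{i}" for i in range(n_sgas)]
    degs = [f"d{i}" for i in range(n_degs)]
    rows, obs = [], set()
    for t in tumours:
        observed = [s for s in sgas if rng.random() < 0.5]
        for s in observed:
            obs.add((t, s))
        if not observed:
            continue
        for d in degs:
            if rng.random() < density:
                s = observed[rng.integers(0, len(observed))]
                rows.append((t, s, d, float(rng.random())))
    return rows, sorted(obs)
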