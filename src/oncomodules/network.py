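"""Weighted DEG co-regulation network with per-edge provenance.

Two DEGs are *co-regulated* in a tumour when both are assigned to the same
SGA there.  Nodes are DEGs appearing as significant-assignment targets in
more than ``min_fraction`` of the tumours (strict), and the weight of edge
(i, j) is the number of distinct tumours in which the pair was co-regulated
by a common SGA.  Every co-regulation instance — a (tumour, SGA, DEG-pair)
triple — is retained as edge provenance so module co-regulation can later be
attributed to individual SGAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Columns of a co-regulation instance table; deg_a < deg_b lexicographically.
INSTANCE_COLUMNS = ["tumour_id", "sga", "deg_a", "deg_b"]

EDGE_COLUMNS = ["deg_a", "deg_b", "weight"]


def node_filter(significant_assignments: pd.DataFrame,
                n_tumours: int | None = None,
                min_fraction: float = 0.10) -> set[str]:
    """DEGs appearing as assignment targets in more than ``min_fraction``
    of the tumours (strict inequality).

    ``n_tumours`` defaults to the number of distinct tumours in the table —
    i.e. tumours that retained at least one significant assignment.
    """
    if n_tumours is None:
        n_tumours = significant_assignments["tumour_id"].nunique()
    if n_tumours == 0:
        raise ValueError("empty cohort: no tumours with significant assignments")
    counts = significant_assignments.groupby("deg")["tumour_id"].nunique()
    cutoff = min_fraction * n_tumours
    return set(counts[counts > cutoff].index)


def enumerate_coreg(significant_assignments: pd.DataFrame,
                    kept_nodes: set[str]) -> pd.DataFrame:
    """All co-regulation instances among kept nodes.

    One row per (tumour, SGA, unordered DEG pair) where both DEGs are
    assigned to that SGA in that tumour; an SGA causing m kept DEGs in a
    tumour yields m(m−1)/2 instances.
    """
    sub = significant_assignments[significant_assignments["deg"].isin(kept_nodes)]
    rows: list[tuple] = []
    for (tumour, sga), grp in sub.groupby(["tumour_id", "sga"], sort=True):
        degs = sorted(set(grp["deg"]))
        for a, b in combinations(degs, 2):
            rows.append((tumour, sga, a, b))
    return pd.DataFrame(rows, columns=INSTANCE_COLUMNS)


@dataclass
class DEGNetwork:
    """Undirected weighted DEG graph plus co-regulation provenance.

    ``edges`` has one row per unordered pair with nonzero weight; ``weight``
    counts distinct tumours.  ``provenance`` lists every co-regulation
    instance behind an edge.
    """

    nodes: list[str]
    edges: pd.DataFrame
    provenance: pd.DataFrame

    def __post_init__(self) -> None:
        self.nodes = sorted(self.nodes)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def affinity_matrix(self) -> tuple[np.ndarray, list[str]]:
        """Dense symmetric weight matrix (zero diagonal) and node order."""
        index = {g: i for i, g in enumerate(self.nodes)}
        W = np.zeros((len(self.nodes), len(self.nodes)))
        for a, b, w in self.edges[EDGE_COLUMNS].itertuples(index=False):
            i, j = index[a], index[b]
            W[i, j] = W[j, i] = w
        return W, list(self.nodes)

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        pd.DataFrame({"deg": self.nodes}).to_csv(
            directory / "nodes.tsv", sep="\t", index=False)
        self.edges.to_csv(directory / "edges.tsv", sep="\t", index=False)
        self.provenance.to_csv(
            directory / "provenance.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, directory: str | Path) -> "DEGNetwork":
        directory = Path(directory)
        nodes = pd.read_csv(directory / "nodes.tsv", sep="\t")["deg"].tolist()
        edges = pd.read_csv(directory / "edges.tsv", sep="\t")
        provenance = pd.read_csv(directory / "provenance.tsv", sep="\t")
        return cls(nodes=nodes, edges=edges, provenance=provenance)


def build_network(instances: pd.DataFrame,
                  kept_nodes: set[str],
                  min_edge_weight: int = 1) -> DEGNetwork:
    """Aggregate co-regulation instances into the weighted network.

    The weight of a pair is the number of *distinct tumours* contributing an
    instance (a tumour can contribute at most once per pair under the
    one-cause rule).  ``min_edge_weight`` > 1 reproduces the stricter
    edge-frequency reading of network construction.
    """
    if len(instances) == 0:
        edges = pd.DataFrame(columns=EDGE_COLUMNS)
        prov = pd.DataFrame(columns=INSTANCE_COLUMNS)
        return DEGNetwork(nodes=sorted(kept_nodes), edges=edges, provenance=prov)
    weights = (instances.groupby(["deg_a", "deg_b"])["tumour_id"]
               .nunique().rename("weight").reset_index())
    weights = weights[weights["weight"] >= min_edge_weight]
    keep_pairs = set(zip(weights["deg_a"], weights["deg_b"]))
    prov_mask = [
        (a, b) in keep_pairs
        for a, b in zip(instances["deg_a"], instances["deg_b"])
    ]
    provenance = instances.loc[prov_mask].reset_index(drop=True)
    logger.info("network: %d nodes, %d edges, %d co-regulation instances",
                len(kept_nodes), len(weights), len(provenance))
    return DEGNetwork(nodes=sorted(kept_nodes),
                      edges=weights.reset_index(drop=True),
                      provenance=provenance)


def network_from_assignments(significant_assignments: pd.DataFrame,
                             min_node_fraction: float = 0.10,
                             min_edge_weight: int = 1,
                             n_tumours: int | None = None) -> DEGNetwork:
    """Convenience: node filter → instance enumeration → aggregation."""
    kept = node_filter(significant_assignments, n_tumours=n_tumours,
                       min_fraction=min_node_fraction)
    instances = enumerate_coreg(significant_assignments, kept)
    return build_network(instances, kept, min_edge_weight=min_edge_weight)
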