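"""Module annotation: dominant driver SGAs and gene-set overlap.

An SGA is a *dominant* SGA of a module when it produced strictly more than
``threshold`` (default 10%) of the co-regulation instances between DEG pairs
lying wholly inside the module.  Gene-set overlaps are scored with the
upper-tail hypergeometric p-value against a configurable gene universe
(default: all network nodes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd
from scipy.stats import hypergeom

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "genes", frozenset(self.genes))


def dominant_sgas(partition_labels: pd.Series, provenance: pd.DataFrame,
                  threshold: float = 0.10) -> pd.DataFrame:
    """Per-module SGA attribution of co-regulation instances.

    Counts provenance instances whose DEG pair lies wholly inside one
    module, grouped by SGA.  Returns a table with columns
    [module, sga, instances, proportion, dominant]; proportions within a
    module sum to 1 (each instance has exactly one SGA) and the dominant
    flag is strict (> threshold).  Modules with zero internal instances get
    no rows.
    """
    label = partition_labels.to_dict()
    rows = []
    mod_a = provenance["deg_a"].map(label)
    mod_b = provenance["deg_b"].map(label)
    internal = provenance.loc[(mod_a == mod_b) & mod_a.notna()].copy()
    internal["module"] = mod_a[internal.index].astype(int)
    if len(internal) == 0:
        return pd.DataFrame(
            columns=["module", "sga", "instances", "proportion", "dominant"])
    for module, grp in internal.groupby("module"):
        total = len(grp)
        counts = grp.groupby("sga").size().sort_values(ascending=False)
        for sga, n in counts.items():
            prop = n / total
            rows.append({"module": int(module), "sga": sga,
                         "instances": int(n), "proportion": prop,
                         "dominant": prop > threshold})
    return pd.DataFrame(rows)


def hypergeom_overlap(module_genes: set[str], gene_set: GeneSet | set[str],
                      universe: set[str]) -> float:
    """Upper-tail hypergeometric p-value of the module/gene-set overlap.

    P(X >= observed overlap) with population |universe|, successes
    |gene_set ∩ universe|, draws |module_genes|.  The module must be a
    subset of the universe.
    """
    if len(universe) == 0:
        raise ValueError("empty universe")
    members = gene_set.genes if isinstance(gene_set, GeneSet) else set(gene_set)
    module_genes = set(module_genes)
    if not module_genes <= set(universe):
        raise ValueError("module genes must be a subset of the universe")
    M = len(universe)
    n = len(members & set(universe))
    N = len(module_genes)
    observed = len(module_genes & members & set(universe))
    return float(hypergeom.sf(observed - 1, M, n, N))


def rank_gene_sets(module_genes: set[str], gmt_collection: list[GeneSet],
                   universe: set[str], top_n: int = 10) -> pd.DataFrame:
    """Top-``top_n`` gene sets by ascending overlap p-value.

    Ties broken by larger overlap, then name.
    """
    if not gmt_collection:
        raise ValueError("empty gene-set collection")
    module_genes = set(module_genes)
    rows = []
    for gs in gmt_collection:
        overlap = len(module_genes & gs.genes & set(universe))
        p = hypergeom_overlap(module_genes, gs, universe)
        rows.append({"name": gs.name, "overlap": overlap, "p_value": p})
    table = pd.DataFrame(rows)
    table = table.sort_values(
        by=["p_value", "overlap", "name"],
        ascending=[True, False, True], kind="mergesort").reset_index(drop=True)
    return table.head(top_n)


def dominance_summary(partition_labels: pd.Series, provenance: pd.DataFrame,
                      effective_sizes: dict[int, int] | None = None,
                      threshold: float = 0.10) -> pd.DataFrame:
    """Per-module composition: DEG counts and dominant SGAs with percentages.

    Mirrors a module-composition report: module index, number of DEGs,
    number of effective DEGs (if supplied), and the dominant SGAs with the
    proportion of co-regulation each produced.
    """
    report = dominant_sgas(partition_labels, provenance, threshold)
    rows = []
    for module, grp in partition_labels.groupby(partition_labels):
        sub = report[(report["module"] == module) & report["dominant"]]
        doms = "; ".join(
            f"{r.sga} ({100 * r.proportion:.1f}%)"
            for r in sub.itertuples())
        rows.append({
            "module": int(module),
            "n_deg": int(len(grp)),
            "n_effective_deg": (effective_sizes or {}).get(int(module), pd.NA),
            "dominant_sgas": doms,
        })
    return pd.DataFrame(rows).sort_values("module").reset_index(drop=True)
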