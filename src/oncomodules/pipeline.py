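"""End-to-end pipeline: filter → network → modules → annotate → features →
groups → survival, with a reproducibility manifest.

Each stage is a pure function of its inputs plus a stage seed derived from
the run seed, and persists its outputs under the run directory so a run can
be restarted from any stage's saved artifacts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from . import io as omio
from .annotation import dominance_summary, dominant_sgas
from .features import assemble_features, module_feature_table, zscore_normalize
from .filtering import FilterThresholds, apply_filters
from .grouping import assign_groups, select_group_count
from .network import DEGNetwork, network_from_assignments
from .simulate import Cohort, SyntheticCohortSpec, generate_cohort, write_cohort
from .spectral import (consensus_labels, consensus_modules, gaussian_kernel,
                       select_k, select_sigma, to_pseudo_distance)
from .survival import cox_reports, kaplan_meier, logrank_test

logger = logging.getLogger(__name__)

STAGES = ["simulate", "filter", "network", "modules", "annotate",
          "features", "groups", "survive"]

DEFAULT_CONFIG: dict[str, Any] = {
    "seed": 0,
    "thresholds": {},           # FilterThresholds overrides
    "cohort": {},               # SyntheticCohortSpec overrides
    "network": {"min_node_fraction": 0.10, "min_edge_weight": 1},
    "modules": {"sigma": "auto", "sigma_quantile": 0.5, "k": "auto",
                "candidate_ks": list(range(2, 9)), "runs": 100,
                "stability_floor": 0.75},
    "groups": {"kmin": 2, "kmax": 8, "resamples": 100,
               "subsample_fraction": 0.8, "feature_set": "all"},
    "features": {"missing_policy": "complete"},
}


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for key, value in (override or {}).items():
        if isinstance(value, dict) and isinstance(out.get(key), dict):
            out[key] = _merge(out[key], value)
        else:
            out[key] = value
    return out


def stage_seed(seed: int, stage: str) -> int:
    """Independent per-stage seed below 2**31, stable across runs."""
    index = STAGES.index(stage)
    ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(index,))
    return int(ss.generate_state(1)[0] % (2 ** 31))


@dataclass
class PipelineResult:
    cohort: Cohort
    filter_result: Any
    network: DEGNetwork
    sigma: float
    k_modules: int
    module_labels: pd.Series
    stability_table: pd.DataFrame
    dominance: pd.DataFrame
    features_all: Any
    features_modules: Any
    group_selection_table: pd.DataFrame
    k_groups: int
    group_labels: pd.Series
    deg_group_labels: pd.Series
    logrank: Any
    deg_logrank: Any
    cox: dict
    km_tables: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)


def run_pipeline(config: dict | None = None,
                 out_dir: str | Path | None = None,
                 cohort: Cohort | None = None) -> PipelineResult:
    """Run all stages on a synthetic (or supplied) cohort.

    ``config`` overrides :data:`DEFAULT_CONFIG`.  When ``out_dir`` is given
    every stage's outputs and a manifest with file digests are written
    there.
    """
    cfg = _merge(DEFAULT_CONFIG, config or {})
    seed = int(cfg["seed"])
    out = Path(out_dir) if out_dir is not None else None
    manifest: dict[str, Any] = {"version": __version__, "config": cfg,
                                "stage_seeds": {}, "digests": {}}

    # --- simulate ---------------------------------------------------------
    if cohort is None:
        sim_seed = stage_seed(seed, "simulate")
        spec = SyntheticCohortSpec(**{**cfg["cohort"], "seed": sim_seed})
        cohort = generate_cohort(spec)
        manifest["stage_seeds"]["simulate"] = sim_seed
    if out is not None:
        paths = write_cohort(cohort, out / "cohort")
        manifest["digests"].update(
            {f"cohort/{k}": omio.sha256_digest(p) for k, p in paths.items()})

    # --- filter -----------------------------------------------------------
    thresholds = FilterThresholds(**cfg["thresholds"])
    filt = apply_filters(cohort.assignments, cohort.observations, thresholds)
    if out is not None:
        (out / "filter").mkdir(parents=True, exist_ok=True)
        filt.significant_assignments.to_csv(
            out / "filter" / "significant.tsv", sep="\t", index=False)
        manifest["digests"]["filter/significant"] = omio.sha256_digest(
            out / "filter" / "significant.tsv")

    # --- network ----------------------------------------------------------
    net_cfg = cfg["network"]
    network = network_from_assignments(
        filt.significant_assignments,
        min_node_fraction=net_cfg["min_node_fraction"],
        min_edge_weight=net_cfg["min_edge_weight"])
    if network.n_nodes < 3:
        raise RuntimeError("pipeline aborted at stage 'network': "
                           "fewer than 3 network nodes after filtering")
    if out is not None:
        network.write(out / "network")
        for f in ("nodes", "edges", "provenance"):
            manifest["digests"][f"network/{f}"] = omio.sha256_digest(
                out / "network" / f"{f}.tsv")

    # --- modules ----------------------------------------------------------
    mod_cfg = cfg["modules"]
    mod_seed = stage_seed(seed, "modules")
    manifest["stage_seeds"]["modules"] = mod_seed
    W, nodes = network.affinity_matrix()
    D = to_pseudo_distance(W)
    sigma = (select_sigma(D, mod_cfg["sigma_quantile"])
             if mod_cfg["sigma"] == "auto" else float(mod_cfg["sigma"]))
    A = gaussian_kernel(D, sigma)
    if mod_cfg["k"] == "auto":
        candidates = [k for k in mod_cfg["candidate_ks"] if k <= len(nodes)]
        k_modules, stability_table = select_k(
            A, candidates, runs=mod_cfg["runs"], base_seed=mod_seed,
            stability_floor=mod_cfg["stability_floor"])
    else:
        k_modules = int(mod_cfg["k"])
        stability_table = pd.DataFrame()
    cons = consensus_modules(A, k_modules, runs=mod_cfg["runs"],
                             base_seed=mod_seed, nodes=nodes)
    partition = consensus_labels(cons, k_modules)
    module_labels = partition.labels
    if out is not None:
        (out / "modules").mkdir(parents=True, exist_ok=True)
        omio.write_module_labels(module_labels, out / "modules" / "modules.tsv")
        stability_table.to_csv(out / "modules" / "stability.tsv",
                               sep="\t", index=False)
        pd.DataFrame(cons.matrix, index=nodes, columns=nodes).to_csv(
            out / "modules" / "consensus.tsv", sep="\t")
        manifest["digests"]["modules/modules"] = omio.sha256_digest(
            out / "modules" / "modules.tsv")

    # --- annotate ---------------------------------------------------------
    dominance = dominant_sgas(module_labels, network.provenance)
    if out is not None:
        (out / "annotate").mkdir(parents=True, exist_ok=True)
        dominance.to_csv(out / "annotate" / "dominance.tsv",
                         sep="\t", index=False)
        summary = dominance_summary(module_labels, network.provenance)
        summary.to_csv(out / "annotate" / "composition.tsv",
                       sep="\t", index=False)

    # --- features ---------------------------------------------------------
    module_feats = module_feature_table(cohort.expression, module_labels)
    feats_all = zscore_normalize(assemble_features(
        module_feats, cohort.clinical,
        missing_policy=cfg["features"]["missing_policy"]))
    feats_mod = zscore_normalize(assemble_features(
        module_feats, None, missing_policy=cfg["features"]["missing_policy"]))
    if out is not None:
        (out / "features").mkdir(parents=True, exist_ok=True)
        omio.write_features(feats_all, out / "features" / "features.tsv")
        manifest["digests"]["features/features"] = omio.sha256_digest(
            out / "features" / "features.tsv")

    # --- groups -----------------------------------------------------------
    grp_cfg = cfg["groups"]
    grp_seed = stage_seed(seed, "groups")
    manifest["stage_seeds"]["groups"] = grp_seed
    k_range = range(grp_cfg["kmin"], grp_cfg["kmax"] + 1)
    selection = select_group_count(
        feats_all.values, k_range=k_range, resamples=grp_cfg["resamples"],
        subsample_fraction=grp_cfg["subsample_fraction"], seed=grp_seed)
    group_labels, medoids = assign_groups(feats_all.values, selection.k,
                                          seed=grp_seed)
    deg_selection = select_group_count(
        feats_mod.values, k_range=k_range, resamples=grp_cfg["resamples"],
        subsample_fraction=grp_cfg["subsample_fraction"], seed=grp_seed)
    deg_group_labels, _ = assign_groups(feats_mod.values, deg_selection.k,
                                        seed=grp_seed)
    if out is not None:
        (out / "groups").mkdir(parents=True, exist_ok=True)
        omio.write_group_labels(group_labels, out / "groups" / "labels.tsv")
        omio.write_group_labels(deg_group_labels,
                                out / "groups" / "deg_labels.tsv")
        selection.table.to_csv(out / "groups" / "aucdfc.tsv",
                               sep="\t", index=False)
        manifest["digests"]["groups/labels"] = omio.sha256_digest(
            out / "groups" / "labels.tsv")

    # --- survive ----------------------------------------------------------
    records = cohort.survival.loc[group_labels.index]
    lr = logrank_test(records, group_labels.to_numpy())
    deg_records = cohort.survival.loc[deg_group_labels.index]
    deg_lr = logrank_test(deg_records, deg_group_labels.to_numpy())
    cox = cox_reports(feats_all.values, records, groups=group_labels)
    km_tables = {
        int(g): kaplan_meier(records.loc[group_labels.index[group_labels == g]])
        for g in sorted(group_labels.unique())
    }
    if out is not None:
        (out / "survive").mkdir(parents=True, exist_ok=True)
        for g, table in km_tables.items():
            table.to_csv(out / "survive" / f"km_group_{g}.tsv",
                         sep="\t", index=False)
        report = pd.DataFrame([
            {"model": name, "c_index": fit.c_index, "n": fit.n,
             "n_events": fit.n_events,
             "significant_covariates": "; ".join(
                 f"{cov} ({row.coef:.3f})"
                 for cov, row in fit.significant_covariates().iterrows())}
            for name, fit in cox.items()])
        report.to_csv(out / "survive" / "cox.tsv", sep="\t", index=False)
        omio.write_json({"logrank_p": lr.p_value,
                         "logrank_statistic": lr.statistic,
                         "deg_logrank_p": deg_lr.p_value},
                        out / "survive" / "logrank.json")
        omio.write_json(manifest, out / "manifest.json")

    logger.info("pipeline complete: %d modules, %d patient groups, "
                "log-rank p=%.3g", k_modules, selection.k, lr.p_value)
    return PipelineResult(
        cohort=cohort, filter_result=filt, network=network, sigma=sigma,
        k_modules=k_modules, module_labels=module_labels,
        stability_table=stability_table, dominance=dominance,
        features_all=feats_all, features_modules=feats_mod,
        group_selection_table=selection.table, k_groups=selection.k,
        group_labels=group_labels, deg_group_labels=deg_group_labels,
        logrank=lr, deg_logrank=deg_lr, cox=cox, km_tables=km_tables,
        manifest=manifest)
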