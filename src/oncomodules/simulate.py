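"""Synthetic tumour cohorts with planted pathway structure.

The generator emulates the statistical shape of the six pipeline inputs:
a tumour-specific SGA→DEG causal-assignment table obeying the one-cause
rule, an SGA observation table, a patient × gene expression matrix, a
clinical covariate table, a survival table, and gene-set collections —
together with the ground truth needed to score recovery.

Structure planted per cohort:

* ``n_pathways`` pathways, each with a set of driver SGAs and a signature
  DEG set (disjoint by default, optional small overlap);
* every tumour belongs to one patient group whose pathway is fully active;
  other pathways switch on at a low background rate with partial
  activation level;
* for each active pathway one of its drivers is observed and assigned as
  the cause of a random subset (rate ``assignment_rate``, at least
  ``min_assigned``) of the signature DEGs with high posteriors;
* passenger SGAs are sprinkled in with low posteriors and few targets, so
  the filtering standards eliminate them;
* expression of a signature gene is effect × activation + Gaussian noise;
* survival is exponential with log-hazard Σ coefficients × activation and
  independent uniform censoring calibrated to a target censoring fraction.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SyntheticCohortSpec:
    """Study conditions of the default synthetic cohort.

    Defaults: 200 tumours, 5 pathways with one driver and a 40-gene
    signature each, per-DEG assignment rate 0.7, background pathway
    activation 5% at level 0.5, 30 passenger SGAs with low posteriors,
    expression effect 1 vs noise sd 1, hazard coefficients spread over
    ±0.9, baseline hazard 1/1000 per day, 30% censoring.
    """

    n_tumours: int = 200
    n_pathways: int = 5
    drivers_per_pathway: int = 1
    signature_degs_per_pathway: int = 40
    signature_overlap: float = 0.0  # fraction of a signature shared with the next
    noise_degs: int = 50
    passenger_sgas: int = 30
    passenger_observation_rate: float = 0.15
    passenger_assignment_rate: float = 0.5
    passenger_max_targets: int = 3
    driver_background_observation_rate: float = 0.20
    background_activation_rate: float = 0.05
    background_activation_level: float = 0.5
    assignment_rate: float = 0.7
    min_assigned: int = 5
    true_posterior: tuple[float, float] = (0.7, 1.0)
    noise_posterior: tuple[float, float] = (0.0, 0.4)
    expression_effect: float = 1.0
    expression_noise_sd: float = 1.0
    platform_dropout: float = 0.0
    hazard_coefficients: tuple[float, ...] | None = None
    baseline_hazard: float = 1.0 / 1000.0  # per day
    censoring_fraction: float = 0.30
    clinical_group_effect: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_tumours", "n_pathways", "drivers_per_pathway",
                     "signature_degs_per_pathway"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        for name in ("signature_overlap", "passenger_observation_rate",
                     "passenger_assignment_rate", "background_activation_rate",
                     "assignment_rate", "platform_dropout",
                     "censoring_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.min_assigned > self.signature_degs_per_pathway:
            raise ValueError("min_assigned exceeds signature size")

    def coefficients(self) -> np.ndarray:
        if self.hazard_coefficients is not None:
            coefs = np.asarray(self.hazard_coefficients, dtype=float)
            if len(coefs) != self.n_pathways:
                raise ValueError("need one hazard coefficient per pathway")
            return coefs
        return np.linspace(0.9, -0.9, self.n_pathways)


@dataclass
class Cohort:
    assignments: pd.DataFrame
    observations: pd.DataFrame
    expression: pd.DataFrame  # patients × genes
    clinical: pd.DataFrame    # patients × covariates
    survival: pd.DataFrame    # patients × (time, event)
    truth: dict = field(default_factory=dict)


def _signatures(spec: SyntheticCohortSpec) -> tuple[list[list[str]], list[list[str]]]:
    drivers, signatures = [], []
    size = spec.signature_degs_per_pathway
    shared = int(round(spec.signature_overlap * size))
    for p in range(spec.n_pathways):
        drivers.append([f"SGA_P{p + 1}_D{i + 1}"
                        for i in range(spec.drivers_per_pathway)])
        sig = [f"DEG_P{p + 1}_G{i + 1}" for i in range(size)]
        if shared and p > 0:
            sig[:shared] = signatures[p - 1][-shared:]
        signatures.append(sig)
    return drivers, signatures


def _calibrate_censoring(times: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring hitting the target fraction.

    The expected censored fraction E[min(t/c, 1)] is decreasing in c;
    bisection solves for c.
    """
    if target <= 0:
        return float(np.inf)

    def frac(c: float) -> float:
        return float(np.mean(np.minimum(times / c, 1.0)))

    lo, hi = float(np.min(times)) * 1e-3, float(np.max(times)) * 1e3
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if frac(mid) > target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate_cohort(spec: SyntheticCohortSpec) -> Cohort:
    """Draw one cohort; byte-identical for identical spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    P = spec.n_pathways
    drivers, signatures = _signatures(spec)
    passengers = [f"PSG_{i + 1}" for i in range(spec.passenger_sgas)]
    noise_degs = [f"DEG_N{i + 1}" for i in range(spec.noise_degs)]
    all_degs = sorted(set(g for sig in signatures for g in sig) | set(noise_degs))
    tumours = [f"T{i + 1:04d}" for i in range(spec.n_tumours)]

    group = rng.integers(0, P, size=spec.n_tumours)
    activation = np.zeros((spec.n_tumours, P))
    activation[np.arange(spec.n_tumours), group] = 1.0
    background = (rng.random((spec.n_tumours, P))
                  < spec.background_activation_rate)
    background[np.arange(spec.n_tumours), group] = False
    activation[background] = spec.background_activation_level

    assign_rows, obs_rows = [], []
    for t_idx, tumour in enumerate(tumours):
        assigned: set[str] = set()
        observed: set[str] = set()
        for p in range(P):
            if activation[t_idx, p] <= 0:
                # drivers can be observed as passengers of inactive pathways
                for d in drivers[p]:
                    if rng.random() < spec.driver_background_observation_rate:
                        observed.add(d)
                continue
            driver = drivers[p][rng.integers(0, len(drivers[p]))]
            observed.add(driver)
            candidates = [g for g in signatures[p] if g not in assigned]
            take = [g for g in candidates
                    if rng.random() < spec.assignment_rate]
            if len(take) < spec.min_assigned:
                rest = [g for g in candidates if g not in take]
                extra = rng.choice(len(rest),
                                   size=min(spec.min_assigned - len(take),
                                            len(rest)),
                                   replace=False)
                take += [rest[i] for i in np.sort(extra)]
            for g in take:
                posterior = rng.uniform(*spec.true_posterior)
                assign_rows.append((tumour, driver, g, posterior))
                assigned.add(g)
        for psg in passengers:
            if rng.random() >= spec.passenger_observation_rate:
                continue
            observed.add(psg)
            if rng.random() >= spec.passenger_assignment_rate:
                continue
            pool = [g for g in all_degs if g not in assigned]
            n_targets = int(rng.integers(1, spec.passenger_max_targets + 1))
            pick = rng.choice(len(pool), size=min(n_targets, len(pool)),
                              replace=False)
            for i in np.sort(pick):
                posterior = rng.uniform(*spec.noise_posterior)
                assign_rows.append((tumour, psg, pool[i], posterior))
                assigned.add(pool[i])
        for s in sorted(observed):
            obs_rows.append((tumour, s))

    assignments = pd.DataFrame(
        assign_rows, columns=["tumour_id", "sga", "deg", "posterior"])
    observations = pd.DataFrame(obs_rows, columns=["tumour_id", "sga"])

    expr = rng.normal(0.0, spec.expression_noise_sd,
                      size=(spec.n_tumours, len(all_degs)))
    col_index = {g: j for j, g in enumerate(all_degs)}
    for p in range(P):
        cols = [col_index[g] for g in signatures[p]]
        expr[:, cols] += spec.expression_effect * activation[:, [p]]
    expression = pd.DataFrame(expr, index=tumours, columns=all_degs)
    expression.index.name = "patient_id"
    if spec.platform_dropout > 0:
        n_drop = int(round(spec.platform_dropout * len(all_degs)))
        drop = rng.choice(len(all_degs), size=n_drop, replace=False)
        expression = expression.drop(
            columns=[all_degs[i] for i in np.sort(drop)])

    coefs = spec.coefficients()
    log_hazard = activation @ coefs
    rate = spec.baseline_hazard * np.exp(log_hazard)
    death = rng.exponential(1.0 / rate)
    c = _calibrate_censoring(death, spec.censoring_fraction)
    censor = rng.uniform(0.0, c, size=spec.n_tumours) if np.isfinite(c) \
        else np.full(spec.n_tumours, np.inf)
    time = np.minimum(death, censor)
    event = (death <= censor).astype(int)
    time = np.maximum(time, 1e-3)  # keep durations strictly positive
    survival = pd.DataFrame({"time": time, "event": event}, index=tumours)
    survival.index.name = "patient_id"

    age = 55.0 + spec.clinical_group_effect * group + rng.normal(0, 8, spec.n_tumours)
    centred = (group - (P - 1) / 2.0) / max(P - 1, 1)
    p1 = np.clip(0.5 + 0.1 * spec.clinical_group_effect * centred, 0.05, 0.95)
    marker1 = (rng.random(spec.n_tumours) < p1).astype(int)
    marker2 = (rng.random(spec.n_tumours) < 0.3).astype(int)
    clinical = pd.DataFrame({"age": age, "marker1": marker1,
                             "marker2": marker2}, index=tumours)
    clinical.index.name = "patient_id"

    truth = {
        "pathways": {
            str(p + 1): {"drivers": drivers[p], "signature": signatures[p]}
            for p in range(P)
        },
        "passengers": passengers,
        "patient_group": {t: int(g + 1) for t, g in zip(tumours, group)},
        "activation": {t: activation[i].tolist()
                       for i, t in enumerate(tumours)},
        "hazard_coefficients": coefs.tolist(),
        "baseline_hazard": spec.baseline_hazard,
        "spec": asdict(spec),
    }
    _assert_one_cause(assignments)
    return Cohort(assignments=assignments, observations=observations,
                  expression=expression, clinical=clinical,
                  survival=survival, truth=truth)


def _assert_one_cause(assignments: pd.DataFrame) -> None:
    multi = assignments.groupby(["tumour_id", "deg"])["sga"].nunique()
    if (multi > 1).any():
        raise AssertionError("generator violated the one-cause rule")


def truth_gene_sets(truth: dict) -> list[tuple[str, str, list[str]]]:
    """Planted signatures as (name, description, members) gene sets."""
    return [(f"PATHWAY_{p}", f"planted signature of pathway {p}",
             list(info["signature"]))
            for p, info in truth["pathways"].items()]


def write_cohort(cohort: Cohort, directory: str | Path) -> dict[str, Path]:
    """Write the six standard inputs plus ground-truth JSON."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {
        "assignments": directory / "assignments.tsv",
        "observations": directory / "observations.tsv",
        "expression": directory / "expression.tsv",
        "clinical": directory / "clinical.tsv",
        "survival": directory / "survival.tsv",
        "truth": directory / "truth.json",
    }
    cohort.assignments.to_csv(paths["assignments"], sep="\t", index=False)
    cohort.observations.to_csv(paths["observations"], sep="\t", index=False)
    cohort.expression.to_csv(paths["expression"], sep="\t")
    cohort.clinical.to_csv(paths["clinical"], sep="\t")
    cohort.survival.to_csv(paths["survival"], sep="\t")
    with open(paths["truth"], "w") as fh:
        json.dump(cohort.truth, fh, indent=1, sort_keys=True)
    return paths


def read_cohort(directory: str | Path) -> Cohort:
    directory = Path(directory)
    assignments = pd.read_csv(directory / "assignments.tsv", sep="\t")
    observations = pd.read_csv(directory / "observations.tsv", sep="\t")
    expression = pd.read_csv(directory / "expression.tsv", sep="\t",
                             index_col="patient_id")
    clinical = pd.read_csv(directory / "clinical.tsv", sep="\t",
                           index_col="patient_id")
    survival = pd.read_csv(directory / "survival.tsv", sep="\t",
                           index_col="patient_id")
    with open(directory / "truth.json") as fh:
        truth = json.load(fh)
    return Cohort(assignments=assignments, observations=observations,
                  expression=expression, clinical=clinical,
                  survival=survival, truth=truth)
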