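"""Filtering of tumour-specific SGA→DEG causal assignments.

Upstream causal inference assigns every differentially expressed gene (DEG)
in a tumour exactly one somatic genome alteration (SGA) as its cause, with a
posterior probability.  Most of those calls involve passenger alterations or
weak evidence.  Four successive standards reduce the raw table to a set of
*significant* drivers and *significant* SGA→DEG relationships:

1. keep assignments whose posterior exceeds a calibration floor;
2. call an SGA a *driver in a tumour* if it causes at least
   ``min_degs_per_driver`` DEGs there;
3. call an SGA a *significant driver* if it is a driver in at least
   ``min_driver_tumours`` tumours AND in at least ``min_driver_fraction`` of
   the tumours where it is observed as an SGA;
4. call (SGA, DEG) a *significant relationship* if the SGA is a significant
   driver AND the DEG is caused by it in at least
   ``min_relationship_tumours`` tumours OR in at least
   ``min_relationship_fraction`` of the tumours where the SGA is a driver.

Count thresholds are inclusive (>=); the posterior floor is strict (>).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

#: Column order of an assignment table.
ASSIGNMENT_COLUMNS = ["tumour_id", "sga", "deg", "posterior"]

#: Column order of an SGA observation table.
OBSERVATION_COLUMNS = ["tumour_id", "sga"]


@dataclass(frozen=True)
class FilterThresholds:
    """Thresholds of the four filtering standards.

    Defaults are the operating point used throughout: posterior floor 0.5
    (standard 1 is a calibration the upstream inference provides; here it is
    a supplied scalar), 5 DEGs per tumour-level driver call, 30 tumours and
    a 25% observed fraction for significant drivers, and 50 tumours or a 20%
    driver-tumour fraction for significant relationships.
    """

    posterior_floor: float = 0.5
    min_degs_per_driver: int = 5
    min_driver_tumours: int = 30
    min_driver_fraction: float = 0.25
    min_relationship_tumours: int = 50
    min_relationship_fraction: float = 0.20

    def __post_init__(self) -> None:
        if not 0.0 <= self.posterior_floor <= 1.0:
            raise ValueError("posterior_floor must lie in [0, 1]")
        for name in ("min_degs_per_driver", "min_driver_tumours",
                     "min_relationship_tumours"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("min_driver_fraction", "min_relationship_fraction"):
            value = getattr(self, name)
            if not 0.0 < value <= 1.0:
                raise ValueError(f"{name} must lie in (0, 1]")


def validate_assignments(assignments: pd.DataFrame) -> pd.DataFrame:
    """Validate an assignment table and collapse duplicate rows.

    Enforces the one-cause rule (within a tumour every DEG has at most one
    SGA assigned) and posterior in [0, 1].  Duplicate (tumour, sga, deg)
    rows are collapsed to the maximum posterior with a logged warning.
    """
    missing = [c for c in ASSIGNMENT_COLUMNS if c not in assignments.columns]
    if missing:
        raise ValueError(f"assignment table missing columns: {missing}")
    df = assignments.loc[:, ASSIGNMENT_COLUMNS]
    if len(df) == 0:
        return df.copy()
    if df["posterior"].lt(0).any() or df["posterior"].gt(1).any():
        raise ValueError("posterior values must lie in [0, 1]")
    dup = df.duplicated(subset=["tumour_id", "sga", "deg"])
    if dup.any():
        logger.warning("collapsing %d duplicate (tumour, sga, deg) rows "
                       "to max posterior", int(dup.sum()))
        df = (df.groupby(["tumour_id", "sga", "deg"], as_index=False, sort=False)
                .agg(posterior=("posterior", "max")))
    multi = df.groupby(["tumour_id", "deg"])["sga"].nunique()
    if (multi > 1).any():
        bad = multi[multi > 1].index[:5].tolist()
        raise ValueError(
            "one-cause rule violated: DEG with multiple SGA causes in one "
            f"tumour, e.g. {bad}")
    return df


def filter_valid(assignments: pd.DataFrame, posterior_floor: float) -> pd.DataFrame:
    """Standard 1: keep assignments with posterior strictly above the floor."""
    if not 0.0 <= posterior_floor <= 1.0:
        raise ValueError("posterior_floor must lie in [0, 1]")
    return assignments.loc[assignments["posterior"] > posterior_floor].copy()


def call_tumour_drivers(assignments: pd.DataFrame,
                        thresholds: FilterThresholds = FilterThresholds(),
                        ) -> set[tuple[str, str]]:
    """Standard 2: (tumour, sga) pairs where the SGA causes enough DEGs.

    ``assignments`` must already be posterior-filtered.
    """
    if len(assignments) == 0:
        return set()
    counts = assignments.groupby(["tumour_id", "sga"])["deg"].nunique()
    hits = counts[counts >= thresholds.min_degs_per_driver]
    return set(hits.index)


def call_significant_drivers(driver_calls: set[tuple[str, str]],
                             observations: pd.DataFrame,
                             thresholds: FilterThresholds = FilterThresholds(),
                             ) -> set[str]:
    """Standard 3: SGAs called driver often enough, absolutely and relatively.

    Both conditions must hold: driver in at least ``min_driver_tumours``
    tumours and in at least ``min_driver_fraction`` of the tumours where the
    SGA is observed as a somatic alteration.
    """
    if len(driver_calls) == 0:
        return set()
    obs = observations.drop_duplicates(subset=OBSERVATION_COLUMNS)
    observed_counts = obs.groupby("sga")["tumour_id"].nunique()
    driver_counts: dict[str, int] = {}
    for _t, s in driver_calls:
        driver_counts[s] = driver_counts.get(s, 0) + 1
    significant = set()
    for sga, n_driver in driver_counts.items():
        n_obs = int(observed_counts.get(sga, 0))
        if n_obs == 0:
            raise ValueError(
                f"SGA {sga!r} called driver but never observed: inconsistent "
                "assignment/observation tables")
        if (n_driver >= thresholds.min_driver_tumours
                and n_driver / n_obs >= thresholds.min_driver_fraction):
            significant.add(sga)
    return significant


def call_significant_relationships(assignments: pd.DataFrame,
                                   significant_drivers: set[str],
                                   driver_calls: set[tuple[str, str]],
                                   thresholds: FilterThresholds = FilterThresholds(),
                                   ) -> list[tuple[str, str]]:
    """Standard 4: (sga, deg) pairs supported in enough tumours.

    The SGA must be a significant driver, and the pair must be assigned in
    at least ``min_relationship_tumours`` tumours OR in at least
    ``min_relationship_fraction`` of the tumours where the SGA is called a
    driver (disjunction).
    """
    if len(assignments) == 0 or not significant_drivers:
        return []
    driver_tumours: dict[str, int] = {}
    for _t, s in driver_calls:
        driver_tumours[s] = driver_tumours.get(s, 0) + 1
    sub = assignments[assignments["sga"].isin(significant_drivers)]
    pair_counts = sub.groupby(["sga", "deg"])["tumour_id"].nunique()
    out = []
    for (sga, deg), n in pair_counts.items():
        n_driver = driver_tumours.get(sga, 0)
        absolute = n >= thresholds.min_relationship_tumours
        relative = (n_driver > 0
                    and n / n_driver >= thresholds.min_relationship_fraction)
        if absolute or relative:
            out.append((sga, deg))
    return sorted(out)


def project_to_significant(assignments: pd.DataFrame,
                           significant_relationships: list[tuple[str, str]],
                           ) -> pd.DataFrame:
    """Restrict the assignment table to significant (sga, deg) pairs.

    Tumours left with zero assignments simply disappear from the table and
    hence from downstream tumour counts.
    """
    if len(assignments) == 0 or not significant_relationships:
        return assignments.iloc[0:0].copy()
    keep = set(significant_relationships)
    mask = [
        (s, d) in keep
        for s, d in zip(assignments["sga"], assignments["deg"])
    ]
    return assignments.loc[mask].copy()


@dataclass
class FilterResult:
    """All intermediate and final products of the four standards."""

    valid: pd.DataFrame
    driver_calls: set[tuple[str, str]] = field(default_factory=set)
    significant_drivers: set[str] = field(default_factory=set)
    significant_relationships: list[tuple[str, str]] = field(default_factory=list)
    significant_assignments: pd.DataFrame | None = None


def apply_filters(assignments: pd.DataFrame,
                  observations: pd.DataFrame,
                  thresholds: FilterThresholds = FilterThresholds(),
                  ) -> FilterResult:
    """Run standards 1–4 in order and return every intermediate product."""
    assignments = validate_assignments(assignments)
    valid = filter_valid(assignments, thresholds.posterior_floor)
    logger.info("standard 1: %d/%d assignments above posterior floor %.3g",
                len(valid), len(assignments), thresholds.posterior_floor)
    driver_calls = call_tumour_drivers(valid, thresholds)
    significant_drivers = call_significant_drivers(
        driver_calls, observations, thresholds)
    relationships = call_significant_relationships(
        valid, significant_drivers, driver_calls, thresholds)
    significant = project_to_significant(valid, relationships)
    logger.info("standards 2-4: %d tumour-level driver calls, %d significant "
                "drivers, %d significant relationships, %d assignments kept",
                len(driver_calls), len(significant_drivers),
                len(relationships), len(significant))
    return FilterResult(
        valid=valid,
        driver_calls=driver_calls,
        significant_drivers=significant_drivers,
        significant_relationships=relationships,
        significant_assignments=significant,
    )
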