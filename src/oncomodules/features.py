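"""Patient feature construction from DEG modules and clinical covariates.

Each DEG module becomes one per-patient feature: the mean expression of the
module's *effective* DEGs (those present on the expression platform).
Clinical covariates (numerically encoded) are appended, and all retained
features are z-normalized across patients with the sample (n−1) standard
deviation.  Constant features are dropped with a warning.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def effective_degs(module_genes: set[str],
                   expression_genes: set[str]) -> list[str]:
    """Module members present on the expression platform, sorted."""
    eff = sorted(set(module_genes) & set(expression_genes))
    if not eff:
        logger.warning("module has no genes on the expression platform; "
                       "its feature will be skipped")
    return eff


def module_feature(expression: pd.DataFrame,
                   effective_set: list[str]) -> pd.Series:
    """Per-patient mean expression over the effective DEGs.

    ``expression`` is patients × genes.  Missing entries are excluded from
    that patient's mean; a patient missing every member gets NaN.
    """
    if not effective_set:
        raise ValueError("effective_set must be non-empty")
    sub = expression.loc[:, list(effective_set)]
    n_missing = int(sub.isna().sum().sum())
    if n_missing:
        logger.info("module feature: %d missing expression entries excluded "
                    "from per-patient means", n_missing)
    return sub.mean(axis=1, skipna=True)


def module_feature_table(expression: pd.DataFrame,
                         partition_labels: pd.Series) -> pd.DataFrame:
    """One column per module: mean expression of its effective DEGs."""
    platform = set(expression.columns)
    cols = {}
    for module, genes in partition_labels.groupby(partition_labels):
        eff = effective_degs(set(genes.index), platform)
        if not eff:
            continue
        cols[f"module_{int(module)}"] = module_feature(expression, eff)
    if not cols:
        raise ValueError("no module has genes on the expression platform")
    return pd.DataFrame(cols, index=expression.index)


@dataclass
class PatientFeatureTable:
    """Patients × features with per-column kind (module | clinical)."""

    values: pd.DataFrame
    kinds: dict[str, str] = field(default_factory=dict)
    normalized: bool = False

    def module_columns(self) -> list[str]:
        return [c for c in self.values.columns if self.kinds.get(c) == "module"]

    def clinical_columns(self) -> list[str]:
        return [c for c in self.values.columns if self.kinds.get(c) == "clinical"]

    def subset(self, kind: str) -> "PatientFeatureTable":
        cols = [c for c in self.values.columns if self.kinds.get(c) == kind]
        return PatientFeatureTable(
            values=self.values[cols].copy(),
            kinds={c: kind for c in cols},
            normalized=self.normalized)


def assemble_features(module_features: pd.DataFrame,
                      clinical: pd.DataFrame | None = None,
                      missing_policy: str = "complete",
                      ) -> PatientFeatureTable:
    """Join module features with clinical covariates on patient id.

    ``missing_policy`` is 'complete' (drop patients with any missing
    feature) or 'median' (impute per-feature medians).  Zero overlapping
    patients signals misaligned inputs.
    """
    kinds = {c: "module" for c in module_features.columns}
    if clinical is not None and len(clinical.columns):
        joined = module_features.join(clinical, how="inner")
        if len(joined) == 0:
            raise ValueError("no overlapping patients between module features "
                             "and clinical table")
        kinds.update({c: "clinical" for c in clinical.columns})
    else:
        joined = module_features.copy()
    n_missing = joined.isna().sum()
    if n_missing.any():
        logger.info("missingness per feature:\n%s",
                    n_missing[n_missing > 0].to_string())
    if missing_policy == "complete":
        before = len(joined)
        joined = joined.dropna(axis=0, how="any")
        if len(joined) < before:
            logger.warning("complete-case policy dropped %d/%d patients",
                           before - len(joined), before)
    elif missing_policy == "median":
        joined = joined.fillna(joined.median(axis=0))
    else:
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    return PatientFeatureTable(values=joined, kinds=kinds, normalized=False)


def zscore_normalize(table: PatientFeatureTable,
                     tol: float = 1e-12) -> PatientFeatureTable:
    """Per-feature (x − mean)/sd across patients, sample sd (ddof=1).

    Constant features are dropped with a warning.  Idempotent within
    numerical tolerance.
    """
    df = table.values
    if len(df) < 2:
        raise ValueError("need at least 2 patients to normalize")
    sd = df.std(axis=0, ddof=1)
    constant = sd.index[sd.abs() <= tol].tolist()
    if constant:
        logger.warning("dropping constant feature(s): %s", constant)
    keep = [c for c in df.columns if c not in constant]
    if not keep:
        raise ValueError("all features constant; nothing to normalize")
    values = (df[keep] - df[keep].mean(axis=0)) / sd[keep]
    kinds = {c: table.kinds.get(c, "module") for c in keep}
    return PatientFeatureTable(values=values, kinds=kinds, normalized=True)
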