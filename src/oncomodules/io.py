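"""Readers and writers for the pipeline's tab-separated table formats.

All tables are UTF-8 TSV with a header row; gene symbols are
case-preserved and matched case-sensitively.  Readers validate required
columns and report malformed rows with line numbers.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd

from .annotation import GeneSet
from .features import PatientFeatureTable

logger = logging.getLogger(__name__)


def _read_tsv(path: str | Path, required: list[str],
              dtypes: dict[str, type] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    if dtypes:
        for col, typ in dtypes.items():
            try:
                df[col] = df[col].astype(typ)
            except (TypeError, ValueError) as exc:
                bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
                lines = [int(i) + 2 for i in bad[:5]]  # +2: header + 1-based
                raise ValueError(
                    f"{path.name}: column {col!r} not {typ.__name__} "
                    f"(lines {lines})") from exc
    return df


def read_assignments(path: str | Path) -> pd.DataFrame:
    return _read_tsv(path, ["tumour_id", "sga", "deg", "posterior"],
                     {"posterior": float})


def read_observations(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["tumour_id", "sga"])
    dup = df.duplicated()
    if dup.any():
        logger.warning("observations: dropping %d duplicate rows",
                       int(dup.sum()))
        df = df.drop_duplicates()
    return df


def read_expression(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["patient_id"])
    if df["patient_id"].duplicated().any():
        raise ValueError(f"{Path(path).name}: duplicate patient_id keys")
    return df.set_index("patient_id")


def read_clinical(path: str | Path) -> pd.DataFrame:
    return read_expression(path)  # same shape: patient_id + numeric columns


def read_survival(path: str | Path) -> pd.DataFrame:
    df = _read_tsv(path, ["patient_id", "time", "event"],
                   {"time": float, "event": int})
    if df["patient_id"].duplicated().any():
        raise ValueError(f"{Path(path).name}: duplicate patient_id keys")
    return df.set_index("patient_id")


def read_module_labels(path: str | Path) -> pd.Series:
    df = _read_tsv(path, ["deg", "module"], {"module": int})
    return df.set_index("deg")["module"]


def write_module_labels(labels: pd.Series, path: str | Path) -> None:
    out = labels.rename("module").rename_axis("deg").reset_index()
    out.to_csv(path, sep="\t", index=False)


def read_group_labels(path: str | Path) -> pd.Series:
    df = _read_tsv(path, ["patient_id", "group"], {"group": int})
    return df.set_index("patient_id")["group"]


def write_group_labels(labels: pd.Series, path: str | Path) -> None:
    out = labels.rename("group").rename_axis("patient_id").reset_index()
    out.to_csv(path, sep="\t", index=False)


def write_features(table: PatientFeatureTable, path: str | Path) -> None:
    """Feature TSV with a leading ``#kind=`` row naming each column's kind."""
    path = Path(path)
    kinds = [table.kinds.get(c, "module") for c in table.values.columns]
    with open(path, "w") as fh:
        fh.write("#kind=\t" + "\t".join(kinds) + "\n")
        table.values.rename_axis("patient_id").to_csv(fh, sep="\t")


def read_features(path: str | Path) -> PatientFeatureTable:
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().rstrip("\n")
        if not first.startswith("#kind="):
            raise ValueError(f"{path.name}: missing '#kind=' header row")
        kinds_row = first.split("\t")[1:]
        df = pd.read_csv(fh, sep="\t", index_col="patient_id")
    if len(kinds_row) != len(df.columns):
        raise ValueError(f"{path.name}: kind row does not match columns")
    return PatientFeatureTable(values=df,
                               kinds=dict(zip(df.columns, kinds_row)),
                               normalized=True)


def read_gmt(path: str | Path) -> list[GeneSet]:
    """Standard GMT: name <tab> description <tab> member genes...

    Duplicate members within a set are deduplicated with a warning; lines
    with fewer than three fields are rejected with their line number.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: GMT line has fewer than 3 fields")
            name, description, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) < len(members):
                logger.warning("%s:%d: %d duplicate member(s) in %s "
                               "deduplicated", path.name, lineno,
                               len(members) - len(unique), name)
            sets.append(GeneSet(name=name, description=description,
                                genes=frozenset(unique)))
    return sets


def write_gmt(sets: list[tuple[str, str, list[str]]] | list[GeneSet],
              path: str | Path) -> None:
    with open(path, "w") as fh:
        for entry in sets:
            if isinstance(entry, GeneSet):
                name, desc, members = entry.name, entry.description, sorted(entry.genes)
            else:
                name, desc, members = entry
            fh.write("\t".join([name, desc, *members]) + "\n")


def sha256_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def write_json(obj: dict, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def read_json(path: str | Path) -> dict:
    with open(path) as fh:
        return json.load(fh)
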