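"""File formats, schemas and run manifests.

Cohort and intake tables travel as comma-delimited UTF-8 CSV with "." as the
decimal mark (Danish-locale decimal commas are rejected with a clear error),
accompanied by a YAML sidecar declaring per-column units so weekly-basis
components (fish, red meat, SSB) supplied as g/day are converted to g/week
on read.  Index definitions (the component cutoff table) round-trip through
YAML.  Every pipeline run emits a JSON manifest with the seed, a
configuration hash, input digests and stage tallies.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from datetime import datetime, timezone
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .scoring import ComponentRule, DANISH_HEI

__all__ = [
    "SchemaError",
    "INTAKE_UNIT_DEFAULTS",
    "read_intake_csv",
    "read_cohort_csv",
    "write_cohort_csv",
    "load_index_yaml",
    "dump_index_yaml",
    "default_index_path",
    "RunManifest",
    "config_hash",
    "file_digest",
]


class SchemaError(ValueError):
    """Input file does not match its declared schema."""


#: Canonical storage units per intake column.
INTAKE_UNIT_DEFAULTS: dict[str, str] = {
    "fruit": "g/day", "vegetables": "g/day", "dietary_fibre": "g/day",
    "fish": "g/week", "red_meat": "g/week", "ssb": "g/week",
    "sfa": "g/day", "sodium": "g/day", "added_sugar": "g/day",
    "energy": "kJ/day", "protein": "g/day", "fat": "g/day",
    "carbohydrate": "g/day",
}

_WEEKLY = {"fish", "red_meat", "ssb"}
_NA_MARKERS = ("", "NA", "NaN", "nan", ".", "missing")


def _read_numeric(df: pd.DataFrame, col: str, path) -> pd.Series:
    raw = df[col].astype(str).str.strip()
    has_comma = raw.str.contains(",", na=False)
    if has_comma.any():
        line = int(df.index[has_comma][0]) + 2  # header is line 1
        raise SchemaError(
            f"{path}: column {col!r} contains a decimal comma at line {line}; "
            "this reader requires '.' as the decimal mark")
    masked = raw.mask(raw.isin(_NA_MARKERS))
    coarse = pd.to_numeric(masked, errors="coerce")
    bad = coarse.isna() & masked.notna()
    if bad.any():
        line = int(df.index[bad][0]) + 2
        raise SchemaError(f"{path}: non-numeric value {raw[bad].iloc[0]!r} in "
                          f"column {col!r} at line {line}")
    # astype(float) parses via correctly-rounded float(), unlike to_numeric's
    # fast path, so written values round-trip bit-exactly
    return masked.astype(float)


def read_intake_csv(path, units: dict[str, str] | str | Path | None = None) -> pd.DataFrame:
    """Read a per-subject intake table, normalising units.

    ``units`` maps column names to their units in the file (or is a YAML
    sidecar path containing such a mapping under ``units:``); weekly-basis
    components declared as ``g/day`` are multiplied by 7.  Unknown columns
    raise a :class:`SchemaError` listing the unmatched names.
    """
    if isinstance(units, (str, Path)):
        with open(units) as fh:
            units = yaml.safe_load(fh).get("units", {})
    units = dict(units or {})
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    known = set(INTAKE_UNIT_DEFAULTS) | {"subject_id"}
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise SchemaError(f"{path}: unknown column(s) {unknown}; expected a subset "
                          f"of {sorted(known)}")
    out = pd.DataFrame()
    if "subject_id" in df.columns:
        out["subject_id"] = df["subject_id"]
    for col in df.columns:
        if col == "subject_id":
            continue
        vals = _read_numeric(df, col, path)
        declared = units.get(col, INTAKE_UNIT_DEFAULTS[col])
        if col in _WEEKLY and declared == "g/day":
            vals = vals * 7.0
        elif col in _WEEKLY and declared not in ("g/week",):
            raise SchemaError(f"{path}: column {col!r} must be g/day or g/week, "
                              f"got {declared!r}")
        out[col] = vals
    return out


_COHORT_NUMERIC = {
    "maternal_hei", "offspring_hei", "maternal_age", "prepregnancy_bmi",
    "maternal_energy", "offspring_energy", "offspring_age",
}
_COHORT_BOOL = {"multiple_birth", "vegetarian", "participated"}


def read_cohort_csv(path) -> pd.DataFrame:
    """Read a cohort table with typed columns and explicit missing markers."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    out = pd.DataFrame(index=df.index)
    for col in df.columns:
        if col in _COHORT_NUMERIC or col.startswith("m_"):
            out[col] = _read_numeric(df, col, path)
        elif col in _COHORT_BOOL:
            out[col] = df[col].str.strip().str.lower().map(
                {"true": True, "false": False, "1": True, "0": False})
        else:
            out[col] = df[col].replace(list(_NA_MARKERS), np.nan)
    return out


def write_cohort_csv(df: pd.DataFrame, path) -> None:
    """Write a cohort table: UTF-8, comma-delimited, full float precision
    (shortest round-trip representation)."""
    df.to_csv(path, index=False, encoding="utf-8")


# ---------------------------------------------------------------------------
# Index YAML

def default_index_path() -> Path:
    """Path of the built-in Danish HEI definition YAML."""
    return Path(str(resources.files("dkhei").joinpath("data/danish_hei.yaml")))


def load_index_yaml(path=None) -> tuple[ComponentRule, ...]:
    """Load an index definition (defaults to the built-in Danish HEI)."""
    if path is None:
        path = default_index_path()
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    rules = []
    for entry in doc["components"]:
        rules.append(ComponentRule(
            name=entry["name"], direction=entry["direction"],
            zero_point=float(entry["zero_point"]), full_point=float(entry["full_point"]),
            basis=entry.get("basis", "grams"), period=entry.get("period", "day"),
            energy_factor=entry.get("energy_factor")))
    return tuple(rules)


def dump_index_yaml(index, path) -> None:
    """Write an index definition; load(dump(load(x))) == load(x)."""
    doc = {"components": []}
    for r in index:
        entry = {"name": r.name, "direction": r.direction,
                 "zero_point": r.zero_point, "full_point": r.full_point,
                 "basis": r.basis, "period": r.period}
        if r.energy_factor is not None:
            entry["energy_factor"] = r.energy_factor
        doc["components"].append(entry)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Manifests

def file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def config_hash(obj) -> str:
    """Stable hash of a JSON-serialisable configuration object."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()[:16]


@dataclass
class RunManifest:
    """Reproducibility record emitted by every pipeline run."""

    command: str
    seed: int | None = None
    config_hash: str | None = None
    inputs: dict = field(default_factory=dict)       # path -> sha256
    exclusion_tally: dict = field(default_factory=dict)
    imputation_log: dict = field(default_factory=dict)
    counts: dict = field(default_factory=dict)       # stage -> rows in/out
    software_version: str = ""
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat())

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=str)
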