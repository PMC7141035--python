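"""Delimited-text readers and writers and the run configuration.

All tables are UTF-8, comma-delimited, '.'-decimal; parsing is
locale-independent. Species lists are long format with header
``reserve_id,species,order[,affinity]``; the reserve covariate table header
must match the covariate field names exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .covariates import RESERVE_COLUMNS
from .tree import Assemblage

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Settings for an end-to-end run; every stage reads only from here."""

    tree_path: str | None = None
    species_lists_path: str | None = None
    reserves_path: str | None = None
    output_dir: str = "phyloldg_out"
    seed: int = 0
    n_trees: int = 200
    moran_classes: int = 10
    moran_permutations: int = 999
    rd_convention: str = "root-inclusive"   # or "edge-count"
    log_richness: bool = True
    verbosity: int = 0

    _KNOWN = None  # populated below

    @classmethod
    def from_mapping(cls, mapping: dict) -> "RunConfig":
        known = {f.name for f in cls.__dataclass_fields__.values()
                 if not f.name.startswith("_")}
        unknown = set(mapping) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        """Flat ``key = value`` (or ``key: value``) config file."""
        mapping: dict = {}
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            sep = "=" if "=" in line else (":" if ":" in line else None)
            if sep is None:
                raise ValueError(f"{path}:{lineno}: expected 'key = value'")
            key, _, value = line.partition(sep)
            key, value = key.strip(), value.strip()
            if key in ("seed", "n_trees", "moran_classes", "moran_permutations",
                       "verbosity"):
                mapping[key] = int(value)
            elif key == "log_richness":
                mapping[key] = value.lower() in ("1", "true", "on", "yes")
            else:
                mapping[key] = value
        return cls.from_mapping(mapping)


def read_reserves(path) -> pd.DataFrame:
    """Read and validate the per-reserve covariate table."""
    df = pd.read_csv(path, encoding="utf-8")
    missing = [c for c in RESERVE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    numeric = [c for c in RESERVE_COLUMNS if c != "reserve_id"]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} "
                f"in column {col!r}, data row {row + 1}")
        df[col] = converted
    if df["reserve_id"].duplicated().any():
        dup = df["reserve_id"][df["reserve_id"].duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicate reserve_id {dup!r}")
    logger.info("read %d reserve records from %s", len(df), path)
    return df


def write_reserves(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, encoding="utf-8")


def read_species_lists(path) -> dict[str, Assemblage]:
    """Read long-format species lists into one Assemblage per reserve."""
    df = pd.read_csv(path, encoding="utf-8", dtype=str)
    required = ["reserve_id", "species", "order"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s): {', '.join(missing)}")
    has_affinity = "affinity" in df.columns
    if not has_affinity:
        logger.warning("%s: no 'affinity' column; affinity analyses disabled", path)
    dup = df.duplicated(subset=["reserve_id", "species"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValueError(f"{path}: duplicate record for species {r['species']!r} "
                         f"in reserve {r['reserve_id']!r}")
    # a species must not straddle orders across reserves
    per_species = df.groupby("species")["order"].nunique()
    conflicted = per_species[per_species > 1]
    if len(conflicted):
        raise ValueError(f"{path}: species {conflicted.index[0]!r} assigned to "
                         "multiple orders")
    out: dict[str, Assemblage] = {}
    for rid, grp in df.groupby("reserve_id", sort=True):
        affinities = (tuple(a if isinstance(a, str) and a else None
                            for a in grp["affinity"])
                      if has_affinity else ())
        out[str(rid)] = Assemblage(
            reserve_id=str(rid),
            species=tuple(grp["species"]),
            orders=tuple(grp["order"]),
            affinities=affinities,
        )
    logger.info("read %d assemblages from %s", len(out), path)
    return out


def write_species_lists(assemblages: dict[str, Assemblage], path) -> None:
    rows = []
    any_aff = any(a.has_affinities for a in assemblages.values())
    for rid in sorted(assemblages):
        a = assemblages[rid]
        for i, sp in enumerate(a.species):
            row = {"reserve_id": rid, "species": sp, "order": a.orders[i]}
            if any_aff:
                row["affinity"] = (a.affinities[i] or "") if a.affinities else ""
            rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, encoding="utf-8")


def write_json_report(obj, path) -> None:
    """Deterministic JSON (sorted keys, fixed float formatting via repr)."""
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")


def _jsonable(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if hasattr(o, "to_dict"):
        return o.to_dict()
    if hasattr(o, "__dataclass_fields__"):
        return asdict(o)
    raise TypeError(f"not JSON-serializable: {type(o)}")
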