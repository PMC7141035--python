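"""Composition helpers tying assemblages, trees, and covariates together.

These produce the per-reserve summary table (richness per group, MRD per
group) consumed by the gradient and importance stages, and the end-to-end
runner used by the command-line interface.
"""

from __future__ import annotations

import logging
from typing import Mapping

import numpy as np
import pandas as pd

from .tree import (Assemblage, CladeOriginTable, DEFAULT_CLADE_ORIGINS, MRDError,
                   OrderTree, group_richness, mean_root_distance, parse_newick,
                   root_distances)

logger = logging.getLogger(__name__)

GROUP_COLUMNS = [
    "richness_total", "richness_Oriental", "richness_Palearctic",
    "richness_widespread", "richness_warm", "richness_cold",
    "mrd", "mrd_warm", "mrd_cold",
]


def _subset(assemblage: Assemblage, keep: list[int]) -> Assemblage | None:
    if not keep:
        return None
    return Assemblage(
        reserve_id=assemblage.reserve_id,
        species=tuple(assemblage.species[i] for i in keep),
        orders=tuple(assemblage.orders[i] for i in keep),
        affinities=(tuple(assemblage.affinities[i] for i in keep)
                    if assemblage.affinities else ()),
    )


def summarize_assemblages(
    assemblages: Mapping[str, Assemblage],
    rd: Mapping[str, int],
    origins: CladeOriginTable = DEFAULT_CLADE_ORIGINS,
) -> pd.DataFrame:
    """Per-reserve richness (total, per affinity, warm/cold clades) and MRD
    (overall and per thermal-origin clade). Missing groups yield 0 richness
    and NaN MRD."""
    rows = []
    for rid in sorted(assemblages):
        a = assemblages[rid]
        row: dict = {"reserve_id": rid, "richness_total": len(a)}
        if a.has_affinities:
            counts, _ = group_richness(a, "affinity")
        else:
            counts = {}
        for aff in ("Oriental", "Palearctic", "widespread"):
            row[f"richness_{aff}"] = counts.get(aff, 0)
        thermal_counts, _ = group_richness(a, "thermal", origins)
        row["richness_warm"] = thermal_counts.get("warm", 0)
        row["richness_cold"] = thermal_counts.get("cold", 0)
        try:
            row["mrd"] = mean_root_distance(a, rd).mrd
        except MRDError:
            row["mrd"] = np.nan
        for cls in ("warm", "cold"):
            keep = [i for i, o in enumerate(a.orders)
                    if origins.thermal_class(o) == cls]
            sub = _subset(a, keep)
            try:
                row[f"mrd_{cls}"] = mean_root_distance(sub, rd).mrd if sub else np.nan
            except MRDError:
                row[f"mrd_{cls}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def reserve_summaries(dataset, convention: str = "root-inclusive") -> pd.DataFrame:
    """Summary table for a synthetic dataset: covariates + group richness + MRD."""
    tree = parse_newick(dataset.tree_newick)
    rd = root_distances(tree, convention)
    records = dataset.species_records()
    assemblages: dict[str, Assemblage] = {}
    for rid, grp in records.groupby("reserve_id", sort=True):
        assemblages[str(rid)] = Assemblage(
            reserve_id=str(rid), species=tuple(grp["species"]),
            orders=tuple(grp["order"]), affinities=tuple(grp["affinity"]),
        )
    # reserves with no species at all still appear, with zero richness
    summary = summarize_assemblages(assemblages, rd)
    merged = dataset.reserves.merge(summary, on="reserve_id", how="left")
    for col in GROUP_COLUMNS:
        if col.startswith("richness"):
            merged[col] = merged[col].fillna(0).astype(int)
    return merged
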