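"""Order-level phylogeny handling and mean root distance (MRD).

Root distance (RD) is the node-count depth of a tip in a rooted tree: the
number of internal nodes on the root-to-tip path, ignoring branch lengths.
MRD of an assemblage is the arithmetic mean of RD over its species, each
species scored by the RD of its order. Higher MRD means the assemblage is,
on average, drawn from more derived (younger) clades.

Two RD conventions are supported:

* ``"root-inclusive"`` (default): the root counts, so every tip of a star
  tree has RD 1.
* ``"edge-count"``: the root is excluded (star-tree tips get RD 0).

The two differ by exactly 1 for every tip, so MRD differences between
assemblages and latitudinal MRD slopes are convention-invariant.
"""

from __future__ import annotations

import io
import logging
import warnings
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import dendropy

logger = logging.getLogger(__name__)

RD_CONVENTIONS = ("root-inclusive", "edge-count")

#: Origination windows (Ma before present) defining thermal-origin classes:
#: orders arising in the Late Carboniferous / Early Permian cold interval are
#: "cold" clades; orders arising in the Triassic-Jurassic warm interval are
#: "warm" clades.
COLD_WINDOW_MA = (274.0, 320.0)
WARM_WINDOW_MA = (145.0, 250.0)


class NewickParseError(ValueError):
    """Raised for malformed newick input (position/label named when known)."""


class MRDError(ValueError):
    """Raised when MRD cannot be computed (e.g. no scorable species)."""


@dataclass(frozen=True)
class OrderTree:
    """A rooted order-level phylogeny (polytomies permitted).

    Thin wrapper over a :class:`dendropy.Tree`; tip labels are the order
    names and are guaranteed unique and nonempty.
    """

    _tree: dendropy.Tree
    tips: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.tips)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree


def parse_newick(text: str) -> OrderTree:
    """Parse a newick string into an :class:`OrderTree`.

    Branch lengths are tolerated and ignored. Raises
    :class:`NewickParseError` on syntax errors, empty input, empty tip
    labels, or duplicate tips (the offending label is named).
    """
    if not text or not text.strip():
        raise NewickParseError("empty newick string")
    stripped = text.strip()
    if not stripped.endswith(";"):
        raise NewickParseError("newick string must end with ';'")
    if stripped.count("(") != stripped.count(")"):
        raise NewickParseError(
            f"unbalanced parentheses: {stripped.count('(')} '(' vs "
            f"{stripped.count(')')} ')'"
        )
    try:
        tree = dendropy.Tree.get(
            data=stripped,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"newick syntax error: {exc}") from exc

    labels = [leaf.taxon.label if leaf.taxon else "" for leaf in tree.leaf_node_iter()]
    for label in labels:
        if not label:
            raise NewickParseError("tip with empty label")
    dupes = [lab for lab, k in Counter(labels).items() if k > 1]
    if dupes:
        raise NewickParseError(f"duplicate tip label: {dupes[0]!r}")
    return OrderTree(_tree=tree, tips=tuple(labels))


def read_tree(path) -> OrderTree:
    """Read a newick tree from a file path."""
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def root_distances(tree: OrderTree, convention: str = "root-inclusive") -> dict[str, int]:
    """Node-count root distance for every tip.

    With the default root-inclusive convention RD(tip) is the number of
    internal nodes on the root-to-tip path including the root, so RD >= 1;
    the ``"edge-count"`` convention subtracts 1 (root excluded).
    """
    if convention not in RD_CONVENTIONS:
        raise ValueError(f"unknown RD convention {convention!r}; use one of {RD_CONVENTIONS}")
    offset = 0 if convention == "root-inclusive" else -1
    rd: dict[str, int] = {}
    for leaf in tree.dendropy_tree.leaf_node_iter():
        # every ancestor of a leaf is an internal node; ancestor_iter
        # includes the root (inclusive=False excludes the leaf itself)
        depth = sum(1 for _ in leaf.ancestor_iter(inclusive=False))
        rd[leaf.taxon.label] = depth + offset
    if not rd:
        raise ValueError("tree has no tips")
    return rd


@dataclass(frozen=True)
class Assemblage:
    """Species records of one reserve: (species, order, optional affinity)."""

    reserve_id: str
    species: tuple[str, ...]
    orders: tuple[str, ...]
    affinities: tuple[str | None, ...] = ()

    def __post_init__(self):
        if len(self.species) != len(self.orders):
            raise ValueError("species and orders must have equal length")
        if self.affinities and len(self.affinities) != len(self.species):
            raise ValueError("affinities length mismatch")
        dupes = [s for s, k in Counter(self.species).items() if k > 1]
        if dupes:
            raise ValueError(
                f"duplicate species {dupes[0]!r} in reserve {self.reserve_id!r}"
            )
        if any(not o for o in self.orders):
            raise ValueError("empty order name")

    def __len__(self) -> int:
        return len(self.species)

    @property
    def has_affinities(self) -> bool:
        return bool(self.affinities) and any(a is not None for a in self.affinities)


@dataclass(frozen=True)
class MRDResult:
    reserve_id: str
    mrd: float
    n_scored: int
    n_excluded: int
    excluded_orders: tuple[str, ...] = ()


def mean_root_distance(assemblage: Assemblage, rd: Mapping[str, int]) -> MRDResult:
    """Mean root distance of an assemblage.

    Species are weighted equally; species whose order is absent from ``rd``
    are excluded (with a warning) and counted in ``n_excluded``. Raises
    :class:`MRDError` if no species can be scored.
    """
    if len(assemblage) == 0:
        raise MRDError(f"assemblage {assemblage.reserve_id!r} is empty")
    scored = [rd[o] for o in assemblage.orders if o in rd]
    excluded = sorted({o for o in assemblage.orders if o not in rd})
    n_excluded = sum(1 for o in assemblage.orders if o not in rd)
    if not scored:
        raise MRDError(f"no scorable species in reserve {assemblage.reserve_id!r}")
    if n_excluded:
        logger.warning(
            "reserve %s: %d species in orders absent from the tree excluded (%s)",
            assemblage.reserve_id, n_excluded, ", ".join(excluded),
        )
    return MRDResult(
        reserve_id=assemblage.reserve_id,
        mrd=sum(scored) / len(scored),
        n_scored=len(scored),
        n_excluded=n_excluded,
        excluded_orders=tuple(excluded),
    )


# -- warm/cold geohistorical-origin clades -----------------------------------

@dataclass(frozen=True)
class CladeOriginTable:
    """Order -> origination age (Ma) with derived thermal-origin class."""

    ages_ma: Mapping[str, float]

    def thermal_class(self, order: str) -> str:
        age = self.ages_ma.get(order)
        if age is None:
            return "unclassified"
        if COLD_WINDOW_MA[0] <= age <= COLD_WINDOW_MA[1]:
            return "cold"
        if WARM_WINDOW_MA[0] <= age <= WARM_WINDOW_MA[1]:
            return "warm"
        return "unclassified"


#: Origination ages of the six species-rich orders used to delimit the warm
#: (Triassic-Jurassic) and cold (Late Carboniferous-Early Permian) clades.
DEFAULT_CLADE_ORIGINS = CladeOriginTable(ages_ma={
    "Hemiptera": 310.0,
    "Coleoptera": 282.0,
    "Hymenoptera": 250.0,
    "Orthoptera": 215.0,
    "Diptera": 170.0,
    "Lepidoptera": 156.0,
})


def classify_thermal_origin(order: str, table: CladeOriginTable = DEFAULT_CLADE_ORIGINS) -> str:
    """Classify an order as "warm", "cold", or "unclassified"."""
    return table.thermal_class(order)


def group_richness(
    assemblage: Assemblage,
    grouping: str,
    origins: CladeOriginTable = DEFAULT_CLADE_ORIGINS,
) -> tuple[dict[str, int], int]:
    """Count species per group within one assemblage.

    ``grouping`` is ``"thermal"`` (warm/cold via the clade-origin table) or
    ``"affinity"`` (Oriental/Palearctic/widespread labels on the records).
    Returns ``(counts, n_unclassified)``; counts sum to the number of
    classifiable species.
    """
    if grouping == "thermal":
        counts: Counter[str] = Counter()
        unclassified = 0
        for order in assemblage.orders:
            cls = origins.thermal_class(order)
            if cls == "unclassified":
                unclassified += 1
            else:
                counts[cls] += 1
        return dict(counts), unclassified
    if grouping == "affinity":
        if not assemblage.has_affinities:
            raise ValueError(
                f"reserve {assemblage.reserve_id!r} has no affinity labels"
            )
        counts = Counter()
        unclassified = 0
        for aff in assemblage.affinities:
            if aff is None or aff == "":
                unclassified += 1
            else:
                counts[aff] += 1
        return dict(counts), unclassified
    raise ValueError(f"unknown grouping {grouping!r}; use 'thermal' or 'affinity'")
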