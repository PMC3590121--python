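"""Turn raw branch-harvest records into the observation table the model fits.

Field crews record, for every branch segment at or above the minimum
measurable diameter, the segment's own wet wood mass and wet leaf mass.
The allometric model instead relates a branch's diameter to *everything
the branch carries*: its length, and the dry stem, leaf and total
aboveground biomass of its entire downstream subtree.  Preprocessing
therefore (1) sums segment masses over each branch's descendants,
(2) converts wet to dry mass with species-specific dry:wet ratios,
(3) forms aboveground mass as stem + leaf, (4) applies the minimum
diameter filter, and (5) natural-log transforms the four traits.

Trait column order everywhere in this package is
``("length", "ag_mass", "stem_mass", "leaf_mass")``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import networkx as nx
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: canonical trait order: branch length, aboveground (total) dry mass,
#: stem dry mass, leaf dry mass
TRAITS: tuple[str, ...] = ("length", "ag_mass", "stem_mass", "leaf_mass")
N_TRAITS = len(TRAITS)

#: required columns of a branch-record table / CSV
RECORD_COLUMNS: tuple[str, ...] = (
    "species_id",
    "tree_id",
    "branch_id",
    "parent_id",
    "diameter_cm",
    "length_m",
    "wood_wet_kg",
    "leaf_wet_kg",
)


class TopologyError(ValueError):
    """Branch topology is not a rooted tree (cycle, orphan, or multi-root)."""


@dataclass
class BranchTopology:
    """Rooted branching structure of a single tree.

    ``parent[i]`` is the index of branch *i*'s parent; the root (main
    stem) has parent ``-1``.  ``diameter`` optionally carries the latent
    branch diameters; generated topologies guarantee strict
    parent-to-daughter diameter decrease.
    """

    parent: np.ndarray
    diameter: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.parent = np.asarray(self.parent, dtype=int)
        if self.diameter is not None:
            self.diameter = np.asarray(self.diameter, dtype=float)
            if self.diameter.shape != self.parent.shape:
                raise TopologyError("diameter and parent length mismatch")
        self.validate()

    @property
    def n_branches(self) -> int:
        return self.parent.size

    def validate(self) -> None:
        n = self.parent.size
        if n == 0:
            raise TopologyError("empty topology")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1:
            raise TopologyError(f"expected exactly one root, found {roots.size}")
        if np.any(self.parent >= n):
            raise TopologyError("parent index out of range")
        g = nx.DiGraph()
        g.add_nodes_from(range(n))
        g.add_edges_from(
            (int(p), int(c)) for c, p in enumerate(self.parent) if p >= 0
        )
        if not nx.is_directed_acyclic_graph(g):
            raise TopologyError("branch topology contains a cycle")
        if n > 1 and not nx.is_weakly_connected(g):
            raise TopologyError("branch topology is not connected")

    def children(self) -> list[list[int]]:
        kids: list[list[int]] = [[] for _ in range(self.n_branches)]
        for c, p in enumerate(self.parent):
            if p >= 0:
                kids[int(p)].append(c)
        return kids

    def topological_order(self) -> np.ndarray:
        """Root-first order; every node appears after its parent."""
        kids = self.children()
        root = int(np.flatnonzero(self.parent < 0)[0])
        order = []
        stack = [root]
        while stack:
            v = stack.pop()
            order.append(v)
            stack.extend(kids[v])
        if len(order) != self.n_branches:
            raise TopologyError("unreachable branches in topology")
        return np.asarray(order, dtype=int)


def to_dry_mass(wet_mass, ratio):
    """Convert wet mass to dry mass with a species dry:wet ratio in (0, 1]."""
    ratio = np.asarray(ratio, dtype=float)
    if np.any(ratio <= 0.0) or np.any(ratio > 1.0):
        raise ValueError(f"dry:wet ratio must lie in (0, 1], got {ratio}")
    wet = np.asarray(wet_mass, dtype=float)
    if np.any(wet < 0.0):
        raise ValueError("wet mass must be non-negative")
    out = wet * ratio
    return float(out) if out.ndim == 0 else out


def aggregate_downstream(topology: BranchTopology, segment_masses) -> np.ndarray:
    """Sum per-segment masses over each branch's downstream subtree.

    ``aggregated[i]`` = segment mass of *i* plus the aggregated mass of
    all of *i*'s daughters; the root aggregate is the tree total.
    """
    m = np.asarray(segment_masses, dtype=float)
    if m.shape != (topology.n_branches,):
        raise ValueError("one segment mass per branch required")
    if np.any(~np.isfinite(m)) or np.any(m < 0.0):
        raise ValueError("segment masses must be finite and non-negative")
    agg = m.copy()
    parent = topology.parent
    for v in topology.topological_order()[::-1]:
        p = parent[v]
        if p >= 0:
            agg[p] += agg[v]
    return agg


@dataclass
class ObservationTable:
    """Log-scale 4-trait observation matrix with species/tree indices.

    Rows are canonicalized on construction: stably sorted so that
    observations of one tree are contiguous and trees are grouped by
    species (species and tree codes follow first appearance).  Column
    order of ``log_traits`` is :data:`TRAITS`.
    """

    diameter: np.ndarray
    log_traits: np.ndarray
    species_idx: np.ndarray
    tree_idx: np.ndarray
    species_labels: tuple
    tree_labels: tuple
    tree_species: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.diameter = np.asarray(self.diameter, dtype=float)
        self.log_traits = np.asarray(self.log_traits, dtype=float)
        self.species_idx = np.asarray(self.species_idx, dtype=int)
        self.tree_idx = np.asarray(self.tree_idx, dtype=int)
        self.tree_species = np.asarray(self.tree_species, dtype=int)
        n = self.diameter.size
        if self.log_traits.shape != (n, N_TRAITS):
            raise ValueError("log_traits must be (n_obs, 4)")
        if not (np.all(np.isfinite(self.log_traits)) and np.all(np.isfinite(self.diameter))):
            raise ValueError("non-finite entries in observation table")
        if np.any(self.diameter <= 0.0):
            raise ValueError("diameters must be positive")
        # every tree maps to exactly one species
        for t in range(len(self.tree_labels)):
            sp = np.unique(self.species_idx[self.tree_idx == t])
            if sp.size > 1:
                raise ValueError(f"tree {self.tree_labels[t]!r} spans several species")
            if sp.size == 1 and sp[0] != self.tree_species[t]:
                raise ValueError("tree_species inconsistent with row indices")
        self._canonicalize()

    def _canonicalize(self) -> None:
        order = np.lexsort((self.tree_idx, self.species_idx))
        if not np.array_equal(order, np.arange(order.size)):
            self.diameter = self.diameter[order]
            self.log_traits = self.log_traits[order]
            self.species_idx = self.species_idx[order]
            self.tree_idx = self.tree_idx[order]
        # renumber trees by first appearance so tree blocks are contiguous
        # and tree_species is non-decreasing
        first = pd.unique(self.tree_idx)
        if not np.array_equal(first, np.arange(len(self.tree_labels))):
            remap = {old: new for new, old in enumerate(first)}
            self.tree_idx = np.asarray([remap[t] for t in self.tree_idx], dtype=int)
            self.tree_labels = tuple(self.tree_labels[old] for old in first)
            self.tree_species = self.tree_species[first]

    @property
    def n_obs(self) -> int:
        return self.diameter.size

    @property
    def n_trees(self) -> int:
        return len(self.tree_labels)

    @property
    def n_species(self) -> int:
        return len(self.species_labels)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "species": [self.species_labels[s] for s in self.species_idx],
                "tree": [self.tree_labels[t] for t in self.tree_idx],
                "diameter_cm": self.diameter,
            }
        )
        for j, name in enumerate(TRAITS):
            df[f"log_{name}"] = self.log_traits[:, j]
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ObservationTable":
        cols = ["species", "tree", "diameter_cm"] + [f"log_{t}" for t in TRAITS]
        missing = set(cols) - set(df.columns)
        if missing:
            raise ValueError(f"observation frame missing columns {sorted(missing)}")
        sp_codes, sp_labels = pd.factorize(df["species"])
        tr_codes, tr_labels = pd.factorize(df["tree"])
        tree_species = np.zeros(len(tr_labels), dtype=int)
        tree_species[tr_codes] = sp_codes
        return cls(
            diameter=df["diameter_cm"].to_numpy(float),
            log_traits=df[[f"log_{t}" for t in TRAITS]].to_numpy(float),
            species_idx=sp_codes,
            tree_idx=tr_codes,
            species_labels=tuple(sp_labels),
            tree_labels=tuple(tr_labels),
            tree_species=tree_species,
        )


def _tree_topology_from_records(group: pd.DataFrame) -> BranchTopology:
    ids = list(group["branch_id"])
    if len(set(ids)) != len(ids):
        raise TopologyError("duplicate branch ids within a tree")
    index = {b: i for i, b in enumerate(ids)}
    parent = np.empty(len(ids), dtype=int)
    for i, p in enumerate(group["parent_id"]):
        if p is None or (isinstance(p, float) and np.isnan(p)) or p == "":
            parent[i] = -1
        else:
            if p not in index:
                raise TopologyError(
                    f"parent_id {p!r} of branch {ids[i]!r} not found in tree"
                )
            parent[i] = index[p]
    return BranchTopology(parent)


def filter_and_log(
    records: pd.DataFrame,
    ratios: Mapping[str, float],
    min_diameter: float = 2.0,
    aggregate: bool | str = "auto",
) -> ObservationTable:
    """Build the log-scale observation table from branch records.

    Parameters
    ----------
    records
        Branch-record table with columns :data:`RECORD_COLUMNS`.
    ratios
        Species-specific dry:wet mass ratios in (0, 1].
    min_diameter
        Inclusive lower diameter bound in cm; smaller branches are dropped
        *after* aggregation, so their mass still counts toward ancestors.
    aggregate
        Whether segment masses must be summed downstream first.  ``"auto"``
        aggregates when any parent link is present.  Pass ``False`` for
        tables whose masses are already subtree aggregates.
    """
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns {sorted(missing)}")
    for sp in pd.unique(records["species_id"]):
        if sp not in ratios:
            raise KeyError(f"no dry:wet ratio for species {sp!r}")

    df = records.reset_index(drop=True).copy()
    n_in = len(df)

    if aggregate == "auto":
        aggregate = bool(df["parent_id"].notna().any())
    if aggregate:
        wood = np.empty(n_in)
        leaf = np.empty(n_in)
        for _, group in df.groupby("tree_id", sort=False):
            topo = _tree_topology_from_records(group)
            idx = group.index.to_numpy()
            wood[idx] = aggregate_downstream(topo, group["wood_wet_kg"].to_numpy(float))
            leaf[idx] = aggregate_downstream(topo, group["leaf_wet_kg"].to_numpy(float))
    else:
        wood = df["wood_wet_kg"].to_numpy(float)
        leaf = df["leaf_wet_kg"].to_numpy(float)

    ratio_per_row = df["species_id"].map(dict(ratios)).to_numpy(float)
    stem_dry = to_dry_mass(wood, ratio_per_row)
    leaf_dry = to_dry_mass(leaf, ratio_per_row)
    ag_dry = stem_dry + leaf_dry

    diam = df["diameter_cm"].to_numpy(float)
    keep_diam = diam >= min_diameter
    n_small = int((~keep_diam).sum())

    traits = np.column_stack(
        [df["length_m"].to_numpy(float), ag_dry, stem_dry, leaf_dry]
    )
    positive = np.all(traits > 0.0, axis=1) & np.isfinite(traits).all(axis=1)
    n_nonpos = int((keep_diam & ~positive).sum())
    if n_nonpos:
        log.warning(
            "dropping %d observation(s) with non-positive trait values "
            "(log-scale model requires positive traits)",
            n_nonpos,
        )
    keep = keep_diam & positive

    kept = df.loc[keep]
    sp_codes, sp_labels = pd.factorize(kept["species_id"])
    tr_codes, tr_labels = pd.factorize(kept["tree_id"])
    tree_species = np.zeros(len(tr_labels), dtype=int)
    tree_species[tr_codes] = sp_codes

    meta = {
        "rows_in": n_in,
        "rows_out": int(keep.sum()),
        "dropped_below_min_diameter": n_small,
        "dropped_nonpositive_trait": n_nonpos,
        "min_diameter": float(min_diameter),
        "aggregated": bool(aggregate),
    }
    return ObservationTable(
        diameter=diam[keep],
        log_traits=np.log(traits[keep]),
        species_idx=sp_codes,
        tree_idx=tr_codes,
        species_labels=tuple(sp_labels),
        tree_labels=tuple(tr_labels),
        tree_species=tree_species,
        meta=meta,
    )
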