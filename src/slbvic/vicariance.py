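"""The dated junction-disjunction area cladogram and its capacity rules.

During a disjunction (seaway open) each lineage is split into an eastern
(Siberian) and a western (Laurussia/Gondwana) branch; during a junction
(land bridge emergent) the whole biota geodisperses and the areas merge
into a single pan-Pangaean branch.  The area cladogram is therefore a chain
of splits and merges along the phase timeline, rooted at the pre-accretion
ephemeral Laurussia-Gondwana connection.

Clado-stratigraphic trees (taxon trees with dated nodes and per-branch
territories) are fitted against that skeleton.  The central constraint is
*branch capacity*: the number of lineages of a clade observed at a given
time and territory can never exceed the number of vicariant branches the
model makes available there.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

from .eustasy import PhaseInterval, PhaseTimeline

TERRITORIES = ("East", "West")


class CladeError(KeyError):
    """Raised when a named clade is absent from a tree."""


# ---------------------------------------------------------------------------
# AreaCladogram


@dataclass(frozen=True)
class AreaNode:
    node_id: int
    age: float
    kind: str  # "root" | "split" | "merge" | "terminal"
    label: str = ""


@dataclass(frozen=True)
class AreaBranch:
    territory: str  # "East" | "West" | "Pan"
    older: float
    younger: float
    parent: int  # node_id of the parent node

    def alive_at(self, age: float) -> bool:
        return self.older >= age > self.younger


@dataclass(frozen=True)
class AreaCladogram:
    nodes: tuple[AreaNode, ...]
    branches: tuple[AreaBranch, ...]
    root: AreaNode

    def branch_count(self, age: float) -> int:
        return sum(b.alive_at(age) for b in self.branches)

    def split_segments(self) -> tuple[AreaBranch, ...]:
        return tuple(b for b in self.branches if b.territory in TERRITORIES)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        nodes = pd.DataFrame(
            [
                {"node_id": n.node_id, "age_ma": n.age, "kind": n.kind, "label": n.label}
                for n in self.nodes
            ]
        )
        branches = pd.DataFrame(
            [
                {
                    "territory": b.territory,
                    "older_ma": b.older,
                    "younger_ma": b.younger,
                    "parent": b.parent,
                }
                for b in self.branches
            ]
        )
        return nodes, branches


def build_area_cladogram(timeline: PhaseTimeline, root_age: float) -> AreaCladogram:
    """Build the dated junction-disjunction area cladogram.

    Disjunction intervals contribute an East/West branch pair hanging from a
    split node at the interval onset; junction intervals contribute a single
    merged pan-Pangaean branch below a merge node.  The root node sits at
    ``root_age`` (the amniote-amphibian split at the ephemeral
    Laurussia-Gondwana connection, ~350 Ma in the packaged fixture).
    """
    if not timeline.intervals:
        raise ValueError("empty phase timeline")
    span_older = timeline.span[0]
    if root_age < span_older:
        raise ValueError(
            f"root age {root_age} younger than oldest interval ({span_older})"
        )
    nodes = [AreaNode(0, root_age, "root", "root")]
    branches: list[AreaBranch] = []
    if root_age > span_older:
        branches.append(AreaBranch("Pan", root_age, span_older, 0))
    last_node = 0
    for iv in timeline.intervals:
        onset = iv.older
        if onset < root_age:  # a fresh node at this phase transition
            kind = "split" if iv.kind == "disjunction" else "merge"
            nodes.append(AreaNode(len(nodes), onset, kind, iv.label))
            last_node = nodes[-1].node_id
        else:  # first interval starts at the root itself
            last_node = 0
        if iv.kind == "disjunction":
            branches.append(AreaBranch("East", iv.older, iv.younger, last_node))
            branches.append(AreaBranch("West", iv.older, iv.younger, last_node))
        else:
            branches.append(AreaBranch("Pan", iv.older, iv.younger, last_node))
    nodes.append(AreaNode(len(nodes), timeline.span[1], "terminal", "present edge"))
    return AreaCladogram(tuple(nodes), tuple(branches), nodes[0])


# ---------------------------------------------------------------------------
# CladoStratTree


@dataclass(frozen=True)
class TreeBranch:
    """One lineage segment: alive over [older, younger) in a territory."""

    branch_id: int
    parent_id: int | None
    name: str  # label of the child node (taxon for leaves)
    territory: str  # "East" | "West"
    older: float
    younger: float

    def alive_at(self, age: float) -> bool:
        return self.older >= age > self.younger

    def overlaps(self, older: float, younger: float) -> bool:
        return self.older > younger and older > self.younger


class CladoStratTree:
    """A time-calibrated taxon tree with per-branch territories and clades.

    Built from a Newick topology plus a sidecar node table
    (``node_id,age_ma,territory,label``).  Node ages are the split dates
    (internal nodes) or extinction dates (leaves); a branch spans from its
    parent's age to its own.  Internal node labels name clades: the clade of
    label L contains every branch of the subtree rooted at L, including L's
    own stem branch.  The root's stem is given by ``origin_age``.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        ages: dict[str, float],
        territories: dict[str, str],
        origin_age: float | None = None,
        label: str = "",
    ) -> None:
        self.tree = tree
        self.label = label
        self.branches: list[TreeBranch] = []
        self._clades: dict[str, set[int]] = {}
        self._build(ages, territories, origin_age)

    # -- construction

    @staticmethod
    def _node_name(node: dendropy.Node) -> str:
        if node.taxon is not None and node.taxon.label:
            return str(node.taxon.label)
        return str(node.label or "")

    def _build(
        self,
        ages: dict[str, float],
        territories: dict[str, str],
        origin_age: float | None,
    ) -> None:
        counter = 0
        for node in self.tree.preorder_node_iter():
            name = self._node_name(node)
            if name not in ages:
                raise ValueError(f"node {name!r} missing from the age table")
            node.age_ma = float(ages[name])
            node.territory = territories.get(name, "West")
            if node.parent_node is not None:
                if node.parent_node.age_ma < node.age_ma:
                    raise ValueError(
                        f"node {name!r} older than its parent "
                        f"({node.age_ma} vs {node.parent_node.age_ma})"
                    )
        root = self.tree.seed_node
        root_name = self._node_name(root)
        if origin_age is None:
            origin_age = root.age_ma
        for node in self.tree.preorder_node_iter():
            parent = node.parent_node
            older = origin_age if parent is None else parent.age_ma
            if older <= node.age_ma and parent is None:
                node.branch_idx = None  # zero-length root stem: no branch
                continue
            branch = TreeBranch(
                counter,
                None if parent is None else parent.branch_idx,
                self._node_name(node),
                node.territory,
                float(older),
                float(node.age_ma),
            )
            node.branch_idx = counter
            self.branches.append(branch)
            counter += 1
        # clade registry from labelled internal nodes (plus the root label)
        for node in self.tree.preorder_node_iter():
            name = self._node_name(node)
            if not name or node.is_leaf():
                continue
            members: set[int] = set()
            for sub in node.preorder_iter():
                if getattr(sub, "branch_idx", None) is not None:
                    members.add(sub.branch_idx)
            self._clades[name] = members
        if root_name and root_name not in self._clades:
            self._clades[root_name] = {b.branch_id for b in self.branches}

    # -- queries

    @property
    def clades(self) -> tuple[str, ...]:
        return tuple(self._clades)

    @property
    def span(self) -> tuple[float, float]:
        older = max(b.older for b in self.branches)
        younger = min(b.younger for b in self.branches)
        return (older, younger)

    def clade_branches(self, clade: str) -> list[TreeBranch]:
        if clade not in self._clades:
            raise CladeError(f"unknown clade {clade!r}; known: {sorted(self._clades)}")
        ids = self._clades[clade]
        return [b for b in self.branches if b.branch_id in ids]

    def node_ages(self, internal_only: bool = True) -> np.ndarray:
        ages = [
            node.age_ma
            for node in self.tree.preorder_node_iter()
            if not (internal_only and node.is_leaf())
        ]
        return np.asarray(ages, dtype=float)

    # -- serialisation

    @classmethod
    def from_files(
        cls, newick: str | Path, node_table: str | Path, label: str = ""
    ) -> "CladoStratTree":
        tree = dendropy.Tree.get(
            path=str(newick),
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
        df = pd.read_csv(node_table)
        ages = dict(zip(df["node_id"].astype(str), df["age_ma"].astype(float)))
        territories = dict(zip(df["node_id"].astype(str), df["territory"].astype(str)))
        origin = None
        if "origin_ma" in df.columns:
            vals = df["origin_ma"].dropna()
            if len(vals):
                origin = float(vals.iloc[0])
        return cls(tree, ages, territories, origin_age=origin, label=label)

    def to_files(self, newick: str | Path, node_table: str | Path) -> None:
        self.tree.write(path=str(newick), schema="newick", suppress_rooting=True)
        rows = []
        origin = max(b.older for b in self.branches)
        for node in self.tree.preorder_node_iter():
            rows.append(
                {
                    "node_id": self._node_name(node),
                    "age_ma": node.age_ma,
                    "territory": node.territory,
                    "label": self._node_name(node),
                    "origin_ma": origin if node.parent_node is None else None,
                }
            )
        pd.DataFrame(rows).to_csv(node_table, index=False)


class BranchTable:
    """A flat clado-stratigraphic branch table with the same query surface
    as :class:`CladoStratTree` (used for simulated lineage histories, where
    no Newick topology is needed)."""

    def __init__(
        self,
        branches: Sequence[TreeBranch],
        clades: dict[str, set[int]] | None = None,
        internal_node_ages: Sequence[float] = (),
        label: str = "",
    ) -> None:
        self.branches = list(branches)
        self.label = label
        if clades is None:
            clades = {"Synthetica": {b.branch_id for b in self.branches}}
        self._clades = clades
        self._internal_ages = np.asarray(internal_node_ages, dtype=float)

    @property
    def clades(self) -> tuple[str, ...]:
        return tuple(self._clades)

    @property
    def span(self) -> tuple[float, float]:
        return (
            max(b.older for b in self.branches),
            min(b.younger for b in self.branches),
        )

    def clade_branches(self, clade: str) -> list[TreeBranch]:
        if clade not in self._clades:
            raise CladeError(f"unknown clade {clade!r}; known: {sorted(self._clades)}")
        ids = self._clades[clade]
        return [b for b in self.branches if b.branch_id in ids]

    def node_ages(self, internal_only: bool = True) -> np.ndarray:
        if internal_only:
            return self._internal_ages.copy()
        tips = np.asarray([b.younger for b in self.branches], dtype=float)
        return np.concatenate([self._internal_ages, tips])


# ---------------------------------------------------------------------------
# Branch capacity


@dataclass(frozen=True)
class CapacityQuery:
    clade: str
    query_time: float
    territory: str = "both"  # "East" | "West" | "both"

    def __post_init__(self) -> None:
        if self.territory not in ("East", "West", "both"):
            raise ValueError(f"bad territory {self.territory!r}")


def branch_capacity(
    tree: CladoStratTree,
    q: CapacityQuery,
    timeline: PhaseTimeline | None = None,
) -> int:
    """Number of available vicariant branches of a clade at a time slice.

    If the query time falls in a disjunction interval, only branches of the
    queried territory count (endemism); in a junction interval every branch
    counts regardless of territory, because geodispersal makes each lineage
    recoverable on either side of Pangaea.  With no timeline the query
    territory is applied literally ("both" counts everything).
    """
    branches = [b for b in tree.clade_branches(q.clade) if b.alive_at(q.query_time)]
    pooled = q.territory == "both"
    if timeline is not None:
        older, younger = timeline.span
        if not older >= q.query_time >= younger:
            raise ValueError(
                f"query time {q.query_time} outside timeline span {timeline.span}"
            )
        if timeline.at(q.query_time).kind == "junction":
            pooled = True
    if pooled:
        return len(branches)
    return sum(b.territory == q.territory for b in branches)


def capacity_overlapping(
    tree: CladoStratTree,
    clade: str,
    older: float,
    younger: float,
    territory: str = "both",
) -> int:
    """Branches of a clade whose life span overlaps an interval.

    Interval-level capacity used by conflict detection: a branch alive at
    any instant of the interval is recoverable from it, so overlap counting
    (not a midpoint slice) is the sound bound for occurrence data.
    """
    branches = [b for b in tree.clade_branches(clade) if b.overlaps(older, younger)]
    if territory == "both":
        return len(branches)
    return sum(b.territory == territory for b in branches)


def doubling_bound(n_disjunctions: int, n_start: int = 1) -> int:
    """Upper bound 2^d on lineage count after d disjunction onsets.

    Every disjunction can at most double each lineage (one eastern and one
    western daughter).  Real trees fall short of this bound through
    extinction and non-dispersing lineages; it is a bound, not a count.
    """
    if n_disjunctions < 0:
        raise ValueError("n_disjunctions must be >= 0")
    return n_start * (2 ** n_disjunctions)


# ---------------------------------------------------------------------------
# Divergence dating


@dataclass(frozen=True)
class DivergenceDate:
    age: float
    window_label: str
    no_prior_disjunction: bool = False


def infer_divergence_date(
    fads_a: Sequence[float],
    fads_b: Sequence[float],
    timeline: PhaseTimeline,
) -> DivergenceDate:
    """Date the split of two lineages against the junction-disjunction model.

    The two lineages separated during a disjunction interval and geodispersed
    (hence can co-occur) during the junction window that terminates it; the
    divergence is reported as that window's onset age.  Operationally: take
    the older of the two first-appearance data; if it falls inside a junction
    window, that window closes the disjunction in which the split happened;
    if it falls inside a disjunction, the split happened there and the next
    younger junction window dates it.  If no disjunction precedes the datum
    the root age is returned with a ``no_prior_disjunction`` flag.
    """
    fads_a = [getattr(x, "fad", x) for x in fads_a]
    fads_b = [getattr(x, "fad", x) for x in fads_b]
    if not len(fads_a) or not len(fads_b):
        raise ValueError("both taxa need at least one dated occurrence")
    older_fad = max(max(fads_a), max(fads_b))
    span_older, span_younger = timeline.span
    if older_fad > span_older or min(min(fads_a), min(fads_b)) < span_younger:
        raise ValueError("occurrences outside the model span")
    host = timeline.at(older_fad)
    idx = timeline.index_of(host)
    if host.kind == "junction":
        has_prior_disjunction = any(
            iv.kind == "disjunction" for iv in timeline.intervals[:idx]
        )
        if not has_prior_disjunction:
            return DivergenceDate(span_older, host.label, no_prior_disjunction=True)
        return DivergenceDate(host.onset, host.label)
    # datum inside a disjunction: the terminating junction is the next one
    for iv in timeline.intervals[idx + 1:]:
        if iv.kind == "junction":
            return DivergenceDate(iv.onset, iv.label)
    return DivergenceDate(host.younger, "", no_prior_disjunction=False)


# ---------------------------------------------------------------------------
# Marine biostratigraphic unit calibration


@dataclass(frozen=True)
class MarineUnit:
    name: str
    order: int
    older: float | None = None
    younger: float | None = None
    excepted: bool = False


@dataclass(frozen=True)
class DatedUnit:
    name: str
    older: float
    younger: float
    excepted: bool
    assigned: bool  # False for pass-through (excepted) units
    highstand_label: str = ""


def calibrate_marine_units(
    units: Sequence[MarineUnit],
    timeline: PhaseTimeline,
    exceptions: Iterable[str] = (),
    start_age: float | None = None,
) -> tuple[list[DatedUnit], list[MarineUnit]]:
    """Assign ordered marine biozones to successive highstand intervals.

    Marine units record geodispersal of marine faunas, which happens while
    sea level is high — i.e. during terrestrial *disjunction* intervals.
    Unit *i* (oldest first) is assigned to the *i*-th highstand interval at
    or younger than ``start_age`` (first-available, strictly order
    preserving).  Units named in ``exceptions`` (or flagged ``excepted``)
    pass through with their input dates.  Units left over when highstands
    run out are returned unassigned, never silently dropped.
    """
    exceptions = set(exceptions)
    highstands = [
        iv
        for iv in timeline.disjunctions
        if start_age is None or iv.older <= start_age
    ]
    dated: list[DatedUnit] = []
    remainder: list[MarineUnit] = []
    cursor = 0
    for unit in sorted(units, key=lambda u: u.order):
        if unit.excepted or unit.name in exceptions:
            if unit.older is None or unit.younger is None:
                raise ValueError(
                    f"excepted unit {unit.name!r} needs its own input dates"
                )
            dated.append(
                DatedUnit(unit.name, unit.older, unit.younger, True, False)
            )
            continue
        if cursor >= len(highstands):
            remainder.append(unit)
            continue
        hs = highstands[cursor]
        dated.append(
            DatedUnit(unit.name, hs.older, hs.younger, False, True, hs.label)
        )
        cursor += 1
    return dated, remainder
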