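"""Common-core detection between two ligands.

The common core (CC) is a shared substructure of two ligands that serves as
the non-physical intermediate endstate of both alchemical paths.  It is found
as the maximum connected common *induced* subgraph of the two bond graphs,
with atoms matched by element (default) or by atom type.  Atoms outside the
CC form one or more connected dummy regions, each attached to the CC through
a single terminal junction atom.

Determinism: when several maximum mappings exist, the one with the largest
matched-bond count wins, then the lexicographically smallest sequence of
ligand-A indices, then the smallest sequence of paired ligand-B indices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import yaml

from .topology import MoleculeTopology

__all__ = [
    "AtomMapping",
    "CommonCoreSpec",
    "find_common_core",
    "derive_cc_spec",
    "validate_terminal_junction",
    "ValidationReport",
]


@dataclass(frozen=True)
class AtomMapping:
    """An injective, connected, induced-subgraph-isomorphic atom pairing."""

    pairs: tuple[tuple[int, int], ...]
    match_policy: str = "element"

    def __post_init__(self) -> None:
        a_side = [p[0] for p in self.pairs]
        b_side = [p[1] for p in self.pairs]
        if len(set(a_side)) != len(a_side) or len(set(b_side)) != len(b_side):
            raise ValueError("mapping must be injective in both directions")

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def a_to_b(self) -> dict[int, int]:
        return dict(self.pairs)

    @property
    def b_to_a(self) -> dict[int, int]:
        return {b: a for a, b in self.pairs}

    def inverse(self) -> "AtomMapping":
        return AtomMapping(
            tuple(sorted((b, a) for a, b in self.pairs)), self.match_policy
        )


@dataclass
class CommonCoreSpec:
    """CC membership, dummy regions and junction atoms for a ligand pair.

    ``dummy_regions`` holds, per ligand, the connected components of non-CC
    atoms.  ``junctions`` lists, per region, the non-CC atoms bonded to a CC
    atom; a valid region has exactly one.  ``attachments`` gives the CC atom
    each junction binds to.
    """

    mapping: AtomMapping
    cc_atoms: dict[str, set[int]]  # keyed "A"/"B"
    dummy_regions: dict[str, list[set[int]]]
    junctions: dict[str, list[list[int]]]  # per region, list of junction atoms
    attachments: dict[str, list[list[int]]]  # per region, CC attachment atoms

    def junction_atom(self, side: str, region: int) -> int:
        js = self.junctions[side][region]
        if len(js) != 1:
            raise ValueError(
                f"dummy region {region} of ligand {side} has {len(js)} "
                "junction atoms; a terminal junction requires exactly one"
            )
        return js[0]

    def attachment_atom(self, side: str, region: int) -> int:
        ats = self.attachments[side][region]
        if len(ats) != 1:
            raise ValueError(
                f"junction of region {region} (ligand {side}) binds "
                f"{len(ats)} CC atoms; exactly one required"
            )
        return ats[0]

    def to_yaml(self, path: str | Path | None = None) -> str:
        doc = {
            "match_policy": self.mapping.match_policy,
            "mapping": [list(p) for p in self.mapping.pairs],
            "cc_atoms": {k: sorted(v) for k, v in self.cc_atoms.items()},
            "dummy_regions": {
                k: [sorted(r) for r in v] for k, v in self.dummy_regions.items()
            },
            "junctions": self.junctions,
            "attachments": self.attachments,
        }
        text = yaml.safe_dump(doc, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class ValidationReport:
    passed: bool
    violations: list[str] = field(default_factory=list)

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {"passed": self.passed, "violations": self.violations}
        )


def _labels(top: MoleculeTopology, policy: str) -> dict[int, str]:
    if policy == "element":
        return {a.index: a.element.upper() for a in top.atoms}
    if policy == "atom_type":
        return {a.index: a.atom_type for a in top.atoms}
    raise ValueError(f"unknown match policy {policy!r}")


def _ring_edges(g: nx.Graph) -> set[frozenset[int]]:
    """Edges that lie on a cycle (i.e. are not bridges)."""
    bridges = {frozenset(e) for e in nx.bridges(g)}
    return {frozenset(e) for e in g.edges} - bridges


def _canon_key(top: MoleculeTopology, policy: str) -> tuple:
    labels = _labels(top, policy)
    g = top.graph()
    return (
        len(top),
        sorted(labels.values()),
        sorted(d for _, d in g.degree),
        top.molecule_id,
    )


def find_common_core(
    lig_a: MoleculeTopology,
    lig_b: MoleculeTopology,
    policy: str = "element",
) -> AtomMapping:
    """Maximum connected common induced subgraph of two bond graphs.

    Vertex labels are given by ``policy``; matched edges must agree in ring
    membership on both sides (a ring bond never maps onto a chain bond), so
    a matched ring is never broken.  Raises ``ValueError`` when no common
    substructure exists.
    """
    if len(lig_a) == 0 or len(lig_b) == 0:
        raise ValueError("both ligands must have at least one atom")
    # canonical argument order makes the search symmetric: swapping the
    # ligands returns the exact inverse pairing
    if _canon_key(lig_b, policy) < _canon_key(lig_a, policy):
        return find_common_core(lig_b, lig_a, policy).inverse()
    ga, gb = lig_a.graph(), lig_b.graph()
    la, lb = _labels(lig_a, policy), _labels(lig_b, policy)
    ring_a, ring_b = _ring_edges(ga), _ring_edges(gb)

    adj_a = {i: set(ga.neighbors(i)) for i in ga.nodes}
    adj_b = {i: set(gb.neighbors(i)) for i in gb.nodes}

    best: list[tuple[int, int], ...] | None = None
    best_key: tuple | None = None

    def mapping_key(pairs: dict[int, int]) -> tuple:
        a_set = set(pairs)
        bonds = sum(1 for i in a_set for j in adj_a[i] if j in a_set and j > i)
        a_seq = sorted(a_set)
        b_seq = [pairs[a] for a in a_seq]
        # larger size/bonds first; smaller index sequences first
        return (-len(pairs), -bonds, a_seq, b_seq)

    def consider(pairs: dict[int, int]) -> None:
        nonlocal best, best_key
        key = mapping_key(pairs)
        if best_key is None or key < best_key:
            best_key = key
            best = sorted(pairs.items())

    def compatible(a: int, b: int, pairs: dict[int, int]) -> bool:
        if la[a] != lb[b]:
            return False
        for a2, b2 in pairs.items():
            a_adj = a2 in adj_a[a]
            b_adj = b2 in adj_b[b]
            if a_adj != b_adj:
                return False
            if a_adj and (
                (frozenset((a, a2)) in ring_a) != (frozenset((b, b2)) in ring_b)
            ):
                return False
        return True

    seen: set[frozenset[tuple[int, int]]] = set()

    def extend(pairs: dict[int, int], a_min: int) -> None:
        state = frozenset(pairs.items())
        if state in seen:
            return
        seen.add(state)
        consider(pairs)
        # upper bound prune: cannot beat the best size even if everything maps
        remaining = min(
            len(adj_a) - len(pairs), len(adj_b) - len(pairs)
        )
        if best_key is not None and len(pairs) + remaining < -best_key[0]:
            return
        used_b = set(pairs.values())
        frontier_a = sorted(
            {
                n
                for a in pairs
                for n in adj_a[a]
                if n not in pairs and n > a_min
            }
        )
        for a in frontier_a:
            for b in sorted(
                {n for bb in used_b for n in adj_b[bb] if n not in used_b}
            ):
                if compatible(a, b, pairs):
                    pairs[a] = b
                    extend(pairs, a_min)
                    del pairs[a]

    # each mapping has a unique minimal ligand-A atom; seed on it
    for a in sorted(adj_a):
        for b in sorted(adj_b):
            if la[a] == lb[b]:
                extend({a: b}, a)

    if best is None:
        raise ValueError("no common substructure under the given match policy")
    return AtomMapping(tuple(best), policy)


def derive_cc_spec(
    mapping: AtomMapping,
    lig_a: MoleculeTopology,
    lig_b: MoleculeTopology,
    overrides: set[int] | None = None,
) -> CommonCoreSpec:
    """Split both ligands into CC atoms and dummy regions.

    ``overrides`` are ligand-A atom indices to exclude from the CC (their
    ligand-B partners are excluded symmetrically); the excluded atoms join
    the dummy regions.  An override that disconnects the remaining CC is an
    error: two disjoint CC fragments cannot be attached through a
    non-interacting dummy region.
    """
    overrides = overrides or set()
    a2b = mapping.a_to_b
    unknown = overrides - set(a2b)
    if unknown:
        raise ValueError(f"override atoms {sorted(unknown)} are not mapped")

    cc_a = set(a2b) - overrides
    cc_b = {a2b[a] for a in cc_a}
    if not cc_a:
        raise ValueError("overrides removed every CC atom")

    ga, gb = lig_a.graph(), lig_b.graph()
    for side, g, cc in (("A", ga, cc_a), ("B", gb, cc_b)):
        sub = g.subgraph(cc)
        if len(cc) and not nx.is_connected(sub):
            raise ValueError(
                f"CC of ligand {side} is disconnected after overrides; "
                "two disjoint CCs attached to a non-interacting dummy "
                "region are not permitted"
            )

    spec = CommonCoreSpec(
        mapping=mapping,
        cc_atoms={"A": cc_a, "B": cc_b},
        dummy_regions={},
        junctions={},
        attachments={},
    )
    for side, g, cc, top in (("A", ga, cc_a, lig_a), ("B", gb, cc_b, lig_b)):
        non_cc = set(g.nodes) - cc
        regions = [set(c) for c in nx.connected_components(g.subgraph(non_cc))]
        regions.sort(key=min)
        junctions, attachments = [], []
        for region in regions:
            js = sorted(
                n for n in region if any(m in cc for m in g.neighbors(n))
            )
            junctions.append(js)
            attachments.append(
                sorted({m for j in js for m in g.neighbors(j) if m in cc})
            )
        spec.dummy_regions[side] = regions
        spec.junctions[side] = junctions
        spec.attachments[side] = attachments
    return spec


def validate_terminal_junction(spec: CommonCoreSpec) -> ValidationReport:
    """Check that every dummy region attaches via exactly one junction atom.

    Regions fused to the CC at several atoms (e.g. a ring sharing two atoms
    with the CC) violate the terminal-junction requirement and are listed in
    the report; an empty dummy set passes vacuously.
    """
    violations: list[str] = []
    for side in ("A", "B"):
        for r, region in enumerate(spec.dummy_regions[side]):
            js = spec.junctions[side][r]
            if len(js) != 1:
                violations.append(
                    f"ligand {side} dummy region {sorted(region)} has "
                    f"{len(js)} junction atoms {js}; exactly one required"
                )
                continue
            ats = spec.attachments[side][r]
            if len(ats) != 1:
                violations.append(
                    f"ligand {side} junction {js[0]} attaches to several CC "
                    f"atoms {ats}; exactly one required"
                )
    return ValidationReport(passed=not violations, violations=violations)
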