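"""Molecular topology data model and mass/charge transformations.

A :class:`MoleculeTopology` is the in-memory representation of one ligand (or
any single molecule): atoms carrying partial charges, Lennard-Jones parameters
and masses, plus the bonded terms (bonds, angles, dihedrals, impropers) that
define the molecular graph.  Everything downstream — common-core detection,
alchemical path construction, per-state parameter emission — operates on this
container.

Units follow the CHARMM convention throughout: energies in kcal/mol, distances
in Å, charges in elementary charge units (e), masses in amu.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx

__all__ = [
    "AtomRecord",
    "BondTerm",
    "AngleTerm",
    "DihedralTerm",
    "ImproperTerm",
    "MoleculeTopology",
    "apply_hmr",
    "total_charge",
    "WATER_RESIDUES",
    "DUMMY_TYPE_PREFIX",
    "JUNCTION_TYPE",
]

#: Residue names treated as water and left untouched by hydrogen mass
#: repartitioning when ``exclude_water`` is set.
WATER_RESIDUES = frozenset({"TIP3", "TIP3P", "HOH", "WAT", "SPC"})

#: Atom-type prefix reserved for fully decoupled dummy atoms.  Types with this
#: prefix (and the junction type) are never classified as hydrogen regardless
#: of their mass, so bond constraints on X–H bonds are never applied to them.
DUMMY_TYPE_PREFIX = "DDD"

#: Atom type of the junction atom X through which a dummy region stays
#: attached to the common core.
JUNCTION_TYPE = "X"


@dataclass(frozen=True)
class AtomRecord:
    """One atom: identity, nonbonded parameters and mass.

    ``lj_epsilon`` is the well depth in kcal/mol (stored positive),
    ``lj_rmin_half`` is Rmin/2 in Å.  A dummy atom has zero charge and zero
    LJ well depth by construction.
    """

    index: int
    name: str
    element: str
    atom_type: str
    charge: float
    mass: float
    lj_epsilon: float = 0.0
    lj_rmin_half: float = 0.0
    is_dummy: bool = False
    residue: str = "LIG"
    segment: str = "LIG"

    def __post_init__(self) -> None:
        if self.lj_epsilon < 0:
            raise ValueError(f"atom {self.index}: lj_epsilon must be >= 0")
        if self.lj_rmin_half < 0:
            raise ValueError(f"atom {self.index}: lj_rmin_half must be >= 0")
        if self.is_dummy and (self.charge != 0.0 or self.lj_epsilon != 0.0):
            raise ValueError(
                f"atom {self.index}: dummy atoms must have zero charge and LJ"
            )

    @property
    def is_hydrogen(self) -> bool:
        """True for physical hydrogens; dummy/junction types never qualify."""
        if self.atom_type.startswith(DUMMY_TYPE_PREFIX) or self.atom_type == JUNCTION_TYPE:
            return False
        return self.element.upper() == "H"


@dataclass(frozen=True)
class BondTerm:
    atoms: tuple[int, int]
    force_constant: float  # kcal/mol/Å²
    equilibrium: float  # Å

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("bond force constant must be >= 0")


@dataclass(frozen=True)
class AngleTerm:
    atoms: tuple[int, int, int]
    force_constant: float  # kcal/mol/rad²
    equilibrium: float  # degrees

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("angle force constant must be >= 0")


@dataclass(frozen=True)
class DihedralTerm:
    atoms: tuple[int, int, int, int]
    force_constant: float  # kcal/mol
    periodicity: int
    phase: float  # degrees

    def __post_init__(self) -> None:
        if self.force_constant < 0:
            raise ValueError("dihedral force constant must be >= 0")


@dataclass(frozen=True)
class ImproperTerm:
    atoms: tuple[int, int, int, int]
    force_constant: float
    equilibrium: float = 0.0


@dataclass
class MoleculeTopology:
    """A molecule: atoms plus the bonded terms connecting them.

    Atom indices are 0-based internally; CHARMM file I/O converts to and from
    the format's 1-based numbering at the boundary.
    """

    atoms: list[AtomRecord]
    bonds: list[BondTerm] = field(default_factory=list)
    angles: list[AngleTerm] = field(default_factory=list)
    dihedrals: list[DihedralTerm] = field(default_factory=list)
    impropers: list[ImproperTerm] = field(default_factory=list)
    molecule_id: str = "LIG"
    segment: str = "LIG"

    def __post_init__(self) -> None:
        seen = set()
        for a in self.atoms:
            if a.index in seen:
                raise ValueError(f"duplicate atom index {a.index}")
            seen.add(a.index)
        n = len(self.atoms)
        for term in (*self.bonds, *self.angles, *self.dihedrals, *self.impropers):
            for i in term.atoms:
                if i not in seen:
                    raise ValueError(
                        f"bonded term {term.atoms} references missing atom {i} "
                        f"(topology has {n} atoms)"
                    )

    def __len__(self) -> int:
        return len(self.atoms)

    def atom(self, index: int) -> AtomRecord:
        for a in self.atoms:
            if a.index == index:
                return a
        raise KeyError(index)

    def graph(self) -> nx.Graph:
        """Bond graph with the atom's element and type as node labels."""
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.index, element=a.element, atom_type=a.atom_type)
        for b in self.bonds:
            g.add_edge(*b.atoms)
        return g

    def neighbors(self, index: int) -> set[int]:
        out: set[int] = set()
        for b in self.bonds:
            i, j = b.atoms
            if i == index:
                out.add(j)
            elif j == index:
                out.add(i)
        return out

    def total_mass(self) -> float:
        return sum(a.mass for a in self.atoms)


def total_charge(topology: MoleculeTopology) -> float:
    """Sum of atomic partial charges in elementary charge units."""
    return sum(a.charge for a in topology.atoms)


def apply_hmr(
    topology: MoleculeTopology,
    factor: float = 3.0,
    exclude_water: bool = True,
    water_residues: frozenset[str] = WATER_RESIDUES,
) -> MoleculeTopology:
    """Hydrogen mass repartitioning.

    Each hydrogen mass is multiplied by ``factor`` and the extra mass is
    subtracted from the single heavy atom it is bonded to, so the molecular
    mass is invariant.  This permits a 4 fs MD time step when all bonds to
    hydrogen are constrained.  Water residues keep their masses when
    ``exclude_water`` (rigid-water integrators handle them separately).

    Raises ``ValueError`` if a hydrogen is not bonded to exactly one heavy
    atom or if a heavy atom's repartitioned mass would become non-positive.
    """
    deltas: dict[int, float] = {a.index: 0.0 for a in topology.atoms}
    for a in topology.atoms:
        if not a.is_hydrogen:
            continue
        if exclude_water and a.residue.upper() in water_residues:
            continue
        heavy = [
            n
            for n in topology.neighbors(a.index)
            if not topology.atom(n).is_hydrogen
        ]
        if len(heavy) != 1:
            raise ValueError(
                f"hydrogen {a.index} ({a.name}) bonded to {len(heavy)} heavy "
                "atoms; HMR requires exactly one"
            )
        increment = a.mass * (factor - 1.0)
        deltas[a.index] += increment
        deltas[heavy[0]] -= increment

    new_atoms = []
    for a in topology.atoms:
        m = a.mass + deltas[a.index]
        if deltas[a.index] != 0.0 and m <= 0.0:
            raise ValueError(
                f"HMR would give atom {a.index} ({a.name}) non-positive mass "
                f"{m:.4f} amu"
            )
        new_atoms.append(replace(a, mass=m) if deltas[a.index] != 0.0 else a)
    return MoleculeTopology(
        atoms=new_atoms,
        bonds=list(topology.bonds),
        angles=list(topology.angles),
        dihedrals=list(topology.dihedrals),
        impropers=list(topology.impropers),
        molecule_id=topology.molecule_id,
        segment=topology.segment,
    )
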