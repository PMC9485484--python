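"""Readers and writers for CHARMM-format files (PSF, RTF/PRM/stream).

The PSF reader accepts both the EXT and non-EXT column layouts of CHARMM and
X-PLOR PSF files (autodetected from the header flags); only PSFs carrying
atom-type *names* are supported — native CHARMM PSFs with numeric type codes
are rejected with an explicit error.  Atom indices are 1-based in the files
and converted to 0-based :class:`~ccsai.topology.MoleculeTopology` indices.

Parameter files (RTF/PRM/stream) are parsed into a :class:`ParameterSet`
keyed by atom-type tuples; lookups are symmetric under tuple reversal and
honour the dihedral wildcard type ``X``.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

from .topology import (
    DUMMY_TYPE_PREFIX,
    AngleTerm,
    AtomRecord,
    BondTerm,
    DihedralTerm,
    ImproperTerm,
    MoleculeTopology,
)

__all__ = [
    "PSFParseError",
    "read_psf",
    "write_psf",
    "ParameterSet",
    "read_parameters",
    "MissingParameterReport",
    "element_from_mass",
]

# Atomic masses (amu) for the elements CGenFF ligands are made of.
_ELEMENT_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "F": 18.998,
    "NA": 22.990, "MG": 24.305, "P": 30.974, "S": 32.06, "CL": 35.45,
    "K": 39.098, "CA": 40.078, "BR": 79.904, "I": 126.904,
}


def element_from_mass(mass: float, tolerance: float = 1.5) -> str:
    """Element symbol whose standard mass is nearest ``mass``.

    Returns ``"X"`` when nothing is within ``tolerance`` amu (e.g. for
    repartitioned or dummy masses).
    """
    best, dist = "X", tolerance
    for sym, m in _ELEMENT_MASSES.items():
        if abs(mass - m) < dist:
            best, dist = sym, abs(mass - m)
    return best.capitalize() if len(best) > 1 else best


class PSFParseError(ValueError):
    """Malformed PSF content; the message names the offending line."""


_SECTION_RE = re.compile(r"!N(\w+)")


def _guess_element(name: str, atom_type: str, mass: float) -> str:
    if atom_type.startswith(DUMMY_TYPE_PREFIX) or atom_type == "X":
        return "DU"
    # CHARMM names start with the element symbol; try two letters, then one.
    for probe in (name[:2].upper(), name[:1].upper()):
        if probe in _ELEMENT_MASSES:
            return probe.capitalize() if len(probe) > 1 else probe
    return element_from_mass(mass)


def read_psf(path: str | Path) -> list[MoleculeTopology]:
    """Parse a CHARMM/X-PLOR PSF into one topology per segment.

    Supports EXT and non-EXT dialects; the NATOM and NBOND headers are
    cross-checked against the parsed records.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or "PSF" not in lines[0].split():
        raise PSFParseError(f"{path}: line 1: not a PSF file")

    sections: dict[str, tuple[int, list[str]]] = {}
    current: str | None = None
    declared = 0
    for ln_no, raw in enumerate(lines[1:], start=2):
        line = raw.rstrip()
        m = _SECTION_RE.search(line)
        if m:
            head = line.split("!")[0].split()
            if not head or not head[0].lstrip("-").isdigit():
                raise PSFParseError(
                    f"{path}: line {ln_no}: malformed section header {line!r}"
                )
            declared = int(head[0])
            current = m.group(1).split(":")[0]
            sections[current] = (declared, [])
        elif current and line.strip():
            sections[current][1].append(line)

    if "ATOM" not in sections:
        raise PSFParseError(f"{path}: missing NATOM section")
    natom, atom_lines = sections["ATOM"]
    if len(atom_lines) != natom:
        raise PSFParseError(
            f"{path}: NATOM header says {natom} atoms, found {len(atom_lines)}"
        )

    atoms: list[AtomRecord] = []
    segments: list[str] = []
    for line in atom_lines:
        parts = line.split()
        if len(parts) < 8:
            raise PSFParseError(f"{path}: short atom line {line!r}")
        idx, seg, _resid, resname, name, atype = parts[:6]
        if atype.lstrip("-").isdigit():
            raise PSFParseError(
                f"{path}: numeric atom-type codes (native CHARMM dialect) are "
                "unsupported; regenerate the PSF with type names (X-PLOR style)"
            )
        charge, mass = float(parts[6]), float(parts[7])
        is_dummy = atype.startswith(DUMMY_TYPE_PREFIX)
        if is_dummy and charge != 0.0:
            raise PSFParseError(
                f"{path}: dummy-typed atom {idx} carries charge {charge}"
            )
        atoms.append(
            AtomRecord(
                index=int(idx) - 1,
                name=name,
                element=_guess_element(name, atype, mass),
                atom_type=atype,
                charge=charge,
                mass=mass,
                is_dummy=is_dummy,
                residue=resname,
                segment=seg,
            )
        )
        segments.append(seg)

    bond_pairs: list[tuple[int, int]] = []
    if "BOND" in sections:
        nbond, bond_lines = sections["BOND"]
        flat = [int(tok) for line in bond_lines for tok in line.split()]
        if len(flat) != 2 * nbond:
            raise PSFParseError(
                f"{path}: NBOND header says {nbond} bonds, found {len(flat) // 2}"
            )
        bond_pairs = [(flat[i] - 1, flat[i + 1] - 1) for i in range(0, len(flat), 2)]

    def _tuples(section: str, width: int) -> list[tuple[int, ...]]:
        if section not in sections:
            return []
        n, seclines = sections[section]
        flat = [int(tok) for line in seclines for tok in line.split()]
        if len(flat) != width * n:
            raise PSFParseError(
                f"{path}: {section} header count mismatch"
            )
        return [
            tuple(v - 1 for v in flat[i : i + width])
            for i in range(0, len(flat), width)
        ]

    angles = _tuples("THETA", 3)
    dihedrals = _tuples("PHI", 4)
    impropers = _tuples("IMPHI", 4)

    out: list[MoleculeTopology] = []
    for seg in dict.fromkeys(segments):  # preserve order
        seg_atoms = [a for a in atoms if a.segment == seg]
        idxset = {a.index for a in seg_atoms}
        out.append(
            MoleculeTopology(
                atoms=seg_atoms,
                bonds=[
                    BondTerm(p, 0.0, 0.0) for p in bond_pairs if p[0] in idxset
                ],
                angles=[
                    AngleTerm(t, 0.0, 0.0) for t in angles if t[0] in idxset
                ],
                dihedrals=[
                    DihedralTerm(t, 0.0, 1, 0.0)
                    for t in dihedrals
                    if t[0] in idxset
                ],
                impropers=[
                    ImproperTerm(t, 0.0) for t in impropers if t[0] in idxset
                ],
                molecule_id=seg,
                segment=seg,
            )
        )
    return out


def write_psf(topologies: MoleculeTopology | list[MoleculeTopology], path: str | Path) -> None:
    """Write an EXT X-PLOR style PSF (type names, wide columns).

    Charges and masses are written at ten decimal places so that staged
    charge fractions (thirds etc.) survive a round trip.
    """
    if isinstance(topologies, MoleculeTopology):
        topologies = [topologies]
    lines = ["PSF EXT XPLOR", "", f"{1:10d} !NTITLE", "* generated by ccsai", ""]
    atoms = [a for t in topologies for a in t.atoms]
    # File indices are 1-based and contiguous across segments; the segment
    # column carries the molecule id so multi-ligand files split on re-read.
    order = {(t.molecule_id, a.index): None for t in topologies for a in t.atoms}
    file_index: dict[tuple[str, int], int] = {
        key: i + 1 for i, key in enumerate(order)
    }
    lines.append(f"{len(atoms):10d} !NATOM")
    for t in topologies:
        for a in t.atoms:
            lines.append(
                f"{file_index[(t.molecule_id, a.index)]:10d} {t.molecule_id:<8s} "
                f"{1:<8d} {a.residue:<8s} {a.name:<8s} {a.atom_type:<6s} "
                f"{a.charge:18.10f}{a.mass:18.10f}{0:8d}"
            )
    lines.append("")

    def _emit(label: str, tuples: list[tuple[int, ...]], per_line: int) -> None:
        lines.append(f"{len(tuples):10d} !N{label}")
        flat = [v for tup in tuples for v in tup]
        width = len(tuples[0]) if tuples else 2
        chunk = per_line * width
        for i in range(0, len(flat), chunk):
            lines.append("".join(f"{v:10d}" for v in flat[i : i + chunk]))
        lines.append("")

    def _collect(attr: str) -> list[tuple[int, ...]]:
        out = []
        for t in topologies:
            for term in getattr(t, attr):
                out.append(tuple(file_index[(t.molecule_id, i)] for i in term.atoms))
        return out

    _emit("BOND: bonds", _collect("bonds"), 4)
    _emit("THETA: angles", _collect("angles"), 3)
    _emit("PHI: dihedrals", _collect("dihedrals"), 2)
    _emit("IMPHI: impropers", _collect("impropers"), 2)
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Parameter files


@dataclass(frozen=True)
class BondParam:
    force_constant: float
    r0: float


@dataclass(frozen=True)
class AngleParam:
    force_constant: float
    theta0: float


@dataclass(frozen=True)
class DihedralParam:
    force_constant: float
    periodicity: int
    phase: float


@dataclass(frozen=True)
class NonbondedParam:
    epsilon: float  # kcal/mol, stored positive
    rmin_half: float  # Å


@dataclass
class MissingParameterReport:
    bonds: list[tuple[str, str]] = field(default_factory=list)
    angles: list[tuple[str, str, str]] = field(default_factory=list)
    dihedrals: list[tuple[str, str, str, str]] = field(default_factory=list)
    atom_types: list[str] = field(default_factory=list)

    def ok(self) -> bool:
        return not (self.bonds or self.angles or self.dihedrals or self.atom_types)


@dataclass
class ParameterSet:
    """Bonded and nonbonded parameters keyed by atom-type tuples."""

    bonds: dict[tuple[str, str], BondParam] = field(default_factory=dict)
    angles: dict[tuple[str, str, str], AngleParam] = field(default_factory=dict)
    dihedrals: dict[tuple[str, str, str, str], list[DihedralParam]] = field(
        default_factory=dict
    )
    impropers: dict[tuple[str, str, str, str], AngleParam] = field(
        default_factory=dict
    )
    nonbonded: dict[str, NonbondedParam] = field(default_factory=dict)
    masses: dict[str, float] = field(default_factory=dict)

    def lookup_bond(self, t1: str, t2: str) -> BondParam | None:
        return self.bonds.get((t1, t2)) or self.bonds.get((t2, t1))

    def lookup_angle(self, t1: str, t2: str, t3: str) -> AngleParam | None:
        return self.angles.get((t1, t2, t3)) or self.angles.get((t3, t2, t1))

    def lookup_dihedral(
        self, t1: str, t2: str, t3: str, t4: str
    ) -> list[DihedralParam] | None:
        """Exact match first, then CHARMM wildcard ``X t2 t3 X``."""
        for key in ((t1, t2, t3, t4), (t4, t3, t2, t1)):
            if key in self.dihedrals:
                return self.dihedrals[key]
        for key in (("X", t2, t3, "X"), ("X", t3, t2, "X")):
            if key in self.dihedrals:
                return self.dihedrals[key]
        return None

    def lookup_nonbonded(self, atom_type: str) -> NonbondedParam | None:
        return self.nonbonded.get(atom_type)

    def resolve(self, topology: MoleculeTopology) -> tuple[MoleculeTopology, MissingParameterReport]:
        """Fill bonded-term parameters and LJ values from this set.

        Returns the parameterized topology and a report of any term whose
        type tuple has no entry.
        """
        report = MissingParameterReport()
        types = {a.index: a.atom_type for a in topology.atoms}

        new_atoms = []
        for a in topology.atoms:
            nb = self.lookup_nonbonded(a.atom_type)
            if nb is None:
                if not a.is_dummy:
                    report.atom_types.append(a.atom_type)
                new_atoms.append(a)
            else:
                new_atoms.append(
                    replace(a, lj_epsilon=nb.epsilon, lj_rmin_half=nb.rmin_half)
                )

        bonds = []
        for b in topology.bonds:
            key = (types[b.atoms[0]], types[b.atoms[1]])
            p = self.lookup_bond(*key)
            if p is None:
                report.bonds.append(key)
                bonds.append(b)
            else:
                bonds.append(BondTerm(b.atoms, p.force_constant, p.r0))

        angles = []
        for a in topology.angles:
            key = tuple(types[i] for i in a.atoms)
            p = self.lookup_angle(*key)
            if p is None:
                report.angles.append(key)  # type: ignore[arg-type]
                angles.append(a)
            else:
                angles.append(AngleTerm(a.atoms, p.force_constant, p.theta0))

        dihedrals = []
        for d in topology.dihedrals:
            key = tuple(types[i] for i in d.atoms)
            plist = self.lookup_dihedral(*key)
            if plist is None:
                report.dihedrals.append(key)  # type: ignore[arg-type]
                dihedrals.append(d)
            else:
                for p in plist:
                    dihedrals.append(
                        DihedralTerm(d.atoms, p.force_constant, p.periodicity, p.phase)
                    )

        topo = MoleculeTopology(
            atoms=new_atoms,
            bonds=bonds,
            angles=angles,
            dihedrals=dihedrals,
            impropers=list(topology.impropers),
            molecule_id=topology.molecule_id,
            segment=topology.segment,
        )
        return topo, report


_PRM_SECTIONS = {
    "BONDS", "ANGLES", "DIHEDRALS", "IMPROPERS", "IMPROPER", "NONBONDED",
    "CMAP", "NBFIX", "HBOND", "END", "ATOMS", "THETAS", "PHI",
}


def read_parameters(paths: list[str | Path] | str | Path) -> ParameterSet:
    """Parse RTF/PRM/stream files into a single :class:`ParameterSet`.

    Later files (and later lines) win on duplicate keys; a conflicting
    duplicate triggers a warning, matching CHARMM's last-wins behaviour.
    """
    if isinstance(paths, (str, Path)):
        paths = [paths]
    ps = ParameterSet()
    for path in paths:
        _parse_one(Path(path), ps)
    return ps


def _parse_one(path: Path, ps: ParameterSet) -> None:
    section = None
    for raw in path.read_text().splitlines():
        line = raw.split("!")[0].strip()
        if not line or line.startswith("*"):
            continue
        upper = line.upper()
        head = upper.split()[0]
        if head in _PRM_SECTIONS:
            section = {"IMPROPER": "IMPROPERS", "THETAS": "ANGLES", "PHI": "DIHEDRALS"}.get(head, head)
            continue
        parts = line.split()
        if head == "MASS" and len(parts) >= 4:
            ps.masses[parts[2]] = float(parts[3])
            continue
        if head in {"READ", "RESI", "PRES", "GROUP", "BOND", "DOUB", "ATOM",
                    "IC", "PATCHING", "DELETE", "DONOR", "ACCEPTOR", "AUTO",
                    "DEFA", "ANGL", "DIHE", "IMPH", "CUTNB", "CUTHB"}:
            continue  # residue-topology / option content we do not need
        try:
            if section == "BONDS" and len(parts) >= 4:
                key = (parts[0], parts[1])
                new = BondParam(float(parts[2]), float(parts[3]))
                _warn_dup(ps.bonds, key, new, "bond")
                ps.bonds[key] = new
            elif section == "ANGLES" and len(parts) >= 5:
                key = (parts[0], parts[1], parts[2])
                new = AngleParam(float(parts[3]), float(parts[4]))
                _warn_dup(ps.angles, key, new, "angle")
                ps.angles[key] = new
            elif section == "DIHEDRALS" and len(parts) >= 7:
                key = (parts[0], parts[1], parts[2], parts[3])
                term = DihedralParam(float(parts[4]), int(parts[5]), float(parts[6]))
                ps.dihedrals.setdefault(key, [])
                if term.periodicity in {t.periodicity for t in ps.dihedrals[key]}:
                    ps.dihedrals[key] = [
                        t for t in ps.dihedrals[key] if t.periodicity != term.periodicity
                    ]
                ps.dihedrals[key].append(term)
            elif section == "IMPROPERS" and len(parts) >= 7:
                key = (parts[0], parts[1], parts[2], parts[3])
                ps.impropers[key] = AngleParam(float(parts[4]), float(parts[6]))
            elif section == "NONBONDED" and len(parts) >= 4:
                # type  ignored  -epsilon  Rmin/2  [1-4 terms]
                ps.nonbonded[parts[0]] = NonbondedParam(
                    abs(float(parts[2])), float(parts[3])
                )
        except ValueError:
            continue  # continuation/option lines inside sections


def _warn_dup(store: dict, key, new, kind: str) -> None:
    rev = tuple(reversed(key))
    old = store.get(key) or store.get(rev)
    if old is not None and old != new:
        warnings.warn(
            f"duplicate {kind} parameters for {key}: {old} -> {new} (last wins)",
            stacklevel=3,
        )
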