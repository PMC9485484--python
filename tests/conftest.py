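"""Shared fixtures: small molecules built programmatically."""

from __future__ import annotations

import pytest

from ccsai.topology import AtomRecord, BondTerm, MoleculeTopology

C_LJ = (0.078, 2.04)
H_LJ = (0.024, 1.34)


def make_molecule(spec: list[tuple[str, float, float]], bonds, molecule_id="MOL"):
    """Build a MoleculeTopology from (element, charge, mass) triples."""
    atoms = []
    counts: dict[str, int] = {}
    for i, (el, q, m) in enumerate(spec):
        counts[el] = counts.get(el, 0) + 1
        lj = H_LJ if el == "H" else C_LJ
        atoms.append(
            AtomRecord(
                index=i,
                name=f"{el}{counts[el]}",
                element=el,
                atom_type=f"{el}T",
                charge=q,
                mass=m,
                lj_epsilon=lj[0],
                lj_rmin_half=lj[1],
            )
        )
    return MoleculeTopology(
        atoms=atoms,
        bonds=[BondTerm(tuple(b), 300.0, 1.5) for b in bonds],
        molecule_id=molecule_id,
    )


@pytest.fixture
def methane():
    return make_molecule(
        [("C", -0.36, 12.011)] + [("H", 0.09, 1.008)] * 4,
        [(0, 1), (0, 2), (0, 3), (0, 4)],
        "METH",
    )


@pytest.fixture
def benzene():
    spec = [("C", -0.115, 12.011)] * 6 + [("H", 0.115, 1.008)] * 6
    ring = [(i, (i + 1) % 6) for i in range(6)]
    ch = [(i, 6 + i) for i in range(6)]
    return make_molecule(spec, ring + ch, "BENZ")


@pytest.fixture
def toluene():
    # ring C0..C5, ring hydrogens H6..H10 on C1..C5, methyl C11 + H12..H14 on C0
    spec = (
        [("C", -0.115, 12.011)] * 6
        + [("H", 0.115, 1.008)] * 5
        + [("C", -0.27, 12.011)]
        + [("H", 0.09, 1.008)] * 3
    )
    ring = [(i, (i + 1) % 6) for i in range(6)]
    ch = [(i, 5 + i) for i in range(1, 6)]
    methyl = [(0, 11), (11, 12), (11, 13), (11, 14)]
    return make_molecule(spec, ring + ch + methyl, "TOLU")
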