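"""Topology data model, CHARMM I/O, HMR and charge audits."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccsai.charmm_io import (
    PSFParseError,
    read_parameters,
    read_psf,
    write_psf,
)
from ccsai.topology import (
    AtomRecord,
    BondTerm,
    MoleculeTopology,
    apply_hmr,
    total_charge,
)

from conftest import make_molecule


# ---------------------------------------------------------------- HMR


class TestHMR:
    def test_methane_hand_values(self, methane):
        """Factor-3 repartitioning of methane: H 3.024, C 12.011 − 4×2.016."""
        out = apply_hmr(methane, factor=3)
        hs = [a for a in out.atoms if a.element == "H"]
        assert all(math.isclose(a.mass, 3.024) for a in hs)
        c = out.atom(0)
        assert math.isclose(c.mass, 12.011 - 4 * 2.016)
        assert math.isclose(out.total_mass(), 16.043)

    def test_factor_one_is_identity(self, methane):
        out = apply_hmr(methane, factor=1)
        assert [a.mass for a in out.atoms] == [a.mass for a in methane.atoms]

    def test_water_excluded(self):
        water = MoleculeTopology(
            atoms=[
                AtomRecord(0, "OH2", "O", "OT", -0.834, 15.9994, residue="TIP3"),
                AtomRecord(1, "H1", "H", "HT", 0.417, 1.008, residue="TIP3"),
                AtomRecord(2, "H2", "H", "HT", 0.417, 1.008, residue="TIP3"),
            ],
            bonds=[BondTerm((0, 1), 450.0, 0.96), BondTerm((0, 2), 450.0, 0.96)],
        )
        out = apply_hmr(water, factor=3, exclude_water=True)
        assert [a.mass for a in out.atoms] == [a.mass for a in water.atoms]

    def test_mass_depletion_error(self):
        # a "heavy" atom lighter than its hydrogens' mass increment
        mol = make_molecule(
            [("C", 0.0, 2.0), ("H", 0.0, 1.008), ("H", 0.0, 1.008)],
            [(0, 1), (0, 2)],
        )
        with pytest.raises(ValueError, match="non-positive mass"):
            apply_hmr(mol, factor=3)

    @settings(max_examples=50, deadline=None)
    @given(
        n_heavy=st.integers(1, 6),
        h_counts=st.lists(st.integers(0, 3), min_size=6, max_size=6),
        factor=st.floats(1.0, 4.0),
    )
    def test_mass_conserved_on_random_topologies(self, n_heavy, h_counts, factor):
        """Per-molecule total mass is invariant to 1e-9 amu for any factor."""
        spec = [("C", 0.0, 12.011)] * n_heavy
        bonds = [(i, i + 1) for i in range(n_heavy - 1)]
        for i in range(n_heavy):
            for _ in range(h_counts[i]):
                spec.append(("H", 0.0, 1.008))
                bonds.append((i, len(spec) - 1))
        mol = make_molecule(spec, bonds)
        out = apply_hmr(mol, factor=factor)
        assert abs(out.total_mass() - mol.total_mass()) < 1e-9


# ---------------------------------------------------------------- charges


def test_total_charge_neutral_and_ion(methane):
    assert math.isclose(total_charge(methane), 0.0, abs_tol=1e-12)
    na = make_molecule([("NA", 1.0, 22.99)], [])
    assert total_charge(na) == 1.0


def test_total_charge_hand_sum():
    mol = make_molecule(
        [("C", -0.27, 12.011)] + [("H", 0.09, 1.008)] * 3 + [("C", 0.0, 12.011)],
        [(0, 1), (0, 2), (0, 3), (0, 4)],
    )
    assert math.isclose(total_charge(mol), 0.0, abs_tol=1e-12)


# ---------------------------------------------------------------- PSF I/O


PSF_5ATOM = """PSF EXT

         1 !NTITLE
* test fixture

         5 !NATOM
         1 LIG      1        LIG      C1       CT3        -0.270000     12.011000       0
         2 LIG      1        LIG      H1       HA3         0.090000      1.008000       0
         3 LIG      1        LIG      H2       HA3         0.090000      1.008000       0
         4 LIG      1        LIG      H3       HA3         0.090000      1.008000       0
         5 LIG      1        LIG      C2       CT2         0.000000     12.011000       0

         4 !NBOND: bonds
         1         2         1         3         1         4         1         5
"""


def test_read_psf_counts_and_charges(tmp_path):
    p = tmp_path / "lig.psf"
    p.write_text(PSF_5ATOM)
    (top,) = read_psf(p)
    assert len(top) == 5
    assert len(top.bonds) == 4
    assert math.isclose(total_charge(top), 0.0, abs_tol=1e-12)
    assert top.atom(0).atom_type == "CT3"
    assert top.atom(0).element == "C"


def test_psf_round_trip(tmp_path, toluene):
    p1, p2 = tmp_path / "a.psf", tmp_path / "b.psf"
    write_psf(toluene, p1)
    (back,) = read_psf(p1)
    write_psf(back, p2)
    (again,) = read_psf(p2)
    key = lambda t: [
        (a.index, a.name, a.atom_type, a.charge, a.mass) for a in t.atoms
    ]
    bonds = lambda t: sorted(tuple(sorted(b.atoms)) for b in t.bonds)
    assert key(back) == key(again)
    assert bonds(back) == bonds(again)
    # and the first read already matches the in-memory molecule
    assert key(back) == key(toluene)
    assert bonds(back) == bonds(toluene)


def test_malformed_header_names_line(tmp_path):
    p = tmp_path / "bad.psf"
    p.write_text("PSF\n\n   oops !NATOM\n")
    with pytest.raises(PSFParseError, match="line 3"):
        read_psf(p)


def test_natom_mismatch_rejected(tmp_path):
    p = tmp_path / "bad.psf"
    p.write_text(PSF_5ATOM.replace("         5 !NATOM", "         6 !NATOM"))
    with pytest.raises(PSFParseError, match="NATOM"):
        read_psf(p)


def test_numeric_type_dialect_rejected(tmp_path):
    p = tmp_path / "native.psf"
    p.write_text(
        "PSF\n\n         1 !NATOM\n"
        "         1 LIG      1        LIG      C1       7        -0.27     12.011       0\n"
    )
    with pytest.raises(PSFParseError, match="unsupported"):
        read_psf(p)


# ---------------------------------------------------------------- parameters


PRM_FIXTURE = """* test parameters
*

BONDS
CT3  HA3   322.00      1.111
CT3  CT2   222.50      1.528

ANGLES
HA3  CT3  HA3    35.50    108.40

DIHEDRALS
X    CT3  CT2  X        0.1600  3     0.00

NONBONDED
CT3     0.0       -0.0780    2.040
HA3     0.0       -0.0240    1.340
CT2     0.0       -0.0560    2.010

END
"""


class TestParameters:
    @pytest.fixture
    def params(self, tmp_path):
        p = tmp_path / "test.prm"
        p.write_text(PRM_FIXTURE)
        return read_parameters([p])

    def test_bond_lookup(self, params):
        b = params.lookup_bond("CT3", "HA3")
        assert b.r0 == 1.111
        assert b.force_constant == 322.0

    def test_lookup_symmetric_under_reversal(self, params):
        assert params.lookup_bond("HA3", "CT3") == params.lookup_bond("CT3", "HA3")
        assert params.lookup_angle("HA3", "CT3", "HA3") is not None

    def test_dihedral_wildcard(self, params):
        terms = params.lookup_dihedral("HA3", "CT3", "CT2", "HA3")
        assert terms is not None and terms[0].periodicity == 3

    def test_nonbonded_epsilon_positive(self, params):
        nb = params.lookup_nonbonded("CT3")
        assert nb.epsilon == 0.078 and nb.rmin_half == 2.04

    def test_missing_angle_reported(self, params):
        mol = make_molecule(
            [("C", 0.0, 12.011), ("C", 0.0, 12.011), ("C", 0.0, 12.011)],
            [(0, 1), (1, 2)],
        )
        from ccsai.topology import AngleTerm

        mol.angles.append(AngleTerm((0, 1, 2), 0.0, 0.0))
        # atom types CT are unknown too; both kinds must be reported
        _, report = params.resolve(mol)
        assert not report.ok()
        assert ("CT", "CT", "CT") in report.angles

    def test_duplicate_conflicting_entry_warns_last_wins(self, tmp_path):
        p = tmp_path / "dup.prm"
        p.write_text(
            "BONDS\nCT3 HA3 322.0 1.111\nCT3 HA3 300.0 1.100\nEND\n"
        )
        with pytest.warns(UserWarning, match="last wins"):
            ps = read_parameters([p])
        assert ps.lookup_bond("CT3", "HA3").r0 == 1.100

    def test_resolve_fills_lj_and_bonds(self, params, tmp_path):
        mol = make_molecule(
            [("C", -0.27, 12.011)] + [("H", 0.09, 1.008)] * 3,
            [(0, 1), (0, 2), (0, 3)],
        )
        # retype to fixture types
        from dataclasses import replace

        mol.atoms = [
            replace(a, atom_type="CT3" if a.element == "C" else "HA3")
            for a in mol.atoms
        ]
        out, report = params.resolve(mol)
        assert report.ok()
        assert out.atom(0).lj_epsilon == 0.078
        assert out.bonds[0].equilibrium == 1.111
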