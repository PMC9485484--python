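"""Staged mutation paths: state counts, charge conservation, stage V."""

from __future__ import annotations

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ccsai.common_core import derive_cc_spec, find_common_core
from ccsai.path_builder import (
    ProtocolConfig,
    build_pair_paths,
    build_path,
    emit_states,
    equalize_common_cores,
    heavy_atom_order,
    scale_charges,
)
from ccsai.topology import JUNCTION_TYPE
from ccsai.toy import make_toy_ligand_pair

from conftest import make_molecule


@pytest.fixture
def pair42():
    """Ligand pair with a 4-heavy + 2-H dummy region vs a single-H region."""
    return make_toy_ligand_pair(4, 2, seed=7)


class TestStageStructure:
    def test_stage_counts_default_protocol(self, pair42):
        """4 heavy + 2 H region with defaults: (I,II,III,IV) = (3,1,3,1)."""
        path = build_path(pair42.lig_a, pair42.spec, side="A")
        counts = path.stage_counts()
        assert (counts["I"], counts["II"], counts["III"], counts["IV"]) == (
            3, 1, 3, 1,
        )
        assert counts["native"] == 1

    def test_identical_ligand_gives_native_only(self):
        ls = make_toy_ligand_pair(0, 0, seed=1)
        path = build_path(ls.lig_a, ls.spec, side="A")
        assert len(path) == 1 and path.states[0].stage == "native"

    def test_single_hydrogen_region_collapses_stages(self, pair42):
        """A lone-H dummy region: 3 elec states, then one H→X state."""
        path = build_path(pair42.lig_b, pair42.spec, side="B")
        counts = path.stage_counts()
        assert counts == {"native": 1, "I": 3, "II": 1}
        final = path.states[-1]
        junction = pair42.spec.junction_atom("B", 0)
        assert final.atom_types[junction] == JUNCTION_TYPE
        assert final.charges[junction] == 0.0

    def test_two_heavy_atoms_per_step_halves_stage_three(self, pair42):
        cfg = ProtocolConfig(max_heavy_atoms_per_step=2)
        path = build_path(pair42.lig_a, pair42.spec, cfg, side="A")
        assert path.stage_counts()["III"] == 2  # ceil(3/2)

    def test_charge_conserved_across_every_state(self, pair42):
        for side, lig in (("A", pair42.lig_a), ("B", pair42.lig_b)):
            path = build_path(lig, pair42.spec, side=side)
            q0 = path.states[0].total_charge()
            for st_ in path.states:
                assert abs(st_.total_charge() - q0) <= 1e-6

    def test_exactly_one_lj_change_per_stage_three_state(self, pair42):
        path = build_path(pair42.lig_a, pair42.spec, side="A")
        prev = None
        for st_ in path.states:
            if st_.stage == "III" and prev is not None:
                changed = [
                    i for i in st_.lj
                    if (st_.lj[i] is None) != (prev.lj[i] is None)
                ]
                assert len(changed) == 1
            prev = st_

    def test_junction_lj_identical_for_both_ligands(self, pair42):
        pa = build_path(pair42.lig_a, pair42.spec, side="A")
        pb = build_path(pair42.lig_b, pair42.spec, side="B")
        ja = pair42.spec.junction_atom("A", 0)
        jb = pair42.spec.junction_atom("B", 0)
        assert pa.states[-1].lj[ja] == pb.states[-1].lj[jb]


class TestChargeScaling:
    def test_compensation_arithmetic(self, pair42):
        """s = 1/3 leaves 2/3 of the region charge on the attachment atom."""
        lig = pair42.lig_a
        native = {a.index: a.charge for a in lig.atoms}
        region = pair42.spec.dummy_regions["A"][0]
        attachment = pair42.spec.attachment_atom("A", 0)
        q_region = sum(native[i] for i in region)
        out = scale_charges(native, 1 / 3, pair42.spec, "A")
        for i in region:
            assert math.isclose(out[i], native[i] / 3)
        assert math.isclose(
            out[attachment], native[attachment] + 2 / 3 * q_region
        )
        assert math.isclose(sum(out.values()), sum(native.values()))

    def test_s_one_is_identity(self, pair42):
        native = {a.index: a.charge for a in pair42.lig_a.atoms}
        assert scale_charges(native, 1.0, pair42.spec, "A") == native

    def test_s_zero_moves_full_region_charge(self, pair42):
        native = {a.index: a.charge for a in pair42.lig_a.atoms}
        region = pair42.spec.dummy_regions["A"][0]
        out = scale_charges(native, 0.0, pair42.spec, "A")
        assert all(out[i] == 0.0 for i in region)
        assert math.isclose(sum(out.values()), sum(native.values()))


class TestHeavyAtomOrder:
    def test_linear_chain_farthest_first(self):
        # J(1)–A(2)–B(3)–C(4) hanging off CC atom 0
        a = make_molecule(
            [("C", 0.0, 12.011)] * 5,
            [(0, 1), (1, 2), (2, 3), (3, 4)],
            "A",
        )
        b = make_molecule([("C", 0.0, 12.011)], [], "B")
        mapping = find_common_core(a, b)
        spec = derive_cc_spec(mapping, a, b)
        (order,) = heavy_atom_order(spec, a, "A")
        assert order == [4, 3, 2]

    def test_branched_tie_breaks_by_higher_index(self):
        # junction 1 bonded to 2; 2 bonded to branches 3 and 4 (equidistant)
        a = make_molecule(
            [("C", 0.0, 12.011)] * 5,
            [(0, 1), (1, 2), (2, 3), (2, 4)],
            "A",
        )
        b = make_molecule([("C", 0.0, 12.011)], [], "B")
        spec = derive_cc_spec(find_common_core(a, b), a, b)
        (order,) = heavy_atom_order(spec, a, "A")
        assert order == [4, 3, 2]

    def test_single_heavy_atom_order(self, pair42):
        ls = make_toy_ligand_pair(1, 0, seed=3)
        assert heavy_atom_order(ls.spec, ls.lig_a, "A") == [[]]  # junction only


class TestStageFive:
    def test_auto_step_count_follows_bond_rule(self, pair42):
        """Δr0 ≈ 0.707 Å at 0.125 Å/step → 6 states."""
        pa, _ = build_pair_paths(pair42.lig_a, pair42.lig_b, pair42.spec)
        assert pa.stage_counts()["V"] == 6

    def test_identical_ccs_need_no_stage_five(self):
        ls = make_toy_ligand_pair(0, 0, seed=2)
        pa, _ = build_pair_paths(ls.lig_a, ls.lig_b, ls.spec)
        assert "V" not in pa.stage_counts()

    def test_manual_step_count_overrides_auto(self, pair42):
        cfg = ProtocolConfig(stage5_steps=5)
        pa, _ = build_pair_paths(pair42.lig_a, pair42.lig_b, pair42.spec, cfg)
        assert pa.stage_counts()["V"] == 5

    def test_endpoint_parameter_identity(self, pair42):
        """After stage V the two CC states agree field by field."""
        pa, pb = build_pair_paths(pair42.lig_a, pair42.lig_b, pair42.spec)
        final_a, final_b = pa.states[-1], pb.states[-1]
        a2b = dict(pair42.spec.mapping.a_to_b)
        ja = pair42.spec.junction_atom("A", 0)
        jb = pair42.spec.junction_atom("B", 0)
        a2b[ja] = jb
        for a, b in a2b.items():
            assert math.isclose(
                final_a.charges[a], final_b.charges[b], abs_tol=1e-12
            )
            assert final_a.lj[a] == final_b.lj[b]
        for (i, j), params in final_a.bonds.items():
            if i in a2b and j in a2b:
                key = tuple(sorted((a2b[i], a2b[j])))
                assert final_b.bonds[key] == pytest.approx(params)

    def test_charge_only_difference_takes_one_step(self, pair42):
        pa, pb = build_pair_paths(pair42.lig_a, pair42.lig_b, pair42.spec)
        cc_a, cc_b = pa.states[-1], pb.states[-1]
        # remove the bond difference by copying B's bonds onto A, leave a
        # charge imbalance of ±0.05 on two mapped atoms
        import copy

        cc_a2 = copy.deepcopy(cc_a)
        cc_a2.bonds = dict(cc_a.bonds)
        ja = pair42.spec.junction_atom("A", 0)
        jb = pair42.spec.junction_atom("B", 0)
        a2b = dict(pair42.spec.mapping.a_to_b) | {ja: jb}
        for (i, j) in list(cc_a2.bonds):
            if i in a2b and j in a2b:
                cc_a2.bonds[(i, j)] = cc_b.bonds[tuple(sorted((a2b[i], a2b[j])))]
        cc_a2.charges[0] += 0.05
        cc_a2.charges[1] -= 0.05
        states = equalize_common_cores(cc_a2, cc_b, pair42.spec)
        assert len(states) == 1

    @settings(max_examples=60, deadline=None)
    @given(dr=st.floats(0.01, 1.0))
    def test_bond_step_bound_property(self, dr):
        """No auto stage-V step moves a bond equilibrium by > 0.125 Å."""
        ls = make_toy_ligand_pair(2, 1, seed=11)
        pa, pb = build_pair_paths(ls.lig_a, ls.lig_b, ls.spec)
        cc_a, cc_b = pa.states[-1], pb.states[-1]
        # shrink/stretch the junction bond difference to the drawn Δr
        ja = ls.spec.junction_atom("A", 0)
        key_a = tuple(sorted((ls.spec.attachment_atom("A", 0), ja)))
        import copy

        cc_a2 = copy.deepcopy(cc_a)
        k0, _ = cc_a2.bonds[key_a]
        jb = ls.spec.junction_atom("B", 0)
        key_b = tuple(sorted((ls.spec.attachment_atom("B", 0), jb)))
        rb = cc_b.bonds[key_b][1]
        cc_a2.bonds[key_a] = (k0, rb + dr)
        states = equalize_common_cores(cc_a2, cc_b, ls.spec)
        assert len(states) == math.ceil(dr / 0.125 - 1e-12)
        prev = cc_a2
        for st_ in states:
            for key in st_.bonds:
                change = abs(st_.bonds[key][1] - prev.bonds[key][1])
                assert change <= 0.125 + 1e-9
            prev = st_


class TestEmission:
    def test_state_directories_and_manifests(self, tmp_path, pair42):
        pa, _ = build_pair_paths(pair42.lig_a, pair42.lig_b, pair42.spec)
        dirs = emit_states(pa, tmp_path)
        assert len(dirs) == len(pa)
        import yaml

        man = yaml.safe_load((dirs[5] / "manifest.yaml").read_text())
        assert man["state_index"] == 5
        assert (dirs[0] / "overrides.prm").exists()

    def test_reemission_is_byte_identical(self, tmp_path, pair42):
        pa, _ = build_pair_paths(pair42.lig_a, pair42.lig_b, pair42.spec)
        d1 = emit_states(pa, tmp_path / "run1")
        d2 = emit_states(pa, tmp_path / "run2")
        for a, b in zip(d1, d2):
            for name in ("manifest.yaml", "overrides.prm"):
                assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_stage_three_manifest_lists_single_delta(self, tmp_path, pair42):
        pa = build_path(pair42.lig_a, pair42.spec, side="A")
        dirs = emit_states(pa, tmp_path)
        import yaml

        stage3 = [
            yaml.safe_load((d / "manifest.yaml").read_text())
            for d in dirs
        ]
        stage3 = [m for m in stage3 if m["stage"] == "III"]
        assert stage3 and all(len(m["deltas"]["lj_off"]) == 1 for m in stage3)


class TestProtocolConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_elec_steps": 0},
            {"n_elec_steps": 6},
            {"max_heavy_atoms_per_step": 3},
            {"max_bond_step": 0.0},
            {"stage5_steps": "sometimes"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ProtocolConfig(**kwargs)
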