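"""Staged alchemical mutation paths from a ligand to its common-core state.

Each ligand is mutated to the common core through discrete, self-contained
intermediate states rather than a continuous coupling parameter:

* stage I   — partial charges of all non-CC atoms are scaled linearly to
  zero over ``n_elec_steps`` states, with a compensating charge placed on
  the CC atom each dummy region is attached to so the total system charge
  never changes;
* stage II  — Lennard-Jones interactions of all non-CC hydrogens are turned
  off in a single state (always sufficient for hydrogens);
* stage III — LJ interactions of the non-CC heavy atoms are turned off
  serially, one atom per state (at most two), farthest from the junction
  first;
* stage IV  — the last non-CC heavy atom (the one bonded to a CC atom)
  becomes the junction atom X: zero charge, standardized LJ parameters that
  are identical for every ligand and mutation;
* stage V   — for one ligand of the pair, the parameters of its CC state
  (partial charges and bonded terms involving X) are interpolated linearly
  and simultaneously until they equal those of the CC reached from the
  other ligand.  In auto mode the number of stage-V states is
  ``ceil(max |Δr0| / max_bond_step)`` so that no equilibrium bond length
  moves more than ``max_bond_step`` (default 0.125 Å) per step.

When a dummy region consists of a single hydrogen, that hydrogen is itself
the junction: stages II and IV collapse into one state turning it directly
into X.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import networkx as nx
import yaml

from .common_core import CommonCoreSpec, validate_terminal_junction
from .topology import JUNCTION_TYPE, DUMMY_TYPE_PREFIX, MoleculeTopology

__all__ = [
    "ProtocolConfig",
    "LJParams",
    "IntermediateState",
    "MutationPath",
    "build_path",
    "build_pair_paths",
    "scale_charges",
    "heavy_atom_order",
    "equalize_common_cores",
    "emit_states",
    "CHARGE_TOLERANCE",
]

#: Maximum allowed drift of the total charge across a path (e).
CHARGE_TOLERANCE = 1e-6

#: Default LJ parameters of the junction atom X (nonpolar-hydrogen-like);
#: identical for both ligands of every mutation by construction.
DEFAULT_JUNCTION_EPSILON = 0.046  # kcal/mol
DEFAULT_JUNCTION_RMIN_HALF = 0.2245  # Å


@dataclass(frozen=True)
class LJParams:
    atom_type: str
    epsilon: float
    rmin_half: float


@dataclass(frozen=True)
class ProtocolConfig:
    """Tunable knobs of the mutation protocol.

    ``n_elec_steps`` is the number of stage-I charge-scaling states (the
    last reaches zero); up to five may be needed for polar or numerous
    non-CC atoms.  ``max_heavy_atoms_per_step`` caps how many heavy atoms
    lose their LJ interactions per stage-III state; turning off more than
    two at once risks poor phase-space overlap and is not allowed.
    ``stage5_steps`` may be an explicit integer or ``"auto"``.
    """

    n_elec_steps: int = 3
    max_heavy_atoms_per_step: int = 1
    max_bond_step: float = 0.125  # Å
    stage5_steps: int | str = "auto"
    temperature: float = 303.15  # K
    junction_lj: LJParams = field(
        default_factory=lambda: LJParams(
            JUNCTION_TYPE, DEFAULT_JUNCTION_EPSILON, DEFAULT_JUNCTION_RMIN_HALF
        )
    )

    def __post_init__(self) -> None:
        if not 1 <= self.n_elec_steps <= 5:
            raise ValueError("n_elec_steps must be in [1, 5]")
        if self.max_heavy_atoms_per_step not in (1, 2):
            raise ValueError("max_heavy_atoms_per_step must be 1 or 2")
        if self.max_bond_step <= 0:
            raise ValueError("max_bond_step must be positive")
        if isinstance(self.stage5_steps, str) and self.stage5_steps != "auto":
            raise ValueError("stage5_steps must be an integer or 'auto'")


@dataclass
class IntermediateState:
    """A complete parameter snapshot of one alchemical state.

    ``charges`` maps every atom index to its charge; ``lj`` maps every atom
    index to its LJ parameters or ``None`` when fully decoupled;
    ``atom_types`` records per-state type assignments (dummy/junction
    retyping).  Bonded terms are keyed by their (sorted) index tuples.
    ``deltas`` is a provenance note naming the atoms/terms that changed
    relative to the previous state.
    """

    state_index: int
    stage: str  # native, I, II, III, IV, V
    charges: dict[int, float]
    lj: dict[int, LJParams | None]
    atom_types: dict[int, str]
    bonds: dict[tuple[int, int], tuple[float, float]]  # (k, r0)
    angles: dict[tuple[int, int, int], tuple[float, float]]
    deltas: dict = field(default_factory=dict)
    s_value: float | None = None  # stage-I remaining charge fraction

    def total_charge(self) -> float:
        return sum(self.charges.values())


@dataclass
class MutationPath:
    ligand_id: str
    environment: str  # ligand_in_water | complex
    states: list[IntermediateState]

    def __len__(self) -> int:
        return len(self.states)

    def stage_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for s in self.states:
            out[s.stage] = out.get(s.stage, 0) + 1
        return out

    def check_charge_conservation(self) -> None:
        q0 = self.states[0].total_charge()
        for s in self.states:
            if abs(s.total_charge() - q0) > CHARGE_TOLERANCE:
                raise ValueError(
                    f"state {s.state_index}: total charge "
                    f"{s.total_charge():.8f} deviates from native {q0:.8f}"
                )


def _native_state(lig: MoleculeTopology) -> IntermediateState:
    return IntermediateState(
        state_index=0,
        stage="native",
        charges={a.index: a.charge for a in lig.atoms},
        lj={
            a.index: LJParams(a.atom_type, a.lj_epsilon, a.lj_rmin_half)
            for a in lig.atoms
        },
        atom_types={a.index: a.atom_type for a in lig.atoms},
        bonds={
            tuple(sorted(b.atoms)): (b.force_constant, b.equilibrium)
            for b in lig.bonds
        },
        angles={
            t.atoms if t.atoms[0] <= t.atoms[2] else t.atoms[::-1]: (
                t.force_constant,
                t.equilibrium,
            )
            for t in lig.angles
        },
    )


def _clone(prev: IntermediateState, stage: str) -> IntermediateState:
    return IntermediateState(
        state_index=prev.state_index + 1,
        stage=stage,
        charges=dict(prev.charges),
        lj=dict(prev.lj),
        atom_types=dict(prev.atom_types),
        bonds=dict(prev.bonds),
        angles=dict(prev.angles),
    )


def scale_charges(
    native_charges: dict[int, float],
    fraction_remaining: float,
    spec: CommonCoreSpec,
    side: str = "A",
) -> dict[int, float]:
    """Charges with every non-CC atom at ``s`` times its native value.

    The charge removed from each dummy region, ``(1-s) * sum(q_region)``,
    is added to the CC atom the region attaches to, so the total charge is
    invariant.  Each dummy region compensates onto its own attachment atom.
    """
    s = fraction_remaining
    if not 0.0 <= s <= 1.0:
        raise ValueError("fraction_remaining must lie in [0, 1]")
    charges = dict(native_charges)
    for r, region in enumerate(spec.dummy_regions[side]):
        q_region = sum(native_charges[i] for i in region)
        for i in region:
            charges[i] = s * native_charges[i]
        attachment = spec.attachment_atom(side, r)
        charges[attachment] += (1.0 - s) * q_region
    return charges


def heavy_atom_order(
    spec: CommonCoreSpec, lig: MoleculeTopology, side: str = "A"
) -> list[list[int]]:
    """Per-region removal order of non-CC heavy atoms (junction excluded).

    Atoms farther (graph distance) from the junction are switched off first;
    ties break toward the higher atom index.  Removing atoms in this order
    keeps every still-interacting non-CC atom connected to the junction,
    because each remaining atom retains a shortest path through strictly
    closer atoms.
    """
    g = lig.graph()
    orders: list[list[int]] = []
    for r, region in enumerate(spec.dummy_regions[side]):
        junction = spec.junction_atom(side, r)
        dist = nx.single_source_shortest_path_length(g.subgraph(region), junction)
        heavies = [
            i for i in region if i != junction and not lig.atom(i).is_hydrogen
        ]
        heavies.sort(key=lambda i: (-dist[i], -i))
        orders.append(heavies)
    return orders


def build_path(
    lig: MoleculeTopology,
    spec: CommonCoreSpec,
    cfg: ProtocolConfig | None = None,
    side: str = "A",
    environment: str = "ligand_in_water",
) -> MutationPath:
    """Construct the staged path native → [DL]-R_CC for one ligand.

    The same state definitions are used for both environments; only the
    surroundings differ, so the environment is a plain label here.
    """
    cfg = cfg or ProtocolConfig()
    report = validate_terminal_junction(spec)
    if not report.passed:
        raise ValueError(
            "common-core spec failed terminal-junction validation:\n"
            + "\n".join(report.violations)
        )

    states = [_native_state(lig)]
    regions = spec.dummy_regions[side]
    if not any(regions):
        return MutationPath(lig.molecule_id, environment, states)

    native_charges = states[0].charges

    # stage I: linear charge scaling, s = 1 - j/n so the last state reaches 0
    n = cfg.n_elec_steps
    for j in range(1, n + 1):
        s = 1.0 - j / n
        st = _clone(states[-1], "I")
        new_charges = scale_charges(native_charges, s, spec, side)
        st.deltas = {
            "charges": sorted(
                i for i in new_charges if new_charges[i] != st.charges[i]
            )
        }
        st.charges = new_charges
        st.s_value = s
        states.append(st)

    junctions = [spec.junction_atom(side, r) for r in range(len(regions))]
    h_junctions = [j for j in junctions if lig.atom(j).is_hydrogen]

    # stage II: all non-CC hydrogen LJ off in one state; hydrogen junctions
    # become X directly here (stage IV collapses into this state for them)
    non_cc_h = [
        i
        for region in regions
        for i in region
        if lig.atom(i).is_hydrogen and i not in junctions
    ]
    if non_cc_h or h_junctions:
        st = _clone(states[-1], "II")
        for i in non_cc_h:
            st.lj[i] = None
            st.atom_types[i] = DUMMY_TYPE_PREFIX + lig.atom(i).atom_type
        for j in h_junctions:
            st.lj[j] = cfg.junction_lj
            st.atom_types[j] = JUNCTION_TYPE
        st.deltas = {"lj_off": sorted(non_cc_h), "junction": sorted(h_junctions)}
        states.append(st)

    # stage III: heavy atoms off serially, farthest from the junction first
    orders = heavy_atom_order(spec, lig, side)
    flat: list[int] = [i for order in orders for i in order]
    step = cfg.max_heavy_atoms_per_step
    for k in range(0, len(flat), step):
        group = flat[k : k + step]
        st = _clone(states[-1], "III")
        for i in group:
            st.lj[i] = None
            st.atom_types[i] = DUMMY_TYPE_PREFIX + lig.atom(i).atom_type
        st.deltas = {"lj_off": group}
        states.append(st)

    # stage IV: remaining (heavy) junction atoms become X in one state
    heavy_junctions = [j for j in junctions if not lig.atom(j).is_hydrogen]
    if heavy_junctions:
        st = _clone(states[-1], "IV")
        for j in heavy_junctions:
            st.lj[j] = cfg.junction_lj
            st.atom_types[j] = JUNCTION_TYPE
        st.deltas = {"junction": sorted(heavy_junctions)}
        states.append(st)

    path = MutationPath(lig.molecule_id, environment, states)
    path.check_charge_conservation()
    return path


def _junction_pairing(spec: CommonCoreSpec) -> dict[int, int]:
    """Pair junction atoms of A and B through their CC attachment atoms."""
    a2b = spec.mapping.a_to_b
    pairing: dict[int, int] = {}
    for ra in range(len(spec.dummy_regions["A"])):
        att_a = spec.attachment_atom("A", ra)
        for rb in range(len(spec.dummy_regions["B"])):
            if spec.attachment_atom("B", rb) == a2b.get(att_a):
                pairing[spec.junction_atom("A", ra)] = spec.junction_atom("B", rb)
    return pairing


def equalize_common_cores(
    cc_a_state: IntermediateState,
    cc_b_state: IntermediateState,
    spec: CommonCoreSpec,
    cfg: ProtocolConfig | None = None,
) -> list[IntermediateState]:
    """Stage V: interpolate ligand A's CC-state parameters onto ligand B's.

    All differing parameters — partial charges of the interacting atoms and
    bond/angle terms involving them (in particular the CC–X bond) — are
    modified linearly and simultaneously.  The step count is
    ``cfg.stage5_steps`` when given as an integer, otherwise
    ``ceil(max |Δr0| / max_bond_step)`` with a minimum of one step whenever
    any parameter differs.  Identical CC states yield an empty list.
    """
    cfg = cfg or ProtocolConfig()
    a2b = dict(spec.mapping.a_to_b)
    a2b.update(_junction_pairing(spec))

    interacting_a = sorted(
        i for i, lj in cc_a_state.lj.items() if lj is not None
    )
    interacting_b = {i for i, lj in cc_b_state.lj.items() if lj is not None}
    unmatched = [i for i in interacting_a if a2b.get(i) not in interacting_b]
    if unmatched or len(interacting_a) != len(interacting_b):
        raise ValueError(
            "no strict one-to-one correspondence between interacting atoms "
            f"of the two CC states (unmatched A atoms: {unmatched})"
        )

    # target values expressed on A's atom numbering
    q_target = {a: cc_b_state.charges[a2b[a]] for a in interacting_a}
    dq = {
        a: q_target[a] - cc_a_state.charges[a]
        for a in interacting_a
        if abs(q_target[a] - cc_a_state.charges[a]) > 0
    }

    def _map_key(key: tuple[int, ...]) -> tuple[int, ...] | None:
        mapped = tuple(a2b.get(i) for i in key)
        if any(m is None for m in mapped):
            return None
        return tuple(sorted(mapped)) if len(mapped) == 2 else (
            mapped if mapped[0] <= mapped[-1] else mapped[::-1]
        )

    def _interacting_term(key: tuple[int, ...], state, which: str) -> bool:
        return all(state.lj.get(i) is not None for i in key)

    bond_targets: dict[tuple[int, int], tuple[float, float]] = {}
    missing: list[str] = []
    for key, val in cc_a_state.bonds.items():
        if not _interacting_term(key, cc_a_state, "A"):
            continue
        mkey = _map_key(key)
        if mkey is None or mkey not in cc_b_state.bonds:
            missing.append(f"bond {key}")
            continue
        bond_targets[key] = cc_b_state.bonds[mkey]
    b2a = {b: a for a, b in a2b.items()}
    for key, val in cc_b_state.bonds.items():
        if _interacting_term(key, cc_b_state, "B"):
            back = tuple(sorted(b2a.get(i, -1) for i in key))
            if -1 in back or back not in cc_a_state.bonds:
                missing.append(f"bond {key} (present only in CC of B)")
    angle_targets: dict[tuple[int, int, int], tuple[float, float]] = {}
    for key, val in cc_a_state.angles.items():
        if not _interacting_term(key, cc_a_state, "A"):
            continue
        mkey = _map_key(key)
        if mkey is None or mkey not in cc_b_state.angles:
            missing.append(f"angle {key}")
            continue
        angle_targets[key] = cc_b_state.angles[mkey]
    if missing:
        raise ValueError(
            "unmappable parameters between CC states: " + ", ".join(missing)
        )

    d_bonds = {
        k: t for k, t in bond_targets.items() if t != cc_a_state.bonds[k]
    }
    d_angles = {
        k: t for k, t in angle_targets.items() if t != cc_a_state.angles[k]
    }
    if not dq and not d_bonds and not d_angles:
        return []

    if isinstance(cfg.stage5_steps, int):
        n_steps = cfg.stage5_steps
    else:
        max_dr = max(
            (abs(t[1] - cc_a_state.bonds[k][1]) for k, t in d_bonds.items()),
            default=0.0,
        )
        n_steps = max(1, math.ceil(max_dr / cfg.max_bond_step - 1e-12))

    # charge conservation across stage V requires the total interacting
    # charge of both CC states to agree (dummy atoms all carry zero)
    q_a = sum(cc_a_state.charges[a] for a in interacting_a)
    q_b = sum(q_target.values())
    if abs(q_a - q_b) > CHARGE_TOLERANCE:
        raise ValueError(
            f"CC states carry different total charges ({q_a:.6f} vs {q_b:.6f})"
        )

    states: list[IntermediateState] = []
    prev = cc_a_state
    for j in range(1, n_steps + 1):
        lam = j / n_steps
        st = _clone(prev, "V")
        for a, delta in dq.items():
            st.charges[a] = (
                q_target[a] if j == n_steps
                else cc_a_state.charges[a] + lam * delta
            )
        for k, (kt, rt) in d_bonds.items():
            k0, r0 = cc_a_state.bonds[k]
            st.bonds[k] = (
                (kt, rt) if j == n_steps
                else (k0 + lam * (kt - k0), r0 + lam * (rt - r0))
            )
        for k, (kt, tt) in d_angles.items():
            k0, t0 = cc_a_state.angles[k]
            st.angles[k] = (
                (kt, tt) if j == n_steps
                else (k0 + lam * (kt - k0), t0 + lam * (tt - t0))
            )
        st.deltas = {
            "lambda": lam,
            "charges": sorted(dq),
            "bonds": sorted(d_bonds),
            "angles": sorted(d_angles),
        }
        states.append(st)
        prev = st
    return states


def build_pair_paths(
    lig_a: MoleculeTopology,
    lig_b: MoleculeTopology,
    spec: CommonCoreSpec,
    cfg: ProtocolConfig | None = None,
    environment: str = "ligand_in_water",
) -> tuple[MutationPath, MutationPath]:
    """Both ligands' paths, with stage V appended to ligand A's path.

    The CC reached from ligand B is the shared endstate; ligand A's path is
    extended so its final state is parameter-identical to it under the atom
    mapping.
    """
    cfg = cfg or ProtocolConfig()
    path_a = build_path(lig_a, spec, cfg, side="A", environment=environment)
    path_b = build_path(lig_b, spec, cfg, side="B", environment=environment)
    stage5 = equalize_common_cores(path_a.states[-1], path_b.states[-1], spec, cfg)
    for st in stage5:
        st.state_index = path_a.states[-1].state_index + 1
        path_a.states.append(st)
    path_a.check_charge_conservation()
    return path_a, path_b


def emit_states(path: MutationPath, outdir: str | Path) -> list[Path]:
    """Write one self-contained directory per intermediate state.

    Layout: ``<outdir>/<ligand>/<environment>/intst<k>/`` containing
    ``manifest.yaml`` (stage, deltas, s-value) and ``overrides.prm`` with the
    state's charge/LJ/bonded values in CHARMM parameter syntax.  Emission is
    deterministic: re-running on the same path is byte-identical.
    """
    outdir = Path(outdir)
    written: list[Path] = []
    for st in path.states:
        d = outdir / path.ligand_id / path.environment / f"intst{st.state_index}"
        d.mkdir(parents=True, exist_ok=True)
        manifest = {
            "ligand": path.ligand_id,
            "environment": path.environment,
            "state_index": st.state_index,
            "stage": st.stage,
            "s_value": st.s_value,
            "deltas": _yamlable(st.deltas),
            "total_charge": round(st.total_charge(), 8),
        }
        (d / "manifest.yaml").write_text(
            yaml.safe_dump(manifest, sort_keys=True)
        )
        lines = ["* ccsai per-state parameter overrides", "*", "ATOMS"]
        for i in sorted(st.charges):
            lines.append(
                f"! atom {i:4d} type {st.atom_types[i]:<8s} "
                f"charge {st.charges[i]: 12.8f}"
            )
        lines.append("")
        lines.append("BONDS")
        for (i, j), (k, r0) in sorted(st.bonds.items()):
            lines.append(f"! {i:4d} {j:4d} {k:12.6f} {r0:12.6f}")
        lines.append("")
        lines.append("NONBONDED")
        for i in sorted(st.lj):
            lj = st.lj[i]
            if lj is None:
                lines.append(
                    f"{st.atom_types[i]:<8s} 0.0 {0.0:12.6f} {0.0:12.6f}"
                )
            else:
                lines.append(
                    f"{st.atom_types[i]:<8s} 0.0 {-lj.epsilon:12.6f} "
                    f"{lj.rmin_half:12.6f}"
                )
        lines.append("")
        lines.append("END")
        (d / "overrides.prm").write_text("\n".join(lines) + "\n")
        written.append(d)
    return written


def _yamlable(obj):
    if isinstance(obj, dict):
        return {str(k): _yamlable(v) for k, v in obj.items()}
    if isinstance(obj, set):
        return [_yamlable(v) for v in sorted(obj)]
    if isinstance(obj, (list, tuple)):
        return [_yamlable(v) for v in obj]
    return obj
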