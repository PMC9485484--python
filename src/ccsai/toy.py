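"""Analytically solvable toy systems standing in for the MD engine.

Each alchemical state is modelled as a D-dimensional harmonic oscillator in
reduced units (β = 1), whose free energy is known in closed form:
f = Σ_d ½ ln(k_d / 2π) up to a shared additive constant, so
Δf = ½ Σ_d ln(k'_d / k_d) exactly.  Exact Gaussian sampling from each state
and evaluation of the reduced energies at all states produce the same K×N
matrices an MD engine adapter would, which makes path construction, MBAR
estimation and network propagation testable end to end without simulation.

The module also builds small synthetic ligand topologies sharing a common
core, emulating a ligand pair whose dummy regions differ in size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .common_core import CommonCoreSpec, derive_cc_spec, find_common_core
from .estimator import (
    BOLTZMANN_KCAL,
    ReducedPotentialMatrix,
    solve_mbar,
)
from .topology import AtomRecord, BondTerm, MoleculeTopology

__all__ = [
    "ToyState",
    "ToyLigandSet",
    "analytic_free_energy",
    "sample_states",
    "harmonic_ladder",
    "make_toy_ligand_pair",
    "simulate_leg",
    "simulate_pair_ddg",
]


@dataclass(frozen=True)
class ToyState:
    """A separable harmonic state: u(x) = ½ Σ_d k_d (x_d − μ_d)²  (kT units)."""

    spring_constants: tuple[float, ...]
    centers: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if any(k <= 0 for k in self.spring_constants):
            raise ValueError("spring constants must be positive")
        if self.centers and len(self.centers) != len(self.spring_constants):
            raise ValueError("centers must match dimensionality")

    @property
    def dimension(self) -> int:
        return len(self.spring_constants)

    def mu(self) -> np.ndarray:
        if self.centers:
            return np.asarray(self.centers)
        return np.zeros(self.dimension)

    def reduced_energy(self, x: np.ndarray) -> np.ndarray:
        k = np.asarray(self.spring_constants)
        return 0.5 * ((x - self.mu()) ** 2 * k).sum(axis=-1)


def analytic_free_energy(state: ToyState) -> float:
    """Reduced free energy f = Σ_d ½ ln(k_d / 2π); differences are exact."""
    k = np.asarray(state.spring_constants)
    return float(0.5 * np.log(k / (2.0 * np.pi)).sum())


def sample_states(
    states: list[ToyState],
    n_per_state: int,
    seed: int,
    temperature: float = 303.15,
) -> ReducedPotentialMatrix:
    """Exact Gaussian draws from each state, evaluated under all states.

    Deterministic for a given seed.  Returns the K×N reduced-potential
    matrix with N_k = ``n_per_state`` samples from every state.
    """
    if n_per_state < 1:
        raise ValueError("n_per_state must be >= 1")
    dims = {s.dimension for s in states}
    if len(dims) != 1:
        raise ValueError("all states must share one dimensionality")
    rng = np.random.default_rng(seed)
    K = len(states)
    xs = []
    for s in states:
        sd = 1.0 / np.sqrt(np.asarray(s.spring_constants))
        xs.append(rng.normal(s.mu(), sd, size=(n_per_state, s.dimension)))
    x_all = np.concatenate(xs, axis=0)  # N×D
    u_kn = np.stack([s.reduced_energy(x_all) for s in states], axis=0)
    return ReducedPotentialMatrix(
        u_kn=u_kn,
        N_k=np.full(K, n_per_state),
        temperature=temperature,
    )


def harmonic_ladder(
    n_states: int, delta_f: float, k_start: float = 1.0
) -> list[ToyState]:
    """1-D states with ln k linear across the ladder and exact endpoint Δf.

    Since Δf = ½ ln(k_end / k_start), the endpoint spring constant is
    k_start·exp(2Δf).  The geometric spacing makes consecutive-state overlap
    uniform; squeezing ``delta_f`` over few states produces the
    poor-overlap regime deliberately.
    """
    if n_states < 2:
        raise ValueError("a ladder needs at least two states")
    log_k = np.linspace(
        np.log(k_start), np.log(k_start) + 2.0 * delta_f, n_states
    )
    return [ToyState((float(np.exp(lk)),)) for lk in log_k]


def simulate_leg(
    n_states: int,
    true_delta_g_kcal: float,
    n_per_state: int,
    seed: int,
    temperature: float = 303.15,
) -> tuple[float, float]:
    """Sample a harmonic ladder whose true ΔG is known and estimate it.

    Returns ``(delta_g, sigma)`` in kcal/mol from MBAR on exact samples of
    an ``n_states``-state ladder with endpoint free energy
    ``true_delta_g_kcal``.
    """
    kt = BOLTZMANN_KCAL * temperature
    ladder = harmonic_ladder(max(2, n_states), true_delta_g_kcal / kt)
    u = sample_states(ladder, n_per_state, seed, temperature)
    result = solve_mbar(u)
    return result.delta_g_kcal, result.d_delta_g_kcal or 0.0


def simulate_pair_ddg(
    ligset: "ToyLigandSet",
    n_per_state: int = 400,
    seed: int = 0,
    temperature: float = 303.15,
):
    """End-to-end ΔΔG(A→B) for a toy ligand pair.

    Builds both ligands' mutation paths, emulates each leg (ligand-in-water
    and complex, for both ligands) as a harmonic ladder with as many states
    as the path has and an endpoint free energy equal to the assigned true
    leg value, runs MBAR on exact samples, and combines the legs through
    the thermodynamic cycle.  Returns a Measurement in kcal/mol.
    """
    from .network import LegResult, Measurement, ddG_pair, ddG_to_cc
    from .path_builder import build_pair_paths

    path_a, path_b = build_pair_paths(ligset.lig_a, ligset.lig_b, ligset.spec)
    lengths = {"A": max(2, len(path_a)), "B": max(2, len(path_b))}
    legs = {}
    sub = np.random.default_rng(seed).integers(0, 2**31 - 1, size=4)
    for i, (side, env) in enumerate(
        (s, e) for s in ("A", "B") for e in ("ligand_in_water", "complex")
    ):
        dg, sigma = simulate_leg(
            lengths[side],
            ligset.true_legs[(side, env)],
            n_per_state,
            int(sub[i]),
            temperature,
        )
        legs[(side, env)] = Measurement(dg, sigma)
    cc_a = ddG_to_cc(
        LegResult("A", legs[("A", "ligand_in_water")], legs[("A", "complex")])
    )
    cc_b = ddG_to_cc(
        LegResult("B", legs[("B", "ligand_in_water")], legs[("B", "complex")])
    )
    return ddG_pair(cc_a, cc_b)


# --------------------------------------------------------------------------
# Synthetic ligand pairs


@dataclass
class ToyLigandSet:
    """Two synthetic ligands reducing to one CC, with assigned true ΔGs."""

    lig_a: MoleculeTopology
    lig_b: MoleculeTopology
    spec: CommonCoreSpec
    true_legs: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0


_CC_BOND = (222.5, 1.528)  # kcal/mol/Å², Å (alkane C–C like)
_CH_BOND = (309.0, 1.111)
_CS_BOND = (198.0, 1.818)  # used for the junction bond of the larger ligand
_C_LJ = (0.078, 2.04)
_H_LJ = (0.024, 1.34)


def _scaffold_atoms() -> tuple[list[AtomRecord], list[BondTerm]]:
    """Shared CC scaffold: propyl backbone C0–C1–C2 with 6 hydrogens.

    C2 keeps one open valence for the dummy region (or its capping H).
    """
    atoms = [
        AtomRecord(0, "C1", "C", "CT3", -0.27, 12.011, *_C_LJ),
        AtomRecord(1, "C2", "C", "CT2", -0.18, 12.011, *_C_LJ),
        AtomRecord(2, "C3", "C", "CT2", -0.10, 12.011, *_C_LJ),
        AtomRecord(3, "H11", "H", "HA3", 0.09, 1.008, *_H_LJ),
        AtomRecord(4, "H12", "H", "HA3", 0.09, 1.008, *_H_LJ),
        AtomRecord(5, "H13", "H", "HA3", 0.09, 1.008, *_H_LJ),
        AtomRecord(6, "H21", "H", "HA2", 0.09, 1.008, *_H_LJ),
        AtomRecord(7, "H22", "H", "HA2", 0.09, 1.008, *_H_LJ),
        AtomRecord(8, "H31", "H", "HA2", 0.09, 1.008, *_H_LJ),
    ]
    bonds = [
        BondTerm((0, 1), *_CC_BOND),
        BondTerm((1, 2), *_CC_BOND),
        BondTerm((0, 3), *_CH_BOND),
        BondTerm((0, 4), *_CH_BOND),
        BondTerm((0, 5), *_CH_BOND),
        BondTerm((1, 6), *_CH_BOND),
        BondTerm((1, 7), *_CH_BOND),
        BondTerm((2, 8), *_CH_BOND),
    ]
    return atoms, bonds


def _with_region(
    molecule_id: str, n_heavy: int, n_h: int, junction_bond: tuple[float, float]
) -> MoleculeTopology:
    """Scaffold plus a dummy region: a chain of carbons (junction first)
    hanging off C2, with hydrogens on the terminal chain atom."""
    atoms, bonds = _scaffold_atoms()
    next_idx = len(atoms)
    region_charge = 0.10  # balances C3's reduced charge vs. the capped form
    if n_heavy == 0 and n_h == 0:
        # bare CC: cap C2 with a hydrogen
        atoms.append(
            AtomRecord(next_idx, "H32", "H", "HA2", region_charge, 1.008, *_H_LJ)
        )
        bonds.append(BondTerm((2, next_idx), *_CH_BOND))
        return MoleculeTopology(atoms, bonds, molecule_id=molecule_id)

    per_atom = region_charge / (n_heavy + n_h)
    chain: list[int] = []
    attach = 2
    for c in range(n_heavy):
        atoms.append(
            AtomRecord(
                next_idx, f"CR{c + 1}", "C", "CT2", per_atom, 12.011, *_C_LJ
            )
        )
        bonds.append(
            BondTerm((attach, next_idx), *(junction_bond if c == 0 else _CC_BOND))
        )
        chain.append(next_idx)
        attach = next_idx
        next_idx += 1
    h_host = chain[-1] if chain else 2
    for h in range(n_h):
        atoms.append(
            AtomRecord(
                next_idx, f"HR{h + 1}", "H", "HA2", per_atom, 1.008, *_H_LJ
            )
        )
        bonds.append(
            BondTerm(
                (h_host, next_idx),
                *(junction_bond if not chain else _CH_BOND),
            )
        )
        next_idx += 1
    return MoleculeTopology(atoms, bonds, molecule_id=molecule_id)


def make_toy_ligand_pair(
    n_noncc_heavy: int,
    n_noncc_h: int,
    seed: int = 0,
    true_ddg_kcal: float = 1.0,
) -> ToyLigandSet:
    """A ligand pair reducing to one CC under the default element policy.

    Ligand A carries a dummy region of ``n_noncc_heavy`` chain carbons plus
    ``n_noncc_h`` hydrogens; ligand B carries a single-hydrogen region (or
    equals the bare CC when both counts are zero).  True leg free energies
    are assigned deterministically from ``seed`` such that the pair's
    ground-truth ΔΔG equals ``true_ddg_kcal``.
    """
    if n_noncc_heavy < 0 or n_noncc_h < 0:
        raise ValueError("region sizes must be >= 0")
    bare = n_noncc_heavy == 0 and n_noncc_h == 0
    lig_a = _with_region("LIGA", n_noncc_heavy, n_noncc_h, _CS_BOND)
    lig_b = _with_region("LIGB", 0, 0 if bare else 1, _CH_BOND)
    mapping = find_common_core(lig_a, lig_b, policy="element")
    spec = derive_cc_spec(mapping, lig_a, lig_b)

    rng = np.random.default_rng(seed)
    dg_a_ligand = float(rng.uniform(-2.0, 2.0))
    dg_b_ligand = float(rng.uniform(-2.0, 2.0))
    ddg_a = float(rng.uniform(0.5, 3.0))  # ΔΔG(A→CC), Eq. 1 for ligand A
    ddg_b = ddg_a - true_ddg_kcal  # so ΔΔG(A→B) = ddg_a − ddg_b
    true_legs = {
        ("A", "ligand_in_water"): dg_a_ligand,
        ("A", "complex"): dg_a_ligand + ddg_a,
        ("B", "ligand_in_water"): dg_b_ligand,
        ("B", "complex"): dg_b_ligand + ddg_b,
    }
    return ToyLigandSet(lig_a, lig_b, spec, true_legs, seed)
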