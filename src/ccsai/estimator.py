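"""Multistate free-energy estimation from reduced-potential matrices.

Samples are drawn independently at each alchemical state; the reduced
potential u(x, λ_k) = βU_k(x) [+ βpV(x) under constant pressure, when
per-frame volumes are supplied] of every sample evaluated at every state
forms the K×N input matrix.  The multistate Bennett acceptance ratio (MBAR)
estimator then yields the dimensionless free energies f_k of all states,
their asymptotic covariance, and a phase-space overlap diagnostic.

The solver uses self-consistent iteration to warm-start a Newton refinement
and is deterministic given its inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import logsumexp

__all__ = [
    "BOLTZMANN_KCAL",
    "ReducedPotentialMatrix",
    "FreeEnergyResult",
    "OverlapMatrix",
    "discard_equilibration",
    "solve_mbar",
    "mbar_uncertainty",
    "overlap_matrix",
    "leg_free_energy",
    "read_energy_tables",
    "write_energy_tables",
]

#: Boltzmann constant in kcal/mol/K.
BOLTZMANN_KCAL = 1.987204259e-3


@dataclass
class ReducedPotentialMatrix:
    """K×N matrix of reduced potentials with per-state sample counts.

    Row k holds u(x_n, λ_k) for every sample n; the first N_k[0] columns were
    sampled from state 0, the next N_k[1] from state 1, and so on.
    """

    u_kn: np.ndarray
    N_k: np.ndarray
    temperature: float = 303.15
    labels: list | None = None

    def __post_init__(self) -> None:
        self.u_kn = np.asarray(self.u_kn, dtype=float)
        self.N_k = np.asarray(self.N_k, dtype=int)
        if self.u_kn.ndim != 2:
            raise ValueError("u_kn must be a K×N matrix")
        K, N = self.u_kn.shape
        if K < 2:
            raise ValueError("at least two states are required for a difference")
        if len(self.N_k) != K or (self.N_k < 0).any():
            raise ValueError("N_k must hold K non-negative counts")
        if self.N_k.sum() != N:
            raise ValueError(f"sum(N_k)={self.N_k.sum()} != N={N}")
        if not np.isfinite(self.u_kn).all():
            raise ValueError("u_kn contains non-finite entries")

    @property
    def n_states(self) -> int:
        return self.u_kn.shape[0]


@dataclass
class FreeEnergyResult:
    """Reduced free energies (f_k, in kT, f_0 = 0) and endpoint difference."""

    f_k: np.ndarray
    temperature: float
    delta_f: float  # f_K-1 - f_0, kT
    d_delta_f: float | None = None  # asymptotic SE, kT
    theta: np.ndarray | None = None  # covariance of f_k

    @property
    def delta_g_kcal(self) -> float:
        return self.delta_f * BOLTZMANN_KCAL * self.temperature

    @property
    def d_delta_g_kcal(self) -> float | None:
        if self.d_delta_f is None:
            return None
        return self.d_delta_f * BOLTZMANN_KCAL * self.temperature


@dataclass
class OverlapMatrix:
    matrix: np.ndarray
    warnings: list[str] = field(default_factory=list)

    def min_consecutive(self) -> float:
        off = [self.matrix[i, i + 1] for i in range(len(self.matrix) - 1)]
        return float(min(off)) if off else 1.0


def discard_equilibration(samples, fraction: float = 0.25):
    """Drop the first ``floor(fraction * n)`` frames of each state's series.

    ``samples`` is a sequence of per-state arrays (frames along axis 0).
    The leading quarter of each trajectory is treated as equilibration by
    default.
    """
    if not 0.0 <= fraction < 1.0:
        raise ValueError("fraction must lie in [0, 1)")
    out = []
    for arr in samples:
        arr = np.asarray(arr)
        n_drop = int(np.floor(fraction * arr.shape[0]))
        out.append(arr[n_drop:])
    return out


def solve_mbar(
    u: ReducedPotentialMatrix,
    tol: float = 1e-10,
    max_iter: int = 10000,
) -> FreeEnergyResult:
    """Solve the MBAR self-consistent equations.

    The estimate satisfies f_i = −ln Σ_n exp(−u_in) / Σ_k N_k exp(f_k − u_kn)
    with f_0 := 0, converged to ``tol`` in the maximum absolute update.
    States with no samples of their own are still estimable.  Raises on
    non-convergence, reporting the residual.
    """
    u_kn, N_k = u.u_kn, u.N_k
    K, N = u_kn.shape
    if not (N_k > 0).any():
        raise ValueError("at least one state must have samples")
    sampled = np.flatnonzero(N_k > 0)
    logN = np.log(N_k[sampled].astype(float))

    f = np.zeros(K)

    def sc_update(f_cur: np.ndarray) -> np.ndarray:
        log_denom = logsumexp(
            logN[:, None] + f_cur[sampled, None] - u_kn[sampled, :], axis=0
        )
        f_new = -logsumexp(-u_kn - log_denom[None, :], axis=1)
        return f_new - f_new[0]

    def newton_step(f_cur: np.ndarray) -> np.ndarray | None:
        """One Newton step on the sampled-state coordinates (first pinned)."""
        fs = f_cur[sampled]
        log_denom = logsumexp(
            logN[:, None] + fs[:, None] - u_kn[sampled, :], axis=0
        )
        W = np.exp(fs[:, None] - u_kn[sampled, :] - log_denom[None, :])  # S×N
        Ns = N_k[sampled].astype(float)
        g = Ns * (W.sum(axis=1) - 1.0)
        WN = W * Ns[:, None]
        H = np.diag(Ns * W.sum(axis=1)) - WN @ WN.T
        try:
            step = np.zeros_like(fs)
            step[1:] = np.linalg.solve(H[1:, 1:], -g[1:])
        except np.linalg.LinAlgError:
            return None
        if not np.isfinite(step).all():
            return None
        f_new = f_cur.copy()
        f_new[sampled] = fs + step
        return f_new - f_new[0]

    # self-consistent warm start, then Newton with SC fallback
    resid = np.inf
    for it in range(max_iter):
        if it < 30 or (cand := newton_step(f)) is None:
            f_new = sc_update(f)
        else:
            f_new = cand
        resid = np.max(np.abs(f_new[sampled] - f[sampled]))
        f = f_new
        if resid < tol:
            break
    else:
        raise RuntimeError(
            f"MBAR did not converge: residual {resid:.3e} > tol {tol:.0e}"
        )

    # final sweep so unsampled states satisfy the estimator equation exactly
    f = sc_update(f)
    f -= f[0]

    result = FreeEnergyResult(
        f_k=f,
        temperature=u.temperature,
        delta_f=float(f[-1] - f[0]),
    )
    try:
        theta = _asymptotic_covariance(u, f)
        result.theta = theta
        result.d_delta_f = float(
            np.sqrt(max(theta[0, 0] + theta[-1, -1] - 2 * theta[0, -1], 0.0))
        )
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance; uncertainties unavailable")
    return result


def _full_weight_matrix(u: ReducedPotentialMatrix, f_k: np.ndarray) -> np.ndarray:
    """N×K matrix W_nk = exp(f_k − u_kn) / Σ_l N_l exp(f_l − u_ln)."""
    u_kn, N_k = u.u_kn, u.N_k
    sampled = N_k > 0
    log_denom = logsumexp(
        np.log(N_k[sampled].astype(float))[:, None]
        + f_k[sampled, None]
        - u_kn[sampled, :],
        axis=0,
    )
    logW = f_k[:, None] - u_kn - log_denom[None, :]
    return np.exp(logW).T


def _asymptotic_covariance(
    u: ReducedPotentialMatrix, f_k: np.ndarray
) -> np.ndarray:
    """Asymptotic covariance Θ of the f_k estimates (kT²).

    Uses the SVD form Θ = V Σ (I − Σ Vᵀ diag(N) V Σ)⁺ Σ Vᵀ of the standard
    MBAR covariance estimate; Θ is defined up to the f_0 = 0 gauge, and only
    differences Θ_ii + Θ_jj − 2Θ_ij are meaningful.
    """
    W = _full_weight_matrix(u, f_k)  # N×K
    U, s, Vt = np.linalg.svd(W, full_matrices=False)
    V = Vt.T
    S = np.diag(s)
    inner = np.eye(len(s)) - S @ V.T @ (u.N_k[:, None] * V) @ S
    theta = V @ S @ np.linalg.pinv(inner, rcond=1e-12) @ S @ V.T
    return theta


def mbar_uncertainty(result: FreeEnergyResult, u: ReducedPotentialMatrix) -> np.ndarray:
    """K×K matrix of standard errors σ(f_i − f_j) in kT.

    Symmetric with zero diagonal; raises/flags when the covariance was
    singular.
    """
    theta = result.theta
    if theta is None:
        theta = _asymptotic_covariance(u, result.f_k)
    d2 = np.diag(theta)[:, None] + np.diag(theta)[None, :] - 2 * theta
    return np.sqrt(np.clip(d2, 0.0, None))


def overlap_matrix(
    result: FreeEnergyResult,
    u: ReducedPotentialMatrix,
    warn_threshold: float = 0.03,
) -> OverlapMatrix:
    """Row-stochastic matrix of MBAR weight overlaps between states.

    O_ij = Σ_n W_ni N_j W_nj estimates how much state j's important region
    is covered by the pooled samples relative to state i.  A warning is
    emitted whenever a consecutive-state overlap falls below
    ``warn_threshold`` (a heuristic default), the signature of a poorly
    converging transformation.
    """
    W = _full_weight_matrix(u, result.f_k)  # N×K
    O = W.T @ (W * u.N_k[None, :])
    warns: list[str] = []
    for i in range(len(O) - 1):
        o = min(O[i, i + 1], O[i + 1, i])
        if o < warn_threshold:
            warns.append(
                f"poor phase-space overlap between states {i} and {i + 1}: "
                f"{o:.4f} < {warn_threshold}"
            )
    if warns:
        for w in warns:
            warnings.warn(w)
    return OverlapMatrix(matrix=O, warnings=warns)


# --------------------------------------------------------------------------
# Energy-table I/O and leg evaluation


def write_energy_tables(
    u: ReducedPotentialMatrix, outdir: str | Path, prefix: str = "energy_state"
) -> list[Path]:
    """One CSV per sampled state: columns = evaluating states, rows = frames."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    K = u.n_states
    paths = []
    start = 0
    for k in range(K):
        n = u.N_k[k]
        block = u.u_kn[:, start : start + n].T  # frames × K
        start += n
        df = pd.DataFrame(block, columns=[str(i) for i in range(K)])
        p = outdir / f"{prefix}_{k}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        paths.append(p)
    return paths


def read_energy_tables(
    paths: list[str | Path],
    temperature: float = 303.15,
    discard_fraction: float = 0.0,
) -> ReducedPotentialMatrix:
    """Assemble a ReducedPotentialMatrix from per-state CSV energy tables.

    File order defines the sampled-state order; each file's header columns
    name the evaluating states and must agree across files.
    """
    frames = [pd.read_csv(p) for p in paths]
    cols = list(frames[0].columns)
    for p, df in zip(paths, frames):
        if list(df.columns) != cols:
            raise ValueError(
                f"{p}: evaluating-state columns {list(df.columns)} do not "
                f"match {cols}"
            )
    if len(cols) != len(paths):
        raise ValueError(
            f"state-count mismatch: {len(paths)} tables but {len(cols)} "
            "evaluating states"
        )
    blocks = discard_equilibration(
        [df.to_numpy(dtype=float) for df in frames], discard_fraction
    )
    u_kn = np.concatenate(blocks, axis=0).T
    N_k = np.array([b.shape[0] for b in blocks])
    return ReducedPotentialMatrix(u_kn=u_kn, N_k=N_k, temperature=temperature)


def leg_free_energy(
    table_paths: list[str | Path],
    temperature: float = 303.15,
    discard_fraction: float = 0.25,
) -> tuple[float, float]:
    """ΔG (kcal/mol) of one leg from its per-state energy tables.

    Reads the tables, discards the leading ``discard_fraction`` of each
    trajectory as equilibration, solves MBAR, and converts the endpoint
    Δf from kT to kcal/mol at ``temperature``.
    Returns ``(delta_g, sigma)`` in kcal/mol.
    """
    u = read_energy_tables(table_paths, temperature, discard_fraction)
    result = solve_mbar(u)
    return result.delta_g_kcal, result.d_delta_g_kcal or 0.0
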