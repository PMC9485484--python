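"""Thermodynamic-cycle bookkeeping and ligand-network statistics.

The relative binding free energy of one ligand against its common core is

    ΔΔG(L→CC) = ΔG_complex(L→CC) − ΔG_ligand(L→CC),

and for two ligands sharing the CC

    ΔΔG(L1→L2) = ΔΔG(L1→CC) − ΔΔG(L2→CC),

with Gaussian (quadrature) error propagation throughout.  Sign convention:
ΔΔG(A→B) = ΔG_bind(B) − ΔG_bind(A), so walking an edge from A to B adds the
edge value to A's absolute binding free energy.  Absolute ΔG values are
propagated from a reference ligand with a known experimental affinity along
unweighted shortest paths; when several equally short paths exist their
values (and their propagated uncertainties) are averaged.

The statistics layer reproduces the usual benchmark summaries: RMSE, MAE,
Pearson R, Spearman ρ with bootstrap percentile confidence intervals,
error-band counts against the expectation of a zero-mean Gaussian with
σ = RMSE, and a least-squares Gaussian fit of the deviation histogram.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "Measurement",
    "LegResult",
    "LigandNetwork",
    "SummaryStats",
    "ddG_to_cc",
    "ddG_pair",
    "combine_replicates",
    "propagate_absolute",
    "summary_stats",
    "error_band_counts",
    "fit_deviation_gaussian",
]


@dataclass(frozen=True)
class Measurement:
    """A value with a 1σ uncertainty (kcal/mol)."""

    value: float
    sigma: float = 0.0

    def __post_init__(self) -> None:
        if not math.isnan(self.sigma) and self.sigma < 0:
            raise ValueError("sigma must be >= 0")

    def __sub__(self, other: "Measurement") -> "Measurement":
        return Measurement(
            self.value - other.value,
            math.hypot(self.sigma, other.sigma),
        )

    def __add__(self, other: "Measurement") -> "Measurement":
        return Measurement(
            self.value + other.value,
            math.hypot(self.sigma, other.sigma),
        )

    def __neg__(self) -> "Measurement":
        return Measurement(-self.value, self.sigma)


@dataclass
class LegResult:
    """Both legs of one ligand's transformation to the CC state."""

    ligand: str
    dg_ligand: Measurement
    dg_complex: Measurement
    replicates_ligand: list[float] = field(default_factory=list)
    replicates_complex: list[float] = field(default_factory=list)


def ddG_to_cc(leg: LegResult) -> Measurement:
    """ΔΔG(L→CC) = ΔG_complex − ΔG_ligand with quadrature σ."""
    return leg.dg_complex - leg.dg_ligand


def ddG_pair(cc_a: Measurement, cc_b: Measurement) -> Measurement:
    """ΔΔG(L1→L2) from the two ligands' CC-referenced values.

    Antisymmetric under swapping the arguments; both ligands must have been
    mapped to the same CC for the difference to be meaningful.
    """
    return cc_a - cc_b


def combine_replicates(values: list[float]) -> Measurement:
    """Mean and standard error of replicate free-energy estimates.

    σ = sample std / √n for n > 1; a single replicate has no spread-based
    error and is flagged with σ = NaN.
    """
    if len(values) < 1:
        raise ValueError("at least one replicate required")
    mean = float(np.mean(values))
    if len(values) == 1:
        warnings.warn("single replicate: statistical error undefined")
        return Measurement(mean, float("nan"))
    sem = float(np.std(values, ddof=1) / math.sqrt(len(values)))
    return Measurement(mean, sem)


class LigandNetwork:
    """Ligands as nodes, ΔΔG(A→B) = ΔG_B − ΔG_A as directed edge labels.

    Storing each edge in both directions keeps the antisymmetry explicit.
    """

    def __init__(self, reference: str, reference_dg: Measurement) -> None:
        self.graph = nx.DiGraph()
        self.reference = reference
        self.graph.add_node(reference)
        self.reference_dg = reference_dg
        self.experimental: dict[str, float] = {}

    def add_edge(self, lig_i: str, lig_j: str, ddg: Measurement) -> None:
        self.graph.add_edge(lig_i, lig_j, ddg=ddg)
        self.graph.add_edge(lig_j, lig_i, ddg=-ddg)

    def set_experimental(self, ligand: str, dg: float) -> None:
        self.experimental[ligand] = dg


def propagate_absolute(
    net: LigandNetwork,
) -> dict[str, Measurement | None]:
    """Absolute ΔG_bind per ligand from the reference node.

    Each ligand's value follows the edges of every unweighted shortest path
    from the reference; equal-length shortest paths are averaged (values and
    propagated σ alike).  Ligands not connected to the reference are
    reported as ``None`` (unresolvable).
    """
    out: dict[str, Measurement | None] = {}
    g = net.graph
    for node in g.nodes:
        if node == net.reference:
            out[node] = net.reference_dg
            continue
        if not nx.has_path(g, net.reference, node):
            out[node] = None
            continue
        vals, sigs = [], []
        for path in nx.all_shortest_paths(g, net.reference, node):
            total = net.reference_dg
            for a, b in zip(path, path[1:]):
                total = total + g.edges[a, b]["ddg"]
            vals.append(total.value)
            sigs.append(total.sigma)
        out[node] = Measurement(float(np.mean(vals)), float(np.mean(sigs)))
    return out


@dataclass
class SummaryStats:
    n: int
    rmse: float
    mae: float
    pearson_r: float
    spearman_rho: float
    rmse_ci: tuple[float, float]
    mae_ci: tuple[float, float]
    pearson_ci: tuple[float, float]
    spearman_ci: tuple[float, float]
    deviations: np.ndarray

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "RMSE": round(self.rmse, 4),
            "MAE": round(self.mae, 4),
            "pearson_R": round(self.pearson_r, 4),
            "spearman_rho": round(self.spearman_rho, 4),
            "RMSE_CI95": [round(v, 4) for v in self.rmse_ci],
            "MAE_CI95": [round(v, 4) for v in self.mae_ci],
            "pearson_CI95": [round(v, 4) for v in self.pearson_ci],
            "spearman_CI95": [round(v, 4) for v in self.spearman_ci],
        }


def _metrics(computed: np.ndarray, experimental: np.ndarray):
    dev = computed - experimental
    rmse = float(np.sqrt(np.mean(dev**2)))
    mae = float(np.mean(np.abs(dev)))
    if np.ptp(computed) == 0 or np.ptp(experimental) == 0:
        r = rho = float("nan")
    else:
        r = float(stats.pearsonr(computed, experimental).statistic)
        rho = float(stats.spearmanr(computed, experimental).statistic)
    return rmse, mae, r, rho


def summary_stats(
    table: pd.DataFrame,
    computed_col: str = "ddG_computed",
    experimental_col: str = "ddG_exp",
    n_boot: int = 1000,
    seed: int = 0,
) -> SummaryStats:
    """RMSE/MAE/R/ρ of computed vs experimental values with bootstrap CIs.

    The bootstrap resamples ligand pairs with replacement (``n_boot`` draws,
    seeded) and reports percentile 95% intervals.  Requires at least two
    pairs for the correlation coefficients.
    """
    comp = table[computed_col].to_numpy(dtype=float)
    exp_ = table[experimental_col].to_numpy(dtype=float)
    if not (np.isfinite(comp).all() and np.isfinite(exp_).all()):
        raise ValueError("non-finite values in comparison table")
    if len(comp) < 2:
        raise ValueError("need at least two pairs for correlations")
    rmse, mae, r, rho = _metrics(comp, exp_)

    rng = np.random.default_rng(seed)
    boots = np.empty((n_boot, 4))
    n = len(comp)
    for b in range(n_boot):
        idx = rng.integers(0, n, size=n)
        boots[b] = _metrics(comp[idx], exp_[idx])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        ci = np.nanpercentile(boots, [2.5, 97.5], axis=0)

    return SummaryStats(
        n=n,
        rmse=rmse,
        mae=mae,
        pearson_r=r,
        spearman_rho=rho,
        rmse_ci=(float(ci[0, 0]), float(ci[1, 0])),
        mae_ci=(float(ci[0, 1]), float(ci[1, 1])),
        pearson_ci=(float(ci[0, 2]), float(ci[1, 2])),
        spearman_ci=(float(ci[0, 3]), float(ci[1, 3])),
        deviations=comp - exp_,
    )


def error_band_counts(
    deviations: np.ndarray,
    bands: tuple[float, ...] = (1.0, 1.5, 2.0),
) -> pd.DataFrame:
    """Fraction of |deviation| within each band vs the Gaussian expectation.

    The expectation assumes errors ~ N(0, σ=RMSE of the deviations); the
    final row counts deviations beyond the last band.
    """
    dev = np.asarray(deviations, dtype=float)
    sigma = float(np.sqrt(np.mean(dev**2)))
    rows = []
    for b in bands:
        frac = float(np.mean(np.abs(dev) <= b))
        expected = (
            float(2 * stats.norm.cdf(b / sigma) - 1) if sigma > 0 else 1.0
        )
        rows.append({"band": f"<= {b}", "fraction": frac, "gaussian_expected": expected})
    last = bands[-1]
    frac = float(np.mean(np.abs(dev) > last))
    expected = float(2 * (1 - stats.norm.cdf(last / sigma))) if sigma > 0 else 0.0
    rows.append({"band": f"> {last}", "fraction": frac, "gaussian_expected": expected})
    return pd.DataFrame(rows)


def fit_deviation_gaussian(
    deviations: np.ndarray,
) -> tuple[float, float]:
    """(μ, σ) of a Gaussian least-squares-fitted to the deviation histogram.

    Bins follow the Freedman–Diaconis rule on a density-normalized
    histogram; the fit is initialized at the sample moments.  This is the
    companion to the fixed μ=0, σ=RMSE overlay used in the band counts.
    """
    dev = np.asarray(deviations, dtype=float)
    if len(dev) < 10:
        raise ValueError("need at least 10 deviations for a histogram fit")
    counts, edges = np.histogram(dev, bins="fd", density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if np.count_nonzero(counts) < 3:
        raise ValueError("degenerate histogram: too few occupied bins")

    def gauss(x, mu, sig, amp):
        return amp * np.exp(-0.5 * ((x - mu) / sig) ** 2)

    p0 = (float(np.mean(dev)), float(np.std(dev)), float(counts.max()))
    popt, _ = optimize.curve_fit(gauss, centers, counts, p0=p0, maxfev=10000)
    return float(popt[0]), float(abs(popt[1]))
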