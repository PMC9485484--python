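# Methods

This note documents the models and numerical choices behind `ccsai`:
how the staged common-core / serial-atom-insertion (CC/SAI) paths are
constructed, how free energies are estimated, what the harmonic toy
backend does and does not emulate, and where the design was genuinely
open.

## Topology model and file formats

A `MoleculeTopology` holds atoms (partial charge in e, mass in amu,
Lennard-Jones well depth in kcal/mol and Rmin/2 in Å) and bonded terms.
Atom indices are 0-based in memory and 1-based in all CHARMM file I/O;
the conversion happens only at the format boundary. The PSF reader
accepts EXT and non-EXT layouts with atom-type *names* (X-PLOR style);
native CHARMM PSFs with numeric type codes are rejected explicitly rather
than mis-parsed. PSF files carry no element column, so elements are
recovered from the atom-name prefix with a nearest-standard-mass
fallback; repartitioned masses therefore do not confuse the assignment.
Parameter files (RTF/PRM/stream) populate a lookup keyed by atom-type
tuples, symmetric under tuple reversal, with the CHARMM `X t2 t3 X`
dihedral wildcard consulted only when no exact key matches. Duplicate
conflicting entries follow CHARMM's last-wins rule and emit a warning.

Dummy atoms use dedicated types prefixed `DDD`, and the junction uses
type `X`. These types are never classified as hydrogen regardless of
mass, so a constraint setup that fixes all bonds to hydrogens never
constrains an alchemically changing bond to X — which is what makes
hydrogen mass repartitioning (HMR) safe alongside the mutation.

### Hydrogen mass repartitioning

`apply_hmr` multiplies each hydrogen mass by a factor (default 3) and
subtracts the summed increments from the single bonded heavy atom, so the
molecular mass is conserved (asserted to 1e-9 amu). This enables a 4 fs
time step with bonds to hydrogen constrained. Water residues
({TIP3, TIP3P, HOH, WAT, SPC}, configurable) are excluded by default:
rigid-water algorithms handle them independently of the time step, and
repartitioning them would change nothing physical while touching the most
numerous residues in the system. Whether to include ions/water is exposed
as a flag rather than hard-coded.

## Common-core detection

The CC is the maximum connected common *induced* subgraph of the two bond
graphs. Atoms are matched by element (default) or by atom type; hydrogens
participate like any other label, and an element-mismatched pairing
(H↔heavy) is never allowed. A matched bond must have the same
ring-membership on both sides — a ring bond never maps onto a chain bond —
which prevents chemically absurd cores that would "break" a matched ring.

The search is a depth-first connected extension with a visited-set and an
upper-bound prune, exact at the molecule sizes this package targets.
Determinism when several maximum mappings exist: larger matched-bond
count first, then the lexicographically smallest index sequence on the
canonically first ligand, then the smallest paired sequence. The two
arguments are put into a canonical order (by atom count, label multiset,
degree sequence, molecule id) before the search, so
`find_common_core(B, A)` returns exactly the inverse pairing of
`find_common_core(A, B)`.

Non-CC atoms form connected dummy regions. Each region must reach the CC
through exactly one junction atom bonded to exactly one CC atom (the
"terminal junction" requirement); `validate_terminal_junction` reports
every violation. User overrides may exclude mapped atoms from the CC, but
an override that disconnects the remaining CC is an error: two disjoint
CC fragments cannot be joined through a non-interacting dummy region.

## Path construction

Stage I scales all non-CC charges linearly with remaining fraction
s = 1 − j/n for j = 1…n (default n = 3, allowed 1–5), so the last
stage-I state reaches zero. The convention — endpoints at the native
ligand and the first fully discharged state, rather than fractions spaced
exclusive of zero — is fixed here and exposed through `n_elec_steps`.
The charge removed from each region is added to that region's attachment
CC atom, per region, keeping the total system charge constant; a global
invariant asserts ≤ 1e-6 e drift across every state of every path.

Stage II switches off the LJ interactions of all non-CC hydrogens in one
state (always sufficient for hydrogens). Stage III removes heavy-atom LJ
serially — default one atom per state, hard cap two — in order of
decreasing graph distance from the junction, ties broken toward the
higher index. Farthest-first guarantees that every still-interacting
non-CC atom keeps a path to the junction through strictly closer atoms.
Stage IV converts the junction atom to type X: zero charge (already zero
after stage I) and fixed LJ parameters ε = 0.046 kcal/mol,
Rmin/2 = 0.2245 Å (nonpolar-hydrogen-like). These values are a declared
default, configurable globally but never per ligand, so the X atoms of
both ligands always carry identical parameters — a requirement for the
dummy contributions to cancel. When a dummy region is a single hydrogen,
that hydrogen is itself the junction and stages II and IV collapse into
one state converting it directly to X.

Stage V makes the two CC states parameter-identical: charges of the
interacting atoms and bond/angle terms involving them (most importantly
the CC–X bond) are interpolated linearly and simultaneously onto the
values of the other ligand's CC. The step count is `stage5_steps` when
given explicitly; in auto mode it is ceil(max|Δr₀| / 0.125 Å) with a
minimum of one step whenever anything differs, because the change of a
bond equilibrium length is the factor that most limits overlap between
consecutive states. A correspondence failure — an interacting term
present in only one CC — is a hard error listing the offending terms.

Every state is emitted as a self-contained directory
(`<ligand>/<environment>/intst<k>/`) holding a YAML manifest (stage,
deltas vs the previous state, stage-I s-value, total charge) and the full
parameter snapshot in CHARMM-style syntax. Serialization is sorted and
fixed-format, so re-emission is byte-identical.

## Free energy estimation

`solve_mbar` solves the MBAR self-consistent equations

    f_i = −ln Σ_n exp(−u_in) / Σ_k N_k exp(f_k − u_kn),  f_0 ≡ 0

with log-sum-exp arithmetic throughout: self-consistent iteration for the
first 30 sweeps, then Newton steps on the sampled-state coordinates
(first state pinned) with self-consistent fallback when the Hessian solve
fails, to a tolerance of 1e-10 on the maximum update. States without
samples of their own are estimated in a final sweep. The asymptotic
covariance uses the SVD form Θ = VΣ(I − ΣVᵀNVΣ)⁺ΣVᵀ of the standard
estimator; only differences Θ_ii + Θ_jj − 2Θ_ij are gauge-invariant and
reported. At K = 2 the solution coincides with the Bennett acceptance
ratio (verified to 1e-13 kT in the tests), and with samples from a single
state it reduces to the exponential estimator.

The reduced potential is u = βU; a βpV term for constant-pressure data is
added only when per-frame volumes are supplied (default off, logged),
since for typical condensed-phase legs the pV contribution cancels to
well below the statistical noise. The first 25% of each per-state
trajectory is discarded as equilibration (floor(fraction·n) frames); no
statistical-inefficiency subsampling is applied by default — all
post-equilibration frames enter the estimator — with subsampling
available as an option.

The overlap matrix O_ij = Σ_n W_ni N_j W_nj is row-stochastic; a warning
fires when any consecutive-state overlap falls below 0.03. The threshold
is a documented heuristic chosen to flag the regime where MBAR
uncertainties become unreliable, not a derived quantity.

Energy tables are plain CSV, one file per sampled state, columns naming
the evaluating states, rows being frames; 1 kT = 0.6024 kcal/mol at the
default 303.15 K.

## Network analysis

Eq.-style bookkeeping: ΔΔG(L→CC) = ΔG_complex − ΔG_ligand and
ΔΔG(L1→L2) = ΔΔG(L1→CC) − ΔΔG(L2→CC), with quadrature error propagation
and three independent replicates combined as mean ± std/√n.

Absolute ΔG_bind values are propagated from a reference ligand whose
experimental affinity anchors the network, along unweighted (edge-count)
shortest paths under the convention ΔΔG(A→B) = ΔG_B − ΔG_A; several
equally short paths are averaged, values and propagated σ alike. A
published formulation of the re-expression subtracts the reference value
instead of adding it, which is dimensionally fine but inconsistent with
that sign convention; this package implements the self-consistent
convention. No cycle-closure correction or centered-RMSE post-processing
is applied — the propagation is deliberately the simplest possible
scheme, and on cycle-consistent inputs it is exactly path-independent
(property-tested against an all-paths oracle).

Benchmark statistics: RMSE, MAE, Pearson R and Spearman ρ with
percentile 95% confidence intervals from 1000 seeded pair-resampling
bootstrap draws; error-band counts at ±1, ±1.5, ±2 kcal/mol compared
against a zero-mean Gaussian with σ = RMSE; and a least-squares Gaussian
fit to the deviation histogram (Freedman–Diaconis binning, initialized at
the sample moments) whose fitted μ exposes systematic offsets.

## The harmonic toy backend

`ccsai.toy` replaces MD sampling with D-dimensional harmonic oscillators
in reduced units: exact Gaussian draws, closed-form free energies
(Δf = ½ Σ ln(k′/k)), and ladders whose ln k is linear across states so
consecutive-state overlap is uniform and controllable — squeezing a large
Δf over few states deliberately reproduces the poor-overlap failure mode.
Synthetic ligand pairs share a propyl scaffold and differ in a dummy
region of configurable size, reducing to one CC under the default element
policy; assigned true leg values give every pair a known ground-truth
ΔΔG.

What passing toy tests show: the path logic, charge bookkeeping,
estimator, uncertainty model and cycle/network algebra are correct, and
the ΔΔG estimate is independent of the dummy-region size, which is the
core cancellation claim of the CC/SAI construction. What they do not
show: force-field accuracy, conformational sampling adequacy, finite
time-step or constraint artifacts, or solvent effects — none of which a
harmonic stand-in can exhibit.

Default problem sizes were chosen so the full suite runs in well under a
minute of estimator time: 5-state ladders with 500–1000 exact samples per
state for single checks, and 100 seeded repetitions for the coverage
test (≥ 99 of 100 within 3σ).

## Known limitations

- The MCS search is exact but exponential in the worst case; it targets
  ligand-sized graphs (tens of atoms), not arbitrary macromolecules.
- Stage-V interpolation covers charges, bonds and angles of the
  interacting atoms; dihedral-term mismatches between CCs are not yet
  interpolated and will surface as a correspondence error.
- The engine adapter layer is out of scope: energy matrices are expected
  as pre-computed per-state tables (the toy sampler writes the identical
  format).
- Overlap warnings are advisory; no automatic state insertion is
  attempted.
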