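# ccsai

Setup and analysis for relative binding free energy (RBFE) calculations
with the **common-core / serial-atom-insertion (CC/SAI)** approach.

## The problem

Lead optimization asks how the binding affinity of a ligand changes when a
functional group is modified. Alchemical free energy simulations answer
this by transforming one ligand L₁ into another L₂ along a non-physical
path, once for the ligand free in water and once bound to the receptor:

    ΔΔG_bind(L1→L2) = ΔG_complex(L1→L2) − ΔG_ligand(L1→L2)

Instead of morphing L₁ directly into L₂ with soft-core potentials and a
continuous coupling parameter, the CC/SAI approach mutates *each* ligand to
a shared **common core** (CC): the atoms outside the maximum common
substructure are converted to dummy atoms in a sequence of discrete,
self-contained intermediate states. Because each state is an ordinary
parameter set, any unmodified MD engine can sample it; and because every
dummy region hangs off the core through a single terminal junction atom X,
the dummy atoms cancel exactly from the double free energy difference

    ΔΔG_bind(L1→L2) = ΔΔG_bind(L1→CC) − ΔΔG_bind(L2→CC).

The staged path for each ligand is:

| stage | change | states |
|---|---|---|
| I | non-CC charges scaled linearly to zero, compensating charge on the attachment atom | 3 (1–5) |
| II | Lennard-Jones of non-CC hydrogens off | 1 |
| III | Lennard-Jones of non-CC heavy atoms off, one atom at a time | one per atom |
| IV | last heavy atom → junction type X (zero charge, standard LJ) | 1 |
| V | CC of one ligand interpolated onto the other's (charges, bonds to X) | ceil(Δr₀/0.125 Å) |

Per-state sampling produces a K×N matrix of reduced potentials
u(x, λ) = βU(x) which the **MBAR** estimator turns into free energy
differences with asymptotic uncertainties and a phase-space-overlap
diagnostic. A network layer combines legs through the thermodynamic cycle,
propagates absolute ΔG_bind values from a reference ligand along shortest
paths, and computes benchmark statistics (RMSE, MAE, Pearson R, Spearman ρ
with bootstrap confidence intervals, error-band counts, Gaussian fit of the
deviation histogram).

An analytically solvable harmonic toy backend (`ccsai.toy`) stands in for
the MD engine, so the entire chain — path construction, per-state emission,
estimation, cycle bookkeeping — is testable on a laptop.

## Worked example

`examples/03_free_energy.py` samples a 5-state harmonic ladder whose true
endpoint free energy is 2 kT and estimates it with MBAR:

```
analytic  Δf = 2.0000 kT
MBAR      Δf = 1.9650 ± 0.0312 kT
          ΔG = 1.1838 ± 0.0188 kcal/mol at 303.15 K (1 kT = 0.6024 kcal/mol)
min consecutive-state overlap: 0.208 (warnings: 0)
```

The estimate agrees with the closed form within ~1σ; the overlap matrix
row for consecutive states (0.208) is far above the 0.03 warning heuristic,
so the ladder spacing is adequate. `examples/02_mutation_path.py` shows the
staged path for a ligand with a 4-heavy-atom + 2-hydrogen dummy region:

```
LIGA: 15 states, stages {'native': 1, 'I': 3, 'II': 1, 'III': 3, 'IV': 1, 'V': 6}
  total-charge drift across states: 1.25e-16 e
```

i.e. the documented (3, 1, 3, 1) stage structure plus six CC-equalization
states (the junction bond changes by 0.71 Å, and no step may move a bond
equilibrium by more than 0.125 Å), with the total system charge conserved
to machine precision across every state.

A thin CLI wraps the library for shell use:

```sh
ccsai setup --ligand-a a.psf --ligand-b b.psf --prm lig.prm --out run/
ccsai analyze run/ --out results.yaml
ccsai network --edges edges.csv --reference L1 --reference-dg -9.0
ccsai stats --results summary.csv
```

Exit codes: 0 success, 2 validation failure, 3 estimation failure.

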