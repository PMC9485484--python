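"""Find the common core of a ligand pair and inspect the dummy regions.

Builds a synthetic ligand pair — a propyl scaffold carrying a butyl-like
side chain (ligand A) versus the same scaffold capped by a hydrogen
(ligand B) — and runs the maximum-common-substructure search.
"""

from ccsai import derive_cc_spec, find_common_core, validate_terminal_junction
from ccsai.toy import make_toy_ligand_pair

ls = make_toy_ligand_pair(n_noncc_heavy=4, n_noncc_h=2, seed=0)

mapping = find_common_core(ls.lig_a, ls.lig_b, policy="element")
spec = derive_cc_spec(mapping, ls.lig_a, ls.lig_b)
report = validate_terminal_junction(spec)

print(f"ligand A: {len(ls.lig_a)} atoms, ligand B: {len(ls.lig_b)} atoms")
print(f"common core: {len(mapping)} mapped atoms")
for side in ("A", "B"):
    for r, region in enumerate(spec.dummy_regions[side]):
        print(
            f"ligand {side} dummy region {r}: {len(region)} atoms, "
            f"junction atom {spec.junction_atom(side, r)} attached to CC atom "
            f"{spec.attachment_atom(side, r)}"
        )
print(f"terminal-junction validation passed: {report.passed}")

# The mapped atoms become the shared endstate of both alchemical paths; the
# non-CC atoms listed above are the ones mutated to dummy atoms.
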