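"""Build the staged mutation paths for a ligand pair and emit state files.

Stages: (I) charges of the non-CC atoms to zero with a compensating charge
on the attachment atom, (II) hydrogen LJ off, (III) heavy-atom LJ off
serially, (IV) the last heavy atom becomes junction type X, (V) the CC
reached from ligand A is interpolated onto the CC reached from ligand B.
"""

import tempfile
from pathlib import Path

from ccsai import ProtocolConfig, build_pair_paths, emit_states
from ccsai.toy import make_toy_ligand_pair

ls = make_toy_ligand_pair(n_noncc_heavy=4, n_noncc_h=2, seed=0)
cfg = ProtocolConfig()  # 3 elec states, 1 heavy atom per step, auto stage V

path_a, path_b = build_pair_paths(ls.lig_a, ls.lig_b, ls.spec, cfg)

for path in (path_a, path_b):
    print(f"{path.ligand_id}: {len(path)} states, stages {path.stage_counts()}")
    q = path.states[0].total_charge()
    drift = max(abs(s.total_charge() - q) for s in path.states)
    print(f"  total-charge drift across states: {drift:.2e} e")

with tempfile.TemporaryDirectory() as tmp:
    dirs = emit_states(path_a, Path(tmp))
    print(f"emitted {len(dirs)} self-contained state directories, e.g.")
    print(f"  {dirs[4].relative_to(tmp)}: "
          f"{sorted(p.name for p in dirs[4].iterdir())}")

# Every state is a complete, standalone parameter set: an unmodified MD
# engine can sample each one independently, with no soft-core code needed.
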