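"""Score a toy nucleosome through the full generator -> scorer loop.

Builds a 24-bp toy nucleosome, plants ground-truth PARCH values, generates
a hydration count series that realizes them, re-scores the structure with
run_parch, and writes the annotated PDB plus the PV TSV sidecar.
"""

from pathlib import Path

from parchscape import make_planted_system, run_parch, write_parch_pdb

system = make_planted_system(seed=1, n_bp=24)
recovered = run_parch(system.structure, system.trajectory)

errors = [
    abs(recovered.get(key, moiety) - system.planted_pv.get(key, moiety))
    for key, moiety in system.planted_pv.keys()
]
print(f"groups scored:        {len(errors)}")
print(f"max recovery error:   {max(errors):.6f}  (zero noise -> exact)")

out = Path("scored_toy.parch.pdb")
out.write_text(write_parch_pdb(system.structure, recovered))
recovered.to_tsv("scored_toy.pv.tsv")
print(f"wrote {out} (PV column after the element field) and scored_toy.pv.tsv")
# The PV of each group is the mean shell-water count over the final 10% of
# annealing frames: ~5 means the group held ~5 waters at high temperature
# (hydrophilic), ~0.3 means it dewetted early (hydrophobic).
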