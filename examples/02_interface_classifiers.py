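"""Classify the histone-DNA interface of a toy nucleosome.

Labels DNA residues proximal/distal (3 Å, any atom), finds DNA-contacting
histone residues (8 Å, center of geometry), and selects the acidic patch.
"""

from collections import Counter

from parchscape import (
    DEFAULT_CHAIN_MAP,
    build_toy_nucleosome,
    classify_proximal_distal,
    contact_residues,
    select_acidic_patch,
)

nucleosome = build_toy_nucleosome()  # 147 bp, 8 chains, 2 per histone type

prox = classify_proximal_distal(nucleosome, cutoff=3.0)
print("proximal/distal DNA:", dict(Counter(prox.labels.values())))
# proximal = DNA residues with any heavy atom within 3 Å of a protein atom

contacts = contact_residues(nucleosome, cutoff=8.0)
print(f"DNA-contacting histone residues (COG within 8 Å): {len(contacts)}")

patch = select_acidic_patch(nucleosome, DEFAULT_CHAIN_MAP)
print(f"acidic-patch residues found: {len(patch.found)} "
      f"(6 H2A + 2 H2B positions x 2 copies = 16)")
print(f"type mismatches flagged:     {len(patch.mismatched)}")
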