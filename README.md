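# parchscape

Hydropathy-landscape analysis of nucleosomes.

Nucleosomes — ~147 bp of DNA wrapped around a histone octamer (two copies
each of H2A, H2B, H3 and H4) — reshape the physicochemical environment of
both the DNA and the histone surface. One way to quantify this is the PARCH
scale (Protocol for Assigning a Residue's Character on a Hydropathy scale):
a residue-resolved, environment-dependent hydropathy measure obtained by
heating a position-restrained solvated structure on a linear ramp
(300 → 800 K at 0.1 K/ps, 5 ns) and watching how long each group retains
its hydration shell. Hydrophilic groups hold water to high temperature
(high PARCH value, PV); hydrophobic groups dewet early (low PV). DNA
residues get two values — sugar-phosphate backbone (BB) and nucleobase
(NB) — and protein residues one.

`parchscape` implements the analysis layer of this workflow as a Python
library:

- **structure model** — legacy-PDB reading/writing (including an annotated
  dialect carrying the PV in an extra fixed-width column, plus a TSV
  sidecar), residue-kind tables, DNA backbone/nucleobase atom partitioning;
- **PARCH scoring** — annealing-schedule arithmetic, hydration-shell water
  counting over trajectory frames or precomputed count series, and
  per-group PV computation (`PV = mean shell-water count over the final
  window of the ramp`);
- **interface classifiers** — proximal/distal DNA (within 3 Å of any
  protein atom), DNA-contacting histone residues (centers of geometry
  within 8 Å), dinucleosome inner/outer residues (within 20 Å of the
  adjacent nucleosome), the H2A/H2B acidic patch
  (E56/E61/E64/D90/E91/E92 + E102/E110) and configurable arginine anchors;
- **ΔPV differencing** — DNA stripping for histone-only partners and
  signed paired differences (DNA present − DNA removed; methylated −
  unmethylated) with polarity labels;
- **in-silico methylation** — a C5 methyl carbon on every cytosine with
  deterministic in-plane external-bisector geometry, producing valid 5CM
  residues;
- **distribution statistics** — Gaussian KDE (Silverman bandwidth), mode
  finding, two-sided Mann-Whitney U comparisons with significance stars
  (`* p<0.05 … **** p<0.0001`), violin five-number summaries;
- **synthetic data** — toy nucleosome/dinucleosome builders, planted
  hydration trajectories, and PV presets encoding the landscape's
  characteristic shapes (bimodal nucleosomal backbone near 1 and 5,
  unimodal free-fragment backbone near 4, nucleobases near 0.35, a planted
  −0.8 methylation shift and a −1.5 inner/outer shift).

Explicit-solvent MD itself (solvation, equilibration, the annealing run)
is out of scope: the scoring layer consumes trajectories or count series
produced externally or by the synthetic generators.

## Worked example

```python
from parchscape import make_planted_system, run_parch, write_parch_pdb

system = make_planted_system(seed=1, n_bp=24)      # toy nucleosome + planted PVs
recovered = run_parch(system.structure, system.trajectory)
errors = [abs(recovered.get(k, m) - system.planted_pv.get(k, m))
          for k, m in system.planted_pv.keys()]
print(len(errors), max(errors))
```

prints

```
222 0.0
```

— 222 scoring groups (one per protein residue, two per DNA residue) and a
maximum recovery error of exactly zero: at zero noise the generator → scorer
loop is the identity, so the pipeline's arithmetic is verifiably correct
before it ever touches real data. The `examples/` directory holds one short
script per capability; `examples/04_distribution_stats.py` for instance
prints

```
nucleosomal backbone modes: [0.99, 5.04]
free-fragment backbone mode: [4.07]
nucleobase mean PV: 0.350  (low: bases dewet early)
dC vs 5mC backbone: p = 7.91e-14 [****], median shift +0.80
inner vs outer backbone: p = 1.55e-44 [****], median shift -1.48
```

i.e. the wrapped-DNA backbone splits into a contact mode near 1 and a
solvent-exposed mode near 5, a free DNA fragment stays unimodal near 4,
nucleobases are uniformly low, and the planted methylation and
dinucleosome-interface shifts are recovered as strongly significant.

A thin CLI mirrors the library (`parchscape simulate|parse|parch|classify|
methylate|delta|stats|report`, all TSV/PDB in and out; exit codes 0/2/3 for
success / bad input / bad config).

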