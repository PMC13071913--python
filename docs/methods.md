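# Methods

## The PARCH hydropathy model

PARCH scoring ranks residues by the thermal stability of their hydration
shell. A solvated structure is position-restrained (restraint constant
10,000 kJ mol⁻¹ nm⁻², recorded as schedule metadata) and heated on a
linear ramp, by default 300 → 800 K at 0.1 K ps⁻¹, i.e. a 5 ns
trajectory; `AnnealingSchedule` implements exactly this arithmetic
(`duration_ps = (t_end − t_start)/rate`, `T(t) = t_start + rate·t`).
Hydrophilic groups keep water molecules in their first shell to high
temperature; hydrophobic groups dewet early.

Scoring groups are one `PROT` group per protein residue and two groups
per DNA residue: the sugar-phosphate backbone `BB` (P, OP1, OP2, O5′,
C5′, C4′, O4′, C3′, O3′, C2′, C1′ — C1′ bridges sugar and base and is
assigned to the backbone so that `NB` is exactly the base ring plus its
exocyclic substituents) and the nucleobase `NB`. Waters and ions are
never scored. Hydrogens are excluded from partitions and all distance
computations by default; crystal and cryo-EM structures rarely resolve
them, and a config flag re-enables them.

**PV definition.** The PARCH value implemented here is

```
PV = scale × mean( shell-water count over the final ⌈window_fraction · n_frames⌉ frames )
```

with `scale = 1` and `window_fraction = 0.1`. The hydration shell is all
water oxygens within `r_shell = 4.0 Å` of any heavy atom of the group
(first-hydration-shell scale), each water counted at most once per
group; "within" is inclusive throughout the package. This definition is
a documented stand-in chosen to be consistent with the scale's
mechanism and magnitudes (backbone values of a few waters, nucleobase
values well below one); a different published normalization can replace
`compute_pv` without changing any caller. Frames are weighted equally —
the schedule only links frame time to temperature.

## Interface classifiers

All classifiers run on heavy atoms and read "within X Å" inclusively
(ties at the cutoff count as within, fixed so tests are exact):

- **proximal/distal DNA** — proximal iff any heavy atom of the DNA
  residue is ≤ 3 Å (default) from any protein heavy atom;
- **contact residues** — protein residues whose center of geometry
  (unweighted heavy-atom mean) is ≤ 8 Å from any DNA residue's center
  of geometry;
- **dinucleosome inner/outer** — with exactly two labeled nucleosome
  units, a residue is inner iff any heavy atom is ≤ 20 Å from any
  protein or DNA heavy atom of the *other* unit. The criterion is
  symmetric under unit swap. The 20 Å default is exposed as a parameter
  because the appropriate value depends on stacking geometry and
  compaction.
- **named sets** — the acidic patch (H2A E56, E61, E64, D90, E91, E92;
  H2B E102, E110, on every copy via a histone-type → chain map) and a
  generic residue-set selector for arginine anchors. Anchor identities
  depend on each structure's numbering, so the shipped anchor config is
  an empty, editable YAML file. Residues whose observed amino acid
  disagrees with the spec are returned flagged, never dropped; missing
  residues are warned about and reported.

## Paired ΔPV

`strip_dna` builds the histone-only partner by deleting DNA residues;
remaining residues share atom objects with the input, so coordinates are
bit-exact, and crystallographic waters/ions are retained by default
(flag to drop — whether production pipelines keep them varies, and
retention is the conservative choice). `delta_pv` matches records by
(chain, seq_id, icode, moiety) — identity matching, since paired systems
are structurally identical; renumbered pairs are aligned with an
explicit per-chain offset map. ΔPV = PV(A) − PV(B); polarity is
MORE_HYDROPHILIC / REDUCED_HYDROPHILICITY with an UNCHANGED deadband of
|ΔPV| < 0.05 so float noise is not labeled as a shift. Differencing is
exactly antisymmetric, and matched + unmatched records account for every
input record.

## In-silico methylation

`methylate_all_cytosines` adds one heavy carbon (`C5M`) per cytosine
(residues named DC, or legacy C) and renames the residue to 5CM ("FMC"
and the alternative methyl names C5A/C7M are accepted on input). The
carbon is placed in the least-squares plane of the pyrimidine ring,
along the external bisector of the C4–C5–C6 angle, 1.50 Å from C5
(standard aromatic C–C bond). Methyl hydrogens are not added (heavy-atom
model throughout). Cytosines missing C4/C5/C6 or with rings bent more
than 0.25 Å out of plane are skipped with a reason; a placed carbon
closer than 1.8 Å to a non-bonded atom is flagged as a clash but kept —
relaxing such contacts is an MD step outside this package. The operation
is idempotent and touches no other residue.

## Distribution statistics

- **KDE**: Gaussian kernel, Silverman's rule of thumb
  `h = 0.9 · min(sd, IQR/1.34) · n^{-1/5}` by default (fixed-bandwidth
  override for bit-reproducible runs), evaluated on a grid spanning
  [min − 3h, max + 3h] with step ≤ h/5. Densities are non-negative and
  integrate to 1 within 1e−3 (trapezoidal).
- **Modes**: interior local maxima with prominence ≥ 5% of the peak
  density (a strictly higher endpoint also counts), ascending order.
- **Group comparisons**: two-sided Mann-Whitney U. Exact enumeration of
  the null for tie-free samples with both n ≤ 20; the tie- and
  continuity-corrected normal approximation otherwise (the exact null
  does not accommodate ties). Stars: `****` p<0.0001, `***` p<0.001,
  `**` p<0.01, `*` p<0.05, `ns` otherwise. The estimator and test are
  package conventions — nonparametric rank-sum is the standard choice
  for violin-plot group comparisons and assumes nothing about PV
  distribution shape.
- **Violin summaries**: five-number summary with linear-interpolation
  quantiles (numpy default), stated here so summaries are
  bit-reproducible.

## Synthetic data: what it emulates and what it does not

The generators stand in for annealing-MD output so the full pipeline is
exercisable with planted ground truth. They emulate *data shapes*, not
physics.

**Toy structures.** The DNA duplex follows a superhelix with textbook
nucleosome geometry (radius 42 Å, pitch 24 Å, 1.65 turns; configurable),
two strands of n_bp residues with full standard heavy-atom names (bases
cycle A/C/G/T against their complements), the second strand the same
path raised 3.4 Å. The pseudo-octamer is a geometric fixture: a 25 Å
residue cylinder (8 chains in 45° sectors, two chains per histone type,
with the acidic-patch and sample arginine positions planted at their
canonical sequence numbers), a "contact ridge" of residues tracking the
central DNA turn 2.9 Å below the first strand — guaranteeing proximal
residues at the 3 Å cutoff with no inter-chain contact under 2 Å — and
axial tail residues flanking the DNA entry/exit so that two stacked
units develop a protein-containing interface. The dinucleosome stacks
two units along the axis (default separation 60 Å, rotated so the
helical path continues); at 60 Å the interfacial DNA and tails fall
inside the 20 Å inner cutoff, at 200 Å everything is outer. An optional
straight linker duplex is placed radially outside the superhelix
opposite the interface and split at its strand midpoint for unit
assignment; note that with a linker present, the residues adjacent
across the midpoint are inner by construction at any separation — the
any-atom criterion necessarily sees the other unit's linker half. The
default build therefore has no linker. Builders validate geometry and
reject inter-chain heavy-atom contacts below 2 Å and overlapping unit
placements.

**Planted trajectories.** Per-group integer count series whose final
window realizes a prescribed PV table: the final `window_fraction` of
frames is flat at the target with Bresenham-style compensating dither
(running sums track the target, so the window mean is exact whenever
`pv × window_frames` is integral — planted tables are quantized to the
0.005 grid realizable by the default 200-frame window), and earlier
frames decay exponentially from a hydrated plateau (target + 6 waters)
to mimic dewetting. Per-frame Gaussian noise (sd `noise_sd`) is added
with unbiased stochastic rounding; recovery error then scales as
`noise_sd/√window_frames` plus a dither term ≤ 0.5/√window_frames, and
at σ = 0.1 at least 95% of groups recover within 0.1.

**Presets.** Truncated-at-zero Gaussian mixtures encoding the
landscape's characteristic shapes:

| preset | components (weight, loc, sd) |
|---|---|
| `nucleosomal_bb` | 0.5·N(1, 0.4²) + 0.5·N(5, 1.2²) |
| `fragment_bb` | N(4, 1.0²) |
| `nucleobase` | N(0.35, 0.05²) |
| `methylation_dc` / `methylation_fmc` | N(4, 1²) / N(3.2, 1²) (−0.8 shift) |
| `dinuc_outer_bb` / `dinuc_inner_bb` | N(5, 1.5²) / N(3.5, 1.5²) (−1.5 shift) |

Component locations are the landscape's characteristic values (backbone
peaks near 1 and 5 for wrapped DNA, near 4 for a free fragment,
nucleobases near 0.3–0.4, methylated backbones shifted down, inner
backbones below outer); weights, spreads and effect sizes are synthetic
choices fixed once at realistic magnitudes and documented here. Passing
tests on these presets demonstrates that the estimators and the planted
effects behave as designed — they say nothing about real annealing-MD
output, which additionally carries frame-to-frame correlation,
residue-to-residue coupling and non-Gaussian tails that the presets do
not model.

## Numerical choices and degenerate inputs

- Distance queries use k-d trees; boundary ties are inclusive everywhere.
- Alt-locs: highest occupancy wins, ties broken by alt-loc character
  order. Multi-model files: first model only, with a warning.
- KDE on a zero-variance sample errors under the bandwidth rule (a fixed
  bandwidth still works); `find_modes` on a single-point grid returns
  that point; empty mode lists are allowed.
- `compute_pv` of an all-zero series is 0 for any window; PVs are
  non-negative by construction and monotone in the counts.
- Zero-tolerance deadband for ΔPV polarity: 0.05.
- Problem sizes in the test-suite and acceptance runs (24–147 bp toys,
  2000-frame trajectories, preset samples of 200–20 000, 100-instance
  oracle sweeps, 1000-replicate null calibration) were chosen as the
  smallest sizes at which the statistical checks are stable.

## Known limitations

- The PV formula is a stand-in consistent with the scale's mechanism;
  absolute values are comparable within this package, not to external
  PARCH implementations.
- Toy geometry is coarse: no base pairing chemistry, no sequence
  realism, pseudo-residues with 5 atoms; it exists to exercise distance
  criteria and I/O, not to model structure.
- mmCIF, crystallographic symmetry and hydrogen placement are out of
  scope; multi-system meta-analysis across structure panels is not
  implemented.
- CpG-pattern-restricted methylation is a config extension, not the
  default (every cytosine is methylated).
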