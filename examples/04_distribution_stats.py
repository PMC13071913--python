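"""Distribution statistics on the packaged PV presets.

Recovers the KDE modes of the bimodal nucleosomal backbone and the unimodal
free-fragment backbone, and runs the planted methylation and dinucleosome
rank-sum comparisons with significance stars.
"""

from parchscape import compare_groups, find_modes, kde, sample_preset

bb = sample_preset("nucleosomal_bb", 5000, seed=1)
print("nucleosomal backbone modes:",
      [round(m, 2) for m in find_modes(kde(bb))])  # expect ~1 and ~5

frag = sample_preset("fragment_bb", 5000, seed=1)
print("free-fragment backbone mode:",
      [round(m, 2) for m in find_modes(kde(frag))])  # expect ~4

nb = sample_preset("nucleobase", 5000, seed=2)
print(f"nucleobase mean PV: {nb.mean():.3f}  (low: bases dewet early)")

meth = compare_groups(sample_preset("methylation_dc", 200, 3),
                      sample_preset("methylation_fmc", 200, 3))
print(f"dC vs 5mC backbone: p = {meth.p_value:.2e} [{meth.stars}], "
      f"median shift {meth.median_shift:+.2f}")

dinuc = compare_groups(sample_preset("dinuc_inner_bb", 500, 4),
                       sample_preset("dinuc_outer_bb", 500, 4))
print(f"inner vs outer backbone: p = {dinuc.p_value:.2e} [{dinuc.stars}], "
      f"median shift {dinuc.median_shift:+.2f}")
# Stars follow the usual convention: * p<0.05, ** p<0.01, *** p<0.001,
# **** p<0.0001, ns otherwise.
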