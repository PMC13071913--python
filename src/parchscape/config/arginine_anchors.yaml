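# Arginine-anchor residue specs (histone arginines inserting into the DNA
# minor groove at superhelical contact points). Anchor identities depend on
# the structure's sequence numbering, so the shipped default is empty; add
# entries of the form
#   - {histone_type: H3, amino_acid: R, seq_id: 83}
# to select anchors through parchscape.classifiers.select_residue_set.
[]
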