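# Default edge-weight parameters for the consensus graph.
# w_cc:      weight on (1 - cc), density-fit term
# w_agree:   reward per additional agreeing trace at the same spot
# p_rama:    penalty for a disallowed junction conformation
# p_ca:      per-Angstrom penalty for CA-CA deviation beyond tol_ca
# d_ca:      ideal consecutive CA-CA distance (trans peptide), Angstrom
# tol_ca:    tolerance before the CA-CA penalty applies, Angstrom
# p_overlap: penalty per spatially overlapping residue of different seq_num
# g_open:    one-time gap-opening penalty
# g_ext:     per-dummy gap-extension penalty (must be < g_open)
w_cc: 1.0
w_agree: 0.5
p_rama: 2.0
p_ca: 2.0
d_ca: 3.8
tol_ca: 0.5
p_overlap: 3.0
g_open: 5.0
g_ext: 1.5
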