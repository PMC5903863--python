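"""Purifying-selection scan: per-codon dN/dS over a simulated alignment.

Simulates 42 isolate sequences of a 510-codon open reading frame in which
nonsynonymous change is suppressed over codons 310-349 (a DNA binding
domain), then profiles dN and dS per amino-acid position.
"""

import numpy as np

from ffltune import dnds_profile, gen_codon_alignment

aln = gen_codon_alignment(seed=11)  # defaults: 510 codons, 42 sequences
prof = dnds_profile(aln)

window = slice(309, 349)
outside = np.r_[prof.dn[: window.start], prof.dn[window.stop :]]
print(f"alignment: {aln.n_sequences} sequences x {aln.length_codons} codons")
print(f"mean dN inside the constrained domain : {np.nanmean(prof.dn[window]):.4f}")
print(f"mean dN outside                       : {np.nanmean(outside):.4f}")
print(f"mean dS (whole protein)               : {np.nanmean(prof.ds):.4f}")
# dN collapses inside the domain while dS is uniform: the purifying-selection
# signature a per-codon scan is designed to expose.

table = prof.to_frame()
print(table.head(5).to_string(index=False))
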