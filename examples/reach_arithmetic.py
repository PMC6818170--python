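"""Worm-like-chain reach of an inhibitory-receptor dephosphorylation reaction.

The reach of each component is sqrt(persistence length x contour length);
component reaches combine as the root of the sum of squares.  For the PD-1 ->
CD28 dephosphorylation reaction the tails contribute 3.0 nm (PD-1, 56
residues to the ITSM tyrosine) and 1.3 nm (CD28, 11 residues to the YMNM
motif), and the SHP-2 phosphatase an estimated 7.9 nm.
"""

from tethersim import combined_reach, contour_length, wlc_reach

lp = 0.4  # persistence length of unstructured peptide, nm

l_cd28 = wlc_reach(lp, contour_length(11))
l_pd1 = wlc_reach(lp, contour_length(56))
l_shp2 = 7.9  # multi-domain enzyme; literature estimate
# combine the one-decimal component estimates, as reported
L = combined_reach([round(l_pd1, 1), l_shp2, round(l_cd28, 1)])

print(f"CD28 tail reach      : {l_cd28:.2f} nm  (~{l_cd28:.1f})")
print(f"PD-1 tail reach      : {l_pd1:.2f} nm  (~{l_pd1:.1f})")
print(f"combined reach L     : {L:.2f} nm  (~{L:.1f})")
print()
print("L is the length scale of the Gaussian contact kernel: separations "
      "beyond ~L make the enzyme-substrate encounter exponentially unlikely.")
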