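"""Parse stapled-peptide notation and inspect the structural facts.

The parent stapled peptide carries an i, i+7 hydrocarbon staple (R8 at
position 4, S5 at 11) and three interfacial hot-spot residues (3, 7, 10)
that occupy the Phe19/Trp23/Leu26 sub-pockets of the MDM2 cleft.
"""

from helixscan import classify_position, parse_sequence, residue_count

p = parse_sequence("Ac-LTF[R8]EYWQL[Cba][S5]SAA-amide", name="MP-292")
print(f"{p.name}: {len(p)} residues, staple {p.staple_pair}, caps {p.n_cap}")
print(f"canonical notation: {p.render()}")
for pos in (3, 4, 5, 7, 10, 11):
    print(f"  position {pos:2d} ({p.residues[pos - 1].code:>3s}): {classify_position(p, pos)}")

# N-terminal cap chemistry (azido-lysine handle + beta-alanine spacer)
q = parse_sequence("Ac-K(N3)-(βA)-LTF[R8]EYWAQ[Cba][S5]SAA-amide", name="MP-081")
print(f"\n{q.name}: core residues {residue_count(q)}, "
      f"with amino-acid-like caps {residue_count(q, include_caps=True)}")
# The residue counts feed the per-residue CD normalization downstream.
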