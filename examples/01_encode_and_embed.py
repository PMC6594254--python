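"""Rank-encode a sequence and embed it on a spiral terrain.

Run: python examples/01_encode_and_embed.py
"""

import seqvis3d as sv

seq = sv.normalize_sequence("TGCCAATCGTTGT", id="demo")
rmap = sv.rank_function(seq)
digits = sv.encode_sequence(seq, rmap)

print(f"sequence : {seq.residues}")
print(f"counts   : {rmap.counts}")
print(f"rank map : {rmap.value}")
print(f"encoding : {digits}")
print("-> each digit is the frequency rank of the base at that position;")
print("   the most frequent base ranks 4, the rarest ranks 1.")

lattice = sv.spiral_embed(seq, rmap)
print(f"\nspiral grid: {lattice.side}x{lattice.side}, {len(lattice)} occupied cells")
by_pos = {n.seq_pos: (c, n.z) for c, n in lattice.nodes.items()}
for pos in range(1, len(seq) + 1):
    cell, z = by_pos[pos]
    print(f"  position {pos:2d} ({seq.residues[pos-1]}) -> cell {cell}, elevation {z}")
print("-> consecutive positions always sit in 4-adjacent cells;")
print("   the elevation is the rank digit, turning the sequence into a terrain.")
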