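"""Build a 51-residue window around a lysine near a protein's N-terminus.

The candidate K sits at offset 0; missing upstream positions are filled by
reflecting downstream residues across the K (mirror extension).
"""

from succsite import ProteinRecord, mirror_extend

protein = ProteinRecord(
    "SP-P0ABS8", "MLKNLAKLDQTEMDKVNVDLAAAGVAFKERYNMPVIAEAVEREQPEHLRSWFRERL"
)
fragment = mirror_extend(protein, site_pos=3)

print("fragment:", fragment.residues)
print("length:  ", len(fragment.residues))
print("offset  0:", fragment.at(0), " (the candidate lysine)")
print("offset -3:", fragment.at(-3), "== offset +3:", fragment.at(3),
      " (mirrored: the protein has only 2 residues upstream of the K)")
# The printed 51-mer reproduces the window exactly as the protein's real
# downstream residues, reflected to fill the 23 missing upstream positions.
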