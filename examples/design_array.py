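"""Design a 64-unit hybrid OL1/UAS operator array by simulated hierarchical assembly.

Builds the initial building block (split OL1 + complete UAS with randomised
spacers), doubles it through six ligation cycles, finalises the array, and
validates the motif counts by independent scan.  The printed step count is the
number of cloning steps including the initial block construction; the motif
counts must both equal the unit count in the finalized construct.
"""

from bifcros import OL1_LAMBDA, UAS_GAL4, assemble_to_target, count_motifs, make_building_block
from bifcros.io import write_array_fasta

block = make_building_block(seed=1)
print(f"building block ({block.unit_length} bp): {block.core}")

array = assemble_to_target(block, target_units=64)
print(f"assembled {array.n_units} units in {array.assembly_steps} cloning steps")
print(f"array length: {len(array.sequence)} bp")
print(f"complete OL1 motifs: {count_motifs(array, OL1_LAMBDA)}")
print(f"complete UAS motifs: {count_motifs(array, UAS_GAL4)}")

write_array_fasta("hybrid_array_64.fasta", array)
print("sequence written to hybrid_array_64.fasta")
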