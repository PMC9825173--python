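"""Reconstruct the two tau circRNAs from their published exon coordinates.

Builds the 12→10 and 12→7 exon chains (acceptor exon first, donor exon
last), reports circle lengths and reading-frame divisibility, and shows the
junction-anchor pair used to recruit read pairs from sequencing libraries.
No genome is needed for the coordinate arithmetic; attaching sequences
requires a genome FASTA (see recompute_published_counts.py).
"""

import circtau as ct

for name, order in [("tau 12→10", ct.TAU_12_10_EXON_ORDER), ("tau 12→7", ct.TAU_12_7_EXON_ORDER)]:
    exons = [ct.MAPT_EXONS[i] for i in order]
    length = ct.circ_length(exons)
    print(f"{name}: exons {order}")
    for i, ex in zip(order, exons):
        print(f"  exon {i:>2}: {ex}  ({ex.length} nt)")
    print(f"  circle length: {length} nt (length % 3 = {length % 3})")
    # A circle whose length is divisible by 3 keeps a ribosome in one frame
    # forever — the precondition for an 'infinite ORF'.
    print()

print("junction anchors (30-mers, 15 nt each side of the backsplice junction):")
print(f"  R1 (forward): {ct.TAU_R1_JUNCTION_ANCHOR}")
print(f"  R2 (revcomp): {ct.TAU_R2_JUNCTION_ANCHOR}")
match = ct.reverse_complement(ct.TAU_R1_JUNCTION_ANCHOR) == ct.TAU_R2_JUNCTION_ANCHOR
print(f"  reverse complement of R1 equals R2: {match}")
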