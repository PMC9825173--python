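# Methods

## Circle model and coordinates

Exon intervals are interpreted 1-based inclusive on both ends; this is the
convention under which the published MAPT exon coordinates give 93 + 82 +
113 = 288 nt for the 12→10 circle. Circles are stored linearized on the
mRNA sense strand with position 1 at the first nucleotide of the acceptor
exon, so the backsplice junction sits between position *L* and position 1.
All position arithmetic is modulo *L*. `rotate` changes the origin while
remapping the junction index, so anchors and site sets are origin-invariant
by construction and tested as such. Minus-strand exons are
reverse-complemented at build time. Tag inserts (e.g. a 3× Flag cassette)
are part of the sequence and of position numbering — matching an alignment
reference that includes the tag — with the occupied range recorded in
`tag_span` for callers that need tag-free numbering.

The 12→7 chain sums to 680 nt under this convention, which is not divisible
by three; the discrepancy with the described always-in-frame behaviour of
the expression constructs presumably reflects construct details (tag and
boundary choices) not derivable from coordinates alone. The package reports
the arithmetic as-is rather than adjusting any coordinate.

## Junction detection and alignment

Read pairs are recruited by exact, case-insensitive substring matching of a
junction anchor (default k = 30: 15 nt each side of the junction, the
length of the published greps) — forward anchor in R1, reverse complement
in R2, with an `unstranded` option that tries both orientations in both
mates. Both mates of a positive pair are kept. Anchor matching is exact by
design: a single mismatch in the anchor window drops the pair, which is
conservative and mirrors the grep-based recruitment it reproduces.

Recruited reads are aligned with a local affine-gap aligner (Biopython
`PairwiseAligner`; match +2, mismatch −3, gap open −5, gap extend −2)
against a **doubled** linearization of the reference, so junction-crossing
reads align contiguously without clipping; reported start positions and
per-column positions are reduced modulo *L*. Both strands are tried;
reverse-strand reads are complemented before alignment so pileup bases are
always on the sense strand. Placements below 90 % identity or 30 aligned
columns are discarded. Score parameters are this package's defaults (the
original analysis used a named preset of an external aligner); they are
exposed as keyword arguments.

Pileups count every aligned column of every mate; mates of a pair are not
deduplicated where they overlap (the original pipeline's behaviour is
unstated; counting per mate is the documented default). A read longer than
the circle contributes one count per traversal of a position.

## Editing-site calling

A position is called when the reference base is A and, in at least one
sample, G/depth ≥ `min_g_fraction` (default 0.01, the published "at least
1 % of G in one sample" rule; the boundary is inclusive) and depth ≥
`min_depth`. The depth floor (default 10) is this package's addition: with
no floor a single G-bearing read calls any position with ≤ 100× coverage.
Set `min_depth=0` for strict parity with the published rule. Called
positions are reported across all samples with per-sample G fractions;
increasing either threshold can only shrink the called set (tested).

## Editing consequences and translation

Edited adenosines are decoded as G throughout (standard nuclear code).
Start gains are restricted to in-frame AUA codons with a called site at the
third position — the only single A>G path to AUG; near-cognate starts
(GUG/CUG) are deliberately out of scope. Stall clusters are maximal groups
of ≥ 3 called sites with ≤ 2 nt between consecutive members, merged
transitively and circularly; both parameters are exposed, and the defaults
reproduce the 97–99 and 195–198 clusters from site lists at those
positions.

Rolling-circle translation defines one round as start codon to start codon.
For *L* divisible by 3 that is *L*/3 codons; otherwise the frame precesses
and a round is *L* codons (three passes). A product is emitted at every
round boundary, at the first entry into each stall cluster per round
(stalling is treated as partial: the truncated product is emitted *and*
translation continues), and at the first stop codon, which halts the
simulation. `max_rounds` defaults to 3, matching the two-to-three discrete
bands typically resolved for such products. Correctness is established
against an independent brute-force oracle — linear translation of explicit
tandem copies of the rotated sequence — over 1000 random circles of lengths
9–300.

Masses are average isotopic (Biopython residue masses plus one water,
18.0153 Da), unmodified residues, no N-terminal Met cleavage; monoisotopic
masses are available for mass-spectrometry cross-checks. Mass additivity
over rounds (mass of *k* rounds = *k*·(one-round mass − water) + water)
holds to numerical precision.

## Synthetic libraries

The simulator emulates an RNase-R-enriched, circRNA-only paired-end
library: fragment starts uniform over circle positions; insert lengths
normal (mean 150 nt, sd 20 nt, truncated at the read length); reads 100 nt;
per-site editing carried independently per fragment (no haplotype/linkage
structure, since none is documented) with the same state on every copy a
long fragment traverses; substitution errors i.i.d. at 0.1 %; constant
quality strings (the pipeline ignores qualities). R1 carries the sense
strand. Pair count is coverage·*L*/(2·read length), giving mean realized
depth within 5 % of nominal. Output is deterministic given the seed.

Default study conditions used throughout the test bench: a 288-nt circle,
five planted sites at 5–20 % (including an AUA third-position site at
20 %), 500× coverage, 0.1 % error. The generator does not emulate
sequencer-specific error profiles, PCR duplication, coverage bias or linear
RNA background — so passing recovery tests demonstrates correctness of the
pipeline's bookkeeping and thresholds under the stated sampling model, not
robustness to those real-data artifacts.

`end_to_end_recovery` always runs the junction scan and reports its
statistics, but quantifies editing from **all** simulated pairs by default:
on a circular-template-only library every pair is on-template, and
restricting the pileup to junction-recruited pairs would only concentrate
coverage inside the anchor footprint, making per-site depth depend on the
distance to the junction rather than on nominal coverage.
`junction_only=True` restores the restricted behaviour appropriate for
whole-library data, where recruitment is what isolates the circle.

## Numerical and degenerate-input choices

The 1 % boundary is evaluated as `g/depth >= min_g_fraction`, an inclusive
comparison on the computed fraction (10/1000 is called). Empty peptides
weigh one water. Zero-depth positions are never called. Anchor length must
be even and at most *L*; rotation origins, profile positions and mutation
reference bases are validated with the offending position in the error.
Editing a base that is already G (or a mutation already applied) is
accepted unchanged, making profile application idempotent.

## Known limitations

Detection is anchored to declared junctions — there is no de novo circRNA
discovery. Editing profiles are inputs or simulations; the package does not
predict which adenosines ADAR will edit from RNA structure. Gel-estimated
product sizes of multi-round translation need not match sequence-predicted
masses and are not modelled. Genome- and accession-dependent quantities
require the user to supply the contig FASTA and FASTQ libraries (see
`examples/recompute_published_counts.py`).
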