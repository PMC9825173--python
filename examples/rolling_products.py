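"""Predict rolling-circle translation products from an edited start codon.

On the 288-nt demo circle the planted AUA codon, once edited at its third
adenosine (AUA→AUI, decoded as AUG), becomes a start codon in a stop-free
frame: translation then proceeds around the circle repeatedly, releasing a
product at every return to the start ('round') and, partially, at clusters
of closely spaced edited sites (ribosome stalls).
"""

import circtau as ct
from circtau.rolling_translation import rolling_translate, stop_free_frames

circ, truth, ata_start = ct.demo_editing_scenario(seed=1)
sample = next(iter(truth))
sites = [ct.EditingSite(p, sample, f) for p, f in sorted(truth[sample].items())]

print(f"circle: {circ.name}, {circ.length} nt")
for scan in stop_free_frames(circ, sites=sites):
    print(f"  frame {scan.frame}: stop-free = {scan.stop_free} ({scan.n_codons} codons)")

gains = ct.find_start_gains(circ, sites, frame=0)
print(f"start codons in frame 0 after editing: "
      f"{[(g.position, g.provenance) for g in gains]}")

clusters = ct.find_stall_clusters(sites, circle_length=circ.length)
print(f"stall clusters among the planted sites (>=3 sites, gap <= 2 nt): "
      f"{[(c.start, c.end, c.n_sites) for c in clusters]}")

# runs of 3-4 edited adenosines stall ribosomes; feed the detector a site
# list shaped like the tau 12→10 clusters to see the grouping rule at work
run_sites = [ct.EditingSite(p, sample, 0.03) for p in (97, 98, 99, 195, 196, 197, 198)]
clusters = ct.find_stall_clusters(run_sites, circle_length=circ.length)
print(f"clusters in a 97-99 / 195-198 site list: "
      f"{[(c.start, c.end, c.n_sites) for c in clusters]}")

products = rolling_translate(
    circ, ata_start, max_rounds=3, sites=sites, stall_clusters=clusters
)
print(f"\nrolling-circle products from the AUI start at position {ata_start}:")
print(f"{'rounds':>7} {'aa':>5} {'mass (Da)':>10}  termination")
for p in products:
    print(f"{p.rounds:>7.2f} {p.length_aa:>5} {p.mass_da:>10.1f}  {p.termination}")
one_round = next(p for p in products if p.rounds == 1.0)
print(f"\none round = start codon to start codon: {one_round.length_aa} residues "
      f"({circ.length} nt / 3), average mass {one_round.mass_da:.1f} Da")
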