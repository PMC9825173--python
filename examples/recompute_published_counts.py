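"""Recompute genome- and accession-dependent tau circRNA quantities.

The circle sequences live on the GRCh38 alt contig chr17_KI270908v1_alt and
the editing tallies come from the deposited sequencing libraries
(GEO accession GSE216791); neither ships with this repository, so this
script takes them as inputs and reruns the full analysis:

  * circle reconstruction from the published exon coordinates, with an
    optional tag insert and point mutations (e.g. V337M, K317M);
  * adenosine counts and in-frame AUA codons (candidate AUI start codons);
  * one-round rolling-circle product length and average mass in Da;
  * per-sample editing-site calls (1%-G rule), per-ADAR counts, their union
    and the highest-edited site, from paired FASTQ files.

Example invocations:

  python recompute_published_counts.py \
      --genome-fasta chr17_KI270908v1_alt.fa --circle 12-10 \
      --tag <3xFlag-DNA-sequence> --tag-exon 0 --tag-offset 30 \
      --mutation 263:G>A:V337M

  python recompute_published_counts.py \
      --genome-fasta chr17_KI270908v1_alt.fa --circle 12-10 \
      --sample ADAR1 --r1 ADAR1_R1.fastq.gz --r2 ADAR1_R2.fastq.gz \
      --sample ADAR2 --r1 ADAR2_R1.fastq.gz --r2 ADAR2_R2.fastq.gz

Mutation coordinates are circle positions (1-based from the acceptor-exon
start, tag included when present — matching the alignment reference).
"""

import argparse
import sys

from Bio import SeqIO

import circtau as ct
from circtau.junction_pipeline import CallerConfig
from circtau.rolling_translation import rolling_translate, stop_free_frames

CHAINS = {"12-10": ct.TAU_12_10_EXON_ORDER, "12-7": ct.TAU_12_7_EXON_ORDER}


def parse_args(argv=None):
    ap = argparse.ArgumentParser(
        description=__doc__, formatter_class=argparse.RawDescriptionHelpFormatter
    )
    ap.add_argument(
        "--genome-fasta",
        required=True,
        help="FASTA containing the chr17_KI270908v1_alt contig (GRCh38)",
    )
    ap.add_argument("--circle", choices=sorted(CHAINS), default="12-10")
    ap.add_argument("--tag", help="tag insert nucleotide sequence (e.g. 3x Flag)")
    ap.add_argument("--tag-exon", type=int, default=0, help="0-based exon index hosting the tag")
    ap.add_argument("--tag-offset", type=int, default=0, help="nt into the host exon")
    ap.add_argument(
        "--mutation",
        action="append",
        default=[],
        metavar="POS:REF>ALT[:LABEL]",
        help="point mutation at a circle position (repeatable)",
    )
    ap.add_argument("--sample", action="append", default=[], help="sample label (repeatable)")
    ap.add_argument("--r1", action="append", default=[], help="R1 FASTQ(.gz), one per --sample")
    ap.add_argument("--r2", action="append", default=[], help="R2 FASTQ(.gz), one per --sample")
    ap.add_argument("--min-g-frac", type=float, default=0.01)
    ap.add_argument("--min-depth", type=int, default=10)
    ap.add_argument("--anchor-k", type=int, default=30)
    return ap.parse_args(argv)


def parse_mutation(text: str) -> ct.PointMutation:
    pos, change = text.split(":", 1)
    label = ""
    if ":" in change:
        change, label = change.split(":", 1)
    ref, alt = change.split(">")
    return ct.PointMutation(int(pos), ref, alt, label or text)


def main(argv=None) -> int:
    args = parse_args(argv)
    if not (len(args.sample) == len(args.r1) == len(args.r2)):
        sys.exit("--sample, --r1 and --r2 must be given the same number of times")

    contigs = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(args.genome_fasta, "fasta")}
    order = CHAINS[args.circle]
    exons = [ct.MAPT_EXONS[i] for i in order]
    try:
        sequences = [contigs[ex.contig][ex.start - 1 : ex.end] for ex in exons]
    except KeyError as exc:
        sys.exit(f"contig {exc} not found in {args.genome_fasta}")
    circ = ct.build_circ(
        f"tau_{args.circle}",
        exons,
        sequences,
        tag=args.tag,
        tag_exon=args.tag_exon if args.tag else None,
        tag_offset=args.tag_offset,
    )
    mutations = [parse_mutation(m) for m in args.mutation]

    print(f"circle tau {args.circle}: {circ.length} nt "
          f"({'tagged, ' + str(len(args.tag)) + ' nt tag' if args.tag else 'untagged'})")
    print(f"adenosines on the circle: {circ.sequence.count('A')}")
    for scan in stop_free_frames(circ, mutations=mutations):
        print(f"  frame {scan.frame}: stop-free = {scan.stop_free}")
        if not scan.stop_free:
            continue
        n_aua = sum(
            1
            for p in range(scan.frame + 1, circ.length, 3)
            if circ.subseq(p, 3) == "ATA"
        )
        print(f"    in-frame AUA codons (candidate AUI starts): {n_aua}")
        starts = ct.find_start_gains(circ, mutations=mutations, frame=scan.frame)
        for g in starts:
            prods = rolling_translate(
                circ, g.position, max_rounds=1, mutations=mutations
            )
            one = prods[-1]
            print(
                f"    start at {g.position} ({g.provenance}): one-round product "
                f"{one.length_aa} aa, average mass {one.mass_da:,.0f} Da"
            )

    if args.sample:
        anchor = ct.junction_anchor(circ, args.anchor_k)
        print(f"\njunction anchor (R1): {anchor.r1}")
        pileups = {}
        for sample, r1, r2 in zip(args.sample, args.r1, args.r2):
            scan = ct.scan_fastq(r1, r2, anchor)
            placements = [
                ct.align_circular(rec, circ)
                for rec in scan.r1_records + scan.r2_records
            ]
            pileups[sample] = ct.build_pileup(placements, circ)
            print(f"{sample}: {scan.n_junction_pairs}/{scan.n_pairs} junction pairs")
        config = CallerConfig(min_g_fraction=args.min_g_frac, min_depth=args.min_depth)
        sites = ct.call_sites(pileups, circ, config)
        summary = ct.compare_samples(sites)
        print(f"editing sites per sample: {summary['per_sample']}")
        print(f"union across samples: {summary['union']}")
        if summary["top_site"]:
            top = summary["top_site"]
            print(
                f"highest-edited site: position {top['position']} "
                f"({top['sample']}, G fraction {top['g_fraction']:.2f})"
            )
    return 0


if __name__ == "__main__":
    sys.exit(main())
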