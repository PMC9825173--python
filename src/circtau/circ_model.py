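"""Circular RNA models built from exon intervals.

A backspliced circRNA is represented as an ordered exon chain — acceptor exon
first, donor exon last — plus an optional tag insert (e.g. a 3x Flag cassette)
and, when available, its nucleotide sequence.  Position arithmetic is 1-based
and modulo the circle length.  By convention position 1 is the first
nucleotide of the acceptor exon; the backsplice junction therefore sits
between position ``length`` (last nucleotide of the donor exon) and
position 1.  :func:`rotate` moves the origin while keeping track of where the
junction is, so junction anchors can be re-derived after rotation.

Genomic coordinates are interpreted 1-based inclusive: this is the convention
under which the published MAPT exon coordinates for exons 10+11+12
(93 + 82 + 113 nt) reproduce the 288 nt tau 12→10 circle.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "GenomicInterval",
    "CircRNA",
    "JunctionAnchor",
    "circ_length",
    "build_circ",
    "junction_anchor",
    "rotate",
    "reverse_complement",
    "read_exon_table",
    "write_exon_table",
    "read_circ_fasta",
    "write_circ_fasta",
    "MAPT_EXONS",
    "TAU_12_10_EXON_ORDER",
    "TAU_12_7_EXON_ORDER",
    "TAU_R1_JUNCTION_ANCHOR",
    "TAU_R2_JUNCTION_ANCHOR",
]


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (case preserved by Biopython)."""
    return str(Seq(seq).reverse_complement())


@dataclass(frozen=True)
class GenomicInterval:
    """One exon's genomic footprint, 1-based inclusive on both ends."""

    contig: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"invalid interval {self.contig}:{self.start}-{self.end}: start > end"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.contig}:{self.start}-{self.end}({self.strand})"


#: Published GRCh38 coordinates of the MAPT exons participating in the two
#: tau circRNAs (alt contig chr17_KI270908v1_alt, 1-based inclusive).
MAPT_EXONS: dict[int, GenomicInterval] = {
    7: GenomicInterval("chr17_KI270908v1_alt", 693579, 693705),
    9: GenomicInterval("chr17_KI270908v1_alt", 698518, 698782),
    10: GenomicInterval("chr17_KI270908v1_alt", 712429, 712521),
    11: GenomicInterval("chr17_KI270908v1_alt", 716362, 716443),
    12: GenomicInterval("chr17_KI270908v1_alt", 720732, 720844),
}

#: Exon order (acceptor first, donor last) for the 12→10 and 12→7 circles.
TAU_12_10_EXON_ORDER: tuple[int, ...] = (10, 11, 12)
TAU_12_7_EXON_ORDER: tuple[int, ...] = (7, 9, 10, 11, 12)

#: Junction-spanning 30-mers used to recruit read pairs from the tau circRNA
#: sequencing libraries (GSE216791): the forward anchor is searched in R1
#: files, its reverse complement in R2 files.
TAU_R1_JUNCTION_ANCHOR = "ATTAATTATCTGCACCTTTTTATTTCCTCC"
TAU_R2_JUNCTION_ANCHOR = "GGAGGAAATAAAAAGGTGCAGATAATTAAT"


def circ_length(exons, tag_len: int = 0) -> int:
    """Total circle length in nt: sum of exon lengths plus the tag insert.

    Parameters
    ----------
    exons : iterable of GenomicInterval
    tag_len : int
        Length of an inserted tag cassette, 0 for untagged circles.
    """
    if tag_len < 0:
        raise ValueError(f"tag_len must be >= 0, got {tag_len}")
    return sum(ex.length for ex in exons) + tag_len


@dataclass(frozen=True)
class CircRNA:
    """A circular RNA: exon chain, optional tag, optional sequence.

    ``sequence`` is the linearized circle read 5'→3' on the mRNA sense strand
    starting at the current origin.  ``junction_index`` is the circle position
    (in current numbering) of the first nucleotide of the acceptor exon; the
    backsplice junction lies immediately 5' of it.  ``tag_span`` records the
    inclusive position range occupied by the tag insert, if any.
    """

    name: str
    exons: tuple[GenomicInterval, ...] = ()
    sequence: str | None = None
    tag: str | None = None
    tag_span: tuple[int, int] | None = None
    junction_index: int = 1

    def __post_init__(self) -> None:
        if self.sequence is not None:
            object.__setattr__(self, "sequence", self.sequence.upper())
            if self.exons:
                expected = circ_length(self.exons, len(self.tag or ""))
                if len(self.sequence) != expected:
                    raise ValueError(
                        f"{self.name}: sequence length {len(self.sequence)} does not "
                        f"match exon chain + tag length {expected}"
                    )
        if self.length < 1:
            raise ValueError(f"{self.name}: empty circle")

    @classmethod
    def from_sequence(cls, name: str, sequence: str, **kw) -> "CircRNA":
        """Build a circle directly from a linearized sequence (origin = position 1)."""
        return cls(name=name, sequence=sequence, **kw)

    @property
    def length(self) -> int:
        if self.sequence is not None:
            return len(self.sequence)
        return circ_length(self.exons, len(self.tag or ""))

    def wrap(self, pos: int) -> int:
        """Reduce any 1-based position onto the circle (modulo length)."""
        return (pos - 1) % self.length + 1

    def base(self, pos: int) -> str:
        self._require_sequence()
        return self.sequence[(pos - 1) % self.length]

    def subseq(self, start: int, n: int) -> str:
        """Circular substring of length ``n`` starting at position ``start``."""
        self._require_sequence()
        if n < 0:
            raise ValueError("n must be >= 0")
        i = (start - 1) % self.length
        tiled = self.sequence * (2 + n // self.length)
        return tiled[i : i + n]

    def _require_sequence(self) -> None:
        if self.sequence is None:
            raise ValueError(f"{self.name}: no sequence attached")


def build_circ(
    name: str,
    exons,
    sequences,
    tag: str | None = None,
    tag_exon: int | None = None,
    tag_offset: int = 0,
) -> CircRNA:
    """Assemble a CircRNA by concatenating per-exon sequences in exon order.

    ``sequences[i]`` is the genomic plus-strand sequence of ``exons[i]`` and
    must match its interval length; minus-strand exons are reverse-complemented
    at build time so the stored circle is always on the mRNA sense strand.
    A tag insert is placed inside exon ``tag_exon`` (0-based index into the
    chain) after ``tag_offset`` exonic nucleotides.  The origin (position 1)
    is the first nucleotide of the acceptor exon, i.e. ``exons[0]``.
    """
    exons = tuple(exons)
    sequences = list(sequences)
    if len(sequences) != len(exons):
        raise ValueError(
            f"{name}: {len(exons)} exons but {len(sequences)} sequences supplied"
        )
    parts: list[str] = []
    for i, (ex, sq) in enumerate(zip(exons, sequences)):
        sq = sq.upper()
        if len(sq) != ex.length:
            raise ValueError(
                f"{name}: exon {i + 1} ({ex}): sequence length {len(sq)} "
                f"!= interval length {ex.length}"
            )
        parts.append(reverse_complement(sq) if ex.strand == "-" else sq)

    tag_span = None
    if tag:
        if tag_exon is None or not (0 <= tag_exon < len(exons)):
            raise ValueError(f"{name}: tag requires a valid tag_exon index")
        if not (0 <= tag_offset <= exons[tag_exon].length):
            raise ValueError(
                f"{name}: tag_offset {tag_offset} outside exon of length "
                f"{exons[tag_exon].length}"
            )
        before = sum(len(p) for p in parts[:tag_exon]) + tag_offset
        tag = tag.upper()
        tag_span = (before + 1, before + len(tag))
        host = parts[tag_exon]
        parts[tag_exon] = host[:tag_offset] + tag + host[tag_offset:]

    return CircRNA(
        name=name, exons=exons, sequence="".join(parts), tag=tag, tag_span=tag_span
    )


@dataclass(frozen=True)
class JunctionAnchor:
    """A k-mer straddling the backsplice junction, k/2 nt each side.

    ``r1`` is the anchor on the sense strand (searched in forward reads),
    ``r2`` its reverse complement (searched in the opposite mate).
    """

    sequence: str

    @property
    def k(self) -> int:
        return len(self.sequence)

    @property
    def r1(self) -> str:
        return self.sequence

    @property
    def r2(self) -> str:
        return reverse_complement(self.sequence)


def junction_anchor(circ: CircRNA, k: int = 30) -> JunctionAnchor:
    """The k-mer spanning the donor-end/acceptor-start junction.

    k must be even and at most the circle length; the anchor takes k/2 nt
    from the donor exon end and k/2 nt from the acceptor exon start, using
    the circle's ``junction_index`` so the anchor survives rotation.
    """
    if k % 2 != 0:
        raise ValueError(f"anchor length k must be even, got {k}")
    if k > circ.length:
        raise ValueError(f"anchor length k={k} exceeds circle length {circ.length}")
    start = circ.wrap(circ.junction_index - k // 2)
    return JunctionAnchor(circ.subseq(start, k))


def rotate(circ: CircRNA, new_origin: int) -> CircRNA:
    """Same circle with position 1 moved to ``new_origin``.

    Rotating by 1 is the identity; rotating by ``length + 1`` equals rotating
    by 1.  The junction index (and tag span, if any) are remapped so that
    junction anchors re-derived from the rotated circle are unchanged.
    """
    circ._require_sequence()
    if not (1 <= new_origin <= circ.length):
        raise ValueError(
            f"new_origin {new_origin} out of range 1..{circ.length}"
        )
    i = new_origin - 1
    remap = lambda p: (p - new_origin) % circ.length + 1  # noqa: E731
    tag_span = tuple(remap(p) for p in circ.tag_span) if circ.tag_span else None
    return dataclasses.replace(
        circ,
        sequence=circ.sequence[i:] + circ.sequence[:i],
        junction_index=remap(circ.junction_index),
        tag_span=tag_span,
    )


# ---------------------------------------------------------------------------
# IO: BED-like exon tables and linearized circle FASTA
# ---------------------------------------------------------------------------

_EXON_COLUMNS = ("contig", "start", "end", "name", "strand")


def read_exon_table(path) -> list[tuple[str, GenomicInterval]]:
    """Read a BED-like TSV (contig, start, end, name, strand; header optional).

    Unlike true BED, coordinates are 1-based inclusive to match the convention
    of the printed exon coordinates this package works with.
    """
    rows: list[tuple[str, GenomicInterval]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if ln == 1 and fields[:3] == list(_EXON_COLUMNS[:3]):
                continue  # header
            if len(fields) < 5:
                raise ValueError(f"{path}: line {ln}: expected 5 columns, got {len(fields)}")
            contig, start, end, name, strand = fields[:5]
            rows.append((name, GenomicInterval(contig, int(start), int(end), strand)))
    return rows


def write_exon_table(rows, path) -> None:
    """Write (name, GenomicInterval) pairs as a BED-like TSV with header."""
    with open(path, "w") as fh:
        fh.write("\t".join(_EXON_COLUMNS) + "\n")
        for name, ex in rows:
            fh.write(f"{ex.contig}\t{ex.start}\t{ex.end}\t{name}\t{ex.strand}\n")


def write_circ_fasta(circ: CircRNA, path) -> None:
    """Write the linearized circle, recording origin metadata in the header."""
    circ._require_sequence()
    rec = SeqRecord(
        Seq(circ.sequence),
        id=circ.name,
        description=f"circular length={circ.length} junction_index={circ.junction_index}",
    )
    SeqIO.write([rec], path, "fasta")


def read_circ_fasta(path, name: str | None = None) -> CircRNA:
    """Read a linearized circle written by :func:`write_circ_fasta`.

    If ``name`` is given the matching record is selected, otherwise the first
    record is used.  A ``junction_index=N`` token in the description is honoured.
    """
    for rec in SeqIO.parse(path, "fasta"):
        if name is not None and rec.id != name:
            continue
        junction = 1
        for token in rec.description.split():
            if token.startswith("junction_index="):
                junction = int(token.split("=", 1)[1])
        return CircRNA(name=rec.id, sequence=str(rec.seq), junction_index=junction)
    raise ValueError(f"{path}: no record named {name!r}")
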