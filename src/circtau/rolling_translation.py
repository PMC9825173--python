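"""Rolling-circle translation of stop-free circular reading frames.

A circRNA whose length is divisible by three and whose reading frame contains
no stop codon is an "infinite ORF": a ribosome that initiates keeps going
around the circle, producing concatemeric peptides.  One *round* is defined
as translation from the start codon back to the same start codon.  For
circles not divisible by three the frame precesses, so a round corresponds
to three passes around the circle and a stop anywhere on the circle, in any
frame, terminates translation.

Products are emitted at every round boundary, optionally at stall clusters
(runs of closely spaced inosines that can release the nascent chain early),
and at the first stop codon encountered.  Edited adenosines are decoded as
guanosines throughout.  Masses are average isotopic by default (sum of
standard residue masses plus one water), with monoisotopic as an option for
mass-spectrometry cross-checks.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio import SeqIO
from Bio.SeqUtils import molecular_weight

from .circ_model import CircRNA
from .editing import apply_profile, _csub

__all__ = [
    "TranslationProduct",
    "FrameScan",
    "stop_free_frames",
    "rolling_translate",
    "peptide_mass",
    "write_products",
    "CODON_TO_AA",
    "STOP_CODONS",
    "WATER_AVERAGE_DA",
    "WATER_MONOISOTOPIC_DA",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]  # standard nuclear code
CODON_TO_AA: dict[str, str] = dict(_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_TABLE.stop_codons)

WATER_AVERAGE_DA = 18.0153
WATER_MONOISOTOPIC_DA = 18.010565

_STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


def peptide_mass(peptide: str, monoisotopic: bool = False) -> float:
    """Molecular mass of a peptide in Da (residue masses + one water).

    Average isotopic masses by default; the empty peptide weighs one water.
    Residues outside the 20 standard amino acids are rejected.
    """
    bad = set(peptide) - _STANDARD_AA
    if bad:
        raise ValueError(f"unknown residue(s) {sorted(bad)} in peptide")
    if not peptide:
        return WATER_MONOISOTOPIC_DA if monoisotopic else WATER_AVERAGE_DA
    return molecular_weight(peptide, seq_type="protein", monoisotopic=monoisotopic)


@dataclass(frozen=True)
class FrameScan:
    frame: int
    stop_free: bool
    n_codons: int


@dataclass(frozen=True)
class TranslationProduct:
    """One peptide released during rolling-circle translation.

    ``rounds`` counts start-to-start laps and is fractional for products
    released mid-round (stalls, stops).  ``termination`` is one of
    ``return_to_start``, ``stall_cluster``, ``stop_codon``, ``max_rounds``.
    """

    start_position: int
    rounds: float
    peptide: str
    mass_da: float
    termination: str

    @property
    def length_aa(self) -> int:
        return len(self.peptide)


def stop_free_frames(circ: CircRNA, sites=(), mutations=()) -> list[FrameScan]:
    """Which reading frames of the circle (after editing) lack stop codons.

    For circles divisible by three each of the three frames is scanned over
    one lap.  Otherwise the frame precesses and each scan covers the full
    codon cycle (three concatenated copies): ``stop_free=True`` then means a
    ribosome would never meet a stop no matter how many laps it makes.
    """
    seq = apply_profile(circ, sites, mutations) if (sites or mutations) else circ.sequence
    if seq is None:
        raise ValueError(f"{circ.name}: no sequence attached")
    L = len(seq)
    out = []
    for frame in range(3):
        n = L // 3 if L % 3 == 0 else L
        starts = [(frame + 3 * k) % L + 1 for k in range(n)]
        stop_free = not any(_csub(seq, p, 3) in STOP_CODONS for p in starts)
        out.append(FrameScan(frame=frame, stop_free=stop_free, n_codons=n))
    return out


def rolling_translate(
    circ: CircRNA,
    start_position: int,
    max_rounds: int = 3,
    stall_clusters=(),
    sites=(),
    mutations=(),
    emit_stalled: bool = True,
    monoisotopic: bool = False,
) -> list[TranslationProduct]:
    """Simulate rolling-circle translation from one start codon.

    The start codon must read AUG under the profile (a genomic AUG, a
    mutation-gained AUG or an edited AUA→AUI).  Translation decodes edited
    adenosines as G, emits a product at every return to the start codon, and
    halts at the first stop codon.  When ``emit_stalled`` is true a truncated
    product is additionally emitted the first time each stall cluster is
    entered in each round — stalling is treated as partial, so translation
    also continues past the cluster.  ``max_rounds`` bounds the simulation
    (default 3, matching the two-to-three discrete product bands typically
    resolved on a gel).
    """
    if max_rounds < 1:
        raise ValueError(f"max_rounds must be >= 1, got {max_rounds}")
    view = apply_profile(circ, sites, mutations) if (sites or mutations) else circ.sequence
    if view is None:
        raise ValueError(f"{circ.name}: no sequence attached")
    L = len(view)
    start_position = circ.wrap(start_position)
    if _csub(view, start_position, 3) != "ATG":
        raise ValueError(
            f"start_position {start_position} is not AUG/AUI under the profile "
            f"(codon {_csub(view, start_position, 3)})"
        )
    cpr = L // 3 if L % 3 == 0 else L  # codons per round (start to start)
    stall_pos: list[frozenset[int]] = [
        frozenset(cl.positions) if cl.positions else frozenset(range(cl.start, cl.end + 1))
        for cl in stall_clusters
    ]

    products: list[TranslationProduct] = []
    aa: list[str] = []
    stalled_emitted: set[tuple[int, int]] = set()

    def emit(rounds: float, termination: str) -> None:
        pep = "".join(aa)
        products.append(
            TranslationProduct(
                start_position=start_position,
                rounds=rounds,
                peptide=pep,
                mass_da=peptide_mass(pep, monoisotopic=monoisotopic),
                termination=termination,
            )
        )

    for i in range(max_rounds * cpr):
        p = (start_position - 1 + 3 * i) % L + 1
        codon = _csub(view, p, 3)
        if codon in STOP_CODONS:
            emit(i / cpr, "stop_codon")
            return products
        aa.append(CODON_TO_AA[codon])
        this_round = i // cpr
        if emit_stalled and stall_pos:
            covered = {(p - 1 + j) % L + 1 for j in range(3)}
            for ci, cluster in enumerate(stall_pos):
                if covered & cluster and (ci, this_round) not in stalled_emitted:
                    stalled_emitted.add((ci, this_round))
                    emit((i + 1) / cpr, "stall_cluster")
        if (i + 1) % cpr == 0:
            r = (i + 1) // cpr
            emit(float(r), "max_rounds" if r == max_rounds else "return_to_start")
    return products


def write_products(products, fasta_path=None, tsv_path=None, name_prefix: str = "product") -> None:
    """Write products as protein FASTA and/or a summary TSV."""
    if fasta_path is not None:
        records = [
            SeqRecord(
                Seq(p.peptide),
                id=f"{name_prefix}_{i + 1}",
                description=(
                    f"start={p.start_position} rounds={p.rounds:g} "
                    f"mass_da={p.mass_da:.2f} termination={p.termination}"
                ),
            )
            for i, p in enumerate(products)
        ]
        SeqIO.write(records, fasta_path, "fasta")
    if tsv_path is not None:
        pd.DataFrame(
            [
                {
                    "start": p.start_position,
                    "rounds": p.rounds,
                    "length_aa": p.length_aa,
                    "mass_da": round(p.mass_da, 3),
                    "termination": p.termination,
                }
                for p in products
            ],
            columns=["start", "rounds", "length_aa", "mass_da", "termination"],
        ).to_csv(tsv_path, sep="\t", index=False)
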