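"""Per-position A-to-I editing profiles on circular RNAs.

ADAR enzymes deaminate adenosines to inosines, which ribosomes (and reverse
transcriptase) decode as guanosines.  This module applies measured or
simulated editing profiles to a circle in that "translation view" (edited
A → G), classifies codon-level consequences — including start-codon gains
where an in-frame AUA becomes AUI, read as AUG — and detects clusters of
closely spaced edited sites, which are associated with ribosome stalling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .circ_model import CircRNA

__all__ = [
    "EditingSite",
    "PointMutation",
    "StallCluster",
    "StartGain",
    "CodonConsequence",
    "apply_profile",
    "find_start_gains",
    "codon_consequence",
    "find_stall_clusters",
    "count_editable",
    "read_sites_tsv",
    "write_sites_tsv",
    "read_mutations_tsv",
    "write_mutations_tsv",
]

_STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class EditingSite:
    """One A>I(G) editing observation at a circle position, per sample."""

    position: int
    sample: str = ""
    g_fraction: float = 0.0
    ref_base: str = "A"
    depth: int | None = None
    a_count: int | None = None
    g_count: int | None = None
    called: bool = True

    def __post_init__(self) -> None:
        if not (0.0 <= self.g_fraction <= 1.0):
            raise ValueError(
                f"position {self.position}: g_fraction {self.g_fraction} outside [0, 1]"
            )
        if self.called and self.ref_base != "A":
            raise ValueError(
                f"position {self.position}: called site must have ref_base A, "
                f"got {self.ref_base!r}"
            )


@dataclass(frozen=True)
class PointMutation:
    """A single-base substitution, e.g. an FTLD-tau start-gain mutation."""

    position: int
    ref: str
    alt: str
    label: str = ""


@dataclass(frozen=True)
class StallCluster:
    """A run of >=3 closely spaced edited sites (potential ribosome stall).

    For clusters spanning the origin, ``end < start`` and the member positions
    wrap around the circle; ``positions`` is always in traversal order.
    """

    start: int
    end: int
    positions: tuple[int, ...] = field(default=())

    @property
    def n_sites(self) -> int:
        return len(self.positions)


@dataclass(frozen=True)
class StartGain:
    position: int
    provenance: str  # genomic_AUG | mutation_gained | editing_gained
    codon_before: str
    codon_after: str


@dataclass(frozen=True)
class CodonConsequence:
    kind: str  # synonymous | missense | start_gain | stop_loss
    codon_start: int
    codon_before: str
    codon_after: str
    aa_before: str
    aa_after: str

    @property
    def aa_change(self) -> str:
        return f"{self.aa_before}>{self.aa_after}"


def _csub(seq: str, start: int, n: int) -> str:
    """Circular substring of a plain string, 1-based start."""
    L = len(seq)
    i = (start - 1) % L
    return (seq * (2 + n // L))[i : i + n]


def _translate_codon(codon: str) -> str:
    from .rolling_translation import CODON_TO_AA

    return "*" if codon in _STOPS else CODON_TO_AA[codon]


def apply_profile(circ: CircRNA, sites=(), mutations=()) -> str:
    """Sequence of the circle as the ribosome would read it.

    Mutations are applied first, then every *called* edited adenosine is
    replaced by G (inosine decoded as guanosine).  The input circle is not
    modified.  A mutation whose ``ref`` does not match the circle base, or a
    called site whose reference base is not A on the circle, is rejected with
    the offending position.  Positions whose base already equals the target
    base are accepted unchanged, so applying a profile to its own output is a
    no-op (idempotence).
    """
    circ._require_sequence()
    seq = list(circ.sequence)
    L = circ.length
    for m in mutations:
        i = (m.position - 1) % L
        if seq[i] not in (m.ref.upper(), m.alt.upper()):
            raise ValueError(
                f"mutation {m.label or m.ref + '>' + m.alt} at position "
                f"{m.position}: circle base is {seq[i]}, expected {m.ref}"
            )
        seq[i] = m.alt.upper()
    for s in sites:
        if not s.called:
            continue
        i = (s.position - 1) % L
        if circ.sequence[i] not in ("A", "G"):
            raise ValueError(
                f"editing site at position {s.position}: circle base is "
                f"{circ.sequence[i]}, expected A"
            )
        seq[i] = "G"
    return "".join(seq)


def _codon_starts(length: int, frame: int) -> list[int]:
    """1-based codon start positions of a reading frame on the circle.

    For circles divisible by 3 each frame has length/3 stable codons.
    Otherwise the frame precesses: a ribosome entering at offset ``frame``
    visits ``length`` distinct codon starts over three passes around the
    circle before returning to its entry point.
    """
    if frame not in (0, 1, 2):
        raise ValueError(f"frame must be 0, 1 or 2, got {frame}")
    n = length // 3 if length % 3 == 0 else length
    return [(frame + 3 * k) % length + 1 for k in range(n)]


def find_start_gains(circ: CircRNA, sites=(), mutations=(), frame: int = 0):
    """All in-frame AUG codons after applying the profile, with provenance.

    Provenance is ``genomic_AUG`` when the codon is AUG on the unedited
    circle, ``mutation_gained`` when a supplied mutation creates it, and
    ``editing_gained`` otherwise — which, for single A>G changes, happens
    exactly when an in-frame AUA codon has a called editing site at its third
    position (AUA → AUI, decoded as AUG).
    """
    circ._require_sequence()
    original = circ.sequence
    mutated = apply_profile(circ, sites=(), mutations=mutations)
    full = apply_profile(circ, sites=sites, mutations=mutations)
    gains = []
    for p in _codon_starts(circ.length, frame):
        after = _csub(full, p, 3)
        if after != "ATG":
            continue
        before = _csub(original, p, 3)
        mid = _csub(mutated, p, 3)
        if before == "ATG":
            provenance = "genomic_AUG"
        elif mid == "ATG":
            provenance = "mutation_gained"
        else:
            provenance = "editing_gained"
        gains.append(StartGain(p, provenance, before, after))
    return gains


def codon_consequence(circ: CircRNA, site: EditingSite, frame: int = 0) -> CodonConsequence:
    """Codon-level consequence of editing one adenosine, in a given frame.

    The codon containing the site is translated before and after the A→G
    substitution with the standard nuclear genetic code; AUA→AUG is reported
    as a start gain, loss of a stop codon as ``stop_loss``.
    """
    circ._require_sequence()
    L = circ.length
    pos = circ.wrap(site.position)
    offset = (pos - 1 - frame) % 3
    codon_start = circ.wrap(pos - offset)
    before = _csub(circ.sequence, codon_start, 3)
    if before[offset] != "A":
        raise ValueError(f"position {pos}: circle base is {before[offset]}, expected A")
    after = before[:offset] + "G" + before[offset + 1 :]
    aa_before = _translate_codon(before)
    aa_after = _translate_codon(after)
    if after == "ATG" and before != "ATG":
        kind = "start_gain"
    elif aa_before == "*" and aa_after != "*":
        kind = "stop_loss"
    elif aa_before == aa_after:
        kind = "synonymous"
    else:
        kind = "missense"
    return CodonConsequence(kind, codon_start, before, after, aa_before, aa_after)


def find_stall_clusters(
    sites,
    min_sites: int = 3,
    max_gap: int = 2,
    circle_length: int | None = None,
) -> list[StallCluster]:
    """Maximal groups of called sites with <= ``max_gap`` nt between neighbours.

    Groups are merged transitively and reported when they contain at least
    ``min_sites`` members.  When ``circle_length`` is given, adjacency across
    the origin is respected: a group ending near position ``circle_length``
    and one starting near position 1 merge into a single wrap-around cluster.
    The defaults (gap <= 2 nt, >= 3 members) reproduce published tau 12→10
    clusters at sites 97–99 and 195–198.
    """
    positions = sorted({s.position for s in sites if getattr(s, "called", True)})
    if not positions:
        return []
    groups: list[list[int]] = [[positions[0]]]
    for p in positions[1:]:
        if p - groups[-1][-1] <= max_gap:
            groups[-1].append(p)
        else:
            groups.append([p])
    if (
        circle_length is not None
        and len(groups) > 1
        and positions[0] + circle_length - positions[-1] <= max_gap
    ):
        groups[0] = groups.pop() + groups[0]
    clusters = [
        StallCluster(start=g[0], end=g[-1], positions=tuple(g))
        for g in groups
        if len(g) >= min_sites
    ]
    # a wrap-around cluster (end < start) sorts first
    return sorted(clusters, key=lambda c: c.positions[0] if c.end >= c.start else -1)


def count_editable(reference, tables: dict) -> dict:
    """Per-sample and union counts of called editing sites on one circle.

    ``reference`` is the circle (or its sequence); ``tables`` maps sample
    label → list of :class:`EditingSite`.  A position appearing with
    conflicting reference bases across tables is rejected.  Returns a dict
    with ``per_sample`` counts, the ``union`` of called positions (counted
    once per position) and ``total_adenosines`` in the reference.
    """
    seq = reference.sequence if isinstance(reference, CircRNA) else str(reference)
    ref_at: dict[int, str] = {}
    per_sample: dict[str, int] = {}
    union: set[int] = set()
    for sample, sites in tables.items():
        called = set()
        for s in sites:
            prev = ref_at.setdefault(s.position, s.ref_base)
            if prev != s.ref_base:
                raise ValueError(
                    f"position {s.position}: conflicting reference bases "
                    f"{prev!r} vs {s.ref_base!r} across samples"
                )
            if s.called:
                called.add(s.position)
        per_sample[sample] = len(called)
        union |= called
    return {
        "per_sample": per_sample,
        "union": len(union),
        "total_adenosines": seq.upper().count("A"),
    }


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

_SITE_COLUMNS = [
    "circ_name",
    "position",
    "ref_base",
    "sample",
    "depth",
    "a_count",
    "g_count",
    "g_fraction",
    "called",
]


def write_sites_tsv(sites, path, circ_name: str = "") -> None:
    rows = []
    for s in sites:
        rows.append(
            {
                "circ_name": circ_name,
                "position": s.position,
                "ref_base": s.ref_base,
                "sample": s.sample,
                "depth": s.depth,
                "a_count": s.a_count,
                "g_count": s.g_count,
                "g_fraction": s.g_fraction,
                "called": s.called,
            }
        )
    pd.DataFrame(rows, columns=_SITE_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sites_tsv(path) -> list[EditingSite]:
    df = pd.read_csv(path, sep="\t")
    sites = []
    for row in df.itertuples(index=False):
        sites.append(
            EditingSite(
                position=int(row.position),
                sample=str(row.sample),
                g_fraction=float(row.g_fraction),
                ref_base=str(row.ref_base),
                depth=None if pd.isna(row.depth) else int(row.depth),
                a_count=None if pd.isna(row.a_count) else int(row.a_count),
                g_count=None if pd.isna(row.g_count) else int(row.g_count),
                called=bool(row.called),
            )
        )
    return sites


def write_mutations_tsv(mutations, path, circ_name: str = "") -> None:
    rows = [
        {
            "circ_name": circ_name,
            "position": m.position,
            "ref": m.ref,
            "alt": m.alt,
            "label": m.label,
        }
        for m in mutations
    ]
    pd.DataFrame(rows, columns=["circ_name", "position", "ref", "alt", "label"]).to_csv(
        path, sep="\t", index=False
    )


def read_mutations_tsv(path) -> list[PointMutation]:
    df = pd.read_csv(path, sep="\t")
    return [
        PointMutation(int(r.position), str(r.ref), str(r.alt), str(r.label))
        for r in df.itertuples(index=False)
    ]
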