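"""Paired-end read simulation from a circular template, with ground truth.

The generator emulates an RNase-R-enriched, circRNA-only sequencing library:
fragments start uniformly over circle positions (rotational uniformity),
insert lengths are normal (truncated at the read length), each fragment
independently carries each planted editing site as G with its per-site
frequency, and substitution errors are i.i.d. per sequenced base.  R1 reports
the template (sense) strand, R2 the reverse complement of the fragment's
other end; base qualities are constant since the pipeline ignores them.
Everything is deterministic given the seed, and the full ground truth
(per-read origins, planted frequencies, realized edited-read counts) is
returned so that every upstream stage can be tested without downloads.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .circ_model import CircRNA, junction_anchor, reverse_complement
from .editing import find_start_gains
from .junction_pipeline import (
    CallerConfig,
    align_circular,
    build_pileup,
    call_sites,
    compare_samples,
    match_pair,
)

__all__ = [
    "SimulationConfig",
    "SimulationTruth",
    "ReadPair",
    "simulate_reads",
    "write_fastq_pair",
    "end_to_end_recovery",
    "read_start_uniformity",
    "random_circle",
    "demo_editing_scenario",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Study conditions for one simulated library.

    ``editing_truth`` maps sample label → {circle position → editing
    frequency in [0, 1]}; every truth position must be an adenosine on the
    circle.  ``coverage`` is mean per-position sequencing depth in x.
    Defaults mirror the conditions used throughout the test-bench: 500x
    coverage, 100 nt reads, 150 ± 20 nt inserts, 0.1% substitution error.
    """

    circ: CircRNA
    editing_truth: dict[str, dict[int, float]]
    coverage: int = 500
    read_length: int = 100
    insert_mean: int = 150
    insert_sd: int = 20
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self) -> None:
        if self.read_length > self.insert_mean:
            raise ValueError("read_length must be <= insert_mean")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        for sample, truth in self.editing_truth.items():
            for pos, freq in truth.items():
                if not (0 <= freq <= 1):
                    raise ValueError(f"{sample}: frequency {freq} at {pos} outside [0, 1]")
                if self.circ.base(pos) != "A":
                    raise ValueError(
                        f"{sample}: truth position {pos} has reference base "
                        f"{self.circ.base(pos)}, expected A"
                    )


@dataclass(frozen=True)
class ReadPair:
    read_id: str
    r1: str
    r2: str
    start: int  # 1-based circle position of the fragment 5' end (sense)
    insert: int


@dataclass
class SimulationTruth:
    """Ground truth of one simulation run."""

    config: SimulationConfig
    n_pairs: dict[str, int]
    starts: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    inserts: dict[str, np.ndarray] = field(repr=False, default_factory=dict)
    #: sample -> position -> (edited fragments covering, total fragments covering)
    realized: dict[str, dict[int, tuple[int, int]]] = field(default_factory=dict)

    def realized_fraction(self, sample: str, position: int) -> float:
        edited, covering = self.realized[sample][position]
        return edited / covering if covering else 0.0


def simulate_reads(config: SimulationConfig):
    """Generate paired reads per sample; returns (reads, truth).

    ``reads`` maps sample → list of :class:`ReadPair`.  The pair count per
    sample is round(coverage * circle_length / (2 * read_length)) so that the
    mean realized depth matches the requested coverage.
    """
    circ = config.circ
    circ._require_sequence()
    L, rl = circ.length, config.read_length
    n = int(round(config.coverage * L / (2 * rl)))
    reads: dict[str, list[ReadPair]] = {}
    truth = SimulationTruth(config=config, n_pairs={})
    for si, sample in enumerate(sorted(config.editing_truth)):
        rng = np.random.default_rng([int(config.seed) % 2**31, si])
        site_pos = sorted(config.editing_truth[sample])
        freqs = np.array([config.editing_truth[sample][p] for p in site_pos])
        starts = rng.integers(0, L, size=n)  # 0-based
        inserts = np.maximum(
            rl, np.rint(rng.normal(config.insert_mean, config.insert_sd, size=n)).astype(int)
        )
        edit_flags = (
            rng.random((n, len(site_pos))) < freqs if site_pos else np.zeros((n, 0), bool)
        )
        realized = {p: [0, 0] for p in site_pos}
        pairs: list[ReadPair] = []
        for i in range(n):
            start, ins = int(starts[i]), int(inserts[i])
            frag = list(circ.subseq(start + 1, ins))
            for j, p in enumerate(site_pos):
                off0 = (p - 1 - start) % L
                covers = off0 < ins
                if covers:
                    realized[p][1] += 1
                    if edit_flags[i, j]:
                        realized[p][0] += 1
                        for off in range(off0, ins, L):
                            frag[off] = "G"  # one molecule: same edit on every copy
            frag = "".join(frag)
            r1 = _with_errors(frag[:rl], rng, config.error_rate)
            r2 = _with_errors(reverse_complement(frag[-rl:]), rng, config.error_rate)
            pairs.append(
                ReadPair(
                    read_id=f"{sample}.{i}",
                    r1=r1,
                    r2=r2,
                    start=start + 1,
                    insert=ins,
                )
            )
        reads[sample] = pairs
        truth.n_pairs[sample] = n
        truth.starts[sample] = starts + 1
        truth.inserts[sample] = inserts
        truth.realized[sample] = {p: (e, c) for p, (e, c) in realized.items()}
    return reads, truth


def _with_errors(seq: str, rng: np.random.Generator, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hit = np.nonzero(rng.random(len(arr)) < error_rate)[0]
    for i in hit:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, len(choices))]
    return arr.tobytes().decode()


def write_fastq_pair(pairs, r1_path, r2_path) -> None:
    """Write simulated pairs as plain 4-line FASTQ (constant 'I' qualities)."""
    with open(r1_path, "w") as f1, open(r2_path, "w") as f2:
        for p in pairs:
            q1, q2 = "I" * len(p.r1), "I" * len(p.r2)
            f1.write(f"@{p.read_id}/1\n{p.r1}\n+\n{q1}\n")
            f2.write(f"@{p.read_id}/2\n{p.r2}\n+\n{q2}\n")


def read_start_uniformity(truth: SimulationTruth, sample: str, bins: int = 24) -> float:
    """Chi-square p-value for uniformity of fragment start positions."""
    L = truth.config.circ.length
    starts = truth.starts[sample]
    edges = np.linspace(0, L, bins + 1)
    observed, _ = np.histogram((starts - 1) % L, bins=edges)
    return float(stats.chisquare(observed).pvalue)


def end_to_end_recovery(
    config: SimulationConfig,
    caller: CallerConfig = CallerConfig(),
    junction_only: bool = False,
    anchor_k: int = 30,
) -> dict:
    """Simulate, run the junction pipeline, and compare calls with truth.

    The junction scan always runs and is reported as detection statistics.
    Quantification (pileup + calling) uses all simulated pairs by default,
    since on a circular-template-only library every pair is on-template;
    ``junction_only=True`` restricts the pileup to junction-positive pairs,
    as one would on a whole-library dataset.

    Returns a machine-readable report: per-sample scan/alignment statistics,
    per planted site the true and estimated frequency with a binomial
    standard error, false positives, and downstream start-gain checks.
    """
    circ = config.circ
    reads, truth = simulate_reads(config)
    anchor = junction_anchor(circ, anchor_k)
    pileups = {}
    scan_stats = {}
    for sample, pairs in reads.items():
        positive = [
            p for p in pairs if max(match_pair(p.r1, p.r2, anchor)) >= 0
        ]
        to_align = positive if junction_only else pairs
        placements = []
        for p in to_align:
            placements.append(align_circular(p.r1, circ, read_id=p.read_id + "/1"))
            placements.append(align_circular(p.r2, circ, read_id=p.read_id + "/2"))
        aligned = [pl for pl in placements if pl is not None]
        pileups[sample] = build_pileup(aligned, circ)
        scan_stats[sample] = {
            "n_pairs": len(pairs),
            "junction_pairs": len(positive),
            "aligned_reads": len(aligned),
        }
    sites = call_sites(pileups, circ, caller)
    called_by_sample: dict[str, set[int]] = {}
    site_row = {(s.sample, s.position): s for s in sites}
    for s in sites:
        if s.called:
            called_by_sample.setdefault(s.sample, set()).add(s.position)

    site_reports = []
    n_recovered = 0
    false_positives = set()
    planted_all = {
        (sample, pos)
        for sample, t in config.editing_truth.items()
        for pos in t
    }
    planted_positions = {pos for _, pos in planted_all}
    for sample, pos in sorted(planted_all):
        true_freq = config.editing_truth[sample][pos]
        row = site_row.get((sample, pos))
        depth = row.depth if row is not None else pileups[sample].depth(pos)
        est = row.g_fraction if row is not None else 0.0
        se = float(np.sqrt(true_freq * (1 - true_freq) / depth)) if depth else float("nan")
        called = pos in called_by_sample.get(sample, set())
        n_recovered += called
        site_reports.append(
            {
                "sample": sample,
                "position": pos,
                "true_freq": true_freq,
                "est_freq": est,
                "depth": depth,
                "binomial_se": se,
                "abs_error": abs(est - true_freq),
                "within_3se": bool(depth and abs(est - true_freq) <= 3 * se),
                "called": called,
            }
        )
    for sample, called in called_by_sample.items():
        truth_pos = set(config.editing_truth[sample])
        false_positives |= called - truth_pos
    gains = find_start_gains(circ, [s for s in sites if s.called], frame=0)
    report = {
        "scan": scan_stats,
        "comparison": compare_samples(sites),
        "sites": site_reports,
        "n_planted": len(planted_all),
        "n_recovered": n_recovered,
        "false_positive_positions": sorted(false_positives - planted_positions),
        "start_gains": [
            {"position": g.position, "provenance": g.provenance} for g in gains
        ],
        "called_sites": sites,
        "truth": truth,
    }
    return report


# ---------------------------------------------------------------------------
# Canned templates for tests and demonstrations
# ---------------------------------------------------------------------------

_SENSE_CODONS = sorted(
    c
    for c in ("".join(b) for b in itertools.product("ACGT", repeat=3))
    if c not in ("TAA", "TAG", "TGA")
)


def random_circle(
    length: int,
    rng,
    name: str | None = None,
    stop_free_frame: int | None = None,
    exclude_codons=(),
) -> CircRNA:
    """A random circular sequence, optionally stop-free in one frame.

    With ``stop_free_frame`` set (requires length divisible by 3) the circle
    is assembled from sense codons in that frame, excluding any codons listed
    in ``exclude_codons``; otherwise bases are i.i.d. uniform.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    if stop_free_frame is None:
        seq = "".join(str(b, "ascii") for b in rng.choice(_BASES, size=length))
    else:
        if length % 3 != 0:
            raise ValueError("stop-free construction requires length divisible by 3")
        pool = [c for c in _SENSE_CODONS if c not in set(exclude_codons)]
        codons = [pool[i] for i in rng.integers(0, len(pool), size=length // 3)]
        seq = "".join(codons)
        shift = stop_free_frame % 3
        seq = seq[-shift:] + seq[:-shift] if shift else seq
    return CircRNA.from_sequence(name or f"random_{length}nt", seq)


def demo_editing_scenario(seed: int = 0, sample: str = "ADAR2"):
    """A 288-nt tau-like test circle with five planted A>G sites (5–20%).

    The circle is stop-free in frame 0 and carries a single in-frame AUA
    codon whose third adenosine is planted at 20% — the editing event that
    creates an AUI start codon.  Four further adenosines inside the
    junction-anchored footprint are planted at 5–15%.  Returns
    ``(circ, editing_truth, ata_codon_start)`` where ``editing_truth`` is
    ready to drop into :class:`SimulationConfig`.
    """
    L = 288
    rng = np.random.default_rng([int(seed) % 2**31, 97])
    circ = random_circle(
        L, rng, name="tau_like_288nt", stop_free_frame=0, exclude_codons=("ATG", "ATA")
    )
    seq = list(circ.sequence)
    ata_start = 250  # frame-0 codon 84, third base = position 252
    seq[ata_start - 1 : ata_start + 2] = "ATA"
    seq = "".join(seq)
    # candidate extra sites: adenosines away from the 30-mer anchor
    # (positions 274..288 and 1..15) and outside the planted AUA codon
    window = [p for p in range(16, 274) if seq[p - 1] == "A" and not (250 <= p <= 252)]
    extra = sorted(rng.choice(window, size=4, replace=False).tolist())
    truth = {int(p): f for p, f in zip(extra, (0.05, 0.10, 0.15, 0.08))}
    truth[ata_start + 2] = 0.20
    circ = CircRNA.from_sequence(circ.name, seq)
    return circ, {sample: truth}, ata_start
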