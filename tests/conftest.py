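import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import circtau as ct

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def toy_circle():
    """6-nt circle; junction between position 6 and position 1."""
    return ct.CircRNA.from_sequence("toy", "ATGGCA")


@pytest.fixture
def stopfree_circle():
    """9-nt circle, stop-free in frame 0 with a genomic AUG at position 1."""
    return ct.CircRNA.from_sequence("toy9", "ATGGCAGCA")


@pytest.fixture(scope="session")
def demo_scenario():
    """288-nt tau-like circle with five planted editing sites (deterministic)."""
    circ, truth, ata_start = ct.demo_editing_scenario(seed=1)
    return circ, truth, ata_start


def oracle_rolling(seq: str, start: int, n_rounds: int):
    """Brute-force rolling-translation oracle by explicit tandem concatenation.

    Translates n_rounds of explicit copies of the rotated sequence linearly,
    codon by codon, and returns the same (peptide, rounds, termination)
    stream the simulator should produce.  Independent of the package's
    modular-arithmetic implementation.
    """
    from Bio.Data import CodonTable

    table = CodonTable.unambiguous_dna_by_id[1]
    L = len(seq)
    cpr = L // 3 if L % 3 == 0 else L
    rotated = seq[start - 1 :] + seq[: start - 1]
    text = rotated * (3 * n_rounds + 2)
    products = []
    aa = []
    for i in range(n_rounds * cpr):
        codon = text[3 * i : 3 * i + 3]
        if codon in table.stop_codons:
            products.append(("".join(aa), i / cpr, "stop_codon"))
            return products
        aa.append(table.forward_table[codon])
        if (i + 1) % cpr == 0:
            r = (i + 1) // cpr
            term = "max_rounds" if r == n_rounds else "return_to_start"
            products.append(("".join(aa), float(r), term))
    return products


@pytest.fixture
def rolling_oracle():
    return oracle_rolling


def plant_start(seq: str, start: int) -> str:
    """Overwrite three circular positions with ATG so translation can begin."""
    L = len(seq)
    s = list(seq)
    for j, b in enumerate("ATG"):
        s[(start - 1 + j) % L] = b
    return "".join(s)


@pytest.fixture
def start_planter():
    return plant_start
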