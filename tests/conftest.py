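import numpy as np
import pandas as pd
import pytest

from dhnkit import simulate as sim
from dhnkit.promoters import PWM
from dhnkit.segments import SEGMENT_CONSENSUS

K_CONSENSUS = SEGMENT_CONSENSUS["K"]


@pytest.fixture(scope="session")
def protein_panel():
    """Canonical eleven-gene panel at zero mutation with its truth."""
    return sim.gen_protein_panel(seed=0)


@pytest.fixture(scope="session")
def reference_loci():
    """Reference five-genome duplication layout plus the group map."""
    return sim.reference_locus_table(gap_tandem=10_000, seed=0)


@pytest.fixture(scope="session")
def sharp_pwm():
    """A near-deterministic 8-bp PWM with a non-palindromic consensus."""
    consensus = "TTGACCGA"
    mat = np.full((4, len(consensus)), 0.01)
    for j, b in enumerate(consensus):
        mat["ACGT".index(b), j] = 0.97
    return PWM("sharp", mat)


@pytest.fixture(scope="session")
def small_expression():
    """8 ecotypes x 4 replicates with the default planted drought effects."""
    truth = sim.default_expression_truth(n_ecotypes=8, n_replicates=4,
                                         dispersion=0.2, seed=11)
    tpm, design = sim.gen_expression_matrix(truth)
    return truth, tpm, design


def brute_force_windows(seq: str, query: str, max_mismatch: int):
    """Independent enumeration of all candidate windows (start, mismatches)."""
    w = len(query)
    out = []
    for i in range(len(seq) - w + 1):
        mm = sum(1 for a, b in zip(seq[i : i + w], query) if a != b or a == "X")
        if mm <= max_mismatch:
            out.append((i, mm))
    return out
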