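import numpy as np
import pytest

from cisreg.motif_model import PositionFrequencyMatrix, pfm_to_pwm

TOY_JASPAR = """\
>MA0001.1 TOY
A [ 8 0 ]
C [ 0 8 ]
G [ 0 0 ]
T [ 0 0 ]
"""


@pytest.fixture
def toy_pfm() -> PositionFrequencyMatrix:
    counts = np.array([[8, 0], [0, 8], [0, 0], [0, 0]], dtype=float)
    return PositionFrequencyMatrix("MA0001.1", "TOY", counts)


@pytest.fixture
def toy_pwm(toy_pfm):
    return pfm_to_pwm(toy_pfm)


def oracle_score(logodds_by_base: dict, kmer: str) -> float:
    """Independent scalar log-odds sum used by brute-force oracles."""
    return sum(logodds_by_base[b][i] for i, b in enumerate(kmer))


def oracle_logodds(pfm: PositionFrequencyMatrix, pseudocount: float = 1.0,
                   background=(0.25, 0.25, 0.25, 0.25)) -> dict:
    """Per-base log-odds computed with plain Python floats (no numpy)."""
    import math

    out = {}
    L = pfm.counts.shape[1]
    sums = [sum(float(pfm.counts[r][i]) for r in range(4)) for i in range(L)]
    for r, base in enumerate("ACGT"):
        out[base] = [
            math.log2(
                (float(pfm.counts[r][i]) + pseudocount * background[r])
                / (sums[i] + pseudocount)
                / background[r]
            )
            for i in range(L)
        ]
    return out


def enumerate_kmers(length: int):
    from itertools import product

    for combo in product("ACGT", repeat=length):
        yield "".join(combo)
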