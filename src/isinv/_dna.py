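"""Small DNA helpers shared across modules."""
from __future__ import annotations

from itertools import product

import numpy as np

BASES = "ACGT"
_COMP = str.maketrans("ACGTNacgtn-", "TGCANtgcan-")

START_CODONS = ("ATG", "GTG", "TTG")
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
CODONS = tuple("".join(p) for p in product(BASES, repeat=3))


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (gaps and N preserved)."""
    return seq.translate(_COMP)[::-1]


def complement(base: str) -> str:
    return base.translate(_COMP)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))


def random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(BASES[i] for i in rng.integers(0, 4, size=n))
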