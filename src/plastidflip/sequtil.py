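"""Low-level nucleotide sequence helpers shared across the package."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")

BASES = "ACGT"
_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (N-safe)."""
    return seq.translate(_COMPLEMENT)[::-1]


def random_seq(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random sequence of given length with expected GC fraction ``gc``."""
    if length < 0:
        raise ValueError("length must be >= 0")
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    idx = rng.choice(4, size=length, p=p)
    return _BASE_ARR[idx].tobytes().decode("ascii")


def gc_fraction(seq: str) -> float:
    """(G+C)/(A+C+G+T); ambiguous bases excluded from the denominator.

    Returns NaN when no unambiguous base is present.
    """
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        return float("nan")
    return gc / (gc + at)


def circular_slice(seq: str, start: int, length: int) -> str:
    """Slice ``length`` bases starting at ``start`` on a circular sequence."""
    n = len(seq)
    if length > n:
        raise ValueError("slice longer than sequence")
    start %= n
    end = start + length
    if end <= n:
        return seq[start:end]
    return seq[start:] + seq[: end - n]


def hamming(a: str, b: str) -> int:
    """Number of mismatching positions between equal-length strings."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(x != y for x, y in zip(a, b))
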