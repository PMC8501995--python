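"""Small DNA-string helpers shared across modules."""

from __future__ import annotations

import numpy as np

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_ALPHABET = np.frombuffer(b"ACGT", dtype=np.uint8)

DNA = "ACGT"


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def random_dna(rng: np.random.Generator, length: int) -> str:
    """Uniform random DNA string of the given length."""
    idx = rng.integers(0, 4, size=length)
    return _ALPHABET[idx].tobytes().decode("ascii")


def find_all(needle: str, haystack: str) -> list[int]:
    """All (possibly overlapping) start indices of needle in haystack."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def check_dna(seq: str, name: str = "sequence") -> str:
    seq = seq.upper()
    if not seq or any(c not in "ACGT" for c in seq):
        raise ValueError(f"{name} must be non-empty and contain only A/C/G/T: {seq!r}")
    return seq
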