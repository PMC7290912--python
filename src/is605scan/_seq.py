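"""Low-level DNA sequence helpers shared across the package.

Sequences are passed around as plain upper-case ``str`` at module
boundaries and as ``uint8`` code arrays (A=0, C=1, G=2, T=3, anything
else=4) inside the alignment kernels.  Code 4 never matches anything,
including itself, which is how masked regions are represented.
"""

from __future__ import annotations

import numpy as np

_CODES = np.full(256, 4, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _CODES[ord(_c)] = _i
    _CODES[ord(_c.lower())] = _i

_BASES = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string as a uint8 code array (A0 C1 G2 T3, other 4)."""
    return _CODES[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)].copy()


def decode(codes: np.ndarray) -> str:
    return _BASES[np.asarray(codes, dtype=np.uint8)].tobytes().decode("ascii")


def complement_base(b: str) -> str:
    return _COMP[b]


def revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTNacgtn", "TGCANtgcan"))[::-1]


def is_wc_pair(x: str, y: str) -> bool:
    """Watson-Crick pairing only (A.T, G.C); no wobble."""
    return _COMP.get(x) == y


def random_seq(rng: np.random.Generator, n: int, gc: float = 0.5) -> str:
    """I.i.d. random DNA with the requested GC content."""
    if not 0.0 <= gc <= 1.0:
        raise ValueError("gc must be in [0, 1]")
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return decode(rng.choice(4, size=n, p=p).astype(np.uint8))


def gc_content(seq: str) -> float:
    if not seq:
        return 0.0
    return (seq.count("G") + seq.count("C")) / len(seq)
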