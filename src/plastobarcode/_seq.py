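"""Low-level DNA string helpers shared across modules.

Sequences are plain upper-case Python strings over {A,C,G,T,N}; numpy uint8
views are used only inside performance-sensitive scanners.
"""

from __future__ import annotations

import numpy as np

_COMP = str.maketrans("ACGTN", "TGCAN")

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")


def complement(seq: str) -> str:
    return seq.translate(_COMP)


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def to_uint8(seq: str) -> np.ndarray:
    """View a DNA string as a uint8 array (ASCII codes)."""
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T."""
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def rotate(seq: str, offset: int) -> str:
    """Rotate a circular sequence so that position ``offset`` becomes position 0."""
    offset %= len(seq)
    return seq[offset:] + seq[:offset]


def gc_percent(seq: str) -> float:
    """GC content in percent; N bases are excluded from the denominator."""
    g = seq.count("G")
    c = seq.count("C")
    denom = g + c + seq.count("A") + seq.count("T")
    if denom == 0:
        raise ValueError("GC content undefined: no unambiguous bases")
    return 100.0 * (g + c) / denom
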