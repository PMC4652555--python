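"""Low-level DNA sequence utilities shared across the package.

Everything here operates on plain Python strings over the alphabet
``{A, C, G, T}``. Ambiguity codes are rejected; reads containing them are
split upstream (see :func:`split_on_ambiguous`).
"""

from __future__ import annotations

import re

__all__ = [
    "InvalidSequenceError",
    "reverse_complement",
    "is_dna",
    "split_on_ambiguous",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DNA_RE = re.compile(r"^[ACGT]*$")
_AMBIG_SPLIT_RE = re.compile(r"[^ACGT]+")


class InvalidSequenceError(ValueError):
    """Raised when a sequence contains characters outside {A, C, G, T}."""


def is_dna(seq: str) -> bool:
    """Return True if *seq* consists only of A/C/G/T (uppercase)."""
    return bool(_DNA_RE.match(seq))


def reverse_complement(seq: str) -> str:
    """Watson–Crick reverse complement of *seq*.

    An involution: ``reverse_complement(reverse_complement(s)) == s``.

    Raises
    ------
    InvalidSequenceError
        If *seq* contains a character outside {A, C, G, T}.
    """
    if not _DNA_RE.match(seq):
        bad = sorted(set(seq) - set("ACGT"))
        raise InvalidSequenceError(f"non-ACGT character(s) in sequence: {bad}")
    return seq.translate(_COMPLEMENT)[::-1]


def split_on_ambiguous(seq: str) -> list[str]:
    """Split *seq* at runs of non-ACGT characters, dropping empty fragments.

    Standard assembler behaviour for reads carrying N or other ambiguity
    codes: each clean fragment is treated as an independent read.
    """
    seq = seq.upper()
    return [frag for frag in _AMBIG_SPLIT_RE.split(seq) if frag]
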