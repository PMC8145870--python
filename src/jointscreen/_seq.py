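"""Small nucleotide-string helpers shared across modules.

Sequences are plain Python ``str`` throughout the package: probes and reads
are short (tens to a few hundred bases) and the hot loops rely on C-level
``str`` searching, so a heavier sequence object would buy nothing.
"""

from __future__ import annotations

from .errors import SequenceError

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")


def clean_seq(seq: str, *, name: str = "sequence") -> str:
    """Uppercase ``seq`` and verify it contains only A/C/G/T.

    IUPAC ambiguity codes are rejected rather than expanded: junction probes
    must stay literal strings for exact read matching.
    """
    if not seq:
        raise SequenceError(f"{name} is empty")
    s = seq.upper()
    if not _VALID.issuperset(s):
        for i, c in enumerate(s):
            if c not in _VALID:
                raise SequenceError(
                    f"{name} contains non-ACGT character {c!r} at offset {i}"
                )
    return s


def revcomp(seq: str) -> str:
    """Reverse complement of an ACGT string."""
    return seq.translate(_COMPLEMENT)[::-1]


def circular_slice(seq: str, start: int, stop: int) -> str:
    """Slice ``[start, stop)`` of a circular sequence, indices taken modulo
    ``len(seq)``.  ``stop - start`` must not exceed the sequence length."""
    n = len(seq)
    length = stop - start
    if length > n:
        raise ValueError("slice longer than the circular sequence")
    if length <= 0:
        return ""
    start %= n
    if start + length <= n:
        return seq[start : start + length]
    return seq[start:] + seq[: start + length - n]
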