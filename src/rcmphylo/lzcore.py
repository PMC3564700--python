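"""Lempel-Ziv production complexity via the exhaustive-history parse.

The production complexity ``c(S)`` of a sequence S is the number of steps
needed to generate S from the empty state when each step copies the longest
substring already reproducible from the history and then appends one new
symbol.  The copy source may *self-overlap*: it can start before the current
position and extend into symbols written during the same step's copy, which
is what allows e.g. ``AAAAAA`` to be produced in two steps (``A`` then
``AAAAA`` copied with overlap).  The final step may end mid-copy, in which
case it contributes a component with no appended symbol but still counts as
one step.

The parse of ``TGATGCGACACA`` is ``T.G.A.TGC.GAC.ACA`` (complexity 6): the
fourth step copies ``TG`` from positions 0-1 and adds ``C``, and the last
step is a pure overlapping copy of ``ACA``.

Concatenation complexities ``c(S1 S2)`` feed the relative complexity
measure: ``c(S2 S1) - c(S2)`` is the number of extra steps needed to produce
S1 when the full history of S2 is already available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

from .sequences import NucSequence, clean_bases

__all__ = ["LZStep", "LZParse", "lz_parse", "lz_complexity", "concat_complexity"]

SequenceLike = Union[NucSequence, str]


@dataclass(frozen=True)
class LZStep:
    """One production step: length of the copied prefix and the added symbol.

    ``add`` is ``None`` only for a copy-only final step.
    """

    copy_len: int
    add: Optional[str]


@dataclass(frozen=True)
class LZParse:
    """Exhaustive-history parse: ordered components whose join is the input."""

    components: tuple[str, ...]
    steps: tuple[LZStep, ...]

    @property
    def complexity(self) -> int:
        return len(self.components)

    @property
    def dotted(self) -> str:
        """Dot-joined component string, e.g. ``T.G.A.TGC.GAC.ACA``."""
        return ".".join(self.components)

    def __str__(self) -> str:
        return self.dotted


def _as_bases(seq: SequenceLike) -> str:
    if isinstance(seq, NucSequence):
        return seq.bases
    if not seq:
        raise ValueError("LZ complexity requires a non-empty sequence")
    return clean_bases(seq)


def _longest_copy(s: str, i: int, n: int) -> int:
    """Longest l such that s[i:i+l] occurs starting at some position < i.

    The search window for the candidate of length l+1 ends at ``i + l``,
    which admits every start position p <= i-1 while letting the occurrence
    itself run past i (self-overlapping copy).
    """
    l = 0
    find = s.find
    while i + l < n and find(s[i : i + l + 1], 0, i + l) != -1:
        l += 1
    return l


def lz_parse(seq: SequenceLike) -> LZParse:
    """Exhaustive-history parse of a nucleotide sequence.

    Raises ``ValueError`` on an empty input and ``SequenceError`` (naming
    position and symbol) on alphabet violations.
    """
    s = _as_bases(seq)
    n = len(s)
    if n == 0:
        raise ValueError("LZ parse requires a non-empty sequence")
    components: list[str] = []
    steps: list[LZStep] = []
    i = 0
    while i < n:
        l = _longest_copy(s, i, n)
        if i + l < n:
            components.append(s[i : i + l + 1])
            steps.append(LZStep(l, s[i + l]))
            i += l + 1
        else:  # sequence ends mid-copy: copy-only final component
            components.append(s[i:])
            steps.append(LZStep(l, None))
            i = n
    return LZParse(tuple(components), tuple(steps))


def _complexity(s: str) -> int:
    # Count-only version of lz_parse; the empty string has complexity 0
    # internally, but the public entry points reject it.
    n = len(s)
    c = 0
    i = 0
    while i < n:
        l = _longest_copy(s, i, n)
        c += 1
        i += l + 1 if i + l < n else l
    return c


def lz_complexity(seq: SequenceLike) -> int:
    """Number of production steps of the exhaustive-history parse."""
    s = _as_bases(seq)
    if not s:
        raise ValueError("LZ complexity requires a non-empty sequence")
    return _complexity(s)


def concat_complexity(s1: SequenceLike, s2: SequenceLike) -> int:
    """``c(S1 S2)``: complexity of plain concatenation, no separator symbol."""
    a = _as_bases(s1)
    b = _as_bases(s2)
    if not a or not b:
        raise ValueError("concat_complexity requires two non-empty sequences")
    return _complexity(a + b)
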