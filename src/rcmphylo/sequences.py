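"""Nucleotide sequence container and FASTA input/output.

The complexity machinery downstream operates on plain upper-case A/C/G/T
strings.  Real marker data (nuclear ITS, chloroplast trnL-trnF) arrive from
GenBank in mixed case, occasionally as RNA (``U``) and sometimes with IUPAC
ambiguity codes; this module is the single place where those are normalised
or rejected, so every other module can assume a clean alphabet.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ALPHABET",
    "AMBIGUITY_CODES",
    "SequenceError",
    "NucSequence",
    "clean_bases",
    "read_fasta",
    "write_fasta",
]

log = logging.getLogger(__name__)

ALPHABET = frozenset("ACGT")
#: IUPAC nucleotide ambiguity codes (everything except A/C/G/T/U and gaps).
AMBIGUITY_CODES = frozenset("RYSWKMBDHVN")


class SequenceError(ValueError):
    """Raised for symbols outside the accepted nucleotide alphabet."""


def clean_bases(raw: str, *, ambiguous: str = "reject", label: str = "<seq>") -> str:
    """Normalise a raw nucleotide string to upper-case A/C/G/T.

    Lower case is upper-cased; ``U`` is mapped to ``T`` with a logged
    warning.  IUPAC ambiguity codes are rejected by default because parsing
    them as extra alphabet symbols would silently change complexity values;
    ``ambiguous="strip"`` deletes them instead (the count is logged).
    Any other symbol is always an error naming its position.
    """
    if ambiguous not in ("reject", "strip"):
        raise ValueError(f"unknown ambiguity policy {ambiguous!r}")
    s = raw.upper()
    if "U" in s:
        log.warning("sequence %s: RNA alphabet detected, mapping U -> T", label)
        s = s.replace("U", "T")
    if ambiguous == "strip":
        kept = []
        dropped = 0
        for i, ch in enumerate(s):
            if ch in ALPHABET:
                kept.append(ch)
            elif ch in AMBIGUITY_CODES:
                dropped += 1
            else:
                raise SequenceError(
                    f"sequence {label}: invalid symbol {ch!r} at position {i}"
                )
        if dropped:
            log.warning("sequence %s: stripped %d ambiguous base(s)", label, dropped)
        return "".join(kept)
    for i, ch in enumerate(s):
        if ch not in ALPHABET:
            kind = "ambiguity code" if ch in AMBIGUITY_CODES else "invalid symbol"
            raise SequenceError(
                f"sequence {label}: {kind} {ch!r} at position {i}"
            )
    return s


@dataclass(frozen=True)
class NucSequence:
    """A labelled nucleotide sequence over the strict {A,C,G,T} alphabet.

    The constructor validates; use :meth:`from_raw` for data that still
    needs case/RNA/ambiguity normalisation.
    """

    id: str
    bases: str

    def __post_init__(self) -> None:
        if not self.bases:
            raise SequenceError(f"sequence {self.id}: empty sequence")
        for i, ch in enumerate(self.bases):
            if ch not in ALPHABET:
                raise SequenceError(
                    f"sequence {self.id}: invalid symbol {ch!r} at position {i}"
                )

    @classmethod
    def from_raw(cls, id: str, raw: str, *, ambiguous: str = "reject") -> "NucSequence":
        return cls(id, clean_bases(raw, ambiguous=ambiguous, label=id))

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return self.bases


def read_fasta(path: Union[str, Path], *, ambiguous: str = "reject") -> list[NucSequence]:
    """Read a multi-record FASTA file into validated :class:`NucSequence`.

    Record IDs are the first whitespace-delimited token of each header.
    """
    seqs = [
        NucSequence.from_raw(rec.id, str(rec.seq), ambiguous=ambiguous)
        for rec in SeqIO.parse(str(path), "fasta")
    ]
    if not seqs:
        raise SequenceError(f"{path}: no FASTA records found")
    return seqs


def write_fasta(seqs: Iterable[NucSequence], path: Union[str, Path]) -> None:
    records = [
        SeqRecord(Seq(s.bases), id=s.id, description="") for s in seqs
    ]
    SeqIO.write(records, str(path), "fasta")
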