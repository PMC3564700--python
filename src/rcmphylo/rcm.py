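"""Relative complexity measure (RCM) distances and distance matrices.

For sequences S1, S2 with LZ production complexities c(.) the distance is

    d(S1,S2) = [ (c(S1S2) - c(S1)) + (c(S2S1) - c(S2)) ]
               / [ (c(S1S2) + c(S2S1)) / 2 ]

``c(S2S1) - c(S2)`` is the number of production steps needed to generate S1
when the exhaustive history of S2 is already available, so the numerator is
the total conditional production cost in both directions and the
denominator normalises by the mean joint complexity.  The measure is
symmetric by construction and, because the conditional costs are at least
1, ``d(S,S)`` is strictly positive (``2 (c(SS)-c(S)) / c(SS)``, i.e.
``2/(c+1)`` whenever ``c(SS) = c(S)+1``).  Emitted matrices nevertheless
write 0.0 on the diagonal, which downstream neighbor joining and the PHYLIP
interchange format both require.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence, Union

import numpy as np

from .lzcore import _complexity, lz_complexity
from .sequences import NucSequence

__all__ = [
    "rcm_distance",
    "distance_matrix",
    "DistanceMatrix",
    "DISTANCE_FUNCTIONS",
]

_SYMMETRY_TOL = 1e-12


def rcm_distance(s1: NucSequence, s2: NucSequence) -> float:
    """RCM distance between two sequences (symmetric, in [0, 2])."""
    a = s1.bases if isinstance(s1, NucSequence) else s1
    b = s2.bases if isinstance(s2, NucSequence) else s2
    if not a or not b:
        raise ValueError("rcm_distance requires two non-empty sequences")
    c1 = _complexity(a)
    c2 = _complexity(b)
    c12 = _complexity(a + b)
    c21 = _complexity(b + a)
    return ((c12 - c1) + (c21 - c2)) / (0.5 * (c12 + c21))


#: Named registry of pairwise distance functions.  Only the RCM variant above
#: is implemented; alternative normalisations of the same conditional
#: complexities can be registered here without touching the matrix builder.
DISTANCE_FUNCTIONS: dict[str, Callable[[NucSequence, NucSequence], float]] = {
    "rcm": rcm_distance,
}


@dataclass
class DistanceMatrix:
    """Labelled symmetric matrix of pairwise distances.

    Invariants checked on construction: square, symmetric to 1e-12, finite,
    non-negative, labels unique and matching the matrix order.
    """

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            dups = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate labels: {dups}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("matrix contains negative entries")
        if np.abs(self.values - self.values.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise ValueError("matrix is not symmetric")

    def __len__(self) -> int:
        return len(self.labels)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    # ---- PHYLIP square matrix interchange -------------------------------

    def to_phylip(self, path: Union[str, Path, None] = None, *, relaxed: bool = False) -> str:
        """Serialise in PHYLIP square format.

        Strict dialect pads/truncates names to 10 characters (the classic
        NEIGHBOR input); ``relaxed=True`` writes full names separated by
        whitespace.  Note the diagonal is written as 0.0 even though the RCM
        self-distance of the formula is strictly positive.
        """
        lines = [f"{len(self.labels):5d}"]
        names = list(self.labels)
        if not relaxed:
            short = [name[:10] for name in names]
            if len(set(short)) != len(short):
                raise ValueError(
                    "strict PHYLIP 10-character names collide; use relaxed=True"
                )
            names = [s.ljust(10) for s in short]
        for name, row in zip(names, self.values):
            vals = " ".join(f"{v:.10f}" for v in row)
            sep = " " if relaxed else ""
            lines.append(f"{name}{sep}{vals}")
        text = "\n".join(lines) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_phylip(cls, source: Union[str, Path]) -> "DistanceMatrix":
        """Parse a PHYLIP square matrix (strict or relaxed dialect).

        ``source`` is a path or the raw text.  Dialect is detected per row:
        if whitespace-splitting yields n+1 tokens the row is relaxed,
        otherwise the first 10 characters are taken as the name.
        """
        text = source if "\n" in str(source) else Path(source).read_text()
        lines = [ln for ln in str(text).splitlines() if ln.strip()]
        n = int(lines[0].split()[0])
        if len(lines) - 1 != n:
            raise ValueError(f"expected {n} matrix rows, found {len(lines) - 1}")
        labels = []
        rows = []
        for ln in lines[1:]:
            toks = ln.split()
            if len(toks) == n + 1:
                labels.append(toks[0])
                rows.append([float(t) for t in toks[1:]])
            else:
                labels.append(ln[:10].strip())
                rows.append([float(t) for t in ln[10:].split()])
        return cls(tuple(labels), np.array(rows, dtype=float))


def distance_matrix(
    seqs: Sequence[NucSequence],
    *,
    distance: str = "rcm",
) -> DistanceMatrix:
    """All-pairs distance matrix over the input sequences.

    Requires at least 3 sequences (the neighbor-joining minimum) with unique
    IDs; the label order follows the input order.  Single-sequence
    complexities are computed once and reused across pairs, so the result is
    identical to independent pairwise calls.
    """
    seqs = list(seqs)
    if len(seqs) < 3:
        raise ValueError(f"need at least 3 sequences, got {len(seqs)}")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        dups = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sequence IDs: {dups}")
    if distance != "rcm":
        # seam for alternative normalisations; generic path has no caching
        fn = DISTANCE_FUNCTIONS[distance]
        n = len(seqs)
        M = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                M[i, j] = M[j, i] = fn(seqs[i], seqs[j])
        return DistanceMatrix(tuple(ids), M)

    singles = [lz_complexity(s) for s in seqs]
    n = len(seqs)
    M = np.zeros((n, n))
    for i in range(n):
        a = seqs[i].bases
        for j in range(i + 1, n):
            b = seqs[j].bases
            c12 = _complexity(a + b)
            c21 = _complexity(b + a)
            d = ((c12 - singles[i]) + (c21 - singles[j])) / (0.5 * (c12 + c21))
            M[i, j] = M[j, i] = d
    return DistanceMatrix(tuple(ids), M)
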