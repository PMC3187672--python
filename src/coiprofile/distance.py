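"""Kimura two-parameter divergences and the pairwise distance matrix.

Transitions are A<->G and C<->T; every other nucleotide mismatch is a
transversion.  Gaps, N and IUPAC ambiguity codes are treated as missing and
skipped per pair (pairwise deletion, the default) or assumed absent
(complete-mask mode).  Distances are proportions internally; report layers
convert to percent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np

from .seqio import AlignedSeqSet

# Base encoding: A=0, C=1, G=2, T=3; anything else (gap/N/ambiguity) = 4.
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i
_CODE[ord("U")] = 3  # RNA alphabet tolerated


class NoComparableSitesError(ValueError):
    """All columns of a pair were removed by deletion handling."""


class SaturationError(ValueError):
    """K2P distance undefined: a logarithm argument is non-positive."""

    def __init__(self, P: float, Q: float):
        super().__init__(
            f"K2P saturated: P={P:.6g}, Q={Q:.6g} "
            f"(1-2P-Q={1 - 2 * P - Q:.6g}, 1-2Q={1 - 2 * Q:.6g})"
        )
        self.P = P
        self.Q = Q


@dataclass(frozen=True)
class PairCounts:
    """Observed site counts for one sequence pair."""

    n: int
    transitions: int
    transversions: int

    @property
    def P(self) -> float:
        return self.transitions / self.n if self.n else 0.0

    @property
    def Q(self) -> float:
        return self.transversions / self.n if self.n else 0.0


def encode(sequence: str) -> np.ndarray:
    """Encode a nucleotide string as int8 (A=0,C=1,G=2,T=3, missing=4)."""
    return _CODE[np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)]


def _pair_counts_encoded(
    x: np.ndarray, y: np.ndarray, deletion: str
) -> PairCounts:
    if deletion == "pairwise":
        valid = (x < 4) & (y < 4)
    elif deletion == "complete-mask":
        if (x >= 4).any() or (y >= 4).any():
            raise ValueError(
                "complete-mask mode assumes gap/ambiguity columns were "
                "already removed set-wide, but missing characters remain"
            )
        valid = np.ones(x.shape, dtype=bool)
    else:
        raise ValueError(f"unknown deletion mode {deletion!r}")
    n = int(valid.sum())
    if n == 0:
        raise NoComparableSitesError("no comparable sites after deletion")
    diff = valid & (x != y)
    s = x + y
    # A+G = 2 and C+T = 4 are the only mismatch sums for transitions.
    ts = diff & ((s == 2) | (s == 4))
    n_ts = int(ts.sum())
    n_tv = int(diff.sum()) - n_ts
    return PairCounts(n=n, transitions=n_ts, transversions=n_tv)


def pair_counts(seq_a: str, seq_b: str, deletion: str = "pairwise") -> PairCounts:
    """Classify the sites of an aligned pair into transitions/transversions."""
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal aligned length")
    return _pair_counts_encoded(
        encode(seq_a.upper()), encode(seq_b.upper()), deletion
    )


def k2p(P: float, Q: float) -> float:
    """Kimura two-parameter distance d = -ln(1-2P-Q)/2 - ln(1-2Q)/4.

    Raises :class:`SaturationError` (carrying P and Q) when either
    logarithm argument is non-positive.
    """
    w1 = 1.0 - 2.0 * P - Q
    w2 = 1.0 - 2.0 * Q
    if w1 <= 0.0 or w2 <= 0.0:
        raise SaturationError(P, Q)
    return -0.5 * math.log(w1) - 0.25 * math.log(w2)


class DistanceMatrix:
    """Symmetric matrix of K2P divergences (proportions).

    Undefined (saturated or incomparable) entries are explicitly masked via
    ``defined`` and stored as NaN — never silently zeroed.
    """

    def __init__(
        self,
        ids: list[str],
        values: np.ndarray,
        defined: np.ndarray | None = None,
    ):
        n = len(ids)
        values = np.asarray(values, dtype=float)
        if values.shape != (n, n):
            raise ValueError("values shape must match number of ids")
        if defined is None:
            defined = ~np.isnan(values)
        defined = np.asarray(defined, dtype=bool)
        if not np.array_equal(values, values.T, equal_nan=True):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(values), 0.0):
            raise ValueError("diagonal must be zero")
        with np.errstate(invalid="ignore"):
            if (values[defined] < 0).any():
                raise ValueError("distances must be non-negative")
        self.ids = list(ids)
        self.values = values
        self.defined = defined
        self._pos = {sid: i for i, sid in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def get(self, a: str, b: str) -> float:
        """Distance between two specimens; NaN if undefined."""
        return float(self.values[self._pos[a], self._pos[b]])

    def is_defined(self, a: str, b: str) -> bool:
        return bool(self.defined[self._pos[a], self._pos[b]])

    def n_pairs(self) -> int:
        n = len(self.ids)
        return n * (n - 1) // 2

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        for i in range(len(self.ids)):
            for j in range(i + 1, len(self.ids)):
                if not self.defined[i, j]:
                    out.append((self.ids[i], self.ids[j]))
        return out

    def iter_pairs(self) -> Iterator[tuple[str, str, float, bool]]:
        """Yield (id_i, id_j, value, defined) for every unordered pair."""
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                yield (
                    self.ids[i],
                    self.ids[j],
                    float(self.values[i, j]),
                    bool(self.defined[i, j]),
                )

    def submatrix(self, ids: Iterable[str]) -> "DistanceMatrix":
        idx = [self._pos[i] for i in ids]
        return DistanceMatrix(
            [self.ids[i] for i in idx],
            self.values[np.ix_(idx, idx)],
            self.defined[np.ix_(idx, idx)],
        )

    # ------------------------------------------------------------------ I/O

    def to_tsv(self, path: str | Path) -> None:
        """Square TSV with a header row/column of ids; undefined as 'NA'."""
        with open(path, "w") as fh:
            fh.write("\t".join([""] + self.ids) + "\n")
            for i, sid in enumerate(self.ids):
                cells = [
                    repr(float(self.values[i, j])) if self.defined[i, j] or i == j
                    else "NA"
                    for j in range(len(self.ids))
                ]
                fh.write("\t".join([sid] + cells) + "\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "DistanceMatrix":
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")[1:]
            n = len(header)
            values = np.zeros((n, n))
            defined = np.ones((n, n), dtype=bool)
            for i, line in enumerate(fh):
                cells = line.rstrip("\n").split("\t")
                for j, cell in enumerate(cells[1:]):
                    if cell == "NA":
                        values[i, j] = np.nan
                        defined[i, j] = False
                    else:
                        values[i, j] = float(cell)
        return cls(header, values, defined)

    def to_phylip(self, path: str | Path) -> None:
        """Lower-triangle PHYLIP-style distance format."""
        with open(path, "w") as fh:
            fh.write(f"{len(self.ids)}\n")
            for i, sid in enumerate(self.ids):
                cells = [
                    f"{self.values[i, j]:.6f}" if self.defined[i, j] else "NA"
                    for j in range(i)
                ]
                fh.write("\t".join([sid] + cells).rstrip("\t") + "\n")


def distance_matrix(
    aln: AlignedSeqSet, deletion: str = "pairwise"
) -> DistanceMatrix:
    """Compute the full pairwise K2P matrix of an alignment.

    Per-pair saturation or lack of comparable sites is recorded as a masked
    undefined entry; counts are exposed on the returned matrix as
    ``n_saturated`` and ``n_no_sites``.
    """
    records = list(aln)
    n = len(records)
    encoded = [encode(r.sequence) for r in records]
    values = np.zeros((n, n))
    defined = np.ones((n, n), dtype=bool)
    n_saturated = 0
    n_no_sites = 0
    for i in range(n):
        for j in range(i + 1, n):
            try:
                pc = _pair_counts_encoded(encoded[i], encoded[j], deletion)
                d = k2p(pc.P, pc.Q)
            except SaturationError:
                values[i, j] = values[j, i] = np.nan
                defined[i, j] = defined[j, i] = False
                n_saturated += 1
                continue
            except NoComparableSitesError:
                values[i, j] = values[j, i] = np.nan
                defined[i, j] = defined[j, i] = False
                n_no_sites += 1
                continue
            values[i, j] = values[j, i] = d
    dm = DistanceMatrix([r.specimen_id for r in records], values, defined)
    dm.n_saturated = n_saturated
    dm.n_no_sites = n_no_sites
    return dm
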