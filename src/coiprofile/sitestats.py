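"""Alignment-level site classification and base-composition means.

Within a column, gap/N/ambiguity cells are ignored; a column with fewer
than two unambiguous cells is excluded from the constant/variable tally and
counted separately.  Composition is the arithmetic mean of per-sequence
frequencies over each sequence's own unambiguous bases.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .distance import encode
from .seqio import AlignedSeqSet


@dataclass(frozen=True)
class SiteClassCounts:
    constant: int
    variable: int
    parsimony_informative: int
    singleton: int
    excluded: int  # columns with < 2 unambiguous cells

    def __post_init__(self) -> None:
        assert self.variable == self.parsimony_informative + self.singleton


@dataclass(frozen=True)
class CompositionMeans:
    """Mean across sequences of per-sequence base frequencies (proportions)."""

    A: float
    C: float
    G: float
    T: float


def classify_sites(
    aln: AlignedSeqSet, scope: list[str] | None = None
) -> SiteClassCounts:
    """Classify columns as constant / parsimony-informative / singleton.

    A column is constant iff exactly one unambiguous state occurs;
    parsimony-informative iff at least two states each occur in at least two
    sequences; singleton otherwise (variable but not informative).
    """
    ids = scope if scope is not None else aln.ids
    if len(ids) < 2:
        raise ValueError("site classification needs >=2 sequences in scope")
    mat = np.stack([encode(aln[i].sequence) for i in ids])  # (nseq, ncol)
    n_col = mat.shape[1]
    constant = variable = informative = singleton = excluded = 0
    for col in range(n_col):
        column = mat[:, col]
        counts = np.bincount(column[column < 4], minlength=4)
        present = counts[counts > 0]
        if present.sum() < 2:
            excluded += 1
            continue
        if present.size == 1:
            constant += 1
        else:
            variable += 1
            if (present >= 2).sum() >= 2:
                informative += 1
            else:
                singleton += 1
    return SiteClassCounts(
        constant=constant,
        variable=variable,
        parsimony_informative=informative,
        singleton=singleton,
        excluded=excluded,
    )


def composition_means(
    aln: AlignedSeqSet, scope: list[str] | None = None
) -> CompositionMeans:
    """Mean of per-sequence A/C/G/T frequencies over unambiguous bases.

    Sequences with no unambiguous base are excluded with a warning.
    """
    ids = scope if scope is not None else aln.ids
    freqs: list[np.ndarray] = []
    for sid in ids:
        counts = np.bincount(
            encode(aln[sid].sequence), minlength=5
        )[:4].astype(float)
        total = counts.sum()
        if total == 0:
            warnings.warn(
                f"sequence {sid!r} has no unambiguous base; "
                "excluded from composition means",
                stacklevel=2,
            )
            continue
        freqs.append(counts / total)
    if not freqs:
        raise ValueError("no sequence with unambiguous bases in scope")
    mean = np.mean(freqs, axis=0)
    return CompositionMeans(
        A=float(mean[0]), C=float(mean[1]), G=float(mean[2]), T=float(mean[3])
    )


def write_sitestats_tsv(
    path: str | Path,
    rows: dict[str, tuple[SiteClassCounts, CompositionMeans]],
) -> None:
    """One row per scope label (e.g. 'all', 'ingroup')."""
    with open(path, "w") as fh:
        fh.write(
            "scope\tconstant\tvariable\tparsimony_informative\tsingleton\t"
            "excluded\tmean_A_pct\tmean_C_pct\tmean_G_pct\tmean_T_pct\n"
        )
        for label, (sc, cm) in rows.items():
            fh.write(
                f"{label}\t{sc.constant}\t{sc.variable}\t"
                f"{sc.parsimony_informative}\t{sc.singleton}\t{sc.excluded}\t"
                f"{cm.A * 100:.2f}\t{cm.C * 100:.2f}\t"
                f"{cm.G * 100:.2f}\t{cm.T * 100:.2f}\n"
            )
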