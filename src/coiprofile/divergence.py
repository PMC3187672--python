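"""Intraspecific vs interspecific divergence summaries and histograms.

Summaries report percent (proportion x 100).  The sample SD uses an n-1
denominator over pairwise divergences and is undefined (None, printed '/')
when fewer than two pairs exist.  Species with a single individual are
omitted from the intraspecific table and listed in the skipped log; groups
with a single species are likewise omitted from the interspecific table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np

from .distance import DistanceMatrix
from .seqio import TaxonMap


@dataclass(frozen=True)
class DivergenceSummary:
    """One row of a Table-1/Table-2 style summary (values in percent)."""

    taxon: str
    n_individuals: int
    n_pairs: int
    mean: float
    range_min: float
    range_max: float
    sd: float | None  # None when < 2 pairs

    def format_row(self) -> list[str]:
        return [
            self.taxon,
            str(self.n_individuals),
            str(self.n_pairs),
            format_percent(self.mean),
            f"{format_percent(self.range_min)}-{format_percent(self.range_max)}",
            format_percent(self.sd) if self.sd is not None else "/",
        ]


@dataclass(frozen=True)
class SummaryTable:
    rows: list[DivergenceSummary]
    overall: DivergenceSummary | None
    skipped: list[str]  # taxa omitted (too few members), for the run log
    n_undefined: int  # saturated/undefined pairs excluded from the stats

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("taxon\tn\tn_pairs\tmean_pct\trange_pct\tsd_pct\n")
            for row in self.rows:
                fh.write("\t".join(row.format_row()) + "\n")
            if self.overall is not None:
                fh.write("\t".join(self.overall.format_row()) + "\n")


def format_percent(value: float) -> str:
    """Two decimals, half-up rounding — matches published table style."""
    return str(
        Decimal(repr(float(value))).quantize(
            Decimal("0.01"), rounding=ROUND_HALF_UP
        )
    )


def _summarize(taxon: str, n_individuals: int, pct: list[float]) -> DivergenceSummary:
    arr = np.asarray(pct, dtype=float)
    sd = float(np.std(arr, ddof=1)) if arr.size >= 2 else None
    return DivergenceSummary(
        taxon=taxon,
        n_individuals=n_individuals,
        n_pairs=arr.size,
        mean=float(arr.mean()),
        range_min=float(arr.min()),
        range_max=float(arr.max()),
        sd=sd,
    )


def _pair_values(
    dm: DistanceMatrix, ids_a: list[str], ids_b: list[str] | None = None
) -> tuple[list[float], int]:
    """Defined divergences (percent) for pairs within ids_a, or across sets.

    Returns (values, n_undefined).
    """
    values: list[float] = []
    n_undef = 0
    if ids_b is None:
        for i, a in enumerate(ids_a):
            for b in ids_a[i + 1 :]:
                if dm.is_defined(a, b):
                    values.append(dm.get(a, b) * 100.0)
                else:
                    n_undef += 1
    else:
        for a in ids_a:
            for b in ids_b:
                if dm.is_defined(a, b):
                    values.append(dm.get(a, b) * 100.0)
                else:
                    n_undef += 1
    return values, n_undef


def intraspecific_summary(
    dm: DistanceMatrix, tax: TaxonMap, ingroup_only: bool = True
) -> SummaryTable:
    """Per-species conspecific divergence rows plus a pooled overall row.

    The overall row pools every conspecific pair across species, so its
    mean is the pair-count-weighted mean of the per-species means.
    """
    members = tax.species_members(dm.ids, ingroup_only=ingroup_only)
    rows: list[DivergenceSummary] = []
    skipped: list[str] = []
    pooled: list[float] = []
    pooled_individuals = 0
    n_undef_total = 0
    for species in sorted(members):
        ids = members[species]
        if len(ids) < 2:
            skipped.append(species)
            continue
        values, n_undef = _pair_values(dm, ids)
        n_undef_total += n_undef
        if not values:
            skipped.append(species)
            continue
        rows.append(_summarize(species, len(ids), values))
        pooled.extend(values)
        pooled_individuals += len(ids)
    if not rows:
        raise ValueError("no species with >=2 comparable individuals")
    overall = _summarize("All", pooled_individuals, pooled)
    return SummaryTable(rows, overall, skipped, n_undef_total)


def interspecific_summary(
    dm: DistanceMatrix,
    tax: TaxonMap,
    mode: str = "representative",
    seed: int = 0,
    ingroup_only: bool = True,
) -> SummaryTable:
    """Per-group between-species divergence rows plus a pooled overall row.

    ``representative`` mode picks one seeded-random specimen per species and
    compares representatives; ``all-pairs`` compares every cross-species
    individual pair within each group.
    """
    if mode not in ("representative", "all-pairs"):
        raise ValueError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    groups = tax.group_species(dm.ids, ingroup_only=ingroup_only)
    rows: list[DivergenceSummary] = []
    skipped: list[str] = []
    pooled: list[float] = []
    pooled_species = 0
    n_undef_total = 0
    for group in sorted(groups):
        species_map = groups[group]
        species_names = sorted(species_map)
        if len(species_names) < 2:
            skipped.append(group)
            continue
        if mode == "representative":
            reps = {
                sp: sorted(species_map[sp])[
                    int(rng.integers(len(species_map[sp])))
                ]
                for sp in species_names
            }
            values, n_undef = _pair_values(dm, [reps[sp] for sp in species_names])
        else:
            values = []
            n_undef = 0
            for i, sp_a in enumerate(species_names):
                for sp_b in species_names[i + 1 :]:
                    vals, nu = _pair_values(
                        dm, species_map[sp_a], species_map[sp_b]
                    )
                    values.extend(vals)
                    n_undef += nu
        n_undef_total += n_undef
        if not values:
            skipped.append(group)
            continue
        rows.append(_summarize(group, len(species_names), values))
        pooled.extend(values)
        pooled_species += len(species_names)
    if not rows:
        raise ValueError("no group with >=2 comparable species")
    overall = _summarize("All", pooled_species, pooled)
    return SummaryTable(rows, overall, skipped, n_undef_total)


@dataclass(frozen=True)
class PooledStats:
    n_pairs: int
    n_excluded: int  # undefined pairs excluded from the statistics
    mean: float  # percent
    min: float
    max: float


def pooled_pair_stats(
    dm: DistanceMatrix, include: list[str] | None = None
) -> PooledStats:
    """Pooled mean/range over all unordered pairs of the included specimens."""
    ids = list(include) if include is not None else dm.ids
    if len(ids) < 2:
        raise ValueError("need >=2 included specimens")
    values, n_undef = _pair_values(dm, ids)
    m = len(ids)
    n_pairs = m * (m - 1) // 2
    arr = np.asarray(values)
    return PooledStats(
        n_pairs=n_pairs,
        n_excluded=n_undef,
        mean=float(arr.mean()),
        min=float(arr.min()),
        max=float(arr.max()),
    )


@dataclass(frozen=True)
class HistogramSpec:
    bin_width: float = 0.5  # percent


@dataclass(frozen=True)
class Histogram:
    bin_width: float
    #: parallel lists; bin i covers [i*w, (i+1)*w)
    intra_counts: list[int]
    inter_counts: list[int]

    @property
    def n_bins(self) -> int:
        return len(self.intra_counts)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("bin_lo_pct\tbin_hi_pct\tintra_count\tinter_count\n")
            for i in range(self.n_bins):
                lo = i * self.bin_width
                hi = (i + 1) * self.bin_width
                fh.write(
                    f"{lo:g}\t{hi:g}\t{self.intra_counts[i]}\t"
                    f"{self.inter_counts[i]}\n"
                )


def divergence_histogram(
    intra: list[float],
    inter: list[float],
    spec: HistogramSpec = HistogramSpec(),
) -> Histogram:
    """Bin intra- and interspecific divergences (percent) into half-open bins."""
    if spec.bin_width <= 0:
        raise ValueError("bin_width must be positive")
    for series in (intra, inter):
        for v in series:
            if v < 0:
                raise ValueError(f"negative divergence {v} (upstream invariant breach)")
    top = max(intra + inter, default=0.0)
    n_bins = max(1, math.floor(top / spec.bin_width) + 1)
    intra_counts = [0] * n_bins
    inter_counts = [0] * n_bins
    for v in intra:
        intra_counts[min(int(v // spec.bin_width), n_bins - 1)] += 1
    for v in inter:
        inter_counts[min(int(v // spec.bin_width), n_bins - 1)] += 1
    return Histogram(spec.bin_width, intra_counts, inter_counts)


def labeled_pairs(
    dm: DistanceMatrix, tax: TaxonMap, ingroup_only: bool = True
) -> tuple[list[float], list[float], list[float]]:
    """Split defined pair divergences (percent) into three labeled series:
    conspecific, heterospecific-within-group, and cross-group."""
    intra: list[float] = []
    inter: list[float] = []
    cross: list[float] = []
    for a, b, value, defined in dm.iter_pairs():
        if a not in tax or b not in tax:
            continue
        if ingroup_only and not (tax.is_ingroup(a) and tax.is_ingroup(b)):
            continue
        if not defined:
            continue
        pct = value * 100.0
        if tax.species_of(a) == tax.species_of(b):
            intra.append(pct)
        elif tax.group_of(a) == tax.group_of(b):
            inter.append(pct)
        else:
            cross.append(pct)
    return intra, inter, cross
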