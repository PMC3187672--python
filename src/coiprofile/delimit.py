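"""Tree- and distance-based species-delimitation diagnostics.

Cohesion is evaluated on the unrooted bipartition structure: a species is
cohesive iff its specimens form one side of some edge-induced split of the
tree (single specimens are cohesive by convention).  Distance-based flags
mark candidate splits (deep intraspecific divergence) and candidate merges
(shallow between-species divergence within a group); they never rename taxa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .distance import DistanceMatrix
from .njtree import Node, TreeError, UnrootedTree
from .seqio import TaxonMap

DEFAULT_SPLIT_THRESHOLD = 0.02
DEFAULT_MERGE_THRESHOLD = 0.015


@dataclass(frozen=True)
class CohesionEntry:
    species: str
    cohesive: bool
    n_individuals: int
    #: foreign leaves inside the best (smallest) split covering the species
    intruders: tuple[str, ...]


@dataclass(frozen=True)
class CohesionReport:
    entries: dict[str, CohesionEntry]

    def __getitem__(self, species: str) -> CohesionEntry:
        return self.entries[species]

    @property
    def n_cohesive(self) -> int:
        return sum(1 for e in self.entries.values() if e.cohesive)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("species\tcohesive\tn_individuals\tintruders\n")
            for sp in sorted(self.entries):
                e = self.entries[sp]
                fh.write(
                    f"{sp}\t{str(e.cohesive).lower()}\t{e.n_individuals}\t"
                    f"{','.join(e.intruders) if e.intruders else '-'}\n"
                )


def _species_leaf_sets(
    tree: UnrootedTree, tax: TaxonMap
) -> dict[str, frozenset[str]]:
    missing = [lf for lf in tree.leaf_nodes if lf not in tax]
    if missing:
        raise TreeError(
            "tree leaves without taxonomy entries: "
            + ", ".join(repr(m) for m in sorted(missing))
        )
    out: dict[str, set[str]] = {}
    for leaf in tree.leaf_nodes:
        out.setdefault(tax.species_of(leaf), set()).add(leaf)
    return {sp: frozenset(s) for sp, s in out.items()}


def cohesion_report(tree: UnrootedTree, tax: TaxonMap) -> CohesionReport:
    """Per-species cohesion (split-based monophyly) on the unrooted tree."""
    species_sets = _species_leaf_sets(tree, tax)
    sides = [side for sa, sb, _ in tree.edge_sides() for side in (sa, sb)]
    side_set = set(sides)
    entries: dict[str, CohesionEntry] = {}
    for species, leaves in species_sets.items():
        if len(leaves) == 1:
            entries[species] = CohesionEntry(species, True, 1, ())
            continue
        if leaves in side_set:
            entries[species] = CohesionEntry(species, True, len(leaves), ())
            continue
        covering = [s for s in sides if leaves <= s]
        best = min(covering, key=len)  # whole leaf set always covers
        intruders = tuple(sorted(best - leaves))
        entries[species] = CohesionEntry(species, False, len(leaves), intruders)
    return CohesionReport(entries)


def conspecific_clades(
    tree: UnrootedTree, tax: TaxonMap, species: str
) -> list[list[str]]:
    """Partition a species' specimens into maximal single-species clades.

    The tree is oriented away from the lexicographically smallest foreign
    leaf (deterministic); maximal pure rooted subtrees are reported, sorted
    by their smallest member.  A species covering every leaf is one clade.
    """
    species_sets = _species_leaf_sets(tree, tax)
    if species not in species_sets:
        raise TreeError(f"unknown species {species!r}")
    target = species_sets[species]
    foreign = sorted(set(tree.leaf_nodes) - target)
    if not foreign:
        return [sorted(target)]
    root = tree.leaf_nodes[foreign[0]]

    clades: list[list[str]] = []

    def walk(node: Node, parent: Node) -> frozenset[str] | None:
        """Return this subtree's leaf set if pure-target, else None
        (emitting maximal pure children along the way)."""
        if node.is_leaf and node.label is not None:
            return frozenset((node.label,)) if node.label in target else None
        children = [nb for nb in node.neighbors if nb is not parent]
        results = [walk(c, node) for c in children]
        if all(r is not None for r in results):
            return frozenset().union(*results)
        for r in results:
            if r is not None:
                clades.append(sorted(r))
        return None

    # The root-adjacent node's children are the top-level clade candidates;
    # the all-but-root side itself never counts as a single clade.
    start = next(iter(root.neighbors))
    if start.is_leaf:
        if start.label in target:  # pragma: no cover - two-leaf corner
            clades.append([start.label])
    else:
        for child in (nb for nb in start.neighbors if nb is not root):
            res = walk(child, start)
            if res is not None:
                clades.append(sorted(res))
    return sorted(clades, key=lambda c: c[0])


@dataclass(frozen=True)
class DeepSplitFlag:
    species: str
    max_intra: float  # proportion
    n_individuals: int


@dataclass(frozen=True)
class LowDivergencePairFlag:
    species_a: str
    species_b: str
    group: str
    mean_between: float  # proportion


@dataclass(frozen=True)
class MisplacedFlag:
    species: str
    assigned_group: str
    neighbor_groups: tuple[str, ...]


@dataclass(frozen=True)
class DelimitFlags:
    deep_intraspecific: list[DeepSplitFlag] = field(default_factory=list)
    low_interspecific: list[LowDivergencePairFlag] = field(default_factory=list)
    misplaced: list[MisplacedFlag] = field(default_factory=list)

    def write_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("flag\ttaxa\tgroup\tstatistic_pct\n")
            for f in self.deep_intraspecific:
                fh.write(
                    f"deep_intraspecific\t{f.species}\t-\t"
                    f"{f.max_intra * 100:.2f}\n"
                )
            for p in self.low_interspecific:
                fh.write(
                    f"low_interspecific\t{p.species_a}|{p.species_b}\t"
                    f"{p.group}\t{p.mean_between * 100:.2f}\n"
                )
            for m in self.misplaced:
                fh.write(
                    f"misplaced\t{m.species}\t{m.assigned_group}->"
                    f"{','.join(m.neighbor_groups)}\t-\n"
                )


def flag_candidates(
    dm: DistanceMatrix,
    tax: TaxonMap,
    split_threshold: float = DEFAULT_SPLIT_THRESHOLD,
    merge_threshold: float = DEFAULT_MERGE_THRESHOLD,
    tree: UnrootedTree | None = None,
    ingroup_only: bool = True,
) -> DelimitFlags:
    """Distance-threshold delimitation flags (thresholds are proportions).

    ``deep_intraspecific``: species whose maximum conspecific divergence is
    >= split_threshold.  ``low_interspecific``: same-group species pairs
    whose mean between-species divergence is <= merge_threshold.
    ``misplaced`` (only when a tree is supplied): cohesive species whose
    nearest split-neighbors all belong to a different declared group.
    """
    if split_threshold <= 0 or merge_threshold <= 0:
        raise ValueError("thresholds must be positive")
    if split_threshold <= merge_threshold:
        raise ValueError("split_threshold must exceed merge_threshold")

    members = tax.species_members(dm.ids, ingroup_only=ingroup_only)
    deep: list[DeepSplitFlag] = []
    for species in sorted(members):
        ids = members[species]
        if len(ids) < 2:
            continue
        values = [
            dm.get(a, b)
            for i, a in enumerate(ids)
            for b in ids[i + 1 :]
            if dm.is_defined(a, b)
        ]
        if values and max(values) >= split_threshold:
            deep.append(DeepSplitFlag(species, max(values), len(ids)))

    low: list[LowDivergencePairFlag] = []
    groups = tax.group_species(dm.ids, ingroup_only=ingroup_only)
    for group in sorted(groups):
        species_names = sorted(groups[group])
        for i, sp_a in enumerate(species_names):
            for sp_b in species_names[i + 1 :]:
                values = [
                    dm.get(a, b)
                    for a in groups[group][sp_a]
                    for b in groups[group][sp_b]
                    if dm.is_defined(a, b)
                ]
                if values and float(np.mean(values)) <= merge_threshold:
                    low.append(
                        LowDivergencePairFlag(
                            sp_a, sp_b, group, float(np.mean(values))
                        )
                    )

    misplaced: list[MisplacedFlag] = []
    if tree is not None:
        report = cohesion_report(tree, tax)
        species_sets = _species_leaf_sets(tree, tax)
        sides = [s for sa, sb, _ in tree.edge_sides() for s in (sa, sb)]
        all_leaves = frozenset(tree.leaf_nodes)
        for species, leaves in sorted(species_sets.items()):
            if not report[species].cohesive:
                continue
            own_group = tax.group_of(next(iter(leaves)))
            # a species alone in its declared group has nothing to be
            # misplaced relative to
            own_group_others = {
                lf
                for lf in all_leaves - leaves
                if tax.group_of(lf) == own_group
            }
            if not own_group_others:
                continue
            strict = [s for s in sides if leaves < s]
            if not strict:
                continue
            best = min(strict, key=lambda s: (len(s), tuple(sorted(s))))
            neighbors = best - leaves
            neighbor_groups = sorted({tax.group_of(lf) for lf in neighbors})
            if neighbors and own_group not in neighbor_groups:
                misplaced.append(
                    MisplacedFlag(species, own_group, tuple(neighbor_groups))
                )
    return DelimitFlags(deep, low, misplaced)
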