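"""Shared fixtures and independent oracle helpers.

The tree oracle here builds random additive trees by direct agglomeration
and tracks path lengths and splits itself — it never touches the package's
NJ or tree code, so it can serve as an independent reference.
"""

from __future__ import annotations

import numpy as np
import pytest

from coiprofile.distance import DistanceMatrix
from coiprofile.seqio import AlignedSeqSet, SequenceRecord, TaxonInfo, TaxonMap


def make_aln(pairs: list[tuple[str, str]]) -> AlignedSeqSet:
    return AlignedSeqSet([SequenceRecord(i, s) for i, s in pairs])


def make_tax(rows: list[tuple[str, str, str, bool]]) -> TaxonMap:
    return TaxonMap(
        {sid: TaxonInfo(sp, grp, ing) for sid, sp, grp, ing in rows}
    )


def canonical_split(side: frozenset[str], all_leaves: frozenset[str]) -> frozenset[str]:
    ref = min(all_leaves)
    return all_leaves - side if ref in side else side


def random_tree_oracle(
    names: list[str],
    rng: np.random.Generator,
    lo: float = 0.05,
    hi: float = 1.0,
):
    """Random additive tree by agglomeration, tracked independently.

    Returns (pair_distances: dict[frozenset[{a,b}], float],
             split_lengths: dict[canonical frozenset, float]) where
    split_lengths covers every edge, leaf edges included.
    """
    all_leaves = frozenset(names)
    clusters = [
        {"leaves": frozenset([n]), "dists": {n: 0.0}} for n in names
    ]
    pair_d: dict[frozenset, float] = {}
    split_len: dict[frozenset, float] = {}

    def cross(ca, cb, extra_a, extra_b):
        for x, dx in ca["dists"].items():
            for y, dy in cb["dists"].items():
                pair_d[frozenset((x, y))] = dx + extra_a + dy + extra_b

    while len(clusters) > 2:
        i, j = sorted(rng.choice(len(clusters), 2, replace=False))
        cb = clusters.pop(int(j))
        ca = clusters.pop(int(i))
        ba, bb = rng.uniform(lo, hi, 2)
        cross(ca, cb, ba, bb)
        split_len[canonical_split(ca["leaves"], all_leaves)] = float(ba)
        split_len[canonical_split(cb["leaves"], all_leaves)] = float(bb)
        merged = {
            "leaves": ca["leaves"] | cb["leaves"],
            "dists": {
                **{x: d + ba for x, d in ca["dists"].items()},
                **{y: d + bb for y, d in cb["dists"].items()},
            },
        }
        clusters.append(merged)
    ca, cb = clusters
    b = float(rng.uniform(lo, hi))
    cross(ca, cb, b, 0.0)
    split_len[canonical_split(ca["leaves"], all_leaves)] = b
    return pair_d, split_len


def matrix_from_pairs(names: list[str], pair_d: dict[frozenset, float]) -> DistanceMatrix:
    n = len(names)
    values = np.zeros((n, n))
    for i, a in enumerate(names):
        for j in range(i + 1, n):
            d = pair_d[frozenset((a, names[j]))]
            values[i, j] = values[j, i] = d
    return DistanceMatrix(names, values)


@pytest.fixture(scope="session")
def default_sim():
    """One default simulation + its distance matrix, shared across tests."""
    from coiprofile.distance import distance_matrix
    from coiprofile.simulate import SimulationConfig, simulate

    result = simulate(SimulationConfig(seed=42))
    dm = distance_matrix(result.alignment)
    return result, dm
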