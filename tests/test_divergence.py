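import numpy as np
import pytest

from coiprofile.distance import DistanceMatrix
from coiprofile.divergence import (
    HistogramSpec,
    divergence_histogram,
    format_percent,
    interspecific_summary,
    intraspecific_summary,
    labeled_pairs,
    pooled_pair_stats,
)

from conftest import make_tax


def matrix(ids, entries):
    n = len(ids)
    values = np.zeros((n, n))
    pos = {x: i for i, x in enumerate(ids)}
    for (a, b), d in entries.items():
        values[pos[a], pos[b]] = values[pos[b], pos[a]] = d
    return DistanceMatrix(ids, values)


@pytest.fixture
def two_species():
    ids = ["a1", "a2", "a3", "b1", "b2"]
    entries = {
        ("a1", "a2"): 0.0,
        ("a1", "a3"): 0.0001,
        ("a2", "a3"): 0.0002,
        ("b1", "b2"): 0.001,
    }
    for a in ("a1", "a2", "a3"):
        for b in ("b1", "b2"):
            entries[(a, b)] = 0.05
    dm = matrix(ids, entries)
    tax = make_tax(
        [(i, "A", "G1", True) for i in ("a1", "a2", "a3")]
        + [(i, "B", "G1", True) for i in ("b1", "b2")]
    )
    return dm, tax


class TestIntraspecificSummary:
    def test_three_value_arithmetic(self, two_species):
        dm, tax = two_species
        table = intraspecific_summary(dm, tax)
        row = next(r for r in table.rows if r.taxon == "A")
        assert row.n_individuals == 3
        assert row.n_pairs == 3
        assert row.mean == pytest.approx(0.01)
        assert row.range_min == pytest.approx(0.0)
        assert row.range_max == pytest.approx(0.02)
        assert format_percent(row.sd) == "0.01"

    def test_single_pair_sd_undefined(self):
        dm = matrix(["x1", "x2"], {("x1", "x2"): 0.0})
        tax = make_tax([("x1", "X", "G", True), ("x2", "X", "G", True)])
        table = intraspecific_summary(dm, tax)
        row = table.rows[0]
        assert row.mean == 0.0
        assert row.sd is None
        assert row.format_row()[-1] == "/"

    def test_pooled_mean_is_pair_weighted(self):
        rng = np.random.default_rng(0)
        ids, entries, rows = [], {}, []
        for s, n in (("A", 3), ("B", 5), ("C", 2)):
            members = [f"{s.lower()}{k}" for k in range(n)]
            ids.extend(members)
            rows.extend((m, s, "G", True) for m in members)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                entries[(a, b)] = float(rng.uniform(0, 0.05))
        table = intraspecific_summary(matrix(ids, entries), make_tax(rows))
        weighted = sum(r.mean * r.n_pairs for r in table.rows) / sum(
            r.n_pairs for r in table.rows
        )
        assert table.overall.mean == pytest.approx(weighted)
        assert table.overall.n_pairs == sum(r.n_pairs for r in table.rows)

    def test_singleton_species_skipped(self, two_species):
        dm, _ = two_species
        tax = make_tax(
            [(i, "A", "G1", True) for i in ("a1", "a2", "a3")]
            + [("b1", "B", "G1", True), ("b2", "C", "G1", True)]
        )
        table = intraspecific_summary(dm, tax)
        assert [r.taxon for r in table.rows] == ["A"]
        assert sorted(table.skipped) == ["B", "C"]

    def test_outgroup_excluded(self, two_species):
        dm, _ = two_species
        tax = make_tax(
            [(i, "A", "G1", True) for i in ("a1", "a2", "a3")]
            + [(i, "B", "G1", False) for i in ("b1", "b2")]
        )
        table = intraspecific_summary(dm, tax)
        assert [r.taxon for r in table.rows] == ["A"]


class TestInterspecificSummary:
    def test_two_singleton_species(self):
        dm = matrix(["a1", "b1"], {("a1", "b1"): 0.05})
        tax = make_tax([("a1", "A", "G", True), ("b1", "B", "G", True)])
        table = interspecific_summary(dm, tax)
        row = table.rows[0]
        assert row.mean == pytest.approx(5.0)
        assert row.range_min == row.range_max == pytest.approx(5.0)
        assert row.sd is None

    def test_three_representative_distances(self):
        ids = ["a1", "b1", "c1"]
        dm = matrix(
            ids,
            {("a1", "b1"): 0.03, ("a1", "c1"): 0.04, ("b1", "c1"): 0.05},
        )
        tax = make_tax([(i, i[0].upper(), "G", True) for i in ids])
        table = interspecific_summary(dm, tax)
        row = table.rows[0]
        assert row.mean == pytest.approx(4.0)
        assert row.range_min == pytest.approx(3.0)
        assert row.range_max == pytest.approx(5.0)

    def test_representative_mode_reproducible(self, two_species):
        dm, tax = two_species
        t1 = interspecific_summary(dm, tax, seed=7)
        t2 = interspecific_summary(dm, tax, seed=7)
        assert t1.rows == t2.rows

    def test_all_pairs_mode(self, two_species):
        dm, tax = two_species
        table = interspecific_summary(dm, tax, mode="all-pairs")
        row = table.rows[0]
        assert row.n_pairs == 6  # 3 A-individuals x 2 B-individuals
        assert row.mean == pytest.approx(5.0)

    def test_single_species_group_skipped(self):
        dm = matrix(
            ["a1", "b1", "c1"],
            {("a1", "b1"): 0.04, ("a1", "c1"): 0.05, ("b1", "c1"): 0.05},
        )
        tax = make_tax(
            [("a1", "A", "G1", True), ("b1", "B", "G1", True),
             ("c1", "C", "G2", True)]
        )
        table = interspecific_summary(dm, tax)
        assert [r.taxon for r in table.rows] == ["G1"]
        assert table.skipped == ["G2"]

    def test_unknown_mode(self, two_species):
        dm, tax = two_species
        with pytest.raises(ValueError, match="mode"):
            interspecific_summary(dm, tax, mode="bogus")

    def test_representative_converges_to_species_mean(self):
        """Averaging representative means over many seeds approaches the
        all-pairs species-level mean (Monte-Carlo property)."""
        rng = np.random.default_rng(1)
        ids, rows, entries = [], [], {}
        for s, n in (("A", 3), ("B", 4)):
            members = [f"{s.lower()}{k}" for k in range(n)]
            ids.extend(members)
            rows.extend((m, s, "G", True) for m in members)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                same = a[0] == b[0]
                entries[(a, b)] = float(
                    rng.uniform(0, 0.005) if same else rng.uniform(0.03, 0.06)
                )
        dm, tax = matrix(ids, entries), make_tax(rows)
        rep_means = [
            interspecific_summary(dm, tax, seed=s).overall.mean
            for s in range(100)
        ]
        allpairs = interspecific_summary(dm, tax, mode="all-pairs").overall.mean
        assert np.mean(rep_means) == pytest.approx(allpairs, abs=0.3)


class TestPooledPairStats:
    def test_known_pair_counts(self):
        # 198 -> 19,503 and 173 -> 14,878 unordered pairs
        assert 198 * 197 // 2 == 19503
        assert 173 * 172 // 2 == 14878

    def test_minimal(self):
        dm = matrix(["a", "b"], {("a", "b"): 0.0})
        st = pooled_pair_stats(dm)
        assert (st.n_pairs, st.mean, st.min, st.max) == (1, 0.0, 0.0, 0.0)

    def test_include_filter(self, two_species):
        dm, _ = two_species
        st = pooled_pair_stats(dm, include=["a1", "a2", "a3"])
        assert st.n_pairs == 3
        assert st.max == pytest.approx(0.02)

    def test_too_few(self, two_species):
        dm, _ = two_species
        with pytest.raises(ValueError):
            pooled_pair_stats(dm, include=["a1"])

    def test_undefined_excluded_and_counted(self):
        values = np.array(
            [[0.0, 0.01, np.nan], [0.01, 0.0, 0.02], [np.nan, 0.02, 0.0]]
        )
        dm = DistanceMatrix(["a", "b", "c"], values)
        st = pooled_pair_stats(dm)
        assert st.n_pairs == 3
        assert st.n_excluded == 1
        assert st.mean == pytest.approx(1.5)


class TestHistogram:
    def test_example_bins(self):
        hist = divergence_histogram([0.1, 0.3], [5.2], HistogramSpec(0.5))
        assert hist.intra_counts[0] == 2
        assert hist.inter_counts[10] == 1
        assert sum(hist.intra_counts) == 2
        assert sum(hist.inter_counts) == 1

    def test_empty_inter(self):
        hist = divergence_histogram([0.1], [], HistogramSpec(0.5))
        assert sum(hist.inter_counts) == 0

    def test_conservation(self):
        rng = np.random.default_rng(2)
        intra = list(rng.uniform(0, 1, 37))
        inter = list(rng.uniform(3, 9, 53))
        hist = divergence_histogram(intra, inter)
        assert sum(hist.intra_counts) == 37
        assert sum(hist.inter_counts) == 53

    def test_half_open_boundary(self):
        hist = divergence_histogram([0.5], [], HistogramSpec(0.5))
        assert hist.intra_counts[0] == 0
        assert hist.intra_counts[1] == 1

    def test_negative_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            divergence_histogram([-0.1], [])

    def test_bad_width(self):
        with pytest.raises(ValueError, match="bin_width"):
            divergence_histogram([0.1], [], HistogramSpec(0.0))


class TestLabeledPairsConservation:
    def test_partition_covers_all_ingroup_pairs(self, default_sim):
        result, dm = default_sim
        intra, inter, cross = labeled_pairs(dm, result.taxonomy)
        m = len(dm.ids)
        assert len(intra) + len(inter) + len(cross) == m * (m - 1) // 2

    def test_barcode_gap_on_synthetic(self, default_sim):
        result, dm = default_sim
        intra, inter, cross = labeled_pairs(dm, result.taxonomy)
        assert max(intra) < min(inter + cross)


class TestFormatting:
    @pytest.mark.parametrize(
        "value,expected",
        [(0.005, "0.01"), (0.004999, "0.00"), (5.0, "5.00"), (2.675, "2.68")],
    )
    def test_half_up_two_decimals(self, value, expected):
        assert format_percent(value) == expected
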