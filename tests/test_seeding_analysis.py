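"""Seeding annotation, capacity Monte Carlo, duration in situ, cavity
structure and SCNA burden."""

import math

import numpy as np
import pytest

from cloneseed import CloneTree, MutationCluster, monte_carlo_capacity_test
from cloneseed.cohort_model import Segment
from cloneseed.migration_inference import MigrationHistory
from cloneseed.seeding_analysis import (
    _breakpoint_count,
    annotate_seeding,
    cavity_summary,
    duration_in_situ,
    scna_burden_comparison,
    sufficiency_threshold,
)


def history(migrations, seeded_by=None):
    h = MigrationHistory(
        model="multi_source", feasible=True, migrations=migrations,
        n_migrations=len(migrations),
        n_comigrations=len({(a, b) for a, b, _ in migrations}),
    )
    h.seeded_by = seeded_by or {}
    return h


def simple_tree():
    return CloneTree(
        nodes={"T", "A", "B", "C"},
        parent={"A": "T", "B": "A", "C": "T"},
    )


class TestAnnotateSeeding:
    def test_roles_and_flags(self):
        tree = simple_tree()
        h = history(
            [("P", "M1", "A"), ("M1", "M2", "B")],
            seeded_by={"M1": "primary", "M2": "metastasis"},
        )
        kinds = {"P": "primary", "M1": "metastasis", "M2": "metastasis"}
        ann = annotate_seeding(h, tree, "P", kinds)
        assert ann.cluster_role["A"] == "primary_to_met_seeder"
        assert ann.cluster_role["B"] == "met_to_met_seeder"
        assert ann.cluster_role["C"] == "non_seeding"
        assert ann.seeds_others["M1"] is True
        assert ann.seeds_others["M2"] is False
        assert ann.n_incoming == {"M1": 1, "M2": 1}

    def test_dual_source_target(self):
        tree = simple_tree()
        h = history(
            [("P", "M1", "A"), ("M2", "M1", "B")],
            seeded_by={"M1": "both"},
        )
        kinds = {"P": "primary", "M1": "metastasis", "M2": "metastasis"}
        ann = annotate_seeding(h, tree, "P", kinds)
        assert ann.seeded_by["M1"] == "both"
        assert ann.n_incoming["M1"] == 2


class TestCapacityMonteCarlo:
    def test_maximally_even_counts_give_p_one(self):
        for seed in (0, 1, 99):
            assert monte_carlo_capacity_test([2, 2, 1], reps=5000,
                                             seed=seed) == 1.0

    def test_even_split_any_k(self):
        assert monte_carlo_capacity_test([4, 4], reps=2000, seed=0) == 1.0
        assert monte_carlo_capacity_test([3, 3, 3, 3], reps=2000, seed=0) == 1.0

    def test_five_zero_matches_exact_enumeration(self):
        # P(all 5 in one of 2 cells) = 2 * (1/2)^5 = 0.0625
        p = monte_carlo_capacity_test([5, 0], reps=200_000, seed=1)
        assert p == pytest.approx(0.0625, abs=0.005)

    def test_single_subclone_undefined(self):
        assert math.isnan(monte_carlo_capacity_test([5], reps=100, seed=0))

    def test_never_exactly_zero(self):
        p = monte_carlo_capacity_test([50, 0, 0], reps=1000, seed=0)
        assert p >= 1 / 1001


class TestDuration:
    def _setup(self):
        tree = simple_tree()
        clusters = {
            "T": MutationCluster("T", {"r": 1.0}, 100, is_trunk=True),
            "A": MutationCluster("A", {"r": 0.5}, 40),
            "B": MutationCluster("B", {"r": 0.2}, 12),
            "C": MutationCluster("C", {"r": 0.3}, 25),
        }
        return tree, clusters

    def test_private_descendant_counts(self):
        tree, clusters = self._setup()
        h = history([("P", "M1", "A")])
        presence = {"T": {"P", "M1"}, "A": {"P", "M1"}, "B": {"M1"},
                    "C": {"P"}}
        profiles = {
            "A": [Segment("1", 0, 50, 2, 1), Segment("1", 50, 100, 2, 2)],
            "B": [Segment("1", 0, 30, 2, 1), Segment("1", 30, 60, 3, 1),
                  Segment("1", 60, 100, 2, 2)],
        }
        out = duration_in_situ("M1", h, tree, clusters, presence, profiles)
        assert out == (12, 1)  # B is private below the seeder; 2 - 1 breakpoints

    def test_no_private_clusters(self):
        tree, clusters = self._setup()
        h = history([("P", "M1", "A")])
        presence = {"T": {"P", "M1"}, "A": {"P", "M1"}, "B": {"P", "M1"},
                    "C": {"P"}}
        assert duration_in_situ("M1", h, tree, clusters, presence) == (0, 0)

    def test_unknown_seeder_missing(self):
        tree, clusters = self._setup()
        h = history([])
        assert duration_in_situ("M1", h, tree, clusters, {}) is None


class TestSufficiency:
    def test_percentile_interpolation(self):
        # emergence counts 100, 150, 200 -> 90th percentile 190
        tree = CloneTree(
            nodes={"T", "A", "B", "C"},
            parent={"A": "T", "B": "T", "C": "T"},
        )
        clusters = {
            "T": MutationCluster("T", {"r": 1.0}, 0, is_trunk=True),
            "A": MutationCluster("A", {"r": 0.5}, 100),
            "B": MutationCluster("B", {"r": 0.5}, 150),
            "C": MutationCluster("C", {"r": 0.5}, 200),
        }
        h = history(
            [("M1", "M2", "A"), ("M1", "M3", "B"), ("M2", "M4", "C")]
        )
        out = sufficiency_threshold(
            h, tree, clusters, {}, {"M1": "metastasis"}, "P"
        )
        assert sorted(out.emergence_counts) == [100, 150, 200]
        assert out.threshold == pytest.approx(190.0)

    def test_single_seeder_degenerate_percentile(self):
        tree = CloneTree(nodes={"T", "A"}, parent={"A": "T"})
        clusters = {
            "T": MutationCluster("T", {"r": 1.0}, 20, is_trunk=True),
            "A": MutationCluster("A", {"r": 0.5}, 100),
        }
        h = history([("M1", "M2", "A")])
        out = sufficiency_threshold(h, tree, clusters, {}, {}, "P")
        assert out.threshold == pytest.approx(120.0)  # inclusive path sum

    def test_boundary_and_monotonicity(self):
        tree = CloneTree(nodes={"T", "A"}, parent={"A": "T"})
        clusters = {
            "T": MutationCluster("T", {"r": 1.0}, 0, is_trunk=True),
            "A": MutationCluster("A", {"r": 0.5}, 120),
        }
        h = history([("M1", "M2", "A")])
        presence = {"T": {"M3"}, "A": set()}
        clusters["T"].n_mutations = 119
        out = sufficiency_threshold(
            h, tree, clusters, presence, {"M3": "metastasis"}, "P"
        )
        # threshold = 119 + 120 = 239 > total 119 -> insufficient
        assert out.sufficient["M3"] is False
        # adding mutations can only flip insufficient -> sufficient
        clusters["T"].n_mutations = 500
        out2 = sufficiency_threshold(
            h, tree, clusters, presence, {"M3": "metastasis"}, "P"
        )
        assert out2.total_mutations["M3"] > out.total_mutations["M3"]

    def test_no_met_to_met_seeder_gives_missing(self):
        tree = CloneTree(nodes={"T", "A"}, parent={"A": "T"})
        clusters = {
            "T": MutationCluster("T", {"r": 1.0}, 10, is_trunk=True),
            "A": MutationCluster("A", {"r": 0.5}, 10),
        }
        h = history([("P", "M1", "A")])
        out = sufficiency_threshold(
            h, tree, clusters, {}, {"M1": "metastasis"}, "P"
        )
        assert out.threshold is None
        assert out.sufficient["M1"] is None


class TestCavitySummary:
    KINDS = {"P": "primary", "M1": "metastasis", "M2": "metastasis",
             "M3": "metastasis"}

    def test_fraction_arithmetic(self):
        cav = {"P": "primary", "M1": "intrathoracic", "M2": "intrathoracic",
               "M3": "extrathoracic"}
        site = {"P": "lung", "M1": "lung", "M2": "pleura", "M3": "liver"}
        h = history([
            ("M1", "M2", "A"), ("M1", "M3", "B"), ("P", "M1", "C"),
        ])
        out = cavity_summary(h, cav, site, self.KINDS)
        assert out.within_cavity_fraction == pytest.approx(0.5)
        assert out.cross_tab[("intrathoracic", "intrathoracic")] == 1
        assert out.cross_tab[("intrathoracic", "extrathoracic")] == 1

    def test_all_within_organ(self):
        cav = {"M1": "intrathoracic", "M2": "intrathoracic"}
        site = {"M1": "lung", "M2": "lung"}
        kinds = {"M1": "metastasis", "M2": "metastasis"}
        h = history([("M1", "M2", "A")])
        out = cavity_summary(h, cav, site, kinds)
        assert out.within_cavity_fraction == 1.0
        assert out.within_organ_fraction == 1.0

    def test_empty_migrations_no_crash(self):
        out = cavity_summary(history([]), {}, {}, {})
        assert out.cross_tab == {}
        assert out.within_cavity_fraction is None


class TestSCNABurden:
    def test_breakpoint_count_example(self):
        segs = [
            Segment("1", 0, 10, 1, 1),
            Segment("1", 10, 20, 2, 1),
            Segment("1", 20, 30, 2, 2),
        ]
        assert _breakpoint_count(segs) == 2

    def test_identical_profiles_give_equal_burden(self):
        tree = simple_tree()
        clusters = {
            c: MutationCluster(c, {"r": 0.5}, 10, is_trunk=(c == "T"))
            for c in tree.nodes
        }
        segs = [Segment("1", 0, 10, 2, 1)]
        profiles = {c: list(segs) for c in tree.nodes}
        h = history([("P", "M1", "A")])
        ann = annotate_seeding(
            h, tree, "P", {"P": "primary", "M1": "metastasis"}
        )
        report = scna_burden_comparison(ann, tree, clusters, profiles)
        assert set(report.burden.values()) == {0}
        assert report.p_seeder_vs_non == 1.0 or math.isnan(
            report.p_seeder_vs_non
        )

    def test_elevated_seeder_burden_detected(self):
        rng = np.random.default_rng(0)
        n = 12
        ids = ["T"] + [f"C{i}" for i in range(n)]
        tree = CloneTree(
            nodes=set(ids), parent={f"C{i}": "T" for i in range(n)}
        )
        clusters = {
            c: MutationCluster(c, {"r": 0.5}, 10, is_trunk=(c == "T"))
            for c in ids
        }
        profiles = {"T": [Segment("1", i * 10, (i + 1) * 10, 1, 1)
                          for i in range(10)]}
        migrations = []
        for i in range(n):
            cid = f"C{i}"
            seeder = i < 4
            segs = []
            for j in range(10):
                cn = 1 + (j % 4 if seeder else 0)
                segs.append(Segment("1", j * 10, (j + 1) * 10, cn, 1))
            profiles[cid] = segs
            if seeder:
                migrations.append(("P", f"M{i}", cid))
        h = history(migrations)
        kinds = {"P": "primary",
                 **{f"M{i}": "metastasis" for i in range(4)}}
        ann = annotate_seeding(h, tree, "P", kinds)
        report = scna_burden_comparison(ann, tree, clusters, profiles)
        assert report.median_by_role["seeder"] > report.median_by_role[
            "non_seeding"
        ]
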