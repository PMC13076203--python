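import pytest

from conftest import make_family_db
from oracles import exhaustive_edges, greedy_cover_reference
from protclust.cascade import (
    DEFAULT_LINEAR_SHAPES,
    CascadeConfig,
    RoundSpec,
    add_sequences,
    all_vs_all_candidates,
    all_vs_all_round,
    cascade_cluster,
    default_cascade,
    linclust,
    round_criterion,
    search_depth_for_round,
)
from protclust.errors import IntegrityError, ParameterError
from protclust.graph import build_graph
from protclust.linear import linear_round
from protclust.pairwise import ClusterCriterion, edge_directions, local_align
from protclust.seeding import SeedShape
from protclust.seqio import Sequence, SequenceDB
from protclust.synth import mutate_to_identity, random_protein


def _round(sensitivity, kind="all-vs-all", depth=1):
    return RoundSpec(sensitivity, kind, None, None, depth)


class TestRoundCriterion:
    def test_default_mode_rounds_use_27_percent_for_base_20(self):
        base = ClusterCriterion(min_identity=0.20, min_coverage=0.80)
        for sensitivity in ("faster", "fast", "default"):
            eff = round_criterion(base, _round(sensitivity))
            assert eff.min_identity == pytest.approx(0.27)
            assert eff.min_coverage == pytest.approx(0.87)

    def test_sensitive_round_bumps_coverage_only(self):
        base = ClusterCriterion(min_identity=0.20, min_coverage=0.80)
        eff = round_criterion(base, _round("sensitive"))
        assert eff.min_identity == pytest.approx(0.20)
        assert eff.min_coverage == pytest.approx(0.85)

    def test_later_rounds_use_base(self):
        base = ClusterCriterion(min_identity=0.20, min_coverage=0.80)
        for sensitivity in ("very-sensitive", "ultra-sensitive"):
            assert round_criterion(base, _round(sensitivity)) == base

    def test_bumps_clamp_at_one(self):
        base = ClusterCriterion(min_identity=0.95, min_coverage=0.97)
        eff = round_criterion(base, _round("default"))
        assert eff.min_identity == 1.0 and eff.min_coverage == 1.0


class TestDepthSchedule:
    @pytest.mark.parametrize(
        "index, kind, expected",
        [(1, "linear-minimizer", 1), (2, "linear", 1), (3, "all-vs-all", 3),
         (4, "all-vs-all", 3), (3, "linear", 2)],
    )
    def test_schedule(self, index, kind, expected):
        assert search_depth_for_round(index, kind) == expected

    def test_default_cascade_structure(self):
        config = default_cascade(4)
        assert [r.kind for r in config.rounds] == [
            "linear-minimizer", "linear", "all-vs-all", "all-vs-all",
        ]
        assert [r.depth for r in config.rounds] == [1, 1, 3, 3]
        assert config.rounds[0].window == 12

    def test_round_count_bounds(self):
        with pytest.raises(ParameterError):
            default_cascade(1)
        with pytest.raises(ParameterError):
            CascadeConfig(tuple(_round("default") for _ in range(7)))

    def test_sensitivity_must_be_non_decreasing(self):
        with pytest.raises(ParameterError):
            CascadeConfig((_round("sensitive"), _round("faster")))


class TestAllVsAllRound:
    def test_identical_pair_edges_both_ways(self, rng):
        res = random_protein(90, rng)
        db = SequenceDB([Sequence("a", res), Sequence("b", res)])
        crit = ClusterCriterion(min_coverage=0.8, mode="bi")
        hits = all_vs_all_round(db, crit, "default")
        edges = set(build_graph(db, hits, crit).edges)
        assert edges == {("a", "b"), ("b", "a")}

    def test_incompatible_lengths_never_aligned(self, rng):
        long = Sequence("a", random_protein(200, rng))
        short = Sequence("b", long.residues[:100])  # ratio 0.5
        db = SequenceDB([long, short])
        crit = ClusterCriterion(min_coverage=0.8, mode="bi")
        assert all_vs_all_candidates(db, crit, "ultra-sensitive") == []

    def test_ultra_sensitive_equals_exhaustive_reference(self, rng):
        db, _ = make_family_db(rng, n_families=3, members=4, singletons=5)
        crit = ClusterCriterion(min_identity=0.3, min_coverage=0.8, mode="bi")
        hits = all_vs_all_round(db, crit, "ultra-sensitive")
        got = set(build_graph(db, hits, crit).edges)
        assert got == exhaustive_edges(db, crit)


class TestCascadeCluster:
    CRIT = ClusterCriterion(min_identity=0.3, min_coverage=0.8, mode="bi")

    def test_dissimilar_sequences_stay_singletons(self, random_db):
        clustering = cascade_cluster(random_db, self.CRIT)
        assert clustering.n_clusters() == len(random_db)

    def test_single_family_collapses_to_one_cluster(self, rng):
        root = Sequence("root", random_protein(150, rng))
        members = [root] + [
            mutate_to_identity(root, 0.95, 0.0, rng, f"m{i}") for i in range(8)
        ]
        db = SequenceDB(members)
        clustering = cascade_cluster(db, self.CRIT)
        assert clustering.n_clusters() == 1
        # oracle: single-round exhaustive graph + greedy cover gives one
        # cluster too
        edges = exhaustive_edges(db, self.CRIT)
        oracle = greedy_cover_reference(
            list(db.ids), {r.id: r.length for r in db}, edges, 1
        )
        assert len(set(oracle.values())) == 1

    def test_cluster_count_non_increasing_across_rounds(self, rng):
        db, _ = make_family_db(rng, n_families=4, members=5, singletons=6)
        result = cascade_cluster(db, self.CRIT, return_details=True)
        counts = [len(set(r.clustering.assignment.values()))
                  for r in result.rounds]
        assert counts == sorted(counts, reverse=True)

    def test_determinism(self, rng):
        db, _ = make_family_db(rng, n_families=3, members=4, singletons=4)
        a = cascade_cluster(db, self.CRIT, seed=7)
        b = cascade_cluster(db, self.CRIT, seed=7)
        assert a == b

    def test_member_representative_chains_realign(self, rng):
        """Recorded paths re-align under each round's criterion."""
        db, _ = make_family_db(rng, n_families=3, members=5, singletons=3)
        result = cascade_cluster(db, self.CRIT, return_details=True)
        n_db = db.total_residues
        for round_result in result.rounds:
            for member, path in round_result.paths.items():
                assert len(path) - 1 <= round_result.spec.depth
                for parent, child in zip(path, path[1:]):
                    hit = local_align(db[parent], db[child],
                                      db_residues=n_db)
                    assert (parent, child) in edge_directions(
                        hit, round_result.criterion
                    )


class TestLinclust:
    CRIT = ClusterCriterion(min_identity=0.3, min_coverage=0.8, mode="bi")

    def test_default_shape_set_is_30_weight_10(self):
        assert len(DEFAULT_LINEAR_SHAPES) == 30
        for s in DEFAULT_LINEAR_SHAPES:
            shape = SeedShape.from_string(s)
            assert shape.weight == 10

    def test_trivial_inputs_match_cascade(self, random_db):
        assert linclust(random_db, self.CRIT).n_clusters() == len(random_db)

    def test_third_round_edges_subset_of_all_vs_all(self, rng):
        db, _ = make_family_db(rng, n_families=3, members=5, singletons=4)
        shapes = tuple(SeedShape.from_string(s) for s in DEFAULT_LINEAR_SHAPES)
        hits = linear_round(db, self.CRIT, shapes)
        edges = set(build_graph(db, hits, self.CRIT).edges)
        assert edges <= exhaustive_edges(db, self.CRIT)

    def test_more_shapes_no_fewer_edges(self, rng):
        db, _ = make_family_db(rng, n_families=4, members=5, singletons=4,
                               identity=(0.8, 0.9))
        shapes = tuple(SeedShape.from_string(s) for s in DEFAULT_LINEAR_SHAPES)
        one = set(build_graph(
            db, linear_round(db, self.CRIT, shapes[:1]), self.CRIT).edges)
        all30 = set(build_graph(
            db, linear_round(db, self.CRIT, shapes), self.CRIT).edges)
        assert one <= all30


class TestAddSequences:
    CRIT = ClusterCriterion(min_identity=0.3, min_coverage=0.8, mode="bi")

    def _base(self, rng):
        db, _ = make_family_db(rng, n_families=3, members=4, singletons=3)
        clustering = cascade_cluster(db, self.CRIT)
        return db, clustering

    def test_identical_to_representative_assigned(self, rng):
        db, clustering = self._base(rng)
        rep = clustering.representatives[0]
        new_db = SequenceDB([Sequence("new0", db[rep].residues)])
        out = add_sequences(clustering, db, new_db, self.CRIT)
        assert out["new0"] == rep

    def test_dissimilar_becomes_new_singleton(self, rng):
        db, clustering = self._base(rng)
        new_db = SequenceDB([Sequence("new0", random_protein(130, rng))])
        out = add_sequences(clustering, db, new_db, self.CRIT)
        assert out["new0"] == "new0"

    def test_partition_of_union_and_old_assignments_kept(self, rng):
        db, clustering = self._base(rng)
        new_db = SequenceDB(
            [Sequence(f"new{i}", random_protein(100, rng)) for i in range(4)]
        )
        out = add_sequences(clustering, db, new_db, self.CRIT)
        assert sorted(out.members) == sorted(db.ids + new_db.ids)
        for member, rep in clustering.assignment.items():
            assert out[member] == rep

    def test_id_collision_rejected(self, rng):
        db, clustering = self._base(rng)
        first = db.ids[0]
        with pytest.raises(IntegrityError):
            add_sequences(clustering, db,
                          SequenceDB([Sequence(first, "MKTVMKTVMKTV")]),
                          self.CRIT)
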