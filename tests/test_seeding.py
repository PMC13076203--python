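import numpy as np
import pytest

from oracles import shape_hits_reference, window_minimizers_reference
from protclust.errors import ParameterError
from protclust.seeding import (
    ColumnAlignment,
    SeedShape,
    enumerate_seeds,
    learn_shapes,
    sample_minimizers,
    shape_hits_alignment,
)
from protclust.seqio import Sequence
from protclust.synth import random_protein


class TestSeedShape:
    def test_string_roundtrip_and_properties(self):
        shape = SeedShape.from_string("1101011")
        assert str(shape) == "1101011"
        assert shape.weight == 5 and shape.span == 7
        assert shape.care_offsets == (0, 1, 3, 5, 6)

    def test_ends_must_be_care_positions(self):
        with pytest.raises(ParameterError):
            SeedShape.from_string("0111")
        with pytest.raises(ParameterError):
            SeedShape.from_string("1110")


class TestEnumerateSeeds:
    def test_window_count_contiguous(self, rng):
        seq = Sequence("a", random_protein(50, rng))
        assert len(enumerate_seeds(seq, SeedShape.contiguous(8))) == 43

    def test_care_position_extraction(self):
        shape = SeedShape.from_string("1101")
        # differs only at the don't-care position -> same key
        k1 = enumerate_seeds(Sequence("a", "ACDE"), shape)[0].key
        k2 = enumerate_seeds(Sequence("b", "ACFE"), shape)[0].key
        k3 = enumerate_seeds(Sequence("c", "AMDE"), shape)[0].key
        assert k1 == k2
        assert k1 != k3

    def test_shared_substring_shares_key(self, rng):
        core = random_protein(12, rng)
        s1 = Sequence("a", random_protein(20, rng) + core)
        s2 = Sequence("b", core + random_protein(15, rng))
        shape = SeedShape.contiguous(9)
        keys1 = {s.key for s in enumerate_seeds(s1, shape)}
        keys2 = {s.key for s in enumerate_seeds(s2, shape)}
        assert keys1 & keys2

    def test_too_short_sequence_empty(self):
        assert enumerate_seeds(Sequence("a", "MKT"), SeedShape.contiguous(5)) == []

    def test_deterministic_across_calls(self, rng):
        seq = Sequence("a", random_protein(100, rng))
        shape = SeedShape.from_string("110101011")
        assert enumerate_seeds(seq, shape) == enumerate_seeds(seq, shape)


class TestMinimizers:
    def test_homopolymer_single_key(self):
        seq = Sequence("a", "A" * 60)
        seeds = sample_minimizers(seq, SeedShape.contiguous(6), w=12)
        assert len({s.key for s in seeds}) == 1
        assert seeds[0].start == 0  # leftmost tie-break

    def test_sequence_of_exactly_span_length(self, rng):
        seq = Sequence("a", random_protein(8, rng))
        seeds = sample_minimizers(seq, SeedShape.contiguous(8), w=12)
        assert len(seeds) == 1 and seeds[0].start == 0

    def test_matches_brute_force_window_scan(self, rng):
        from protclust.seeding import _seed_keys

        shape = SeedShape.from_string("1101011011")
        for _ in range(10):
            seq = Sequence("a", random_protein(300, rng))
            keys = list(_seed_keys(seq, shape))
            expected = window_minimizers_reference(keys, 12)
            got = {s.start for s in sample_minimizers(seq, shape, w=12)}
            assert got == expected

    def test_subset_of_enumerated_seeds(self, rng):
        shape = SeedShape.contiguous(7)
        seq = Sequence("a", random_protein(150, rng))
        all_seeds = set(enumerate_seeds(seq, shape))
        mins = set(sample_minimizers(seq, shape))
        assert mins and mins <= all_seeds
        assert len(mins) <= len(all_seeds)


class TestShapeHits:
    def test_identical_alignment_hit_by_any_shape(self, rng):
        res = random_protein(30, rng)
        aln = ColumnAlignment(res, res)
        for pattern in ("1111", "110011", "101010101"):
            assert shape_hits_alignment(SeedShape.from_string(pattern), aln)

    def test_no_long_gap_free_run(self):
        aln = ColumnAlignment("MKT-VLA-MK", "MKTA-LAQMK")
        assert not shape_hits_alignment(SeedShape.contiguous(5), aln)

    def test_agrees_with_exhaustive_scan(self, rng):
        patterns = ["1111", "11011", "10101", "110011", "1001001"]
        residues = list("ACDEFG-")
        for _ in range(50):
            n = int(rng.integers(6, 40))
            a = "".join(rng.choice(residues, n))
            b = "".join(rng.choice(residues, n))
            aln = ColumnAlignment(a, b)
            for p in patterns:
                assert shape_hits_alignment(
                    SeedShape.from_string(p), aln
                ) == shape_hits_reference(p, a, b)


def _run_alignment(match_mask: str) -> ColumnAlignment:
    """Build an alignment whose columns are M(match)/X(mismatch)/-(gap)."""
    a, b = [], []
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    for i, c in enumerate(match_mask):
        if c == "M":
            a.append(alphabet[i % 20])
            b.append(alphabet[i % 20])
        elif c == "X":
            a.append("A")
            b.append("C")
        else:
            a.append("-")
            b.append(alphabet[i % 20])
    return ColumnAlignment("".join(a), "".join(b))


class TestLearnShapes:
    def test_unique_maximizer_selected_first(self):
        # runs of exactly 4 matched columns flanked by gaps: only the
        # contiguous weight-4 shape can hit them
        alns = [_run_alignment("-MMMM-") for _ in range(5)]
        shapes = learn_shapes(alns, weight=4, max_span=7, count=30)
        assert str(shapes[0][0]) == "1111"
        assert shapes[0][1] == 5

    def test_early_stop_when_collection_empty(self):
        group_a = [_run_alignment("-MMMM-") for _ in range(3)]
        group_b = [_run_alignment("-MMXMM-") for _ in range(2)]
        shapes = learn_shapes(group_a + group_b, weight=4, max_span=7, count=30)
        assert [str(s) for s, _ in shapes] == ["1111", "11011"]

    def test_weight_exceeding_span_rejected(self):
        with pytest.raises(ParameterError):
            learn_shapes([_run_alignment("MMMM")], weight=5, max_span=4)

    def test_greedy_progress_and_shape_invariants(self, rng):
        from protclust.synth import FamilySpec, simulate_alignment_collection

        spec = FamilySpec(identity_range=(0.5, 0.9), indel_rate=0.03,
                          root_length_range=(60, 120), seed=7)
        alns = simulate_alignment_collection(spec, 60, rng)
        shapes = learn_shapes(alns, weight=4, max_span=7, count=10)
        assert shapes
        for shape, hits in shapes:
            assert shape.weight == 4
            assert shape.pattern[0] and shape.pattern[-1]
            assert hits > 0
        # remaining-alignment count strictly decreases while selection continues
        remaining = list(alns)
        for shape, hits in shapes:
            survivors = [a for a in remaining
                         if not shape_hits_alignment(shape, a)]
            assert len(survivors) == len(remaining) - hits
            assert len(survivors) < len(remaining)
            remaining = survivors

    def test_hill_climb_mode_runs_deterministically(self, rng):
        from protclust.synth import FamilySpec, simulate_alignment_collection

        spec = FamilySpec(identity_range=(0.6, 0.9), root_length_range=(60, 100),
                          seed=3)
        alns = simulate_alignment_collection(spec, 20, rng)
        s1 = learn_shapes(alns, weight=6, max_span=11, count=2,
                          rng=np.random.default_rng(5))
        s2 = learn_shapes(alns, weight=6, max_span=11, count=2,
                          rng=np.random.default_rng(5))
        assert [(str(a), n) for a, n in s1] == [(str(a), n) for a, n in s2]
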