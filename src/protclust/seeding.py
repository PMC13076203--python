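"""Spaced seeds, minimizer subsampling and empirical seed-shape learning.

A *seed shape* is a mask of care/don't-care positions (care at both ends);
a seed instance hashes the residues at the care positions of one window of
a sequence.  Minimizer subsampling keeps, for every window of ``w``
consecutive seed positions, only the seed with the smallest hash, which
subsamples the seed space reproducibly and proportionally to sequence
length.

Shapes themselves can be learned from a collection of gapped pairwise
alignments by greedy set cover: repeatedly pick the shape hitting the most
alignments not yet hit, remove those alignments, and continue until the
requested number of shapes is reached or nothing is left.  A shape *hits*
an alignment if some run of ``span`` gap-free columns matches at every care
position.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, NamedTuple, Optional, Sequence as TSequence

import numpy as np

from .errors import ParameterError
from .seqio import AA_EXTENDED, Sequence

#: default minimizer window (consecutive seed positions per window)
MINIMIZER_WINDOW = 12

_RESIDUE_CODE = {aa: np.uint64(i) for i, aa in enumerate(AA_EXTENDED)}
_CODE_LUT = np.zeros(128, dtype=np.uint64)
for _aa, _code in _RESIDUE_CODE.items():
    _CODE_LUT[ord(_aa)] = _code

_M64 = np.uint64(0xFFFFFFFFFFFFFFFF)


def _mix64(x: np.ndarray) -> np.ndarray:
    """Fixed 64-bit finalizer (splitmix64); deterministic across platforms."""
    x = x.astype(np.uint64, copy=True)
    with np.errstate(over="ignore"):
        x ^= x >> np.uint64(30)
        x *= np.uint64(0xBF58476D1CE4E5B9)
        x ^= x >> np.uint64(27)
        x *= np.uint64(0x94D049BB133111EB)
        x ^= x >> np.uint64(31)
    return x


@dataclass(frozen=True)
class SeedShape:
    """Care/don't-care mask; care positions required at both ends."""

    pattern: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ParameterError("empty seed shape")
        if not (self.pattern[0] and self.pattern[-1]):
            raise ParameterError("seed shape must have care positions at both ends")

    @classmethod
    def from_string(cls, s: str) -> "SeedShape":
        if set(s) - {"0", "1"}:
            raise ParameterError(f"seed shape string must be over 0/1: {s!r}")
        return cls(tuple(c == "1" for c in s))

    @classmethod
    def contiguous(cls, weight: int) -> "SeedShape":
        if weight < 1:
            raise ParameterError("weight must be positive")
        return cls((True,) * weight)

    @classmethod
    def from_offsets(cls, offsets: Iterable[int]) -> "SeedShape":
        offs = sorted(set(offsets))
        span = offs[-1] + 1
        return cls(tuple(i in set(offs) for i in range(span)))

    @property
    def span(self) -> int:
        return len(self.pattern)

    @property
    def weight(self) -> int:
        return sum(self.pattern)

    @property
    def care_offsets(self) -> tuple[int, ...]:
        return tuple(i for i, c in enumerate(self.pattern) if c)

    def __str__(self) -> str:
        return "".join("1" if c else "0" for c in self.pattern)


class Seed(NamedTuple):
    key: int
    seq_id: str
    start: int


def _seed_keys(seq: Sequence, shape: SeedShape) -> np.ndarray:
    """Hashed keys for every window position, vectorized; empty if too short."""
    n = seq.length - shape.span + 1
    if n <= 0:
        return np.empty(0, dtype=np.uint64)
    codes = _CODE_LUT[np.frombuffer(seq.residues.encode("ascii"), dtype=np.uint8)]
    packed = np.zeros(n, dtype=np.uint64)
    with np.errstate(over="ignore"):
        for i, off in enumerate(shape.care_offsets):
            packed |= codes[off:off + n] << np.uint64(5 * i)
    return _mix64(packed)


def enumerate_seeds(seq: Sequence, shape: SeedShape) -> list[Seed]:
    """One seed per window position ``0..L-span``; key from care positions only."""
    keys = _seed_keys(seq, shape)
    return [Seed(int(k), seq.id, i) for i, k in enumerate(keys)]


def sample_minimizers(seq: Sequence, shape: SeedShape,
                      w: int = MINIMIZER_WINDOW) -> list[Seed]:
    """Minimal-hash seed of every window of ``w`` seed positions (leftmost tie).

    Sequences with fewer than ``w`` seed positions still emit the single
    minimal seed so that every seedable sequence is represented.
    """
    if w < 1:
        raise ParameterError("minimizer window must be positive")
    keys = _seed_keys(seq, shape)
    n = len(keys)
    if n == 0:
        return []
    if n <= w:
        pos = int(np.argmin(keys))
        return [Seed(int(keys[pos]), seq.id, pos)]
    windows = np.lib.stride_tricks.sliding_window_view(keys, w)
    mins = np.argmin(windows, axis=1)  # leftmost minimum per window
    starts = np.unique(mins + np.arange(n - w + 1))
    return [Seed(int(keys[p]), seq.id, int(p)) for p in starts]


# ---------------------------------------------------------------------------
# shape learning

class ColumnAlignment(NamedTuple):
    """A gapped pairwise alignment as two equal-length strings ('-' = gap)."""

    a: str
    b: str


def _alignment_arrays(aln: ColumnAlignment) -> tuple[np.ndarray, np.ndarray]:
    a = np.frombuffer(aln.a.encode("ascii"), dtype=np.uint8)
    b = np.frombuffer(aln.b.encode("ascii"), dtype=np.uint8)
    if a.shape != b.shape:
        raise ParameterError("alignment strings differ in length")
    gap = np.uint8(ord("-"))
    gap_free = (a != gap) & (b != gap)
    match = gap_free & (a == b)
    return gap_free, match


def _hits(gap_free: np.ndarray, match: np.ndarray, shape: SeedShape) -> bool:
    span = shape.span
    n = len(gap_free) - span + 1
    if n <= 0:
        return False
    ok = np.lib.stride_tricks.sliding_window_view(gap_free, span).all(axis=1)
    for off in shape.care_offsets:
        ok &= match[off:off + n]
        if not ok.any():
            return False
    return bool(ok.any())


def shape_hits_alignment(shape: SeedShape, alignment: ColumnAlignment) -> bool:
    """True iff some gap-free window matches at every care position."""
    gap_free, match = _alignment_arrays(alignment)
    return _hits(gap_free, match, shape)


def _candidate_shapes(weight: int, max_span: int) -> list[SeedShape]:
    shapes = []
    for span in range(weight, max_span + 1):
        for interior in combinations(range(1, span - 1), weight - 2):
            shapes.append(SeedShape.from_offsets((0, *interior, span - 1)))
    return shapes


def _count_hits(shape: SeedShape, arrays) -> int:
    return sum(1 for gf, m in arrays if _hits(gf, m, shape))


def _hill_climb(arrays, weight: int, max_span: int,
                rng: np.random.Generator, restarts: int = 3) -> tuple[SeedShape, int]:
    """Local search over care-offset sets, seeded restarts, deterministic."""
    def evaluate(offsets: frozenset[int]) -> int:
        return _count_hits(SeedShape.from_offsets(offsets), arrays)

    starts = [frozenset(range(weight))]
    for _ in range(restarts):
        interior = rng.choice(np.arange(1, max_span), size=weight - 1, replace=False)
        starts.append(frozenset({0, *(int(x) for x in interior)}))
    best_offsets, best_score = None, -1
    for offsets in starts:
        score = evaluate(offsets)
        improved = True
        while improved:
            improved = False
            movable = sorted(offsets - {0})
            free = sorted(set(range(1, max_span)) - offsets)
            for src in movable:
                for dst in free:
                    cand = frozenset(offsets - {src} | {dst})
                    s = evaluate(cand)
                    if s > score:
                        offsets, score = cand, s
                        improved = True
                        break
                if improved:
                    break
        if score > best_score or (
            score == best_score and str(SeedShape.from_offsets(offsets))
            < str(SeedShape.from_offsets(best_offsets))
        ):
            best_offsets, best_score = offsets, score
    return SeedShape.from_offsets(best_offsets), best_score


def learn_shapes(
    alignments: TSequence[ColumnAlignment],
    weight: int = 10,
    max_span: int = 16,
    count: int = 30,
    rng: Optional[np.random.Generator] = None,
    exhaustive_limit: tuple[int, int] = (5, 10),
) -> list[tuple[SeedShape, int]]:
    """Greedy set cover over seed shapes against an alignment collection.

    Returns ``(shape, hit_count)`` in selection order.  The candidate search
    is exhaustive for small spaces (weight/span within ``exhaustive_limit``)
    and hill-climbing with seeded random restarts otherwise.
    """
    if weight > max_span:
        raise ParameterError("weight must not exceed max span")
    if not alignments:
        raise ParameterError("alignment collection is empty")
    if rng is None:
        rng = np.random.default_rng(0)
    arrays = [_alignment_arrays(a) for a in alignments]
    exhaustive = weight <= exhaustive_limit[0] and max_span <= exhaustive_limit[1]
    candidates = _candidate_shapes(weight, max_span) if exhaustive else None
    selected: list[tuple[SeedShape, int]] = []
    remaining = arrays
    while remaining and len(selected) < count:
        if exhaustive:
            best_shape, best_n = None, -1
            for shape in candidates:
                n = _count_hits(shape, remaining)
                if n > best_n or (n == best_n and str(shape) < str(best_shape)):
                    best_shape, best_n = shape, n
        else:
            best_shape, best_n = _hill_climb(remaining, weight, max_span, rng)
        if best_n == 0:
            break
        selected.append((best_shape, best_n))
        remaining = [
            (gf, m) for gf, m in remaining if not _hits(gf, m, best_shape)
        ]
    return selected
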