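"""Cascaded clustering: multi-round composition at increasing sensitivity.

A cascade chains 2–6 rounds over a shrinking representative set.  The first
round generates candidates with the linear-stage algorithm plus minimizer
subsampling (window 12); the second repeats it without minimizers; later
rounds run seeded all-vs-all comparison at escalating sensitivity.  Rounds
up to default sensitivity tighten the base criterion by +7% on identity and
coverage, the sensitive round adds +5% to coverage only, and later rounds
use the base criterion unchanged.  Greedy vertex cover uses search depth 1
in the first two rounds and 3 afterwards; the pure linear mode replaces the
all-vs-all stages with a third linear round over 30 learned spaced seed
shapes of weight 10 at depth 2.

Sensitivity levels name seeding configurations (the ladder below): higher
sensitivity means lighter-weight and more numerous seed shapes, up to
exhaustive comparison within length-compatible ranges at ultra-sensitive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence as TSequence

from .errors import IntegrityError, ParameterError
from .graph import build_graph, compose, greedy_vertex_cover
from .linear import align_pairs, group_by_seed, linear_round
from .pairwise import (
    DEFAULT_SCORING,
    EPSILON_LENGTH,
    AlignmentHit,
    ClusterCriterion,
    ScoringScheme,
    length_compatible,
)
from .seqio import Clustering, SequenceDB
from .seeding import MINIMIZER_WINDOW, SeedShape

logger = logging.getLogger(__name__)

SENSITIVITY_LEVELS = (
    "faster", "fast", "default", "sensitive", "very-sensitive", "ultra-sensitive",
)

#: sensitivity ladder: level -> (seed shape strings or None for exhaustive
#: comparison, max candidate pairs per query or None for unlimited)
SENSITIVITY_SEEDING: dict[str, tuple[Optional[tuple[str, ...]], Optional[int]]] = {
    "faster": (("111111111",), None),
    "fast": (("11111111",), None),
    "default": (("1111111", "11011010011"), None),
    "sensitive": (("111111", "110101011", "101100111"), None),
    "very-sensitive": (("11111", "1101011", "1011011", "1100111"), None),
    "ultra-sensitive": (None, None),
}

# DEFAULT_LINEAR_SHAPES (end of module): 30 spaced seed shapes of weight 10
# for the linear mode's third round, learned with
# :func:`protclust.seeding.learn_shapes` from a simulated alignment
# collection at a fixed seed (regenerable via the learn-seeds CLI).


def _level_index(sensitivity: str) -> int:
    try:
        return SENSITIVITY_LEVELS.index(sensitivity)
    except ValueError:
        raise ParameterError(f"unknown sensitivity level {sensitivity!r}") from None


def _shapes_for(sensitivity: str) -> Optional[tuple[SeedShape, ...]]:
    strings, _ = SENSITIVITY_SEEDING[sensitivity]
    if strings is None:
        return None
    return tuple(SeedShape.from_string(s) for s in strings)


@dataclass(frozen=True)
class RoundSpec:
    """One round of the cascade."""

    sensitivity: str
    kind: str  # 'linear-minimizer' | 'linear' | 'all-vs-all'
    shapes: Optional[tuple[SeedShape, ...]] = None
    window: Optional[int] = None
    depth: int = 1

    def __post_init__(self) -> None:
        _level_index(self.sensitivity)
        if self.kind not in ("linear-minimizer", "linear", "all-vs-all"):
            raise ParameterError(f"unknown round kind {self.kind!r}")
        if self.depth < 1:
            raise ParameterError("search depth must be >= 1")


@dataclass(frozen=True)
class CascadeConfig:
    """Ordered rounds plus the base criterion's stringency offsets."""

    rounds: tuple[RoundSpec, ...]
    identity_bump: float = 0.07
    coverage_bump: float = 0.07
    sensitive_coverage_bump: float = 0.05

    def __post_init__(self) -> None:
        if not 2 <= len(self.rounds) <= 6:
            raise ParameterError("a cascade chains between 2 and 6 rounds")
        levels = [_level_index(r.sensitivity) for r in self.rounds]
        if levels != sorted(levels):
            raise ParameterError("sensitivity levels must be non-decreasing")


def search_depth_for_round(round_index: int, stage_kind: str) -> int:
    """Depth schedule: rounds 1–2 use depth 1; later linear rounds 2, else 3."""
    if round_index <= 2:
        return 1
    if stage_kind in ("linear", "linear-minimizer"):
        return 2
    return 3


def default_cascade(n_rounds: int = 4) -> CascadeConfig:
    """Standard deep cascade: linear+minimizers, linear, then all-vs-all
    rounds escalating default → sensitive → very-sensitive → ultra-sensitive."""
    if not 2 <= n_rounds <= 6:
        raise ParameterError("a cascade chains between 2 and 6 rounds")
    rounds = [
        RoundSpec("faster", "linear-minimizer", _shapes_for("faster"),
                  MINIMIZER_WINDOW, search_depth_for_round(1, "linear-minimizer")),
        RoundSpec("fast", "linear", _shapes_for("fast"), None,
                  search_depth_for_round(2, "linear")),
    ]
    for i, level in enumerate(
        ("default", "sensitive", "very-sensitive", "ultra-sensitive")[: n_rounds - 2]
    ):
        rounds.append(
            RoundSpec(level, "all-vs-all", _shapes_for(level), None,
                      search_depth_for_round(3 + i, "all-vs-all"))
        )
    return CascadeConfig(tuple(rounds))


def linear_config(shapes30: Optional[TSequence[SeedShape]] = None) -> CascadeConfig:
    """Pure linear mode: two standard linear rounds, then a linear round over
    the 30 weight-10 spaced seed shapes at search depth 2."""
    if shapes30 is None:
        shapes30 = tuple(SeedShape.from_string(s) for s in DEFAULT_LINEAR_SHAPES)
    base = default_cascade(4)
    rounds = (
        base.rounds[0],
        base.rounds[1],
        RoundSpec("default", "linear", tuple(shapes30), None,
                  search_depth_for_round(3, "linear")),
    )
    return CascadeConfig(rounds)


def round_criterion(base: ClusterCriterion, rnd: RoundSpec,
                    config: Optional[CascadeConfig] = None) -> ClusterCriterion:
    """Per-round stringency schedule, clamped at 1.0.

    Rounds at sensitivity up to and including default add the +7% bumps to
    identity and coverage; the sensitive round adds +5% to coverage only;
    more sensitive rounds use the base criterion unchanged.
    """
    id_bump = config.identity_bump if config else 0.07
    cov_bump = config.coverage_bump if config else 0.07
    sens_bump = config.sensitive_coverage_bump if config else 0.05
    lvl = _level_index(rnd.sensitivity)
    if lvl <= _level_index("default"):
        return replace(
            base,
            min_identity=min(1.0, base.min_identity + id_bump),
            min_coverage=min(1.0, base.min_coverage + cov_bump),
        )
    if rnd.sensitivity == "sensitive":
        return replace(base, min_coverage=min(1.0, base.min_coverage + sens_bump))
    return base


def all_vs_all_candidates(
    db: SequenceDB,
    criterion: ClusterCriterion,
    sensitivity: str,
    epsilon: float = EPSILON_LENGTH,
) -> list[tuple[str, str]]:
    """Unordered candidate pairs for an all-vs-all round.

    Seeded levels pair sequences sharing a seed key; ultra-sensitive
    considers every pair.  Query/target symmetry means each unordered pair
    is evaluated once.  In bi-directional mode the permissive length-ratio
    prefilter (``min/max >= c - epsilon``) is applied over the
    length-descending order, which restricts each query to a contiguous
    index range of compatible partners.
    """
    shapes = _shapes_for(sensitivity)
    c = criterion.min_coverage
    bi = criterion.mode == "bi"
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[str, str]] = []

    def emit(a: str, b: str) -> None:
        key = (a, b) if a <= b else (b, a)
        if key not in seen:
            seen.add(key)
            pairs.append(key)

    if shapes is None:
        order = [db.records[i] for i in db.by_length]
        for i, qi in enumerate(order):
            for qj in order[i + 1:]:
                if bi and not length_compatible(qi.length, qj.length, c, -epsilon):
                    break  # lengths only shrink further along the sorted order
                emit(qi.id, qj.id)
        return pairs

    for group in group_by_seed(db, shapes, window=None):
        members = group.members
        lengths = [db.length_of(m) for m in members]
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                if bi and not length_compatible(lengths[i], lengths[j], c, -epsilon):
                    break
                emit(members[i], members[j])
    return pairs


def all_vs_all_round(
    db: SequenceDB,
    criterion: ClusterCriterion,
    sensitivity: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    epsilon: float = EPSILON_LENGTH,
) -> list[AlignmentHit]:
    """Self-comparison of the representative set at the given sensitivity."""
    pairs = all_vs_all_candidates(db, criterion, sensitivity, epsilon)
    hits = align_pairs(db, pairs, criterion, scoring)
    logger.info(
        "all-vs-all round (%s): %d candidate pairs, %d accepted alignments",
        sensitivity, len(pairs), len(hits),
    )
    return hits


@dataclass
class RoundResult:
    spec: RoundSpec
    criterion: ClusterCriterion
    clustering: Clustering
    paths: dict[str, list[str]] = field(default_factory=dict)
    n_hits: int = 0


@dataclass
class CascadeResult:
    clustering: Clustering
    rounds: list[RoundResult]


def cascade_cluster(
    db: SequenceDB,
    criterion: ClusterCriterion,
    config: Optional[CascadeConfig] = None,
    seed: int = 0,
    scoring: ScoringScheme = DEFAULT_SCORING,
    return_details: bool = False,
):
    """Run the full cascade over a deduplicated database.

    Returns the final :class:`Clustering` (a partition of all input ids), or
    a :class:`CascadeResult` with per-round clusterings and the
    representative→member paths recorded at extraction time when
    ``return_details`` is set.  The computation is deterministic; ``seed``
    is accepted for interface uniformity with the stochastic entry points.
    """
    del seed  # deterministic pipeline
    if config is None:
        config = default_cascade()
    total = Clustering.identity(db.ids)
    current = db
    results: list[RoundResult] = []
    for idx, rnd in enumerate(config.rounds, 1):
        crit = round_criterion(criterion, rnd, config)
        if rnd.kind == "all-vs-all":
            hits = all_vs_all_round(current, crit, rnd.sensitivity, scoring)
        else:
            window = rnd.window if rnd.kind == "linear-minimizer" else None
            hits = linear_round(current, crit, rnd.shapes, window, scoring)
        graph = build_graph(current, hits, crit)
        clustering, paths = greedy_vertex_cover(graph, rnd.depth, return_paths=True)
        total = compose(clustering, total)
        current = current.subset(clustering.representatives)
        results.append(RoundResult(rnd, crit, clustering, paths, len(hits)))
        logger.info(
            "round %d (%s, %s): %d representatives remain",
            idx, rnd.kind, rnd.sensitivity, len(current),
        )
    if return_details:
        return CascadeResult(total, results)
    return total


def linclust(
    db: SequenceDB,
    criterion: ClusterCriterion,
    shapes30: Optional[TSequence[SeedShape]] = None,
    seed: int = 0,
    scoring: ScoringScheme = DEFAULT_SCORING,
    return_details: bool = False,
):
    """Pure linear mode: no all-vs-all stage anywhere."""
    return cascade_cluster(
        db, criterion, linear_config(shapes30), seed, scoring, return_details
    )


def add_sequences(
    existing: Clustering,
    rep_db: SequenceDB,
    new_db: SequenceDB,
    criterion: ClusterCriterion,
    scoring: ScoringScheme = DEFAULT_SCORING,
    config: Optional[CascadeConfig] = None,
) -> Clustering:
    """Incrementally extend a clustering with new sequences.

    New sequences are seeded against the existing representatives and
    assigned to the best criterion-passing representative (highest score,
    ties to the smaller id); the remainder is clustered among itself with
    the cascade and merged.  Existing assignments are never changed.
    """
    overlap = set(existing.assignment) & {r.id for r in new_db}
    if overlap:
        raise IntegrityError(f"new ids collide with existing: {sorted(overlap)[:5]}")
    reps = set(existing.representatives)
    missing = reps - {r.id for r in rep_db}
    if missing:
        raise IntegrityError(f"representative sequences missing: {sorted(missing)[:5]}")

    shapes = _shapes_for("sensitive")
    combined = SequenceDB(
        list(rep_db.subset(reps).records) + list(new_db.records)
    )
    new_ids = {r.id for r in new_db}
    candidate_pairs: set[tuple[str, str]] = set()
    for group in group_by_seed(combined, shapes, window=None):
        members = group.members
        for a in members:
            if a not in reps:
                continue
            for b in members:
                if b in new_ids and (
                    criterion.mode != "bi"
                    or length_compatible(
                        combined.length_of(a), combined.length_of(b),
                        criterion.min_coverage, -EPSILON_LENGTH,
                    )
                ):
                    candidate_pairs.add((a, b))
    hits = align_pairs(combined, sorted(candidate_pairs), criterion, scoring)
    best: dict[str, tuple[int, str]] = {}
    for hit in hits:
        # orient: which end is the new sequence?
        for rep, member in (
            (hit.query_id, hit.target_id), (hit.target_id, hit.query_id)
        ):
            if rep in reps and member in new_ids:
                from .pairwise import passes_criterion
                side = "target" if member == hit.target_id else "query"
                if passes_criterion(hit, criterion, member=side):
                    cand = (-hit.score, rep)
                    if member not in best or cand < best[member]:
                        best[member] = cand
    assignment = dict(existing.assignment)
    leftovers = []
    for rec in new_db:
        if rec.id in best:
            assignment[rec.id] = best[rec.id][1]
        else:
            leftovers.append(rec)
    if leftovers:
        sub = cascade_cluster(SequenceDB(leftovers), criterion, config)
        assignment.update(sub.assignment)
    return Clustering(assignment)


DEFAULT_LINEAR_SHAPES = (
    "1100010110110111",
    "1010011100011111",
    "1111010011001101",
    "11110101001111",
    "110011011110101",
    "1110001010110111",
    "1001011111101001",
    "1010111100100111",
    "101011101011101",
    "111000110111101",
    "1011011111000101",
    "101011001110111",
    "1110100101110101",
    "1100011000111111",
    "1100011110111001",
    "1111000010101111",
    "1001011101110011",
    "101001111110011",
    "11100011101111",
    "101011101111001",
    "1001111110110001",
    "1111001011010011",
    "111111010100101",
    "1010111111100001",
    "111110000111101",
    "110110111100011",
    "1101111010000111",
    "1010011110011011",
    "1001110101101011",
    "101111101100011",
)
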