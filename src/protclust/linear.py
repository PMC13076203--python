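"""Linear-scaling candidate-pair generation.

Sequences sharing a seed key form a *seed group*, ordered by length
descending.  Instead of trialing all pairs inside a group, the
uni-directional rule compares each member only against the group's longest
sequence; the bi-directional rule sweeps a length-ratio-compatible interval
and compares its members against the interval's median sequence, so that
every emitted pair already satisfies the stringent length-ratio filter
``min/max >= c + delta`` and cannot be excluded a priori from reaching
bi-directional coverage ``c``.
"""

from __future__ import annotations

import logging
from typing import NamedTuple, Optional, Sequence as TSequence

from .errors import ParameterError
from .pairwise import (
    DELTA_LENGTH,
    DEFAULT_SCORING,
    AlignmentHit,
    ClusterCriterion,
    ScoringScheme,
    edge_directions,
    evalue,
    local_align,
    score_only,
)
from .seqio import SequenceDB
from .seeding import SeedShape, enumerate_seeds, sample_minimizers

logger = logging.getLogger(__name__)


class SeedGroup(NamedTuple):
    """Sequences containing the same seed, length-sorted descending."""

    key: tuple[int, int]  # (shape index, seed hash)
    members: tuple[str, ...]


def group_by_seed(
    db: SequenceDB,
    shapes: TSequence[SeedShape],
    window: Optional[int] = None,
) -> list[SeedGroup]:
    """Groups of >= 2 sequences per distinct seed key.

    With ``window`` set, seeds are minimizer-subsampled per sequence before
    grouping.  Member order inside a group is length descending, ties by id.
    """
    buckets: dict[tuple[int, int], set[str]] = {}
    for rec in db:
        for shape_idx, shape in enumerate(shapes):
            seeds = (
                sample_minimizers(rec, shape, window)
                if window is not None
                else enumerate_seeds(rec, shape)
            )
            for seed in seeds:
                buckets.setdefault((shape_idx, seed.key), set()).add(rec.id)
    groups = []
    for key in sorted(buckets):
        ids = buckets[key]
        if len(ids) < 2:
            continue
        members = tuple(sorted(ids, key=lambda i: (-db.length_of(i), i)))
        groups.append(SeedGroup(key, members))
    return groups


def candidates_uni(group: SeedGroup) -> list[tuple[str, str]]:
    """Each member paired with the group's longest sequence."""
    if len(group.members) < 2:
        raise ParameterError("seed group must have at least 2 members")
    longest = group.members[0]
    return [(longest, m) for m in group.members[1:]]


def candidates_bi(
    group: SeedGroup,
    lengths: dict[str, int],
    c: float,
    delta: float = DELTA_LENGTH,
) -> list[tuple[str, str]]:
    """Interval/median sweep for bi-directional coverage candidates.

    Starting at the longest sequence, take the maximal run ``[i; j]`` whose
    lengths satisfy ``l_k / l_i >= c + delta``, pair every run member with
    the median-index sequence, then advance ``i`` to the first index whose
    length is ratio-compatible with ``l_(j+1)`` (shorter over longer) and
    repeat until the run reaches the end of the group.
    """
    if not 0 < c + delta <= 1:
        raise ParameterError("c + delta must be in (0, 1]")
    members = group.members
    ls = [lengths[m] for m in members]
    n = len(members)
    pairs: list[tuple[str, str]] = []
    i = 0
    while i < n:
        j = i
        while j + 1 < n and ls[j + 1] / ls[i] >= c + delta:
            j += 1
        med = (i + j) // 2
        for k in range(i, j + 1):
            if k != med:
                pairs.append((members[med], members[k]))
        if j == n - 1:
            break
        nxt_len = ls[j + 1]
        i += 1
        while i < n and nxt_len / ls[i] < c + delta:
            i += 1
    return pairs


def linear_round(
    db: SequenceDB,
    criterion: ClusterCriterion,
    shapes: TSequence[SeedShape],
    window: Optional[int] = None,
    scoring: ScoringScheme = DEFAULT_SCORING,
    delta: float = DELTA_LENGTH,
) -> list[AlignmentHit]:
    """One linear candidate-generation round.

    Groups by seed (optionally minimizer-subsampled), generates candidate
    pairs per the criterion's coverage mode, aligns each distinct pair once
    and keeps alignments that support at least one directed edge under the
    round criterion.
    """
    lengths = {rec.id: rec.length for rec in db}
    groups = group_by_seed(db, shapes, window)
    seen: set[tuple[str, str]] = set()
    pairs: list[tuple[str, str]] = []
    for group in groups:
        if criterion.mode == "bi":
            cands = candidates_bi(group, lengths, criterion.min_coverage, delta)
        else:
            cands = candidates_uni(group)
        for a, b in cands:
            key = (a, b) if a <= b else (b, a)
            if key not in seen:
                seen.add(key)
                pairs.append(key)
    hits = align_pairs(db, pairs, criterion, scoring)
    logger.info(
        "linear round: %d groups, %d candidate pairs, %d accepted alignments",
        len(groups), len(pairs), len(hits),
    )
    return hits


def align_pairs(
    db: SequenceDB,
    pairs: TSequence[tuple[str, str]],
    criterion: ClusterCriterion,
    scoring: ScoringScheme = DEFAULT_SCORING,
) -> list[AlignmentHit]:
    """Align candidate pairs, keeping hits that support >= 1 directed edge.

    The e-value database size is the residue total of the current set.  A
    score-only pass gates the (more expensive) traceback on the e-value
    bound.
    """
    n_db = db.total_residues
    aligner = scoring.make_aligner()
    hits = []
    for a, b in pairs:
        qa, qb = db[a], db[b]
        s = score_only(qa, qb, scoring, _aligner=aligner)
        if evalue(s, qa.length, n_db, scoring) > criterion.max_evalue:
            continue
        hit = local_align(qa, qb, scoring, db_residues=n_db, _aligner=aligner)
        if edge_directions(hit, criterion):
            hits.append(hit)
    return hits
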