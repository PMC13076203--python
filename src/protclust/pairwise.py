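"""Local pairwise alignment and the clustering criterion.

A cluster assignment is justified by a pairwise local alignment that passes
the *clustering criterion*: an e-value bound (default 0.001), a minimum
sequence identity (0 = deep clustering) and a minimum coverage ``c`` under a
coverage mode.  Coverage of a side is the length of the range spanned by the
local alignment divided by that sequence's length; *bi-directional* mode
requires coverage ``>= c`` of both sequences, *uni-directional* mode only of
the member (non-representative) sequence.

Alignments are computed with the Smith–Waterman algorithm under an affine
gap model (BLOSUM62, gap open 11, extend 1 by default); e-values follow the
Karlin–Altschul formula ``E = K * m * n * exp(-lambda * S)`` with ``m`` the
query length and ``n`` the residue count of the database searched (here: the
current representative set).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Literal, Optional

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import IntegrityError, ParameterError
from .seqio import AA_CANONICAL, AA_EXTENDED, Sequence

#: default slack subtracted from the coverage threshold in the permissive
#: all-vs-all length-ratio prefilter (accounts for gap columns)
EPSILON_LENGTH = 0.05
#: default slack added to the coverage threshold in the stringent
#: linear-stage length-ratio filter
DELTA_LENGTH = 0.05

_CANONICAL_SET = frozenset(AA_CANONICAL)


@lru_cache(maxsize=4)
def _extended_matrix(name: str):
    """Substitution matrix extended to the 25-letter alphabet.

    Pairs undefined in the named matrix (U/O against anything) score 0 so
    that ambiguity codes neither reward nor punish an alignment.
    """
    base = substitution_matrices.load(name)
    base_alpha = set(base.alphabet)
    ext = substitution_matrices.Array(alphabet=AA_EXTENDED, dims=2)
    for a in AA_EXTENDED:
        for b in AA_EXTENDED:
            if a in base_alpha and b in base_alpha:
                ext[a, b] = base[a, b]
            else:
                ext[a, b] = 0.0
    return ext


@dataclass(frozen=True)
class ScoringScheme:
    """Substitution matrix, affine gap penalties and Karlin–Altschul constants.

    The default lambda/K are the standard gapped values for BLOSUM62 with
    gap open 11 and extend 1.
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    karlin_lambda: float = 0.267
    karlin_k: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_extend > self.gap_open:
            raise ParameterError("gap extend penalty must not exceed gap open")
        if self.karlin_lambda <= 0 or self.karlin_k <= 0:
            raise ParameterError("Karlin–Altschul constants must be positive")

    def make_aligner(self) -> Align.PairwiseAligner:
        aligner = Align.PairwiseAligner()
        aligner.mode = "local"
        aligner.substitution_matrix = _extended_matrix(self.matrix_name)
        # a gap of length k costs gap_open + k * gap_extend
        aligner.open_gap_score = -(self.gap_open + self.gap_extend)
        aligner.extend_gap_score = -self.gap_extend
        return aligner


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise local alignment with the quantities the criterion needs.

    Spans are 0-based half-open residue intervals; ``columns`` counts aligned
    residue pairs plus gap columns.
    """

    query_id: str
    target_id: str
    score: int
    identities: int
    columns: int
    query_span: tuple[int, int]
    target_span: tuple[int, int]
    query_length: int
    target_length: int
    evalue: float
    aligned: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if self.identities > self.columns:
            raise IntegrityError(
                f"identities ({self.identities}) exceed alignment columns ({self.columns})"
            )
        qs, qe = self.query_span
        ts, te = self.target_span
        if not (0 <= qs <= qe <= self.query_length):
            raise IntegrityError(f"query span {self.query_span} outside sequence")
        if not (0 <= ts <= te <= self.target_length):
            raise IntegrityError(f"target span {self.target_span} outside sequence")

    @property
    def query_coverage(self) -> float:
        return coverage(self, "query")

    @property
    def target_coverage(self) -> float:
        return coverage(self, "target")

    @property
    def identity(self) -> float:
        return identity_fraction(self)


@dataclass(frozen=True)
class ClusterCriterion:
    """Acceptance rule for a pairwise alignment.

    ``min_identity = 0`` disables the identity threshold (deep clustering).
    """

    max_evalue: float = 1e-3
    min_identity: float = 0.0
    min_coverage: float = 0.8
    mode: Literal["uni", "bi"] = "bi"

    def __post_init__(self) -> None:
        if not 0.0 <= self.min_identity <= 1.0:
            raise ParameterError("min identity must be in [0, 1]")
        if not 0.0 <= self.min_coverage <= 1.0:
            raise ParameterError("min coverage must be in [0, 1]")
        if self.max_evalue < 0:
            raise ParameterError("max e-value must be non-negative")
        if self.mode not in ("uni", "bi"):
            raise ParameterError(f"unknown coverage mode {self.mode!r}")


def evalue(score: float, query_length: int, db_residue_count: int,
           scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    """Karlin–Altschul expectation ``K * m * n * exp(-lambda * S)``."""
    if query_length <= 0 or db_residue_count <= 0:
        raise ParameterError("lengths must be positive")
    return scoring.karlin_k * query_length * db_residue_count * math.exp(
        -scoring.karlin_lambda * score
    )


def bitscore(score: float, scoring: ScoringScheme = DEFAULT_SCORING) -> float:
    return (scoring.karlin_lambda * score - math.log(scoring.karlin_k)) / math.log(2)


def local_align(
    query: Sequence,
    target: Sequence,
    scoring: ScoringScheme = DEFAULT_SCORING,
    db_residues: Optional[int] = None,
    keep_alignment: bool = False,
    _aligner: Optional[Align.PairwiseAligner] = None,
) -> AlignmentHit:
    """Optimal Smith–Waterman local alignment of two sequences.

    ``db_residues`` is the database size used for the e-value (defaults to
    the target length, i.e. a single-pair search).  With ``keep_alignment``
    the gapped alignment strings are attached to the hit (used by the
    spaced-seed learner).
    """
    if db_residues is None:
        db_residues = target.length
    aligner = _aligner if _aligner is not None else scoring.make_aligner()
    alignments = aligner.align(query.residues, target.residues)
    if len(alignments) == 0 or alignments.score <= 0:
        # fully dissimilar pair: empty alignment with score 0
        return AlignmentHit(
            query.id, target.id, 0, 0, 0, (0, 0), (0, 0),
            query.length, target.length,
            evalue(0, query.length, db_residues, scoring),
        )
    aln = alignments[0]
    blocks_q, blocks_t = aln.aligned
    identities = 0
    pair_columns = 0
    gap_columns = 0
    for (qs, qe), (ts, te) in zip(blocks_q, blocks_t):
        pair_columns += qe - qs
        for a, b in zip(query.residues[qs:qe], target.residues[ts:te]):
            if a == b and a in _CANONICAL_SET:
                identities += 1
    for k in range(1, len(blocks_q)):
        gap_columns += blocks_q[k][0] - blocks_q[k - 1][1]
        gap_columns += blocks_t[k][0] - blocks_t[k - 1][1]
    query_span = (int(blocks_q[0][0]), int(blocks_q[-1][1]))
    target_span = (int(blocks_t[0][0]), int(blocks_t[-1][1]))
    aligned = None
    if keep_alignment:
        aligned = _gapped_strings(query.residues, target.residues, blocks_q, blocks_t)
    score = int(round(aln.score))
    return AlignmentHit(
        query.id, target.id, score, identities, pair_columns + gap_columns,
        query_span, target_span, query.length, target.length,
        evalue(score, query.length, db_residues, scoring),
        aligned=aligned,
    )


def _gapped_strings(qres, tres, blocks_q, blocks_t) -> tuple[str, str]:
    out_q, out_t = [], []
    for k, ((qs, qe), (ts, te)) in enumerate(zip(blocks_q, blocks_t)):
        if k:
            gq = qs - blocks_q[k - 1][1]
            gt = ts - blocks_t[k - 1][1]
            # unaligned jump: emit target-gap columns then query-gap columns
            out_q.append(qres[qs - gq:qs])
            out_t.append("-" * gq)
            out_q.append("-" * gt)
            out_t.append(tres[ts - gt:ts])
        out_q.append(qres[qs:qe])
        out_t.append(tres[ts:te])
    return "".join(out_q), "".join(out_t)


def score_only(
    query: Sequence,
    target: Sequence,
    scoring: ScoringScheme = DEFAULT_SCORING,
    _aligner: Optional[Align.PairwiseAligner] = None,
) -> int:
    """Smith–Waterman score without traceback (cheap pre-filter)."""
    aligner = _aligner if _aligner is not None else scoring.make_aligner()
    return int(round(aligner.score(query.residues, target.residues)))


def coverage(hit: AlignmentHit, side: Literal["query", "target"],
             seq_length: Optional[int] = None) -> float:
    """Span length divided by sequence length for the given side."""
    if side == "query":
        start, end = hit.query_span
        length = hit.query_length if seq_length is None else seq_length
    elif side == "target":
        start, end = hit.target_span
        length = hit.target_length if seq_length is None else seq_length
    else:
        raise ParameterError(f"unknown side {side!r}")
    return (end - start) / length


def identity_fraction(hit: AlignmentHit) -> float:
    """Identical aligned pairs over all alignment columns (gaps included)."""
    if hit.columns < 1:
        raise ParameterError("identity fraction undefined for an empty alignment")
    return hit.identities / hit.columns


def passes_criterion(
    hit: AlignmentHit,
    criterion: ClusterCriterion,
    member: Literal["query", "target"] = "target",
) -> bool:
    """Does the alignment justify representing the ``member`` side?

    In bi-directional mode both coverages must reach the threshold; in
    uni-directional mode only the member side's coverage is required.
    """
    if hit.evalue > criterion.max_evalue:
        return False
    if criterion.min_identity > 0:
        if hit.columns < 1 or identity_fraction(hit) < criterion.min_identity:
            return False
    c = criterion.min_coverage
    if criterion.mode == "bi":
        return hit.query_coverage >= c and hit.target_coverage >= c
    return coverage(hit, member) >= c


def edge_directions(hit: AlignmentHit, criterion: ClusterCriterion) -> list[tuple[str, str]]:
    """Directed (representative, member) edges this alignment supports."""
    edges = []
    if passes_criterion(hit, criterion, member="target"):
        edges.append((hit.query_id, hit.target_id))
    if passes_criterion(hit, criterion, member="query"):
        edges.append((hit.target_id, hit.query_id))
    return edges


def length_compatible(l1: int, l2: int, c: float, tol: float = 0.0) -> bool:
    """Length-ratio prefilter: ``min/max >= c + tol``.

    A local alignment can only cover fraction ``c`` of both sequences when
    their length ratio (shorter over longer) is at least about ``c``; ``tol``
    is negative for the permissive all-vs-all filter (epsilon slack for gap
    columns) and positive for the stringent linear-stage filter (delta).
    """
    if l1 < 1 or l2 < 1:
        raise ParameterError("lengths must be positive")
    lo, hi = (l1, l2) if l1 <= l2 else (l2, l1)
    return lo / hi >= c + tol - 1e-12


def write_hits_tsv(hits, path) -> None:
    """BLAST outfmt-6-like 12-column TSV (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        for h in hits:
            pident = 100.0 * h.identities / h.columns if h.columns else 0.0
            mismatches = sum(
                1 for a, b in zip(*(h.aligned or ("", ""))) if a != b and a != "-" and b != "-"
            ) if h.aligned else max(h.columns - h.identities, 0)
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.query_id, h.target_id, f"{pident:.1f}", h.columns,
                        mismatches, 0,
                        h.query_span[0] + 1, h.query_span[1],
                        h.target_span[0] + 1, h.target_span[1],
                        f"{h.evalue:.2e}", f"{bitscore(h.score):.1f}",
                    )
                )
                + "\n"
            )
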