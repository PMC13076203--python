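"""Independent reference implementations used only to check the package.

Each oracle is deliberately the simplest correct formulation of its
operation (full dynamic programming, fresh-scan greedy, union-find,
exhaustive enumeration) and shares no code path with the implementation it
checks.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from protclust.seqio import AA_EXTENDED

NEG = -(10 ** 9)


@njit(cache=False)
def _gotoh_local_score(q, t, sub, gap_open_total, gap_extend):
    n, m = len(q), len(t)
    H = np.zeros((n + 1, m + 1), dtype=np.int64)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int64)
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - gap_open_total
            if E[i, j - 1] - gap_extend > e:
                e = E[i, j - 1] - gap_extend
            E[i, j] = e
            f = H[i - 1, j] - gap_open_total
            if F[i - 1, j] - gap_extend > f:
                f = F[i - 1, j] - gap_extend
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[q[i - 1], t[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
    return best


_CODE = {aa: i for i, aa in enumerate(AA_EXTENDED)}


def _encode(residues: str) -> np.ndarray:
    return np.array([_CODE[c] for c in residues], dtype=np.int64)


def sw_score_reference(query: str, target: str, scoring) -> int:
    """Full-DP Smith-Waterman/Gotoh local alignment score.

    A gap of length k costs ``gap_open + k * gap_extend``, matching the
    package's affine model.
    """
    from protclust.pairwise import _extended_matrix

    mat = _extended_matrix(scoring.matrix_name)
    sub = np.array(mat, dtype=np.int64)
    return int(
        _gotoh_local_score(
            _encode(query), _encode(target), sub,
            scoring.gap_open + scoring.gap_extend, scoring.gap_extend,
        )
    )


def greedy_cover_reference(nodes, lengths, edges, depth):
    """Greedy vertex cover scanning the full adjacency each iteration."""
    out = {n: set() for n in nodes}
    for a, b in edges:
        if a != b:
            out[a].add(b)
    live = set(nodes)
    assignment = {}
    while live:
        rep = min(live, key=lambda n: (-len(out[n] & live), -lengths[n], n))
        cluster = {rep}
        frontier = {rep}
        for _ in range(depth):
            nxt = set()
            for u in frontier:
                nxt |= out[u] & live
            nxt -= cluster
            if not nxt:
                break
            cluster |= nxt
            frontier = nxt
        for member in cluster:
            assignment[member] = rep
        live -= cluster
    return assignment


def components_reference(nodes, edges):
    """Weakly connected components via union-find; returns frozenset of frozensets."""
    parent = {n: n for n in nodes}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in edges:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb
    groups = {}
    for n in nodes:
        groups.setdefault(find(n), set()).add(n)
    return frozenset(frozenset(g) for g in groups.values())


def window_minimizers_reference(keys, w):
    """Per-window minimum scan: leftmost minimal key per window of size w."""
    n = len(keys)
    if n == 0:
        return set()
    if n <= w:
        best = min(range(n), key=lambda i: (keys[i], i))
        return {best}
    picks = set()
    for start in range(n - w + 1):
        best = min(range(start, start + w), key=lambda i: (keys[i], i))
        picks.add(best)
    return picks


def shape_hits_reference(pattern: str, row_a: str, row_b: str) -> bool:
    """Exhaustive per-offset scan of a gapped alignment for a shape hit."""
    span = len(pattern)
    cols = list(zip(row_a, row_b))
    for start in range(len(cols) - span + 1):
        window = cols[start:start + span]
        if any(a == "-" or b == "-" for a, b in window):
            continue
        if all(window[i][0] == window[i][1]
               for i, c in enumerate(pattern) if c == "1"):
            return True
    return False


def exhaustive_edges(db, criterion, scoring=None):
    """Directed criterion-passing edges from aligning every unordered pair.

    The e-value depends only on the score, so a score-only gate on the
    e-value bound is lossless.
    """
    from protclust.pairwise import (
        DEFAULT_SCORING, edge_directions, evalue, local_align, score_only,
    )

    scoring = scoring or DEFAULT_SCORING
    n_db = db.total_residues
    aligner = scoring.make_aligner()
    records = list(db)
    edges = set()
    for i in range(len(records)):
        for j in range(i + 1, len(records)):
            a, b = records[i], records[j]
            s = score_only(a, b, scoring, _aligner=aligner)
            if evalue(s, a.length, n_db, scoring) > criterion.max_evalue:
                continue
            hit = local_align(a, b, scoring, db_residues=n_db, _aligner=aligner)
            edges.update(edge_directions(hit, criterion))
    return edges


def evaluate_reference(clustering, architectures, clans):
    """Naive quadratic recomputation of sensitivity and precision."""
    from protclust.evaluate import clan_equivalent

    annotated = [s for s in architectures if s in clustering.assignment]
    sens, prec = {}, {}
    for s in annotated:
        arch = architectures[s]
        rep = clustering.assignment[s]
        same_arch_total = sum(1 for t in annotated if architectures[t] == arch)
        mates = [t for t in annotated if clustering.assignment[t] == rep]
        same_in_cluster = sum(1 for t in mates if architectures[t] == arch)
        equivalent = sum(
            1 for t in mates if clan_equivalent(architectures[t], arch, clans)
        )
        sens[s] = same_in_cluster / same_arch_total
        prec[s] = equivalent / len(mates)
    return sens, prec
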