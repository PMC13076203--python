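"""Sequence and clustering I/O.

Protein records are plain amino-acid strings over the 20-letter alphabet
plus the ambiguity codes X/B/Z/U/O.  A :class:`SequenceDB` keeps records in
input order together with a length-descending index used by the candidate
generation stages; a :class:`Clustering` is the member → representative
assignment that every clustering algorithm in this package produces.

Cluster assignments are serialized as a two-column TSV
(representative, member), one row per member, with representatives listed
as their own members — the common convention for clustering output of
sequence-clustering tools.
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

#: canonical 20-letter amino-acid alphabet
AA_CANONICAL = "ACDEFGHIKLMNPQRSTVWY"
#: 25-letter alphabet including ambiguity codes
AA_EXTENDED = AA_CANONICAL + "BZXUO"

_EXTENDED_SET = frozenset(AA_EXTENDED)


@dataclass(frozen=True)
class Sequence:
    """A protein sequence with a stable accession."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if not self.residues:
            raise FormatError(f"sequence record {self.id!r} has empty residues")

    @property
    def length(self) -> int:
        return len(self.residues)


def normalize_residues(residues: str, record_id: str = "?") -> str:
    """Upper-case, strip terminal '*' stop characters, map unknown letters to X."""
    residues = residues.upper().strip("*")
    if not set(residues) <= _EXTENDED_SET:
        cleaned = "".join(c if c in _EXTENDED_SET else "X" for c in residues)
        warnings.warn(
            f"record {record_id!r}: residues outside the 25-letter alphabet replaced by X",
            stacklevel=2,
        )
        residues = cleaned
    return residues


class SequenceDB:
    """Ordered collection of sequences with unique ids and a length-sorted index."""

    def __init__(self, records: Iterable[Sequence]):
        self._records: list[Sequence] = list(records)
        self._index: dict[str, int] = {}
        for pos, rec in enumerate(self._records):
            if rec.id in self._index:
                raise IntegrityError(f"duplicate sequence id {rec.id!r}")
            self._index[rec.id] = pos

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[Sequence]:
        return iter(self._records)

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self._index

    def __getitem__(self, seq_id: str) -> Sequence:
        return self._records[self._index[seq_id]]

    @property
    def records(self) -> tuple[Sequence, ...]:
        return tuple(self._records)

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self._records)

    @property
    def by_length(self) -> tuple[int, ...]:
        """Record positions sorted by length descending; ties keep input order."""
        return tuple(
            sorted(range(len(self._records)), key=lambda i: -self._records[i].length)
        )

    @property
    def total_residues(self) -> int:
        return sum(r.length for r in self._records)

    def length_of(self, seq_id: str) -> int:
        return self[seq_id].length

    def subset(self, ids: Iterable[str]) -> "SequenceDB":
        """New db restricted to ``ids``, preserving the original record order."""
        keep = set(ids)
        missing = keep - set(self._index)
        if missing:
            raise IntegrityError(f"unknown sequence ids: {sorted(missing)[:5]}")
        return SequenceDB(r for r in self._records if r.id in keep)


def read_fasta(path) -> SequenceDB:
    """Parse a (optionally gzipped) FASTA file into a :class:`SequenceDB`."""
    path = str(path)
    opener = gzip.open if path.endswith(".gz") else open
    records = []
    with opener(path, "rt") as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if not rec.id:
                raise FormatError(f"{path}: FASTA record with empty id")
            residues = normalize_residues(str(rec.seq), rec.id)
            if not residues:
                raise FormatError(f"{path}: FASTA record {rec.id!r} has empty sequence")
            records.append(Sequence(rec.id, residues))
    db = SequenceDB(records)
    logger.info("read %d sequences from %s", len(db), path)
    return db


def write_fasta(db: SequenceDB, path) -> None:
    with open(path, "w") as fh:
        for rec in db:
            fh.write(f">{rec.id}\n{rec.residues}\n")
    logger.info("wrote %d sequences to %s", len(db), path)


def deduplicate(db: SequenceDB) -> tuple[SequenceDB, dict[str, str]]:
    """Collapse exact-duplicate residue strings, keeping the first-seen record.

    Returns the reduced database and a map from each removed id to the id of
    the record kept in its place.
    """
    seen: dict[str, str] = {}
    kept: list[Sequence] = []
    duplicate_map: dict[str, str] = {}
    for rec in db:
        prior = seen.get(rec.residues)
        if prior is None:
            seen[rec.residues] = rec.id
            kept.append(rec)
        else:
            duplicate_map[rec.id] = prior
    out = SequenceDB(kept)
    logger.info("deduplicate: %d -> %d records", len(db), len(out))
    return out, duplicate_map


@dataclass(frozen=True)
class Clustering:
    """Member → representative assignment forming a partition.

    Every key is a member id; every representative maps to itself.
    """

    assignment: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for member, rep in self.assignment.items():
            if rep not in self.assignment:
                raise IntegrityError(
                    f"representative {rep!r} of {member!r} is not itself assigned"
                )
            if self.assignment[rep] != rep:
                raise IntegrityError(f"representative {rep!r} does not map to itself")

    @classmethod
    def identity(cls, ids: Iterable[str]) -> "Clustering":
        return cls({i: i for i in ids})

    def __len__(self) -> int:
        return len(self.assignment)

    def __getitem__(self, member: str) -> str:
        return self.assignment[member]

    def __contains__(self, member: str) -> bool:
        return member in self.assignment

    def __eq__(self, other) -> bool:
        if not isinstance(other, Clustering):
            return NotImplemented
        return dict(self.assignment) == dict(other.assignment)

    @property
    def members(self) -> tuple[str, ...]:
        return tuple(self.assignment)

    @property
    def representatives(self) -> tuple[str, ...]:
        seen = []
        done = set()
        for rep in self.assignment.values():
            if rep not in done:
                done.add(rep)
                seen.append(rep)
        return tuple(seen)

    def clusters(self) -> dict[str, list[str]]:
        """Representative → sorted member list."""
        out: dict[str, list[str]] = {}
        for member, rep in self.assignment.items():
            out.setdefault(rep, []).append(member)
        for members in out.values():
            members.sort()
        return out

    def n_clusters(self) -> int:
        return len(set(self.assignment.values()))


def write_clusters(clustering: Clustering, path) -> None:
    """Two-column TSV: representative, member; representatives self-listed."""
    rows = sorted(clustering.assignment.items(), key=lambda kv: (kv[1], kv[0]))
    with open(path, "w") as fh:
        for member, rep in rows:
            fh.write(f"{rep}\t{member}\n")
    logger.info("wrote %d cluster assignments to %s", len(rows), path)


def read_clusters(path) -> Clustering:
    assignment: dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            rep, member = parts
            if member in assignment:
                raise IntegrityError(f"{path}:{lineno}: member {member!r} listed twice")
            assignment[member] = rep
    clustering = Clustering(assignment)
    logger.info("read %d cluster assignments from %s", len(clustering), path)
    return clustering


def read_annotations(
    arch_path, clan_path=None
) -> tuple[dict[str, tuple[str, ...]], dict[str, str]]:
    """Read per-sequence domain architectures and an optional family→clan map.

    The architecture file is a two-column TSV: sequence id, comma-separated
    ordered family labels.  Sequences absent from the file count as
    non-annotated.
    """
    architectures: dict[str, tuple[str, ...]] = {}
    with open(arch_path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise FormatError(
                    f"{arch_path}:{lineno}: expected 2 columns, got {len(parts)}"
                )
            seq_id, labels = parts
            if seq_id in architectures:
                raise FormatError(f"{arch_path}:{lineno}: duplicate id {seq_id!r}")
            architectures[seq_id] = tuple(x for x in labels.split(",") if x)
    clans: dict[str, str] = {}
    if clan_path is not None:
        with open(clan_path) as fh:
            for lineno, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line:
                    continue
                parts = line.split("\t")
                if len(parts) != 2:
                    raise FormatError(
                        f"{clan_path}:{lineno}: expected 2 columns, got {len(parts)}"
                    )
                clans[parts[0]] = parts[1]
    logger.info("read %d architectures, %d clan entries", len(architectures), len(clans))
    return architectures, clans
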