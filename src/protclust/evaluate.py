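"""Clustering evaluation against domain-architecture annotations.

A sequence's *sensitivity* is the number of sequences of its exact domain
architecture that share its cluster, divided by the number of sequences of
that architecture in the whole input; its *precision* is the number of
cluster mates whose architecture is clan-equivalent to its own, divided by
the cluster size.  Non-annotated sequences are ignored throughout: they
contribute to no numerator, no denominator and no cluster size.  Two
architectures are clan-equivalent when they have the same number of domains
and the families at each position are identical or belong to the same clan.
Per-sequence values are aggregated with the arithmetic mean.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Optional

from .errors import IntegrityError
from .seqio import Clustering

Architecture = tuple[str, ...]


def clan_equivalent(
    a: Architecture, b: Architecture, clans: Mapping[str, str]
) -> bool:
    """Positional equivalence of two architectures under the clan map."""
    if len(a) != len(b):
        return False
    for fa, fb in zip(a, b):
        if fa == fb:
            continue
        ca, cb = clans.get(fa), clans.get(fb)
        if ca is None or ca != cb:
            return False
    return True


@dataclass(frozen=True)
class EvalResult:
    per_sequence_sensitivity: dict[str, float]
    per_sequence_precision: dict[str, float]
    mean_sensitivity: float
    mean_precision: float
    annotated_count: int

    def write_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("#metric\tid\tvalue\n")
            fh.write(f"mean_sensitivity\t-\t{self.mean_sensitivity:.6f}\n")
            fh.write(f"mean_precision\t-\t{self.mean_precision:.6f}\n")
            fh.write(f"annotated_count\t-\t{self.annotated_count}\n")
            for sid in sorted(self.per_sequence_sensitivity):
                fh.write(
                    f"sequence\t{sid}\t{self.per_sequence_sensitivity[sid]:.6f}"
                    f"\t{self.per_sequence_precision[sid]:.6f}\n"
                )


def sequence_sensitivity(
    seq_id: str,
    clustering: Clustering,
    architectures: Mapping[str, Architecture],
) -> float:
    """Same-architecture cluster mates over same-architecture input sequences."""
    arch = architectures[seq_id]
    rep = clustering[seq_id]
    total = sum(1 for a in architectures.values() if a == arch)
    same = sum(
        1
        for member, r in clustering.assignment.items()
        if r == rep and architectures.get(member) == arch
    )
    return same / total


def sequence_precision(
    seq_id: str,
    clustering: Clustering,
    architectures: Mapping[str, Architecture],
    clans: Optional[Mapping[str, str]] = None,
) -> float:
    """Clan-equivalent annotated cluster mates over annotated cluster size."""
    clans = clans or {}
    arch = architectures[seq_id]
    rep = clustering[seq_id]
    mates = [
        member
        for member, r in clustering.assignment.items()
        if r == rep and member in architectures
    ]
    equivalent = sum(
        1 for m in mates if clan_equivalent(architectures[m], arch, clans)
    )
    return equivalent / len(mates)


def evaluate(
    clustering: Clustering,
    architectures: Mapping[str, Architecture],
    clans: Optional[Mapping[str, str]] = None,
) -> EvalResult:
    """Per-sequence sensitivity/precision over all annotated sequences."""
    clans = clans or {}
    missing = [sid for sid in architectures if sid not in clustering]
    if missing:
        raise IntegrityError(
            f"annotated sequences absent from clustering: {sorted(missing)[:5]}"
        )
    arch_counts = Counter(architectures.values())
    clusters: dict[str, list[str]] = {}
    for member in architectures:
        clusters.setdefault(clustering[member], []).append(member)
    sens: dict[str, float] = {}
    prec: dict[str, float] = {}
    for rep, members in clusters.items():
        member_archs = [architectures[m] for m in members]
        size = len(members)
        cluster_arch_counts = Counter(member_archs)
        for m, arch in zip(members, member_archs):
            sens[m] = cluster_arch_counts[arch] / arch_counts[arch]
            equivalent = sum(
                n
                for other, n in cluster_arch_counts.items()
                if clan_equivalent(other, arch, clans)
            )
            prec[m] = equivalent / size
    n = len(sens)
    return EvalResult(
        per_sequence_sensitivity=sens,
        per_sequence_precision=prec,
        mean_sensitivity=sum(sens.values()) / n if n else 0.0,
        mean_precision=sum(prec.values()) / n if n else 0.0,
        annotated_count=n,
    )
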