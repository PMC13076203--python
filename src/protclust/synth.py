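"""Synthetic protein families with ground-truth labels.

The generator emulates the structure a clustering benchmark needs without
any download: families of sequences derived from a random root by point
substitutions to a controlled target identity, occasional short indels, and
optional terminal truncations that cap the attainable coverage; plus a pool
of unrelated singleton sequences.  Every sequence carries a ground-truth
family and domain-architecture label, so clusterings can be scored exactly.

Residues are drawn from a fixed canonical background amino-acid frequency
table (Robinson–Robinson counts); substitutions always replace a residue
with a *different* one so the realized co-linear identity matches the
target exactly up to rounding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import ParameterError
from .seqio import AA_CANONICAL, Clustering, Sequence, SequenceDB
from .seeding import ColumnAlignment

#: background amino-acid frequencies over ACDEFGHIKLMNPQRSTVWY
#: (Robinson & Robinson composition, normalized)
BACKGROUND_FREQS = {
    "A": 0.0780, "C": 0.0152, "D": 0.0535, "E": 0.0668, "F": 0.0397,
    "G": 0.0733, "H": 0.0229, "I": 0.0574, "K": 0.0592, "L": 0.0934,
    "M": 0.0221, "N": 0.0454, "P": 0.0520, "Q": 0.0426, "R": 0.0512,
    "S": 0.0712, "T": 0.0568, "V": 0.0660, "W": 0.0131, "Y": 0.0324,
}

_AA = np.array(list(AA_CANONICAL))
_FREQS = np.array([BACKGROUND_FREQS[a] for a in AA_CANONICAL])
_FREQS = _FREQS / _FREQS.sum()


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_AA, size=length, p=_FREQS))


def _substitute(residue: str, rng: np.random.Generator) -> str:
    """Background-frequency draw excluding the original residue."""
    idx = AA_CANONICAL.index(residue) if residue in AA_CANONICAL else -1
    p = _FREQS.copy()
    if idx >= 0:
        p[idx] = 0.0
        p = p / p.sum()
    return str(rng.choice(_AA, p=p))


def _mutate(
    root: str,
    target_identity: float,
    indel_rate: float,
    rng: np.random.Generator,
) -> tuple[str, str, str]:
    """Mutant plus the true gapped alignment (root row, mutant row)."""
    if not 0 < target_identity <= 1:
        raise ParameterError("target identity must be in (0, 1]")
    length = len(root)
    n_sub = int(round((1.0 - target_identity) * length))
    sub_pos = set(rng.choice(length, size=n_sub, replace=False)) if n_sub else set()
    mutant = [
        _substitute(c, rng) if i in sub_pos else c for i, c in enumerate(root)
    ]
    aligned_root = list(root)
    aligned_mut = mutant[:]
    n_events = rng.poisson(indel_rate * length) if indel_rate > 0 else 0
    for _ in range(n_events):
        pos = int(rng.integers(0, len(aligned_root) + 1))
        size = int(rng.integers(1, 4))
        if rng.random() < 0.5:  # insertion into the mutant
            ins = [str(rng.choice(_AA, p=_FREQS)) for _ in range(size)]
            aligned_root[pos:pos] = ["-"] * size
            aligned_mut[pos:pos] = ins
        else:  # deletion from the mutant
            end = min(pos + size, len(aligned_root))
            for k in range(pos, end):
                if aligned_mut[k] != "-":
                    aligned_mut[k] = "-"
    mutant_seq = "".join(c for c in aligned_mut if c != "-")
    if not mutant_seq:
        return root, root, root
    return mutant_seq, "".join(aligned_root), "".join(aligned_mut)


def mutate_to_identity(
    root: Sequence,
    target_identity: float,
    indel_rate: float,
    rng: np.random.Generator,
    new_id: Optional[str] = None,
) -> Sequence:
    """Derived sequence at the given co-linear identity to the root."""
    mutant, _, _ = _mutate(root.residues, target_identity, indel_rate, rng)
    return Sequence(new_id or f"{root.id}_mut", mutant)


@dataclass(frozen=True)
class FamilySpec:
    """Study conditions for a synthetic dataset.

    Ranges are inclusive ``(low, high)`` and sampled uniformly per family or
    member.  ``domain_range`` > 1 produces multi-domain families whose
    architecture concatenates per-domain labels (roots joined by 5-residue
    linkers); ``families_per_clan`` groups consecutive domain families into
    shared clans.
    """

    n_families: int = 20
    members_range: tuple[int, int] = (10, 10)
    root_length_range: tuple[int, int] = (120, 250)
    identity_range: tuple[float, float] = (0.85, 0.95)
    truncation_range: tuple[float, float] = (0.0, 0.0)
    indel_rate: float = 0.01
    n_singletons: int = 50
    seed: int = 0
    domain_range: tuple[int, int] = (1, 1)
    families_per_clan: int = 1

    def __post_init__(self) -> None:
        lo, hi = self.identity_range
        if not (0 < lo <= hi <= 1):
            raise ParameterError("identity range must be within (0, 1]")
        lo, hi = self.truncation_range
        if not (0 <= lo <= hi < 1):
            raise ParameterError("truncation range must be within [0, 1)")
        if self.indel_rate < 0:
            raise ParameterError("indel rate must be non-negative")


@dataclass(frozen=True)
class GroundTruth:
    """id → family, id → architecture, family-label → clan."""

    family: dict[str, str]
    architectures: dict[str, tuple[str, ...]]
    clans: dict[str, str] = field(default_factory=dict)

    def clustering(self) -> Clustering:
        """True family partition (representative = first member per family)."""
        rep_of: dict[str, str] = {}
        assignment: dict[str, str] = {}
        for sid, fam in self.family.items():
            rep_of.setdefault(fam, sid)
            assignment[sid] = rep_of[fam]
        return Clustering(assignment)


def _uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    return lo if lo == hi else float(rng.uniform(lo, hi))


def simulate(spec: FamilySpec) -> tuple[SequenceDB, GroundTruth]:
    """Generate the dataset described by ``spec`` (fully seed-reproducible)."""
    rng = np.random.default_rng(spec.seed)
    records: list[Sequence] = []
    family: dict[str, str] = {}
    architectures: dict[str, tuple[str, ...]] = {}
    clans: dict[str, str] = {}
    linker = "GGSGG"
    for f in range(spec.n_families):
        fam_label = f"F{f:03d}"
        n_domains = int(rng.integers(spec.domain_range[0], spec.domain_range[1] + 1))
        domain_labels = (
            (fam_label,) if n_domains == 1
            else tuple(f"{fam_label}_D{d}" for d in range(n_domains))
        )
        if spec.families_per_clan > 1:
            for lbl in domain_labels:
                clans[lbl] = f"CL{f // spec.families_per_clan:03d}"
        roots = [
            random_protein(
                int(rng.integers(spec.root_length_range[0],
                                 spec.root_length_range[1] + 1)),
                rng,
            )
            for _ in range(n_domains)
        ]
        root = linker.join(roots) if n_domains > 1 else roots[0]
        n_members = int(rng.integers(spec.members_range[0], spec.members_range[1] + 1))
        for m in range(n_members):
            sid = f"{fam_label}_M{m:02d}"
            if m == 0:
                residues = root  # the family root itself anchors the family
            else:
                ident = _uniform(rng, *spec.identity_range)
                residues, _, _ = _mutate(root, ident, spec.indel_rate, rng)
                trunc = _uniform(rng, *spec.truncation_range)
                if trunc > 0:
                    cut = int(round(trunc * len(residues)))
                    if cut:
                        residues = (
                            residues[cut:] if rng.random() < 0.5 else residues[:-cut]
                        )
                if not residues:
                    residues = root
            records.append(Sequence(sid, residues))
            family[sid] = fam_label
            architectures[sid] = domain_labels
    for s in range(spec.n_singletons):
        sid = f"S{s:03d}"
        length = int(rng.integers(spec.root_length_range[0],
                                  spec.root_length_range[1] + 1))
        records.append(Sequence(sid, random_protein(length, rng)))
        family[sid] = sid
        architectures[sid] = (sid,)
    return SequenceDB(records), GroundTruth(family, architectures, clans)


def simulate_alignment_collection(
    spec: FamilySpec,
    count: int,
    rng: Optional[np.random.Generator] = None,
) -> list[ColumnAlignment]:
    """Column-level root/mutant alignments for the spaced-seed learner."""
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    out = []
    for _ in range(count):
        length = int(rng.integers(spec.root_length_range[0],
                                  spec.root_length_range[1] + 1))
        root = random_protein(length, rng)
        ident = _uniform(rng, *spec.identity_range)
        _, row_a, row_b = _mutate(root, ident, spec.indel_rate, rng)
        out.append(ColumnAlignment(row_a, row_b))
    return out
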