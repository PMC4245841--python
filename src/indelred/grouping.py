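"""Candidate redundant group construction.

Two indels can only be redundant if they have the same type and length and
sit close together, so the all-pairs comparison is restricted to *candidate
groups*: maximal chains of same-chromosome, same-type, same-length indels
in which each member lies within ``max_distance`` of the previous one.
Chaining distance is measured between start positions of adjacent records
after partitioning by (chrom, type, length); the comparison is ``<= D`` so
co-positioned duplicates group at any D >= 0.  Groups of one are discarded:
a singleton has nothing to be redundant with.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import groupby

from .io_model import IndelRecord, IndelType, InputError

__all__ = ["GroupingConfig", "CandidateGroup", "cluster_candidates", "pair_count"]

DEFAULT_MAX_DISTANCE = 100


@dataclass(frozen=True)
class GroupingConfig:
    """``max_distance`` is the adjacency threshold D in base pairs."""

    max_distance: int = DEFAULT_MAX_DISTANCE

    def __post_init__(self) -> None:
        if self.max_distance < 0:
            raise InputError(f"max_distance must be >= 0, got {self.max_distance}")


@dataclass
class CandidateGroup:
    group_id: int
    chrom: str
    type: IndelType
    length: int
    members: list[IndelRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.members)


def cluster_candidates(
    indels: list[IndelRecord], config: GroupingConfig = GroupingConfig()
) -> list[CandidateGroup]:
    """Partition by (chrom, type, length), then chain by adjacency <= D.

    Group ids are sequential from 0 in (chrom, type, length, first-pos)
    order; output is fully deterministic for a given input set.
    """
    D = config.max_distance
    keyed = sorted(
        indels,
        key=lambda r: (r.chrom, r.type.value, r.length, r.pos, r.id),
    )
    groups: list[CandidateGroup] = []
    for (chrom, type_v, length), part in groupby(
        keyed, key=lambda r: (r.chrom, r.type.value, r.length)
    ):
        chain: list[IndelRecord] = []
        for rec in part:
            if chain and rec.pos - chain[-1].pos > D:
                if len(chain) >= 2:
                    groups.append(
                        CandidateGroup(0, chrom, IndelType(type_v), length, chain)
                    )
                chain = []
            chain.append(rec)
        if len(chain) >= 2:  # flush the trailing chain
            groups.append(CandidateGroup(0, chrom, IndelType(type_v), length, chain))
    groups.sort(key=lambda g: (g.chrom, g.type.value, g.length, g.members[0].pos))
    for i, g in enumerate(groups):
        g.group_id = i
    return groups


def pair_count(groups: list[CandidateGroup]) -> int:
    """Number of unordered pairs the redundancy check will examine."""
    return sum(len(g) * (len(g) - 1) // 2 for g in groups)
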