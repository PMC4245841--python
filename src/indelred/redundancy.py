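"""Redundancy decision, equivalence clustering, and rate summaries.

Two same-type, same-length indels A and B (A not after B) are *redundant*
when applying either to the reference yields the identical chromosome.
Comparing full chromosomes is wasteful, so the decision works on a local
template substring instead:

* insertions — template = reference[P_A .. P_B - 1]; A's variant string is
  ``allele_A + template`` and B's is ``template + allele_B``; the indels
  are redundant iff the two variant strings are equal.
* deletions  — template = reference[P_A .. P_B + L - 1]; A's variant drops
  the template's first L characters, B's drops the last L; equality again
  decides redundancy.

Under the "insert immediately before pos" coordinate convention this local
comparison is *exactly* equivalent to full-sequence comparison (both
chromosomes share the prefix before P_A and the suffix after the template
window); :func:`apply_indel` is the brute-force oracle that property tests
use to pin this down.

Because redundancy is full-sequence equality it is an equivalence relation,
so redundant pairs within a candidate group are merged into clusters by
union-find and each cluster keeps its leftmost member as representative.
The number of *redundant* indels is the number of cluster members minus the
number of clusters (one survivor per cluster).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

from .grouping import CandidateGroup, GroupingConfig
from .io_model import ComputationError, IndelRecord, IndelType, ReferenceGenome

__all__ = [
    "VariantSubstringPair",
    "RedundancyCluster",
    "TypeCounts",
    "RedundancyReport",
    "build_variant_pair",
    "pair_redundant",
    "apply_indel",
    "find_clusters",
    "summarize",
    "nonredundant_records",
]


@dataclass(frozen=True)
class VariantSubstringPair:
    template: str
    v_a: str
    v_b: str


@dataclass
class RedundancyCluster:
    cluster_id: int
    members: list[IndelRecord]

    @property
    def representative(self) -> IndelRecord:
        return min(self.members, key=lambda r: (r.pos, r.id))

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class TypeCounts:
    total: int
    redundant: int

    @property
    def rate(self) -> float:
        return self.redundant / self.total if self.total else 0.0


@dataclass
class RedundancyReport:
    clusters: list[RedundancyCluster]
    overall: TypeCounts
    ins: TypeCounts
    dels: TypeCounts
    max_distance: int


def _check_pair_preconditions(a: IndelRecord, b: IndelRecord) -> None:
    if a.chrom != b.chrom:
        raise ComputationError(f"pair {a.id}/{b.id}: different chromosomes")
    if a.type is not b.type:
        raise ComputationError(f"pair {a.id}/{b.id}: different types")
    if a.length != b.length:
        raise ComputationError(f"pair {a.id}/{b.id}: different lengths")
    if a.pos > b.pos:
        raise ComputationError(f"pair {a.id}/{b.id}: A must not be after B")


def build_variant_pair(
    a: IndelRecord, b: IndelRecord, ref: ReferenceGenome
) -> VariantSubstringPair:
    """Template and both variant substrings for an ordered candidate pair."""
    _check_pair_preconditions(a, b)
    L = a.length
    if a.type is IndelType.INS:
        template = ref.fetch(a.chrom, a.pos, b.pos - 1)
        return VariantSubstringPair(template, a.allele + template, template + b.allele)
    template = ref.fetch(a.chrom, a.pos, b.pos + L - 1)
    return VariantSubstringPair(template, template[L:], template[:-L])


def pair_redundant(a: IndelRecord, b: IndelRecord, ref: ReferenceGenome) -> bool:
    """True iff a and b produce the identical mutated sequence."""
    if a.type is not b.type or a.length != b.length or a.chrom != b.chrom:
        return False
    if a.pos > b.pos or (a.pos == b.pos and a.id > b.id):
        a, b = b, a
    pair = build_variant_pair(a, b, ref)
    return pair.v_a == pair.v_b


def apply_indel(indel: IndelRecord, ref: ReferenceGenome) -> str:
    """Full mutated chromosome — the brute-force redundancy oracle.

    INS inserts the allele immediately before ``pos``; DEL removes
    ``[pos, pos + L - 1]`` and requires the allele to match the reference
    there.
    """
    seq = ref.sequence(indel.chrom)
    i = indel.pos - 1
    if indel.type is IndelType.INS:
        if indel.pos > len(seq) + 1:
            raise ComputationError(f"indel {indel.id}: pos beyond chromosome end")
        return seq[:i] + indel.allele + seq[i:]
    end = i + indel.length
    if end > len(seq):
        raise ComputationError(f"indel {indel.id}: deletion window out of bounds")
    if seq[i:end] != indel.allele:
        raise ComputationError(
            f"indel {indel.id}: deletion allele {indel.allele!r} does not match "
            f"reference {seq[i:end]!r} at pos {indel.pos}"
        )
    return seq[:i] + seq[end:]


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x: int, y: int) -> None:
        rx, ry = self.find(x), self.find(y)
        if rx != ry:
            self.parent[ry] = rx


def find_clusters(
    groups: list[CandidateGroup], ref: ReferenceGenome
) -> list[RedundancyCluster]:
    """All-pairs redundancy within each candidate group, merged by union-find.

    Sequence equality is transitive, so connected components are genuine
    equivalence classes.  Cluster ids are sequential in (chrom,
    representative pos, representative id) order.
    """
    clusters: list[RedundancyCluster] = []
    for group in groups:
        members = group.members
        uf = _UnionFind(len(members))
        for (i, a), (j, b) in combinations(enumerate(members), 2):
            try:
                if pair_redundant(a, b, ref):
                    uf.union(i, j)
            except ComputationError as exc:
                raise ComputationError(
                    f"group {group.group_id}, pair {a.id}/{b.id}: {exc}"
                ) from None
        comps: dict[int, list[IndelRecord]] = {}
        for i, rec in enumerate(members):
            comps.setdefault(uf.find(i), []).append(rec)
        for comp in comps.values():
            if len(comp) >= 2:
                comp.sort(key=lambda r: (r.pos, r.id))
                clusters.append(RedundancyCluster(0, comp))
    clusters.sort(
        key=lambda c: (
            c.members[0].chrom,
            c.representative.pos,
            c.representative.id,
        )
    )
    for i, c in enumerate(clusters):
        c.cluster_id = i
    return clusters


def summarize(
    clusters: list[RedundancyCluster],
    all_indels: list[IndelRecord],
    config: GroupingConfig = GroupingConfig(),
) -> RedundancyReport:
    """Per-type and overall redundancy counts and rates.

    Each cluster of size m contributes m - 1 redundant indels (one member
    is kept as the representative annotation).
    """
    totals = {IndelType.INS: 0, IndelType.DEL: 0}
    for rec in all_indels:
        totals[rec.type] += 1
    redundant = {IndelType.INS: 0, IndelType.DEL: 0}
    for cluster in clusters:
        redundant[cluster.members[0].type] += len(cluster) - 1
    ins = TypeCounts(totals[IndelType.INS], redundant[IndelType.INS])
    dels = TypeCounts(totals[IndelType.DEL], redundant[IndelType.DEL])
    overall = TypeCounts(ins.total + dels.total, ins.redundant + dels.redundant)
    return RedundancyReport(
        clusters=clusters, overall=overall, ins=ins, dels=dels,
        max_distance=config.max_distance,
    )


def nonredundant_records(
    clusters: list[RedundancyCluster], all_indels: list[IndelRecord]
) -> list[IndelRecord]:
    """Representatives plus every unclustered record, input order preserved."""
    drop: set[str] = set()
    for cluster in clusters:
        rep = cluster.representative
        drop.update(m.id for m in cluster.members if m.id != rep.id)
    return [rec for rec in all_indels if rec.id not in drop]
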