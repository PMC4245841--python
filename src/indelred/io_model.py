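"""Domain types and file I/O for indel redundancy analysis.

Coordinate convention
---------------------
All positions are 1-based and inclusive.  For a deletion, ``pos`` is the
first deleted base; for an insertion, the allele is inserted immediately
*before* the base at ``pos``.  The insertion convention is the unique one
under which the template-substring redundancy check (see
:mod:`indelred.redundancy`) is exactly equivalent to comparing the full
mutated chromosomes, and it is pinned down by property tests.

The canonical on-disk indel format is a five-column TSV with header
``id  chrom  pos  type  allele``; a small adapter converts anchored VCF
indel records into the same representation.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from Bio import SeqIO

__all__ = [
    "InputError",
    "ComputationError",
    "IndelType",
    "IndelRecord",
    "RawLoctypeRecord",
    "ReferenceGenome",
    "read_fasta",
    "write_fasta",
    "read_indel_tsv",
    "write_indel_tsv",
    "read_vcf_indels",
    "write_report",
    "INDEL_TSV_HEADER",
]

ALLELE_ALPHABET = frozenset("ACGTN")
INDEL_TSV_HEADER = "id\tchrom\tpos\ttype\tallele"


class InputError(ValueError):
    """Invalid or malformed user input (file contents, records, config)."""


class ComputationError(RuntimeError):
    """A computation could not be carried out on otherwise valid input."""


class IndelType(str, enum.Enum):
    INS = "INS"
    DEL = "DEL"

    @classmethod
    def _missing_(cls, value):
        if isinstance(value, str):
            return cls.__members__.get(value.upper())
        return None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class IndelRecord:
    """One indel annotation: identity, locus, type and allele.

    ``length`` is always ``len(allele)``; the allele is uppercased on
    construction and restricted to A/C/G/T/N.  N is treated as a literal
    character throughout (N matches N only): redundancy is defined on
    strings, not on base ambiguity.
    """

    id: str
    chrom: str
    pos: int
    type: IndelType
    allele: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "allele", self.allele.upper())
        object.__setattr__(self, "type", IndelType(self.type))
        if not self.id:
            raise InputError("indel id must be non-empty")
        if not self.allele:
            raise InputError(f"indel {self.id}: allele must be non-empty")
        if set(self.allele) - ALLELE_ALPHABET:
            bad = "".join(sorted(set(self.allele) - ALLELE_ALPHABET))
            raise InputError(
                f"indel {self.id}: allele contains illegal characters {bad!r}"
            )
        if self.pos < 1:
            raise InputError(f"indel {self.id}: pos must be >= 1, got {self.pos}")

    @property
    def length(self) -> int:
        return len(self.allele)

    def sort_key(self) -> tuple:
        return (self.chrom, self.pos, self.id)


@dataclass(frozen=True)
class RawLoctypeRecord:
    """An indel still carrying its raw alignment-type code.

    Only loctypes 1 and 3 (small indels) are accepted; range types are out
    of scope.  Resolution to INS/DEL semantics lives in
    :mod:`indelred.classify`.
    """

    id: str
    chrom: str
    pos: int
    loctype: int
    allele: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "allele", self.allele.upper())
        if self.loctype not in (1, 3):
            raise InputError(
                f"record {self.id}: loctype must be 1 or 3, got {self.loctype}"
            )
        if not self.allele or set(self.allele) - ALLELE_ALPHABET:
            raise InputError(f"record {self.id}: invalid allele {self.allele!r}")
        if self.pos < 1:
            raise InputError(f"record {self.id}: pos must be >= 1")

    @property
    def length(self) -> int:
        return len(self.allele)


class ReferenceGenome:
    """Chromosome name -> uppercase sequence, with 1-based inclusive lookup."""

    def __init__(self, sequences: Mapping[str, str]):
        self._seqs: dict[str, str] = {}
        for name, seq in sequences.items():
            if not seq:
                raise InputError(f"chromosome {name!r}: empty sequence")
            self._seqs[name] = seq.upper()

    def __contains__(self, chrom: str) -> bool:
        return chrom in self._seqs

    @property
    def chroms(self) -> list[str]:
        return list(self._seqs)

    def length(self, chrom: str) -> int:
        return len(self.sequence(chrom))

    def sequence(self, chrom: str) -> str:
        try:
            return self._seqs[chrom]
        except KeyError:
            raise InputError(f"unknown chromosome {chrom!r}") from None

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Substring at 1-based inclusive [start, end].

        ``end == start - 1`` yields the empty string (a zero-width window,
        needed for the degenerate insertion template); anything else outside
        the chromosome raises rather than silently truncating.
        """
        seq = self.sequence(chrom)
        if start < 1 or end > len(seq) or end < start - 1:
            raise InputError(
                f"window [{start}, {end}] out of bounds for {chrom} "
                f"(length {len(seq)})"
            )
        return seq[start - 1 : end]


def read_fasta(path: str | Path) -> ReferenceGenome:
    """Load a FASTA reference; headers truncated at first whitespace."""
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise InputError(f"duplicate chromosome name {rec.id!r} in {path}")
        seq = str(rec.seq).upper()
        if not re.fullmatch(r"[A-Z]+", seq or ""):
            raise InputError(f"record {rec.id!r}: empty or non-alphabetic sequence")
        seqs[rec.id] = seq
    if not seqs:
        raise InputError(f"no FASTA records in {path}")
    return ReferenceGenome(seqs)


def write_fasta(ref: ReferenceGenome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in ref.chroms:
            fh.write(f">{chrom}\n")
            seq = ref.sequence(chrom)
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_indel_tsv(path: str | Path) -> list[IndelRecord]:
    """Parse the canonical indel TSV; output sorted by (chrom, pos, id)."""
    records: list[IndelRecord] = []
    seen: set[str] = set()
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if header != INDEL_TSV_HEADER:
            raise InputError(
                f"{path}: bad header {header!r}, expected {INDEL_TSV_HEADER!r}"
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise InputError(f"{path}:{lineno}: expected 5 columns, got {len(fields)}")
            rid, chrom, pos_s, type_s, allele = fields
            try:
                pos = int(pos_s)
            except ValueError:
                raise InputError(f"{path}:{lineno}: non-integer pos {pos_s!r}") from None
            try:
                itype = IndelType(type_s.upper())
            except ValueError:
                raise InputError(f"{path}:{lineno}: unknown type {type_s!r}") from None
            try:
                rec = IndelRecord(id=rid, chrom=chrom, pos=pos, type=itype, allele=allele)
            except InputError as exc:
                raise InputError(f"{path}:{lineno}: {exc}") from None
            if rec.id in seen:
                raise InputError(f"{path}:{lineno}: duplicate id {rec.id!r}")
            seen.add(rec.id)
            records.append(rec)
    records.sort(key=IndelRecord.sort_key)
    return records


def write_indel_tsv(records: Iterable[IndelRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(INDEL_TSV_HEADER + "\n")
        for rec in records:
            fh.write(f"{rec.id}\t{rec.chrom}\t{rec.pos}\t{rec.type.value}\t{rec.allele}\n")


def read_vcf_indels(
    path: str | Path, ref: ReferenceGenome | None = None
) -> tuple[list[IndelRecord], int]:
    """Convert anchored VCF indel records to :class:`IndelRecord`.

    Convertible records have exactly one of REF/ALT of length 1, that base
    matching the first base of the longer allele (the usual left-anchored
    VCF indel shape).  For REF=A ALT=ATT at VCF pos p the result is an INS
    at ``p + 1`` with allele TT; for REF=ATT ALT=A a DEL at ``p + 1`` with
    allele TT.  Everything else (SNVs, complex or symbolic ALTs) is counted
    in ``skipped``, never raised.  Multi-allelic records expand to one
    candidate per ALT.
    """
    import pysam

    allele_re = re.compile(r"[ACGTN]+")
    records: list[IndelRecord] = []
    seen: set[str] = set()
    skipped = 0
    try:
        vcf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise InputError(f"cannot read VCF {path}: {exc}") from None
    with vcf:
        for rec in vcf:
            vref = (rec.ref or "").upper()
            if ref is not None and rec.chrom in ref:
                window = ref.fetch(rec.chrom, rec.pos, rec.pos + len(vref) - 1)
                if window != vref:
                    raise InputError(
                        f"VCF record {rec.id or rec.chrom + ':' + str(rec.pos)}: "
                        f"REF {vref!r} disagrees with reference {window!r}"
                    )
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                alt = (alt or "").upper()
                if not allele_re.fullmatch(alt) or not allele_re.fullmatch(vref):
                    skipped += 1
                    continue
                if len(vref) == 1 and len(alt) > 1 and alt[0] == vref:
                    itype, allele = IndelType.INS, alt[1:]
                elif len(alt) == 1 and len(vref) > 1 and vref[0] == alt:
                    itype, allele = IndelType.DEL, vref[1:]
                else:
                    skipped += 1
                    continue
                base_id = rec.id or f"{rec.chrom}_{rec.pos}"
                rid = base_id if len(alts) == 1 else f"{base_id}_alt{i + 1}"
                while rid in seen:
                    rid += "x"
                seen.add(rid)
                records.append(
                    IndelRecord(
                        id=rid, chrom=rec.chrom, pos=rec.pos + 1,
                        type=itype, allele=allele,
                    )
                )
    records.sort(key=IndelRecord.sort_key)
    return records, skipped


def _pct(numer: int, denom: int) -> str:
    return f"{(100.0 * numer / denom if denom else 0.0):.2f}"


def write_report(report, prefix: str | Path) -> tuple[Path, Path]:
    """Write a redundancy report as ``<prefix>.clusters.tsv`` + ``<prefix>.summary.txt``.

    The cluster TSV has one row per cluster member; the summary is a
    key-value block with totals and redundancy rates (percentages, two
    decimals) overall and per type.
    """
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    clusters_path = prefix.with_name(prefix.name + ".clusters.tsv")
    summary_path = prefix.with_name(prefix.name + ".summary.txt")

    with open(clusters_path, "w") as fh:
        fh.write("cluster_id\trepresentative_id\tmember_id\tchrom\ttype\tlength\tpos\n")
        for cluster in report.clusters:
            rep = cluster.representative
            for m in cluster.members:
                fh.write(
                    f"{cluster.cluster_id}\t{rep.id}\t{m.id}\t{m.chrom}\t"
                    f"{m.type.value}\t{m.length}\t{m.pos}\n"
                )

    lines = [
        ("max_distance", str(report.max_distance)),
        ("total_indels", str(report.overall.total)),
        ("redundant_total", str(report.overall.redundant)),
        ("redundancy_rate_total", _pct(report.overall.redundant, report.overall.total)),
        ("total_ins", str(report.ins.total)),
        ("redundant_ins", str(report.ins.redundant)),
        ("redundancy_rate_ins", _pct(report.ins.redundant, report.ins.total)),
        ("total_del", str(report.dels.total)),
        ("redundant_del", str(report.dels.redundant)),
        ("redundancy_rate_del", _pct(report.dels.redundant, report.dels.total)),
        ("n_clusters", str(len(report.clusters))),
    ]
    with open(summary_path, "w") as fh:
        for key, val in lines:
            fh.write(f"{key}\t{val}\n")
    return clusters_path, summary_path
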