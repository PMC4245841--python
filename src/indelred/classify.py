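"""Resolve raw alignment-type codes to INS/DEL semantics.

dbSNP-style annotations mark small indels with a numeric loctype rather
than an explicit direction relative to the reference.  Empirically,
loctype 1 behaves as a deletion of reference sequence and loctype 3 as an
insertion: a deletion's allele must exist verbatim in the reference at the
annotated position, an insertion's need not.  The audit below makes that
check explicit, and the validation step quarantines deletion records whose
allele cannot be found (they cannot represent a deletion of the reference
and would poison the template-substring comparison downstream).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .io_model import (
    IndelRecord,
    IndelType,
    InputError,
    RawLoctypeRecord,
    ReferenceGenome,
)

__all__ = [
    "LoctypeAudit",
    "allele_present_at",
    "audit_loctypes",
    "resolve_types",
    "validate_deletions",
    "write_rejects_tsv",
]

LOCTYPE_TO_TYPE = {1: IndelType.DEL, 3: IndelType.INS}


@dataclass
class LoctypeAudit:
    """Per-loctype tally of allele presence in the reference."""

    total: int = 0
    allele_found: int = 0
    allele_missing: int = 0

    @property
    def fraction_missing(self) -> float:
        return self.allele_missing / self.total if self.total else 0.0


def allele_present_at(
    ref: ReferenceGenome, chrom: str, pos: int, allele: str
) -> bool:
    """True iff the reference carries ``allele`` verbatim at 1-based ``pos``.

    An out-of-bounds window is simply ``False``; an unknown chromosome is an
    error (the caller supplied the wrong reference).
    """
    if chrom not in ref:
        raise InputError(f"unknown chromosome {chrom!r}")
    if pos < 1:
        raise InputError(f"pos must be >= 1, got {pos}")
    end = pos + len(allele) - 1
    if end > ref.length(chrom):
        return False
    return ref.fetch(chrom, pos, end) == allele.upper()


def audit_loctypes(
    records: list[RawLoctypeRecord], ref: ReferenceGenome
) -> tuple[dict[int, LoctypeAudit], list[RawLoctypeRecord]]:
    """Count, per loctype, how many alleles are found in the reference.

    Records on chromosomes absent from the reference are excluded from the
    counts and returned separately.
    """
    audits: dict[int, LoctypeAudit] = {}
    failures: list[RawLoctypeRecord] = []
    for rec in records:
        if rec.chrom not in ref:
            failures.append(rec)
            continue
        audit = audits.setdefault(rec.loctype, LoctypeAudit())
        audit.total += 1
        if allele_present_at(ref, rec.chrom, rec.pos, rec.allele):
            audit.allele_found += 1
        else:
            audit.allele_missing += 1
    return audits, failures


def resolve_types(records: list[RawLoctypeRecord]) -> list[IndelRecord]:
    """Map loctype 1 -> DEL, loctype 3 -> INS; all other fields copied."""
    out = []
    for rec in records:
        try:
            itype = LOCTYPE_TO_TYPE[rec.loctype]
        except KeyError:
            raise InputError(
                f"record {rec.id}: unsupported loctype {rec.loctype}"
            ) from None
        out.append(
            IndelRecord(
                id=rec.id, chrom=rec.chrom, pos=rec.pos,
                type=itype, allele=rec.allele,
            )
        )
    return out


def validate_deletions(
    records: list[IndelRecord], ref: ReferenceGenome
) -> tuple[list[IndelRecord], list[tuple[IndelRecord, str]]]:
    """Split records into analysable ones and flagged rejects.

    A DEL whose allele is not present at its position cannot be a deletion
    of the reference and is rejected with a reason; so is any record on an
    unknown chromosome.  INS alleles are deliberately not checked — an
    inserted sequence need not occur in the reference.
    """
    kept: list[IndelRecord] = []
    rejects: list[tuple[IndelRecord, str]] = []
    for rec in records:
        if rec.chrom not in ref:
            rejects.append((rec, "unknown_chromosome"))
        elif rec.type is IndelType.DEL and not allele_present_at(
            ref, rec.chrom, rec.pos, rec.allele
        ):
            rejects.append((rec, "deletion_allele_not_in_reference"))
        else:
            kept.append(rec)
    return kept, rejects


def write_rejects_tsv(
    rejects: list[tuple[IndelRecord, str]], path: str | Path
) -> None:
    with open(path, "w") as fh:
        fh.write("id\tchrom\tpos\ttype\tallele\treason\n")
        for rec, reason in rejects:
            fh.write(
                f"{rec.id}\t{rec.chrom}\t{rec.pos}\t{rec.type.value}\t"
                f"{rec.allele}\t{reason}\n"
            )
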