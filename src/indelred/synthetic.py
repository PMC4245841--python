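"""Synthetic references and indel sets with known ground truth.

Redundant indel annotations arise in tandem repeats: inserting or deleting
one repeat unit produces the same sequence no matter which copy of the
unit the annotation points at, so equally optimal alignments report the
variant at different positions.  The generator mirrors that mechanism
directly: it plants homopolymer and di-/tri-nucleotide tandem tracts into
a random background sequence, then emits equivalence classes by sliding a
unit-sized indel along a tract one period at a time.  Every planted class
is verified equivalent through the full-sequence mutation oracle before it
is emitted, so the truth partition is guaranteed correct by construction.

Singleton (non-redundant) indels are placed at Gamma-distributed gaps with
Pareto-distributed sizes — the distance and size laws observed for real
indel catalogues — with deletion alleles copied from the reference so that
every deletion is valid.  Defaults correspond to genome-wide average
estimates for human indels: Pareto size shape 1.43 and Gamma distance
parameters (0.4, 8.09e-4), giving a mean spacing near 500 bp.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .io_model import (
    IndelRecord,
    IndelType,
    InputError,
    ReferenceGenome,
)
from .redundancy import apply_indel
from .stats import Family

__all__ = [
    "SimConfig",
    "SimTruth",
    "RepeatTract",
    "simulate_reference",
    "find_repeat_tracts",
    "simulate_indels",
    "simulate",
    "sample_distribution",
    "write_truth_json",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated chromosome.

    ``planted_redundancy_rate`` is the fraction of emitted annotations that
    are redundant copies of another annotation; ``repeat_density`` is the
    fraction of the chromosome covered by planted repeat tracts.
    """

    seed: int
    chrom: str = "sim1"
    chrom_length: int = 250_000
    repeat_density: float = 0.15
    n_indels: int = 300
    planted_redundancy_rate: float = 0.2
    pareto_shape: float = 1.43
    gamma_shape: float = 0.4
    gamma_rate: float = 8.09e-4
    max_distance_within_cluster: int = 100

    def __post_init__(self) -> None:
        if self.chrom_length < 100:
            raise InputError("chrom_length too small")
        if not 0.0 <= self.repeat_density < 0.9:
            raise InputError("repeat_density must be in [0, 0.9)")
        if not 0.0 <= self.planted_redundancy_rate <= 1.0:
            raise InputError("planted_redundancy_rate must be in [0, 1]")
        for name in ("pareto_shape", "gamma_shape", "gamma_rate"):
            if getattr(self, name) <= 0:
                raise InputError(f"{name} must be positive")
        if self.n_indels < 1 or self.max_distance_within_cluster < 1:
            raise InputError("n_indels and max_distance_within_cluster must be >= 1")


@dataclass(frozen=True)
class RepeatTract:
    """A planted or detected tandem tract: 1-based [start, end], unit period."""

    start: int
    end: int
    period: int

    @property
    def copies(self) -> int:
        return (self.end - self.start + 1) // self.period


@dataclass
class SimTruth:
    reference: ReferenceGenome
    records: list[IndelRecord]
    partition: list[list[str]]  # id-sets; classes of size >= 2 are redundant
    config: SimConfig

    @property
    def expected_redundant(self) -> int:
        return sum(len(c) - 1 for c in self.partition if len(c) >= 2)

    @property
    def expected_rate(self) -> float:
        return self.expected_redundant / len(self.records) if self.records else 0.0


def _plant_tracts(
    seq: np.ndarray, config: SimConfig, rng: np.random.Generator
) -> list[RepeatTract]:
    L = config.chrom_length
    target = int(round(config.repeat_density * L))
    planted = 0
    occupied = np.zeros(L, dtype=bool)
    tracts: list[RepeatTract] = []
    attempts = 0
    while planted < target:
        period = int(rng.integers(1, 4))  # homopolymer, di- or tri-nucleotide
        copies = int(rng.integers(4, 13)) if period == 1 else int(rng.integers(4, 11))
        tract_len = period * copies
        attempts += 1
        if attempts > 50 * max(1, target):
            raise InputError(
                "requested repeat_density not achievable on this chromosome"
            )
        start0 = int(rng.integers(0, L - tract_len))  # 0-based
        if occupied[start0 : start0 + tract_len].any():
            continue
        unit = rng.choice(_BASES, size=period)
        seq[start0 : start0 + tract_len] = np.tile(unit, copies)
        occupied[start0 : start0 + tract_len] = True
        tracts.append(RepeatTract(start0 + 1, start0 + tract_len, period))
        planted += tract_len
    tracts.sort(key=lambda t: t.start)
    return tracts


def _reference_with_tracts(config: SimConfig) -> tuple[str, list[RepeatTract]]:
    rng = np.random.default_rng(config.seed)
    seq = rng.choice(_BASES, size=config.chrom_length)
    tracts = _plant_tracts(seq, config, rng)
    return "".join(seq), tracts


def simulate_reference(config: SimConfig) -> str:
    """Deterministic repeat-rich chromosome for the given seed."""
    return _reference_with_tracts(config)[0]


def find_repeat_tracts(seq: str, min_copies: int = 4) -> list[RepeatTract]:
    """Maximal perfect tandem tracts of period 1-3 with >= min_copies copies.

    Works on any sequence (planted or natural), so indel placement does not
    depend on private generator state.
    """
    n = len(seq)
    tracts: list[RepeatTract] = []
    covered_until = 0
    i = 0
    while i < n:
        best: RepeatTract | None = None
        for period in (1, 2, 3):
            j = i + period
            while j < n and seq[j] == seq[j - period]:
                j += 1
            copies = (j - i) // period
            if copies >= min_copies:
                cand = RepeatTract(i + 1, i + copies * period, period)
                if best is None or cand.end - cand.start > best.end - best.start:
                    best = cand
        if best is not None and best.end > covered_until:
            tracts.append(best)
            covered_until = best.end
            i = best.end  # jump past the tract
        else:
            i += 1
    return tracts


def _class_sizes(n_extra: int, rng: np.random.Generator) -> list[int]:
    """Split the extra-annotation budget into class sizes (mostly pairs)."""
    sizes = []
    while n_extra > 0:
        c = 3 if (n_extra >= 2 and rng.random() < 0.2) else 2
        sizes.append(c)
        n_extra -= c - 1
    return sizes


def simulate_indels(ref_seq: str, config: SimConfig) -> SimTruth:
    """Emit indel annotations with a known equivalence partition.

    Redundant classes slide a unit-sized indel along a repeat tract one
    period at a time (each emitted class is re-verified with the
    full-sequence oracle); singletons are Gamma-spaced with Pareto sizes
    and avoid the used tracts.
    """
    rng = np.random.default_rng((config.seed, 1))
    ref = ReferenceGenome({config.chrom: ref_seq})
    L = len(ref_seq)

    n_extra = int(round(config.planted_redundancy_rate * config.n_indels))
    class_sizes = _class_sizes(n_extra, rng)
    n_singletons = config.n_indels - n_extra - len(class_sizes)
    if n_singletons < 0:
        raise InputError("planted_redundancy_rate too high for n_indels")

    tracts = [
        t
        for t in find_repeat_tracts(ref_seq)
        if t.period <= config.max_distance_within_cluster
    ]
    if class_sizes and not tracts:
        raise InputError(
            "cannot place planted redundancy: no usable repeat tracts; "
            "increase repeat_density"
        )
    usable = [t for t in tracts if t.copies >= max(class_sizes, default=0)]
    if len(usable) < len(class_sizes):
        raise InputError(
            f"cannot place {len(class_sizes)} redundant classes: only "
            f"{len(usable)} sufficiently long repeat tracts; increase "
            "repeat_density or chrom_length"
        )
    chosen_idx = rng.choice(len(usable), size=len(class_sizes), replace=False)
    chosen = [usable[int(i)] for i in chosen_idx]

    records: list[IndelRecord] = []
    partition: list[list[str]] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"sim{counter:06d}"

    blocked = np.zeros(L + 2, dtype=bool)  # 1-based; margin for pos L+1
    for t in chosen:
        blocked[max(1, t.start - 3) : min(L, t.end + 3) + 1] = True

    for tract, csize in zip(chosen, class_sizes):
        p = tract.period
        itype = IndelType.INS if rng.random() < 0.5 else IndelType.DEL
        ids: list[str] = []
        class_records: list[IndelRecord] = []
        for k in range(csize):
            pos = tract.start + k * p
            allele = ref.fetch(config.chrom, pos, pos + p - 1)
            rec = IndelRecord(
                id=next_id(), chrom=config.chrom, pos=pos, type=itype, allele=allele
            )
            class_records.append(rec)
            ids.append(rec.id)
        # generation-time oracle check: no false planted equivalences
        mutated0 = apply_indel(class_records[0], ref)
        for rec in class_records[1:]:
            if apply_indel(rec, ref) != mutated0:
                raise AssertionError(
                    f"planted class at tract {tract} failed the oracle check"
                )
        records.extend(class_records)
        partition.append(ids)

    # Gamma-spaced singletons outside the used tracts
    cursor = 1
    placed = 0
    attempts = 0
    while placed < n_singletons:
        attempts += 1
        if attempts > 100 * config.n_indels:
            raise InputError(
                "could not place all singleton indels; increase chrom_length"
            )
        gap = max(1, int(np.ceil(rng.gamma(config.gamma_shape, 1.0 / config.gamma_rate))))
        cursor += gap
        if cursor > L - 1:
            cursor = 1 + int(rng.integers(1, L // 2))  # wrap into free space
            continue
        size = int(np.ceil(sample_distribution(
            Family.PARETO, {"shape": config.pareto_shape}, 1, rng=rng
        )[0]))
        itype = IndelType.INS if rng.random() < 0.5 else IndelType.DEL
        if itype is IndelType.DEL and cursor + size - 1 > L:
            continue
        if blocked[cursor : min(L, cursor + size) + 1].any():
            continue
        if itype is IndelType.DEL:
            allele = ref.fetch(config.chrom, cursor, cursor + size - 1)
        else:
            allele = "".join(rng.choice(_BASES, size=size))
        rec = IndelRecord(
            id=next_id(), chrom=config.chrom, pos=cursor, type=itype, allele=allele
        )
        records.append(rec)
        partition.append([rec.id])
        placed += 1

    records.sort(key=IndelRecord.sort_key)
    return SimTruth(reference=ref, records=records, partition=partition, config=config)


def simulate(config: SimConfig) -> SimTruth:
    """Reference + indels in one call."""
    return simulate_indels(simulate_reference(config), config)


def sample_distribution(
    family: Family | str,
    params: dict,
    n: int,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Seeded i.i.d. draws from one of the four fitted families.

    Pareto (location 1) uses the inverse CDF ``(1 - u)^(-1/shape)``; the
    others use the standard numpy samplers.
    """
    if rng is None:
        if seed is None:
            raise InputError("either seed or rng must be given")
        rng = np.random.default_rng(seed)
    family = Family(family)
    if n < 1:
        raise InputError("n must be >= 1")
    if any(v <= 0 for v in params.values()):
        raise InputError("distribution parameters must be positive")
    if family is Family.PARETO:
        u = rng.random(n)
        return (1.0 - u) ** (-1.0 / params["shape"])
    if family is Family.GAMMA:
        return rng.gamma(params["shape"], 1.0 / params["rate"], size=n)
    if family is Family.EXPONENTIAL:
        return rng.exponential(1.0 / params["rate"], size=n)
    if family is Family.WEIBULL:
        return params["scale"] * rng.weibull(params["shape"], size=n)
    raise InputError(f"unknown family {family!r}")  # pragma: no cover


def write_truth_json(truth: SimTruth, path: str | Path) -> None:
    payload = {
        "chrom": truth.config.chrom,
        "seed": truth.config.seed,
        "n_records": len(truth.records),
        "partition": truth.partition,
        "expected_redundant": truth.expected_redundant,
        "expected_rate": truth.expected_rate,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")
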