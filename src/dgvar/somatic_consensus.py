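"""Multi-caller somatic consensus and hard filters.

Somatic SNVs/indels are consumed as normalized per-caller VCFs (MuTect2,
Strelka, VarScan, SomaticSniper; indels from Strelka/VarScan only — that is
a property of the inputs, not enforced here). Variants are aggregated by
(tumor, locus) and retained only when identified by at least two callers,
then filtered on: tumor depth >= 10, >= 3 alt-supporting reads, tumor
VAF >= 5%, normal VAF <= 1%, dbSNP membership (unless also in COSMIC), and
a platform artifact blacklist. The filters are conjunctive, so their order
is irrelevant; removals are attributed to the first failing criterion for
trace accounting only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pandas as pd
import pysam

from .errors import InputError, ParseError
from .io_cohort import VariantKey

CALLERS = ("mutect2", "strelka", "varscan", "somaticsniper")

SOMATIC_FILTER_ORDER = (
    "tumor_depth",
    "tumor_alt",
    "tumor_vaf",
    "normal_vaf",
    "dbsnp_not_cosmic",
    "artifact",
)


@dataclass(frozen=True)
class SomaticCall:
    tumor_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    callers: frozenset[str]
    tumor_depth: int
    tumor_alt: int
    normal_vaf: float
    dbsnp: bool = False
    cosmic: bool = False
    artifact_flag: bool = False

    def __post_init__(self) -> None:
        if not self.callers:
            raise InputError("somatic call must name at least one caller")

    @property
    def key(self) -> VariantKey:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def tumor_vaf(self) -> float:
        return self.tumor_alt / self.tumor_depth if self.tumor_depth > 0 else 0.0

    @property
    def is_indel(self) -> bool:
        return len(self.ref) != 1 or len(self.alt) != 1


@dataclass(frozen=True)
class CopyNumberEvent:
    tumor_id: str
    gene: str
    direction: str  # loss | gain

    def __post_init__(self) -> None:
        if self.direction not in ("loss", "gain"):
            raise InputError(f"bad copy-number direction {self.direction!r}")


def read_caller_vcf(path: str | Path, caller: str, tumor_id: str) -> list[SomaticCall]:
    """Read one caller's normalized VCF.

    Expected INFO keys: TDP (tumor depth), TAD (tumor alt reads), NVAF
    (normal VAF); flags DB (dbSNP) and COS (COSMIC).
    """
    if caller not in CALLERS:
        raise InputError(f"unknown caller {caller!r}; expected one of {CALLERS}")
    try:
        vcf = pysam.VariantFile(str(path))
    except (ValueError, OSError) as exc:
        raise ParseError(f"{path}: malformed VCF ({exc})") from exc
    calls = []
    with vcf:
        for rec in vcf:
            info = rec.info
            for alt in rec.alts or ():
                calls.append(
                    SomaticCall(
                        tumor_id=tumor_id,
                        chrom=rec.chrom,
                        pos=rec.pos,
                        ref=rec.ref,
                        alt=str(alt),
                        callers=frozenset({caller}),
                        tumor_depth=int(info.get("TDP", 0)),
                        tumor_alt=int(info.get("TAD", 0)),
                        normal_vaf=float(info.get("NVAF", 0.0)),
                        dbsnp=bool(info.get("DB", False)),
                        cosmic=bool(info.get("COS", False)),
                    )
                )
    return calls


def merge_callers(
    per_caller_calls: Mapping[str, Iterable[SomaticCall]]
) -> list[SomaticCall]:
    """Union by (tumor, locus); keep calls supported by >= 2 callers.

    Duplicate loci within one caller's list are deduplicated with a warning.
    Per-call numeric fields are taken from the first supporting caller in
    canonical caller order (inputs are normalized, so they agree).
    """
    merged: dict[tuple[str, VariantKey], SomaticCall] = {}
    for caller in sorted(per_caller_calls, key=lambda c: CALLERS.index(c)):
        seen: set[tuple[str, VariantKey]] = set()
        for call in per_caller_calls[caller]:
            # each input list speaks for exactly one caller
            if call.callers != frozenset({caller}):
                call = replace(call, callers=frozenset({caller}))
            k = (call.tumor_id, call.key)
            if k in seen:
                warnings.warn(f"duplicate locus {call.key} in {caller} output; deduplicated")
                continue
            seen.add(k)
            if k in merged:
                prev = merged[k]
                merged[k] = replace(prev, callers=prev.callers | call.callers)
            else:
                merged[k] = call
    consensus = [c for c in merged.values() if len(c.callers) >= 2]
    consensus.sort(key=lambda c: (c.tumor_id, c.chrom, c.pos, c.ref, c.alt))
    return consensus


def apply_somatic_filters(
    calls: Iterable[SomaticCall],
    blacklist: set[VariantKey] | frozenset = frozenset(),
    min_tumor_depth: int = 10,
    min_tumor_alt: int = 3,
    min_tumor_vaf: float = 0.05,
    max_normal_vaf: float = 0.01,
) -> tuple[list[SomaticCall], dict[str, int]]:
    """Hard somatic filters; returns (retained, per-criterion removal counts)."""
    retained = []
    removed = {name: 0 for name in SOMATIC_FILTER_ORDER}
    for call in calls:
        entries = (
            ("tumor_depth", call.tumor_depth >= min_tumor_depth),
            ("tumor_alt", call.tumor_alt >= min_tumor_alt),
            ("tumor_vaf", call.tumor_vaf >= min_tumor_vaf),
            ("normal_vaf", call.normal_vaf <= max_normal_vaf),
            ("dbsnp_not_cosmic", not (call.dbsnp and not call.cosmic)),
            ("artifact", not (call.artifact_flag or call.key in blacklist)),
        )
        if all(ok for _, ok in entries):
            retained.append(call)
        else:
            removed[next(name for name, ok in entries if not ok)] += 1
    return retained, removed


def read_cn_events(path: str | Path) -> list[CopyNumberEvent]:
    """Gene-level copy-number events TSV: tumor_id, gene, direction."""
    df = pd.read_csv(path, sep="\t")
    for col in ("tumor_id", "gene", "direction"):
        if col not in df.columns:
            raise ParseError(f"{path}: copy-number table needs column {col!r}")
    events = []
    seen = set()
    for row in df.itertuples(index=False):
        ev = CopyNumberEvent(str(row.tumor_id), str(row.gene), str(row.direction))
        k = (ev.tumor_id, ev.gene, ev.direction)
        if k in seen:
            continue  # one event per (tumor, gene, direction)
        seen.add(k)
        events.append(ev)
    return events
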