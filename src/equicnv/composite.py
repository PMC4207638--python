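"""Cross-study CNVR integration into a composite dataset.

CNV/CNVR records from multiple studies are normalized onto a common
1-based inclusive coordinate convention and merged positionally with the
same relation used for within-cohort consolidation (overlap ≥1 base or a
shared boundary coordinate, transitive). A composite region is *shared*
when at least two studies contribute to it and *novel* (study-specific)
otherwise. Merging is purely positional; gain/loss state is carried as
metadata but never prevents a merge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .genome import GenomeBuild
from .intervals import merge_groups

__all__ = [
    "StudyCnvr",
    "CompositeCnvr",
    "normalize_records",
    "integrate_studies",
    "novelty_accounting",
]

CONVENTIONS = ("one_based_inclusive", "bed_half_open")


@dataclass(frozen=True)
class StudyCnvr:
    study_id: str
    chromosome: str
    start: int  # 1-based inclusive after normalization
    end: int
    state: str | None = None
    n_carriers: int | None = None

    def __post_init__(self) -> None:
        if self.end < self.start or self.start < 1:
            raise ValueError(
                f"invalid record {self.study_id} {self.chromosome}:{self.start}-{self.end}"
            )


@dataclass(frozen=True)
class CompositeCnvr:
    chromosome: str
    start: int
    end: int
    members: tuple[StudyCnvr, ...]

    @property
    def studies(self) -> frozenset:
        return frozenset(m.study_id for m in self.members)

    @property
    def status(self) -> str:
        return "shared" if len(self.studies) >= 2 else "novel"

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def normalize_records(
    records: pd.DataFrame,
    convention: str,
    genome: GenomeBuild,
    study_id: str | None = None,
) -> list[StudyCnvr]:
    """Normalize raw study records to 1-based inclusive StudyCnvr objects.

    ``records`` needs columns ``chromosome, start, end`` and optionally
    ``study_id, state, n_carriers``. BED-convention starts are shifted by
    +1; out-of-bounds coordinates are clipped to the chromosome with a
    warning; unknown chromosomes raise, listing the offenders.
    """
    if convention not in CONVENTIONS:
        raise ValueError(f"unknown convention {convention!r}; expected one of {CONVENTIONS}")
    unknown = sorted(set(records["chromosome"]) - set(genome.names))
    if unknown:
        raise KeyError(f"records on chromosomes absent from the genome: {unknown}")
    out: list[StudyCnvr] = []
    for row in records.itertuples(index=False):
        d = row._asdict()
        start, end = int(d["start"]), int(d["end"])
        if convention == "bed_half_open":
            start += 1
        chrom = d["chromosome"]
        length = genome.length(chrom)
        if start < 1 or end > length:
            warnings.warn(
                f"record {chrom}:{start}-{end} clipped to chromosome bounds [1, {length}]"
            )
            start, end = max(start, 1), min(end, length)
        sid = str(d.get("study_id", study_id) or study_id)
        if sid in (None, "None"):
            raise ValueError("study_id missing: pass a study_id column or argument")
        out.append(
            StudyCnvr(
                study_id=sid,
                chromosome=chrom,
                start=start,
                end=end,
                state=d.get("state"),
                n_carriers=d.get("n_carriers"),
            )
        )
    return out


def integrate_studies(
    studies: list[list[StudyCnvr]],
    genome: GenomeBuild | None = None,
) -> list[CompositeCnvr]:
    """Positionally merge the records of several studies into composite CNVRs.

    The result is invariant to study input order (regions are re-sorted by
    coordinate) and idempotent: integrating a composite set with itself
    returns the same spans, all shared.
    """
    if not studies:
        raise ValueError("need at least one study")
    flat = [rec for study in studies for rec in study]
    chrom_order = genome.order if genome is not None else None
    groups = merge_groups(
        flat,
        chrom_of=lambda r: r.chromosome,
        start_of=lambda r: r.start,
        end_of=lambda r: r.end,
        chrom_order=chrom_order,
    )
    return [
        CompositeCnvr(chromosome=c, start=s, end=e, members=tuple(members))
        for c, s, e, members in groups
    ]


def novelty_accounting(
    composites: list[CompositeCnvr],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-study and global shared/novel tallies over a composite set.

    A study contributes at most once per composite region regardless of how
    many of its records merged into it. Returns a per-study table
    (``study_id, total, novel, shared_contrib``) and global totals
    ``{"total", "shared", "novel"}``.
    """
    per_study: dict[str, dict[str, int]] = {}
    n_shared = 0
    for comp in composites:
        shared = comp.status == "shared"
        n_shared += shared
        for sid in comp.studies:
            rec = per_study.setdefault(sid, {"total": 0, "novel": 0, "shared_contrib": 0})
            rec["total"] += 1
            if shared:
                rec["shared_contrib"] += 1
            else:
                rec["novel"] += 1
    table = pd.DataFrame(
        [(sid, r["total"], r["novel"], r["shared_contrib"]) for sid, r in sorted(per_study.items())],
        columns=["study_id", "total", "novel", "shared_contrib"],
    )
    totals = {
        "total": len(composites),
        "shared": n_shared,
        "novel": len(composites) - n_shared,
    }
    return table, totals
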