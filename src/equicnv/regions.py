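"""CNVR consolidation: merge per-sample calls into cohort-level regions.

A copy-number variable region (CNVR) is the union of overlapping or
boundary-adjacent CNV calls across all samples (single-linkage, transitive).
Each CNVR carries a state (gain / loss / complex), a sharing status
(shared iff carried by ≥2 distinct individuals) and, when a sample→breed
map is available, a breed-specificity flag.
"""

from __future__ import annotations

from dataclasses import dataclass

from .calling import CnvCall
from .genome import GenomeBuild
from .intervals import merge_groups

__all__ = [
    "Cnvr",
    "consolidate_calls",
    "classify_state",
    "sharing_status",
    "breed_specific_cnvrs",
]


@dataclass
class Cnvr:
    chromosome: str
    start: int
    end: int
    member_calls: tuple[CnvCall, ...]
    state: str = ""
    sharing: str = ""
    breeds: frozenset = frozenset()
    breed_specific: bool = False
    # annotation fields, populated by annotate_stats
    genic: bool | None = None
    gene_ids: tuple[str, ...] = ()
    subtelomeric: bool | None = None

    def __post_init__(self) -> None:
        if not self.member_calls:
            raise ValueError("CNVR needs at least one member call")
        chroms = {c.chromosome for c in self.member_calls}
        if chroms != {self.chromosome}:
            raise ValueError("member calls span multiple chromosomes")
        if not self.state:
            self.state = classify_state(self)
        if not self.sharing:
            self.sharing = sharing_status(self)

    @property
    def samples(self) -> frozenset:
        return frozenset(c.sample_id for c in self.member_calls)

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def classify_state(cnvr: Cnvr) -> str:
    """gain if all members are gains, loss if all losses, complex otherwise."""
    directions = {c.direction for c in cnvr.member_calls}
    if directions == {"gain"}:
        return "gain"
    if directions == {"loss"}:
        return "loss"
    return "complex"


def sharing_status(cnvr: Cnvr) -> str:
    """shared iff carried by at least two distinct individuals."""
    return "shared" if len(cnvr.samples) >= 2 else "private"


def consolidate_calls(
    calls: list[CnvCall],
    genome: GenomeBuild | None = None,
    sample_breeds: dict[str, str] | None = None,
) -> list[Cnvr]:
    """Merge all samples' calls into CNVRs.

    Two calls merge iff they overlap by ≥1 base or the end of one equals the
    start of the next (1-based inclusive); merging is transitive, so a chain
    of pairwise-mergeable calls yields one region. The resulting regions are
    pairwise non-mergeable and each spans the union of its members.
    """
    chrom_order = genome.order if genome is not None else None
    groups = merge_groups(
        calls,
        chrom_of=lambda c: c.chromosome,
        start_of=lambda c: c.start,
        end_of=lambda c: c.end,
        chrom_order=chrom_order,
    )
    cnvrs = [
        Cnvr(chromosome=c, start=s, end=e, member_calls=tuple(members))
        for c, s, e, members in groups
    ]
    if sample_breeds is not None:
        breed_specific_cnvrs(cnvrs, sample_breeds)
    return cnvrs


def breed_specific_cnvrs(
    cnvrs: list[Cnvr], sample_breeds: dict[str, str]
) -> list[Cnvr]:
    """Flag CNVRs carried by ≥2 individuals of exactly one breed.

    A region qualifies iff it is shared (≥2 distinct samples), every carrier
    belongs to the same breed, and — because consolidation already pooled
    every sample's calls — no sample of any other breed carries it. Sets
    ``breeds`` and ``breed_specific`` on each region in place and returns
    the flagged subset.
    """
    flagged = []
    for r in cnvrs:
        missing = [s for s in r.samples if s not in sample_breeds]
        if missing:
            raise KeyError(f"samples without breed mapping: {sorted(missing)}")
        breeds = frozenset(sample_breeds[s] for s in r.samples)
        r.breeds = breeds
        r.breed_specific = len(r.samples) >= 2 and len(breeds) == 1
        if r.breed_specific:
            flagged.append(r)
    return flagged
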