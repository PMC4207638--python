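"""Genic/sub-telomeric annotation, chromosome enrichment and cohort summaries.

Annotation uses an any-overlap rule: a CNVR is genic iff it shares at least
one base with at least one gene interval, and sub-telomeric iff it reaches
into the terminal window (default 1 Mb) of either chromosome end.
Enrichment of a chromosome is the percentage of its length covered by
CNVRs; consolidated CNVRs are non-overlapping, so lengths sum directly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .calling import CnvCall
from .genome import GenomeBuild
from .regions import Cnvr

__all__ = [
    "GeneInterval",
    "CohortSummary",
    "annotate_genic",
    "flag_subtelomeric",
    "chromosome_enrichment",
    "enrichment_percent",
    "cohort_summary",
    "summarize_call_counts",
    "tissue_comparison",
]


@dataclass(frozen=True)
class GeneInterval:
    gene_id: str
    chromosome: str
    start: int  # 1-based inclusive
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start or self.start < 1:
            raise ValueError(f"invalid gene interval {self.gene_id}")


def annotate_genic(
    cnvrs: list[Cnvr],
    genes: list[GeneInterval],
    genome: GenomeBuild | None = None,
) -> list[Cnvr]:
    """Mark each CNVR genic (≥1 bp overlap with ≥1 gene) or intergenic.

    Overlapping gene ids are recorded on the region. If a genome is supplied,
    genes on chromosomes absent from it are skipped with a warning.
    """
    trees: dict[str, IntervalTree] = {}
    for g in genes:
        if genome is not None and g.chromosome not in genome:
            warnings.warn(f"gene {g.gene_id} on unknown chromosome {g.chromosome}; skipped")
            continue
        # interval tree uses half-open ends
        trees.setdefault(g.chromosome, IntervalTree()).addi(g.start, g.end + 1, g.gene_id)
    for r in cnvrs:
        tree = trees.get(r.chromosome)
        hits = sorted({iv.data for iv in tree.overlap(r.start, r.end + 1)}) if tree else []
        r.gene_ids = tuple(hits)
        r.genic = bool(hits)
    return cnvrs


def flag_subtelomeric(
    cnvrs: list[Cnvr],
    genome: GenomeBuild,
    window: int = 1_000_000,
    both_ends: bool = True,
) -> list[Cnvr]:
    """Flag CNVRs overlapping the terminal window of a chromosome end.

    ``both_ends=False`` restricts to the distal (q-arm) end, the relevant
    choice for acrocentric karyotypes where the proximal end is centromeric.
    """
    for r in cnvrs:
        length = genome.length(r.chromosome)
        in_tail = r.end > length - window
        in_head = both_ends and r.start <= window
        r.subtelomeric = bool(in_head or in_tail)
    return cnvrs


def enrichment_percent(cnvr_length_total: float, chrom_length: float) -> float:
    """Total CNVR length on a chromosome as a percentage of its length."""
    return 100.0 * cnvr_length_total / chrom_length


def chromosome_enrichment(cnvrs: list[Cnvr], genome: GenomeBuild) -> pd.DataFrame:
    """Per-chromosome CNVR counts, total length and enrichment percentage.

    Returns one row per genome chromosome (zero-filled where no CNVRs),
    with the unrounded enrichment in ``enrichment_percent`` and the 2-decimal
    reporting value in ``enrichment_percent_2dp``.
    """
    for r in cnvrs:
        if r.chromosome not in genome:
            raise KeyError(f"CNVR on unknown chromosome {r.chromosome}")
    rows = []
    by_chrom: dict[str, list[Cnvr]] = {}
    for r in cnvrs:
        by_chrom.setdefault(r.chromosome, []).append(r)
    for chrom, length in genome.chromosomes:
        rs = by_chrom.get(chrom, [])
        total = sum(r.length for r in rs)
        pct = enrichment_percent(total, length)
        rows.append({
            "chromosome": chrom,
            "n_cnvr": len(rs),
            "n_gain": sum(r.state == "gain" for r in rs),
            "n_loss": sum(r.state == "loss" for r in rs),
            "n_complex": sum(r.state == "complex" for r in rs),
            "n_shared": sum(r.sharing == "shared" for r in rs),
            "n_private": sum(r.sharing == "private" for r in rs),
            "n_genic": sum(bool(r.genic) for r in rs),
            "n_intergenic": sum(r.genic is False for r in rs),
            "n_subtelomeric": sum(bool(r.subtelomeric) for r in rs),
            "cnvr_length_total": total,
            "chrom_length": length,
            "enrichment_percent": pct,
            "enrichment_percent_2dp": round(pct, 2),
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class CohortSummary:
    per_sample: pd.DataFrame  # sample_id, n_calls, n_gains, n_losses
    mean_calls: float
    median_calls: float
    mean_gains: float
    median_gains: float
    mean_losses: float
    median_losses: float
    n_cnvr: int
    mean_cnvr_size: float
    median_cnvr_size: float
    min_cnvr_size: int
    max_cnvr_size: int
    genome_enrichment_percent: float


def summarize_call_counts(per_sample: pd.DataFrame) -> dict[str, float]:
    """Mean/median of per-sample call, gain and loss counts.

    Expects columns ``n_calls, n_gains, n_losses``; each row is one
    individual.
    """
    out = {}
    for col, name in (("n_calls", "calls"), ("n_gains", "gains"), ("n_losses", "losses")):
        out[f"mean_{name}"] = float(per_sample[col].mean())
        out[f"median_{name}"] = float(per_sample[col].median())
    return out


def cohort_summary(
    calls: list[CnvCall], cnvrs: list[Cnvr], genome: GenomeBuild
) -> CohortSummary:
    """Cohort-level call counts, CNVR size statistics and genome enrichment.

    Genome enrichment is total CNVR length over total genome length
    (including any unplaced-contig pseudo-chromosome present in the build).
    """
    if not calls or not cnvrs:
        raise ValueError("cohort_summary needs non-empty calls and cnvrs")
    counts: dict[str, list[int]] = {}
    for c in calls:
        rec = counts.setdefault(c.sample_id, [0, 0, 0])
        rec[0] += 1
        rec[1] += c.direction == "gain"
        rec[2] += c.direction == "loss"
    per_sample = pd.DataFrame(
        [(sid, *vals) for sid, vals in counts.items()],
        columns=["sample_id", "n_calls", "n_gains", "n_losses"],
    ).sort_values("sample_id", ignore_index=True)
    stats_counts = summarize_call_counts(per_sample)
    sizes = np.array([r.length for r in cnvrs])
    return CohortSummary(
        per_sample=per_sample,
        mean_calls=stats_counts["mean_calls"],
        median_calls=stats_counts["median_calls"],
        mean_gains=stats_counts["mean_gains"],
        median_gains=stats_counts["median_gains"],
        mean_losses=stats_counts["mean_losses"],
        median_losses=stats_counts["median_losses"],
        n_cnvr=len(cnvrs),
        mean_cnvr_size=float(sizes.mean()),
        median_cnvr_size=float(np.median(sizes)),
        min_cnvr_size=int(sizes.min()),
        max_cnvr_size=int(sizes.max()),
        genome_enrichment_percent=enrichment_percent(int(sizes.sum()), genome.total_length),
    )


def tissue_comparison(
    per_sample_counts,
    tissues,
    groups: tuple[str, str] = ("blood", "hair"),
) -> tuple[float, float]:
    """Equal-variance two-sample Student's t test of call counts by tissue.

    Samples of tissues outside ``groups`` (e.g. fibroblast cultures) are
    excluded. Returns (t statistic, two-sided p value).
    """
    counts = np.asarray(per_sample_counts, dtype=float)
    tissues = np.asarray(tissues)
    a = counts[tissues == groups[0]]
    b = counts[tissues == groups[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each tissue group needs at least 2 samples")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)
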