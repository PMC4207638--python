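"""Tiling probe maps.

Emulates a whole-genome 60-mer tiling design with three spacing tiers:
~7.5 kb genome-wide, ~4 kb in sub-telomeres (the terminal 1 Mb of each
chromosome end) and ~20 kb on the Y chromosome. Probes are laid on a
jittered regular grid; sequence-aware placement (uniqueness filtering,
repeat masking) is out of scope for the simulator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GenomeBuild

__all__ = ["ProbeMap", "design_probe_map", "DEFAULT_SPACING"]

DEFAULT_SPACING = {"default": 7500, "subtelomere": 4000, "chrY": 20000}
PROBE_LENGTH = 60

CATEGORIES = ("genic", "intergenic", "subtelomeric", "chrY")


@dataclass(frozen=True)
class ProbeMap:
    """Ordered tiling probes aligned to a genome build.

    The table has columns ``probe_id, chromosome, start, end, category`` and
    is sorted by (chromosome order, start). Row position is the canonical
    probe index used to align hybridization values.
    """

    table: pd.DataFrame
    genome: GenomeBuild

    def __post_init__(self) -> None:
        t = self.table
        if list(t.columns[:5]) != ["probe_id", "chromosome", "start", "end", "category"]:
            raise ValueError("probe table must have columns probe_id, chromosome, start, end, category")
        if (t["end"] < t["start"]).any():
            raise ValueError("probe end < start")
        order = t["chromosome"].map(self.genome.order)
        if not (order.diff().fillna(0) >= 0).all():
            raise ValueError("probes not sorted by chromosome order")
        for chrom, sub in t.groupby("chromosome", sort=False):
            if not sub["start"].is_monotonic_increasing:
                raise ValueError(f"probes on {chrom} not sorted by start")
            if int(sub["end"].max()) > self.genome.length(chrom):
                raise ValueError(f"probe beyond end of {chrom}")

    def __len__(self) -> int:
        return len(self.table)

    def chrom_slices(self) -> dict[str, slice]:
        """Row slice of each chromosome, in genome order."""
        out: dict[str, slice] = {}
        codes = self.table["chromosome"].to_numpy()
        starts = np.flatnonzero(np.r_[True, codes[1:] != codes[:-1]])
        bounds = np.r_[starts, len(codes)]
        for i, s in enumerate(starts):
            out[codes[s]] = slice(int(bounds[i]), int(bounds[i + 1]))
        return out

    def starts(self) -> np.ndarray:
        return self.table["start"].to_numpy()

    def ends(self) -> np.ndarray:
        return self.table["end"].to_numpy()


def _is_y(name: str) -> bool:
    return name.lower().lstrip("chr") == "y"


def design_probe_map(
    genome: GenomeBuild,
    spacing: dict | None = None,
    subtelomere_window: int = 1_000_000,
    jitter_fraction: float = 0.2,
    seed: int = 0,
    genic_fraction: float = 0.2,
) -> ProbeMap:
    """Place 60-bp probes on a jittered regular grid over a genome.

    Within ``subtelomere_window`` of either chromosome end the sub-telomeric
    spacing applies; on a Y chromosome the chrY spacing applies everywhere.
    ``jitter_fraction`` perturbs each step uniformly in
    ``±jitter_fraction * spacing``; with 0 the grid is exact. Non-Y,
    non-sub-telomeric probes are labelled genic with probability
    ``genic_fraction`` (the array's approximate exon-probe share),
    intergenic otherwise.

    Chromosomes shorter than one spacing step receive zero probes, with a
    warning.
    """
    sp = dict(DEFAULT_SPACING)
    if spacing:
        sp.update(spacing)
    if not 0 <= jitter_fraction < 0.5:
        raise ValueError("jitter_fraction must be in [0, 0.5)")
    for key, val in sp.items():
        if val <= 0:
            raise ValueError(f"spacing[{key!r}] must be positive")

    rng = np.random.default_rng(seed)
    rows: list[tuple[str, str, int, int, str]] = []
    for chrom, length in genome.chromosomes:
        y = _is_y(chrom)
        base_step = sp["chrY"] if y else min(sp["default"], sp["subtelomere"])
        if length < base_step + PROBE_LENGTH:
            warnings.warn(f"chromosome {chrom} shorter than one spacing unit; no probes placed")
            continue
        pos = 1
        while pos + PROBE_LENGTH - 1 <= length:
            subtel = pos <= subtelomere_window or pos > length - subtelomere_window
            if y:
                step, cat = sp["chrY"], "chrY"
            elif subtel:
                step, cat = sp["subtelomere"], "subtelomeric"
            else:
                step = sp["default"]
                cat = "genic" if rng.random() < genic_fraction else "intergenic"
            end = pos + PROBE_LENGTH - 1
            rows.append((f"P_{chrom}_{pos}", chrom, pos, end, cat))
            jitter = rng.uniform(-jitter_fraction, jitter_fraction) if jitter_fraction else 0.0
            pos += max(PROBE_LENGTH, int(round(step * (1.0 + jitter))))
    table = pd.DataFrame(rows, columns=["probe_id", "chromosome", "start", "end", "category"])
    return ProbeMap(table=table, genome=genome)
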