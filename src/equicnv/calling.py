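"""Per-sample CNV calling by a thresholded-run rule.

A CNV is emitted for every maximal run of at least ``min_probes``
consecutive same-chromosome probes whose log2 ratios all lie strictly
beyond ±``log2_threshold`` with a common sign. This per-probe exceedance
rule is a deterministic, conservative reading of the "±0.5 over 5
neighboring probes" calling contract used on Agilent aCGH data; it is
deliberately not the proprietary ADM-2 interval score. Set
``min_probes`` and ``log2_threshold`` to taste for other platforms.

Calls whose run mean exceeds ±``hom_threshold`` (default 2.0, i.e. below
one copy on a log2 scale) are flagged as putatively homozygous; an array
cannot distinguish alleles, so the flag is tentative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .probes import ProbeMap
from .simulate import Hybridization

__all__ = ["CallingParams", "CnvCall", "call_cnvs", "classify_zygosity"]

HETEROZYGOUS_OR_UNKNOWN = "heterozygous-or-unknown"
PUTATIVE_HOMOZYGOUS = "putative_homozygous"


@dataclass(frozen=True)
class CallingParams:
    log2_threshold: float = 0.5
    min_probes: int = 5
    hom_threshold: float = 2.0

    def __post_init__(self) -> None:
        if self.log2_threshold <= 0 or self.hom_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if self.min_probes < 2:
            raise ValueError("min_probes must be >= 2")


@dataclass(frozen=True)
class CnvCall:
    """A called segment: first probe's start through last probe's end."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    n_probes: int
    mean_log2: float
    direction: str  # gain | loss
    zygosity: str

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError("call end < start")
        if self.direction not in ("gain", "loss"):
            raise ValueError(f"bad direction {self.direction!r}")
        if (self.mean_log2 > 0) != (self.direction == "gain"):
            raise ValueError("sign of mean_log2 does not match direction")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def classify_zygosity(mean_log2: float, params: CallingParams = CallingParams()) -> str:
    """Putatively homozygous iff |mean log2| strictly exceeds hom_threshold."""
    return PUTATIVE_HOMOZYGOUS if abs(mean_log2) > params.hom_threshold else HETEROZYGOUS_OR_UNKNOWN


def call_cnvs(
    hyb: Hybridization,
    probe_map: ProbeMap,
    params: CallingParams = CallingParams(),
) -> list[CnvCall]:
    """Call CNVs from one hybridization.

    Missing-value probes are removed before adjacency is computed, so a run
    may bridge a dropped probe; runs never cross chromosome boundaries.
    Thresholding is strict: values exactly at ±threshold do not qualify.
    ``mean_log2`` is the arithmetic mean over the run's probes.
    """
    if len(hyb.log2) != len(probe_map):
        raise ValueError("hybridization not aligned to probe map")
    starts = probe_map.starts()
    ends = probe_map.ends()
    calls: list[CnvCall] = []
    for chrom, sl in probe_map.chrom_slices().items():
        vals = hyb.log2[sl]
        keep = ~np.isnan(vals)
        vals = vals[keep]
        if vals.size == 0:
            continue
        idx = np.arange(sl.start, sl.stop)[keep]
        state = np.zeros(vals.size, dtype=np.int8)
        state[vals > params.log2_threshold] = 1
        state[vals < -params.log2_threshold] = -1
        # maximal runs of constant non-zero state
        change = np.flatnonzero(state[1:] != state[:-1])
        run_starts = np.r_[0, change + 1]
        run_ends = np.r_[change, vals.size - 1]
        for a, b in zip(run_starts, run_ends):
            s = int(state[a])
            n = int(b - a + 1)
            if s == 0 or n < params.min_probes:
                continue
            mean = float(vals[a : b + 1].mean())
            calls.append(
                CnvCall(
                    sample_id=hyb.sample_id,
                    chromosome=chrom,
                    start=int(starts[idx[a]]),
                    end=int(ends[idx[b]]),
                    n_probes=n,
                    mean_log2=mean,
                    direction="gain" if s > 0 else "loss",
                    zygosity=classify_zygosity(mean, params),
                )
            )
    return calls


def calls_to_frame(calls: list[CnvCall]) -> pd.DataFrame:
    """Tabulate calls (1-based inclusive coordinates)."""
    return pd.DataFrame(
        [
            (c.sample_id, c.chromosome, c.start, c.end, c.length, c.n_probes,
             c.mean_log2, c.direction, c.zygosity)
            for c in calls
        ],
        columns=["sample_id", "chromosome", "start", "end", "length", "n_probes",
                 "mean_log2", "direction", "zygosity"],
    )
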