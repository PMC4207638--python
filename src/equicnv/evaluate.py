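"""Recovery scoring of planted truth against calls, and null false-call rates.

A planted CNV is *detectable* when it covers at least ``min_probes`` array
probes and its expected log2 shift clears the calling threshold with margin
(|shift| ≥ 1 leaves ~3.6 sigma of room at blood-like noise). A detectable
CNV counts as *recovered* when the union of the sample's same-direction
calls overlapping it has both boundaries within one probe spacing of the
truth boundaries. The union is used because the strict per-probe run rule
may fragment a long CNV at a single sub-threshold probe; fragmentation
changes segmentation, not detection, and the union's boundaries remain
probe-accurate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .calling import CnvCall
from .probes import ProbeMap
from .simulate import TruthCnv

__all__ = ["RecoveryReport", "probes_covered", "score_recovery"]


@dataclass(frozen=True)
class RecoveryReport:
    n_detectable: int
    n_recovered: int
    misses: tuple[TruthCnv, ...]

    @property
    def recall(self) -> float:
        if self.n_detectable == 0:
            raise ValueError("no detectable truth CNVs to score")
        return self.n_recovered / self.n_detectable


def probes_covered(truth: TruthCnv, probe_map: ProbeMap) -> int:
    """Number of probes overlapping a truth interval by ≥1 base."""
    sl = probe_map.chrom_slices().get(truth.chromosome)
    if sl is None:
        return 0
    starts, ends = probe_map.starts(), probe_map.ends()
    lo = int(np.searchsorted(ends[sl], truth.start, side="left"))
    hi = int(np.searchsorted(starts[sl], truth.end, side="right"))
    return max(0, hi - lo)


def score_recovery(
    truth: list[TruthCnv],
    calls: list[CnvCall],
    probe_map: ProbeMap,
    boundary_tol: int | None = None,
    min_probes: int = 5,
    min_abs_log2: float = 1.0,
) -> RecoveryReport:
    """Score which detectable planted CNVs were recovered by the caller.

    ``boundary_tol`` is the allowed distance between truth and recovered
    boundaries; by default one (jittered) default-tier probe spacing plus
    the probe length, derived from the probe map's largest inter-probe gap.
    """
    if boundary_tol is None:
        starts = probe_map.starts()
        gaps = []
        for sl in probe_map.chrom_slices().values():
            if sl.stop - sl.start >= 2:
                gaps.append(np.diff(starts[sl]).max())
        boundary_tol = int(max(gaps)) + 60
    by_key: dict[tuple[str, str, str], list[CnvCall]] = {}
    for c in calls:
        by_key.setdefault((c.sample_id, c.chromosome, c.direction), []).append(c)

    n_detectable = 0
    n_recovered = 0
    misses = []
    for t in truth:
        if abs(t.expected_log2) < min_abs_log2:
            continue
        if probes_covered(t, probe_map) < min_probes:
            continue
        n_detectable += 1
        direction = "loss" if t.expected_log2 < 0 else "gain"
        overlapping = [
            c
            for c in by_key.get((t.sample_id, t.chromosome, direction), [])
            if c.start <= t.end and t.start <= c.end
        ]
        if not overlapping:
            misses.append(t)
            continue
        span_start = min(c.start for c in overlapping)
        span_end = max(c.end for c in overlapping)
        if abs(span_start - t.start) <= boundary_tol and abs(span_end - t.end) <= boundary_tol:
            n_recovered += 1
        else:
            misses.append(t)
    return RecoveryReport(n_detectable, n_recovered, tuple(misses))
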