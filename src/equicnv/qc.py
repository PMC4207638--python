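"""Hybridization quality metrics and platform false-discovery estimation.

The derivative log ratio standard deviation (DLRSD) measures probe-to-probe
log2-ratio noise: the spread of consecutive-probe differences, divided by
√2 so that for i.i.d. per-probe noise of sd σ the statistic estimates σ
itself (the difference of two independent N(0, σ²) values has sd σ√2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .probes import ProbeMap
from .simulate import Hybridization

__all__ = [
    "QualityReport",
    "compute_dlrsd",
    "classify_quality",
    "self_to_self_fdr",
    "quality_report",
]

#: band thresholds: DLRSD < 0.2 excellent, 0.2–0.3 good, > 0.3 poor
EXCELLENT_MAX = 0.2
GOOD_MAX = 0.3


@dataclass(frozen=True)
class QualityReport:
    sample_id: str
    dlrsd: float
    band: str
    n_probes_used: int
    fdr_percent: float | None = None


def compute_dlrsd(hyb: Hybridization, probe_map: ProbeMap, robust: bool = False) -> float:
    """Spread of consecutive-probe log2 differences, normalized by √2.

    Probes are taken in (chromosome order, start) order; pairs spanning a
    chromosome boundary are excluded and missing values are dropped before
    pairing. ``robust=True`` replaces the sample standard deviation with the
    normalized interquartile range (IQR / 1.349), which ignores the tails
    that real CNVs contribute.
    """
    if len(hyb.log2) != len(probe_map):
        raise ValueError("hybridization not aligned to probe map")
    diffs = []
    for sl in probe_map.chrom_slices().values():
        vals = hyb.log2[sl]
        vals = vals[~np.isnan(vals)]
        if vals.size >= 2:
            diffs.append(np.diff(vals))
    if not diffs:
        raise ValueError("need >= 2 usable probes on some chromosome")
    d = np.concatenate(diffs)
    if robust:
        q25, q75 = np.percentile(d, [25, 75])
        spread = (q75 - q25) / 1.3489795003921634
    else:
        spread = float(np.std(d, ddof=1)) if d.size > 1 else 0.0
    return float(spread / math.sqrt(2))


def classify_quality(dlrsd: float) -> str:
    """Band a DLRSD value: <0.2 excellent, 0.2–0.3 good, >0.3 poor."""
    if dlrsd < 0:
        raise ValueError("DLRSD cannot be negative")
    if dlrsd < EXCELLENT_MAX:
        return "excellent"
    if dlrsd <= GOOD_MAX:
        return "good"
    return "poor"


def self_to_self_fdr(n_self_calls: int, n_total_calls: int) -> float:
    """Platform FDR: 100 × (calls in self-to-self hybridization) / (all calls).

    In a self-to-self hybridization both channels carry the same DNA, so any
    CNV call is a false positive.
    """
    if n_total_calls <= 0:
        raise ValueError("total call count must be positive")
    if not 0 <= n_self_calls <= n_total_calls:
        raise ValueError("need 0 <= n_self_calls <= n_total_calls")
    return 100.0 * n_self_calls / n_total_calls


def quality_report(
    hyb: Hybridization,
    probe_map: ProbeMap,
    robust: bool = False,
    fdr_percent: float | None = None,
) -> QualityReport:
    dlrsd = compute_dlrsd(hyb, probe_map, robust=robust)
    n_used = int(np.sum(~np.isnan(hyb.log2)))
    return QualityReport(
        sample_id=hyb.sample_id,
        dlrsd=dlrsd,
        band=classify_quality(dlrsd),
        n_probes_used=n_used,
        fdr_percent=fdr_percent,
    )
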