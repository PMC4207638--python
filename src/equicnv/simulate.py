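"""Synthetic aCGH cohorts: planted CNV truth sets and noisy log2 profiles.

The simulator emulates two-channel hybridizations of a sample against a
copy-neutral reference: each probe reports ``log2(sample/reference)`` equal
to the expected shift of the covering planted CNV (0 where copy-neutral)
plus i.i.d. Gaussian noise. Tissue-specific noise levels default to the
blood-like (sd 0.14) and hair-like (sd 0.41) regimes observed on real
hybridizations.

Expected per-probe shifts are ``log2(copy/2)`` for copy states 1, 3 and 4
(−1.0, +0.585, +1.0); a homozygous loss (copy 0) is represented by a finite
floor (default −4.0) since the true −∞ is unobservable on an array.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from .genome import GenomeBuild
from .probes import ProbeMap, _is_y

__all__ = [
    "SampleInfo",
    "TruthCnv",
    "Hybridization",
    "SimParams",
    "COPY_STATE_LOG2",
    "HOM_LOSS_LOG2_FLOOR",
    "plant_truth_cnvs",
    "simulate_hybridization",
    "simulate_cohort",
]

HOM_LOSS_LOG2_FLOOR = -4.0

COPY_STATE_LOG2 = {
    "hom_loss": HOM_LOSS_LOG2_FLOOR,
    "het_loss": -1.0,
    "het_gain": math.log2(3 / 2),
    "multi_gain": 1.0,
}

COPY_STATES = tuple(COPY_STATE_LOG2)


@dataclass(frozen=True)
class SampleInfo:
    sample_id: str
    breed: str
    tissue: str = "blood"  # blood | hair | fibroblast
    sex: str = "F"


@dataclass(frozen=True)
class TruthCnv:
    """A planted copy-number variant (ground truth for one sample)."""

    sample_id: str
    chromosome: str
    start: int
    end: int
    copy_state: str
    expected_log2: float

    def __post_init__(self) -> None:
        if self.copy_state not in COPY_STATE_LOG2:
            raise ValueError(f"unknown copy state {self.copy_state!r}")
        if self.end < self.start or self.start < 1:
            raise ValueError("invalid truth interval")


@dataclass
class Hybridization:
    """One sample-vs-reference experiment: per-probe log2 ratios + metadata.

    ``log2`` is aligned positionally to a :class:`~equicnv.probes.ProbeMap`;
    missing probes are NaN.
    """

    sample_id: str
    reference_id: str
    tissue: str
    sex: str
    breed: str
    log2: np.ndarray

    def __post_init__(self) -> None:
        self.log2 = np.asarray(self.log2, dtype=float)
        present = self.log2[~np.isnan(self.log2)]
        if present.size and not np.isfinite(present).all():
            raise ValueError("non-finite log2 values")


@dataclass(frozen=True)
class SimParams:
    """Cohort-level simulation parameters.

    Defaults reproduce the discovery-study conditions: ~26.4 calls per
    individual, sizes 1 kb–2.5 Mb (log-uniform), losses ~72% of calls
    (19.1/26.4), a small homozygous fraction (16 of ~950 calls), and
    blood/hair/fibroblast noise of 0.14/0.41/0.14.
    """

    mean_cnvs_per_sample: float = 26.4
    size_range: tuple[int, int] = (1_000, 2_500_000)
    loss_fraction: float = 0.72
    hom_fraction: float = 0.017
    shared_fraction: float = 0.30
    breed_restricted_fraction: float = 0.01
    noise_sd_by_tissue: dict = field(
        default_factory=lambda: {"blood": 0.14, "hair": 0.41, "fibroblast": 0.14}
    )
    max_placement_retries: int = 100

    def __post_init__(self) -> None:
        for name in ("loss_fraction", "hom_fraction", "shared_fraction", "breed_restricted_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.mean_cnvs_per_sample < 0:
            raise ValueError("mean_cnvs_per_sample must be >= 0")
        lo, hi = self.size_range
        if not 1 <= lo <= hi:
            raise ValueError("invalid size_range")


def _overlaps(intervals: list[tuple[int, int]], start: int, end: int) -> bool:
    return any(s <= end and start <= e for s, e in intervals)


def _draw_region(
    rng: np.random.Generator,
    chrom_names: list[str],
    chrom_lengths: np.ndarray,
    weights: np.ndarray,
    size_range: tuple[int, int],
) -> tuple[str, int, int]:
    ci = int(rng.choice(len(chrom_names), p=weights))
    chrom = chrom_names[ci]
    length = int(chrom_lengths[ci])
    lo, hi = size_range
    hi = min(hi, length)
    size = int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))
    size = max(lo, min(size, length))
    start = int(rng.integers(1, length - size + 2))
    return chrom, start, start + size - 1


def plant_truth_cnvs(
    genome: GenomeBuild,
    samples: list[SampleInfo],
    params: SimParams = SimParams(),
    seed: int = 0,
    hom_loss_log2: float = HOM_LOSS_LOG2_FLOOR,
) -> list[TruthCnv]:
    """Plant non-overlapping truth CNVs across a cohort.

    Per-sample event counts are Poisson(mean); sizes are log-uniform within
    ``size_range``. A ``shared_fraction`` of events is copied into one or two
    additional random samples; a ``breed_restricted_fraction`` is planted in
    ≥2 samples of the originator's breed and in no other breed. Within a
    sample, truth CNVs never overlap; infeasible placements raise after
    bounded retries. No CNVs are planted on a Y chromosome.
    """
    if len({s.sample_id for s in samples}) != len(samples):
        raise ValueError("duplicate sample ids")
    autos = [(n, l) for n, l in genome.chromosomes if not _is_y(n)]
    chrom_names = [n for n, _ in autos]
    chrom_lengths = np.array([l for _, l in autos], dtype=float)
    if params.size_range[0] > chrom_lengths.min():
        raise ValueError("size_range lower bound exceeds smallest chromosome")
    weights = chrom_lengths / chrom_lengths.sum()

    rng = np.random.default_rng(seed)
    by_sample: dict[str, dict[str, list[tuple[int, int]]]] = {
        s.sample_id: {} for s in samples
    }
    by_breed: dict[str, list[SampleInfo]] = {}
    for s in samples:
        by_breed.setdefault(s.breed, []).append(s)

    def place(sample_id: str, chrom: str, start: int, end: int) -> bool:
        occ = by_sample[sample_id].setdefault(chrom, [])
        if _overlaps(occ, start, end):
            return False
        occ.append((start, end))
        return True

    truth: list[TruthCnv] = []
    for s in samples:
        n_events = int(rng.poisson(params.mean_cnvs_per_sample))
        for _ in range(n_events):
            for attempt in range(params.max_placement_retries):
                chrom, start, end = _draw_region(
                    rng, chrom_names, chrom_lengths, weights, params.size_range
                )
                if place(s.sample_id, chrom, start, end):
                    break
            else:
                raise RuntimeError(
                    f"could not place a CNV for {s.sample_id} on {chrom} after "
                    f"{params.max_placement_retries} retries"
                )
            if rng.random() < params.loss_fraction:
                state = "hom_loss" if rng.random() < params.hom_fraction else "het_loss"
            else:
                state = "multi_gain" if rng.random() < params.hom_fraction else "het_gain"
            log2 = hom_loss_log2 if state == "hom_loss" else COPY_STATE_LOG2[state]
            carriers = [s.sample_id]
            u = rng.random()
            breed_mates = [m for m in by_breed[s.breed] if m.sample_id != s.sample_id]
            if u < params.breed_restricted_fraction and breed_mates:
                extra = rng.choice(len(breed_mates), size=1)
                for j in extra:
                    m = breed_mates[int(j)]
                    if place(m.sample_id, chrom, start, end):
                        carriers.append(m.sample_id)
            elif u < params.breed_restricted_fraction + params.shared_fraction and len(samples) > 1:
                others = [m for m in samples if m.sample_id != s.sample_id]
                k = min(int(rng.integers(1, 3)), len(others))
                picks = rng.choice(len(others), size=k, replace=False)
                for j in picks:
                    m = others[int(j)]
                    if place(m.sample_id, chrom, start, end):
                        carriers.append(m.sample_id)
            for sid in carriers:
                truth.append(TruthCnv(sid, chrom, start, end, state, log2))

    order = {sid: i for i, sid in enumerate(s.sample_id for s in samples)}
    truth.sort(key=lambda t: (order[t.sample_id], genome.order(t.chromosome), t.start))
    return truth


def _baseline(
    probe_map: ProbeMap,
    truth: list[TruthCnv],
    sex_effect: str,
) -> np.ndarray:
    base = np.zeros(len(probe_map))
    starts = probe_map.starts()
    ends = probe_map.ends()
    slices = probe_map.chrom_slices()
    for cnv in truth:
        sl = slices.get(cnv.chromosome)
        if sl is None:
            warnings.warn(f"truth CNV on {cnv.chromosome} has no probes; undetectable")
            continue
        lo = sl.start + int(np.searchsorted(ends[sl], cnv.start, side="left"))
        hi = sl.start + int(np.searchsorted(starts[sl], cnv.end, side="right"))
        if hi <= lo:
            warnings.warn(
                f"truth CNV {cnv.chromosome}:{cnv.start}-{cnv.end} covers zero probes; undetectable"
            )
            continue
        base[lo:hi] = cnv.expected_log2
    if sex_effect == "male_vs_female_ref":
        chroms = probe_map.table["chromosome"].to_numpy()
        is_x = np.array([c.lower().lstrip("chr") == "x" for c in chroms])
        base[is_x] += -1.0
    elif sex_effect != "off":
        raise ValueError(f"unknown sex_effect {sex_effect!r}")
    return base


def simulate_hybridization(
    probe_map: ProbeMap,
    truth: list[TruthCnv],
    noise_sd: float,
    sex_effect: str = "off",
    seed: int = 0,
    sample: SampleInfo | None = None,
    reference_id: str | None = None,
) -> Hybridization:
    """Simulate one noisy log2 profile from a sample's truth set.

    Each probe covered by a truth CNV takes that CNV's expected log2 shift,
    all others 0; i.i.d. N(0, noise_sd²) noise is added. With
    ``sex_effect="male_vs_female_ref"`` all X-chromosome probes get an extra
    −1.0 baseline shift, emulating a male sample on a female reference.
    """
    if noise_sd <= 0:
        raise ValueError("noise_sd must be > 0")
    if sample is None:
        sid = truth[0].sample_id if truth else "sample"
        sample = SampleInfo(sample_id=sid, breed="unknown")
    foreign = {t.sample_id for t in truth} - {sample.sample_id}
    if foreign:
        raise ValueError(f"truth records for other samples supplied: {sorted(foreign)}")
    base = _baseline(probe_map, truth, sex_effect)
    rng = np.random.default_rng(seed)
    values = base + rng.normal(0.0, noise_sd, size=len(probe_map))
    if reference_id is None:
        reference_id = "Twilight" if sample.sex == "F" else "Bravo"
    return Hybridization(
        sample_id=sample.sample_id,
        reference_id=reference_id,
        tissue=sample.tissue,
        sex=sample.sex,
        breed=sample.breed,
        log2=values,
    )


def simulate_cohort(
    genome: GenomeBuild,
    probe_map: ProbeMap,
    samples: list[SampleInfo],
    params: SimParams = SimParams(),
    seed: int = 0,
) -> tuple[list[Hybridization], list[TruthCnv]]:
    """Simulate a full cohort: plant truth, then one hybridization per sample.

    Reproducibility scheme: ``numpy.random.SeedSequence(seed)`` is spawned
    into ``1 + len(samples)`` children; child 0 seeds truth planting and
    child ``i+1`` seeds sample ``i``'s noise, so any sample can be
    regenerated in isolation.
    """
    children = np.random.SeedSequence(seed).spawn(1 + len(samples))
    truth = plant_truth_cnvs(
        genome, samples, params, seed=np.random.default_rng(children[0]).integers(2**31)
    )
    by_sample: dict[str, list[TruthCnv]] = {s.sample_id: [] for s in samples}
    for t in truth:
        by_sample[t.sample_id].append(t)
    hybs = []
    for s, child in zip(samples, children[1:]):
        sd = params.noise_sd_by_tissue.get(s.tissue)
        if sd is None:
            raise ValueError(f"no noise sd configured for tissue {s.tissue!r}")
        hybs.append(
            simulate_hybridization(
                probe_map,
                by_sample[s.sample_id],
                noise_sd=sd,
                seed=np.random.default_rng(child).integers(2**31),
                sample=s,
            )
        )
    return hybs, truth
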