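#!/usr/bin/env python
"""Integrate the simulated CNVR set with synthetic prior-study sets.

Emulates cross-study consolidation: the simulated cohort's CNVRs are merged
positionally with two synthetic earlier studies — one that re-reports a
fraction of the same regions with jittered boundaries (as an independent
platform would) and one mostly disjoint — then the composite set is
classified shared/novel and contributions are tallied per study. Writes
results/composite_cnvrs.tsv and results/study_accounting.tsv.
"""

import argparse
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from equicnv import (
    SimParams,
    StudyCnvr,
    build_genome,
    call_cnvs,
    consolidate_calls,
    design_probe_map,
    integrate_studies,
    novelty_accounting,
    simulate_cohort,
)

import importlib.util as _ilu

_spec = _ilu.spec_from_file_location(
    "sim02", Path(__file__).with_name("02_simulate_cohort.py")
)
_sim02 = _ilu.module_from_spec(_spec)
_spec.loader.exec_module(_sim02)


def jittered_replica(cnvrs, study_id, rng, keep=0.5, jitter=5_000, genome=None):
    """A synthetic prior study: a subset of regions with shifted boundaries."""
    out = []
    for r in cnvrs:
        if rng.random() > keep:
            continue
        start = max(1, r.start + int(rng.integers(-jitter, jitter)))
        end = max(start, r.end + int(rng.integers(-jitter, jitter)))
        if genome is not None:
            end = min(end, genome.length(r.chromosome))
        out.append(StudyCnvr(study_id, r.chromosome, start, end))
    return out


def random_study(genome, study_id, rng, n=120, size=(5_000, 500_000)):
    """A synthetic mostly-disjoint study of n random regions."""
    names = [c for c, _ in genome.chromosomes]
    lengths = np.array([l for _, l in genome.chromosomes], dtype=float)
    w = lengths / lengths.sum()
    out = []
    for _ in range(n):
        i = int(rng.choice(len(names), p=w))
        s = int(np.exp(rng.uniform(np.log(size[0]), np.log(size[1]))))
        start = int(rng.integers(1, lengths[i] - s))
        out.append(StudyCnvr(study_id, names[i], start, start + s - 1))
    return out


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=Path("results"))
    args = parser.parse_args()

    genome = build_genome(preset="equcab2_table2")
    pm = design_probe_map(genome, seed=args.seed)
    samples = _sim02.make_samples()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hybs, _ = simulate_cohort(genome, pm, samples, SimParams(), seed=args.seed)
    calls = [c for h in hybs for c in call_cnvs(h, pm)]
    cnvrs = consolidate_calls(calls, genome=genome)

    rng = np.random.default_rng(args.seed + 1)
    this_study = [StudyCnvr("this_study", r.chromosome, r.start, r.end) for r in cnvrs]
    replica = jittered_replica(cnvrs, "prior_cgh", rng, genome=genome)
    disjoint = random_study(genome, "prior_snp", rng)

    composites = integrate_studies([this_study, replica, disjoint], genome=genome)
    table, totals = novelty_accounting(composites)

    args.outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            (c.chromosome, c.start, c.end, len(c.studies),
             ",".join(sorted(c.studies)), c.status)
            for c in composites
        ],
        columns=["chromosome", "start", "end", "n_studies", "studies", "status"],
    ).to_csv(args.outdir / "composite_cnvrs.tsv", sep="\t", index=False)
    table.to_csv(args.outdir / "study_accounting.tsv", sep="\t", index=False)

    print(table.to_string(index=False))
    print(f"\n{totals['total']} composite CNVRs: {totals['shared']} shared by >=2 "
          f"studies, {totals['novel']} study-specific.")


if __name__ == "__main__":
    main()
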