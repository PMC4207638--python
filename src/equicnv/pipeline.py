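"""Pipeline driver: simulate → qc → call → merge → annotate → stats [→ integrate].

A :class:`PipelineConfig` (optionally loaded from YAML) fully determines a
run; with the same config and seed the output bundle is byte-identical
(floats are written with fixed formats and the run log carries no
timestamps), so the run log alone suffices to re-execute a run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .annotate import (
    annotate_genic,
    chromosome_enrichment,
    cohort_summary,
    flag_subtelomeric,
    tissue_comparison,
)
from .calling import CallingParams, call_cnvs
from .composite import integrate_studies, normalize_records, novelty_accounting
from .genome import build_genome
from .io import (
    read_chrom_sizes,
    read_gene_annotation,
    write_calls,
    write_chrom_sizes,
    write_cnvrs,
    write_log2_table,
    write_probe_map,
    write_sample_metadata,
    write_truth_bed,
)
from .probes import design_probe_map
from .qc import quality_report
from .regions import consolidate_calls
from .simulate import SampleInfo, SimParams, simulate_cohort

__all__ = ["PipelineConfig", "load_config", "run_pipeline"]


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    genome_preset: str | None = "toy"
    chrom_sizes: str | None = None
    probe_params: dict = field(default_factory=dict)
    samples: list[dict] = field(default_factory=list)
    sim_params: dict = field(default_factory=dict)
    calling_params: dict = field(default_factory=dict)
    annotation_path: str | None = None
    annotation_format: str = "BED"
    subtelomere_window: int = 1_000_000
    # optional cross-study integration: [{study_id, path, convention}, ...]
    studies: list[dict] = field(default_factory=list)
    write_profiles: bool = True

    def __post_init__(self) -> None:
        if (self.genome_preset is None) == (self.chrom_sizes is None):
            raise ValueError("configure exactly one of genome_preset / chrom_sizes")
        if not self.samples:
            raise ValueError("configure at least one sample")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return PipelineConfig(**raw)


def _fmt(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6f")


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute the full pipeline and write the artifact bundle.

    Returns a mapping from artifact name to path. Stage failures propagate
    with the stage name prefixed.
    """
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict[str, Path] = {}

    def stage(name: str, fn):
        try:
            return fn()
        except Exception as exc:
            raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    # genome + probe design
    genome = stage(
        "genome",
        lambda: read_chrom_sizes(config.chrom_sizes)
        if config.chrom_sizes
        else build_genome(preset=config.genome_preset),
    )
    probe_map = stage(
        "probes",
        lambda: design_probe_map(genome, seed=config.seed, **config.probe_params),
    )
    bundle["chrom_sizes"] = out / "chrom_sizes.tsv"
    write_chrom_sizes(genome, bundle["chrom_sizes"])
    bundle["probe_map"] = out / "probe_map.tsv"
    write_probe_map(probe_map, bundle["probe_map"])

    # simulate
    samples = [SampleInfo(**s) for s in config.samples]
    params = SimParams(**config.sim_params)
    hybs, truth = stage(
        "simulate",
        lambda: simulate_cohort(genome, probe_map, samples, params, seed=config.seed),
    )
    bundle["samples"] = out / "samples.tsv"
    write_sample_metadata(samples, bundle["samples"])
    bundle["truth"] = out / "truth.bed"
    write_truth_bed(truth, bundle["truth"])
    if config.write_profiles:
        for hyb in hybs:
            p = out / f"log2_{hyb.sample_id}.tsv"
            write_log2_table(hyb, probe_map, p)
            bundle[f"log2_{hyb.sample_id}"] = p

    # qc
    reports = stage("qc", lambda: [quality_report(h, probe_map) for h in hybs])
    bundle["qc"] = out / "qc.tsv"
    _fmt(
        pd.DataFrame(
            [(r.sample_id, r.dlrsd, r.band, r.n_probes_used) for r in reports],
            columns=["sample_id", "dlrsd", "band", "n_probes_used"],
        ),
        bundle["qc"],
    )

    # call + merge
    def do_call():
        cp = CallingParams(**config.calling_params)
        return [c for h in hybs for c in call_cnvs(h, probe_map, cp)]

    calls = stage("call", do_call)
    bundle["calls"] = out / "calls.tsv"
    write_calls(calls, bundle["calls"])
    breeds = {s.sample_id: s.breed for s in samples}
    cnvrs = stage(
        "merge", lambda: consolidate_calls(calls, genome=genome, sample_breeds=breeds)
    )

    # annotate
    if config.annotation_path:
        genes = stage(
            "annotate",
            lambda: read_gene_annotation(config.annotation_path, config.annotation_format),
        )
        annotate_genic(cnvrs, genes, genome=genome)
    flag_subtelomeric(cnvrs, genome, window=config.subtelomere_window)
    bundle["cnvrs"] = out / "cnvrs.tsv"
    write_cnvrs(cnvrs, bundle["cnvrs"])

    # stats
    def make_stats():
        chrom = chromosome_enrichment(cnvrs, genome)
        if not config.annotation_path:
            chrom = chrom.drop(columns=["n_genic", "n_intergenic"])
        summary = cohort_summary(calls, cnvrs, genome) if calls and cnvrs else None
        return chrom, summary

    chrom_stats, summary = stage("stats", make_stats)
    bundle["chromosome_summary"] = out / "chromosome_summary.tsv"
    _fmt(chrom_stats, bundle["chromosome_summary"])
    if summary is not None:
        bundle["per_sample_counts"] = out / "per_sample_counts.tsv"
        _fmt(summary.per_sample, bundle["per_sample_counts"])
        rows = {
            "mean_calls": summary.mean_calls,
            "median_calls": summary.median_calls,
            "mean_gains": summary.mean_gains,
            "median_gains": summary.median_gains,
            "mean_losses": summary.mean_losses,
            "median_losses": summary.median_losses,
            "n_cnvr": summary.n_cnvr,
            "mean_cnvr_size": summary.mean_cnvr_size,
            "median_cnvr_size": summary.median_cnvr_size,
            "min_cnvr_size": summary.min_cnvr_size,
            "max_cnvr_size": summary.max_cnvr_size,
            "genome_enrichment_percent": summary.genome_enrichment_percent,
        }
        tissues = summary.per_sample["sample_id"].map(
            {s.sample_id: s.tissue for s in samples}
        )
        try:
            t, p = tissue_comparison(summary.per_sample["n_calls"], tissues)
            rows["blood_vs_hair_t"] = t
            rows["blood_vs_hair_p"] = p
        except ValueError:
            pass  # fewer than 2 samples in a tissue group
        bundle["cohort_summary"] = out / "cohort_summary.tsv"
        _fmt(
            pd.DataFrame(sorted(rows.items()), columns=["statistic", "value"]),
            bundle["cohort_summary"],
        )

    # integrate
    if config.studies:
        def make_composite():
            own = [
                normalize_records(
                    pd.DataFrame(
                        [(r.chromosome, r.start, r.end) for r in cnvrs],
                        columns=["chromosome", "start", "end"],
                    ),
                    "one_based_inclusive",
                    genome,
                    study_id="this_study",
                )
            ]
            for s in config.studies:
                df = pd.read_csv(s["path"], sep="\t")
                own.append(
                    normalize_records(df, s["convention"], genome, study_id=s["study_id"])
                )
            return integrate_studies(own, genome=genome)

        composites = stage("integrate", make_composite)
        bundle["composite"] = out / "composite_cnvrs.tsv"
        _fmt(
            pd.DataFrame(
                [
                    (c.chromosome, c.start, c.end, len(c.studies),
                     ",".join(sorted(c.studies)), c.status)
                    for c in composites
                ],
                columns=["chromosome", "start", "end", "n_studies", "studies", "status"],
            ),
            bundle["composite"],
        )
        accounting, totals = novelty_accounting(composites)
        bundle["study_accounting"] = out / "study_accounting.tsv"
        _fmt(accounting, bundle["study_accounting"])

    # run log: everything needed to re-execute this run
    bundle["run_log"] = out / "run_log.yaml"
    with open(bundle["run_log"], "w") as fh:
        yaml.safe_dump(
            {
                "equicnv_version": __version__,
                "config": asdict(config),
                "artifacts": {k: str(v) for k, v in sorted(bundle.items())},
            },
            fh,
            sort_keys=True,
        )
    return bundle
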