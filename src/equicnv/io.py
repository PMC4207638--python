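"""Readers and writers for the pipeline's on-disk formats.

Native tabular dialect is TSV with a header. Internal coordinates are
1-based inclusive everywhere; BED output converts to 0-based half-open at
the file boundary (``start_bed = start - 1``, ``end_bed = end``) and
round-trips losslessly through :func:`equicnv.composite.normalize_records`.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .annotate import GeneInterval
from .calling import CnvCall, calls_to_frame
from .genome import GenomeBuild
from .probes import ProbeMap
from .regions import Cnvr
from .simulate import Hybridization, SampleInfo, TruthCnv

__all__ = [
    "read_chrom_sizes", "write_chrom_sizes",
    "read_probe_map", "write_probe_map",
    "read_log2_table", "write_log2_table",
    "read_sample_metadata", "write_sample_metadata",
    "read_calls", "write_calls",
    "write_cnvrs", "write_truth_bed", "write_bed",
    "read_gene_annotation",
]


def write_chrom_sizes(genome: GenomeBuild, path) -> None:
    pd.DataFrame(list(genome.chromosomes), columns=["chromosome", "length"]).to_csv(
        path, sep="\t", index=False
    )


def read_chrom_sizes(path) -> GenomeBuild:
    df = pd.read_csv(path, sep="\t")
    return GenomeBuild(tuple(zip(df["chromosome"], df["length"].astype(int))))


def write_probe_map(probe_map: ProbeMap, path) -> None:
    probe_map.table.to_csv(path, sep="\t", index=False)


def read_probe_map(path, genome: GenomeBuild) -> ProbeMap:
    df = pd.read_csv(path, sep="\t")
    return ProbeMap(table=df, genome=genome)


def write_log2_table(hyb: Hybridization, probe_map: ProbeMap, path) -> None:
    pd.DataFrame(
        {"probe_id": probe_map.table["probe_id"], "log2": hyb.log2}
    ).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_log2_table(
    path,
    probe_map: ProbeMap,
    sample: SampleInfo | None = None,
    reference_id: str = "reference",
) -> Hybridization:
    """Load a per-probe log2 TSV and align it to a probe map by probe id.

    Probes absent from the file come back as NaN (missing); file rows with
    unknown probe ids are dropped with a warning; an empty file is an error.
    """
    try:
        df = pd.read_csv(path, sep="\t", dtype={"probe_id": str})
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"empty log2 table: {path}") from exc
    if df.empty:
        raise ValueError(f"empty log2 table: {path}")
    missing_cols = {"probe_id", "log2"} - set(df.columns)
    if missing_cols:
        raise ValueError(f"log2 table {path} lacks columns: {sorted(missing_cols)}")
    bad = pd.to_numeric(df["log2"], errors="coerce").isna() & df["log2"].notna()
    if bad.any():
        line = int(np.flatnonzero(bad)[0]) + 2  # header is line 1
        raise ValueError(f"malformed log2 value at {path} line {line}")
    known = set(probe_map.table["probe_id"])
    unknown = df.loc[~df["probe_id"].isin(known), "probe_id"]
    if len(unknown):
        warnings.warn(f"{len(unknown)} unknown probe ids in {path} ignored (e.g. {unknown.iloc[0]})")
        df = df[df["probe_id"].isin(known)]
    values = (
        df.set_index("probe_id")["log2"]
        .astype(float)
        .reindex(probe_map.table["probe_id"])
        .to_numpy()
    )
    if sample is None:
        sample = SampleInfo(sample_id=str(Path(path).stem), breed="unknown")
    return Hybridization(
        sample_id=sample.sample_id,
        reference_id=reference_id,
        tissue=sample.tissue,
        sex=sample.sex,
        breed=sample.breed,
        log2=values,
    )


def write_sample_metadata(samples: list[SampleInfo], path, references: dict | None = None) -> None:
    refs = references or {}
    pd.DataFrame(
        [
            (s.sample_id, s.breed, s.tissue, s.sex,
             refs.get(s.sample_id, "Twilight" if s.sex == "F" else "Bravo"))
            for s in samples
        ],
        columns=["sample_id", "breed", "tissue", "sex", "reference"],
    ).to_csv(path, sep="\t", index=False)


def read_sample_metadata(path) -> list[SampleInfo]:
    df = pd.read_csv(path, sep="\t")
    return [
        SampleInfo(sample_id=str(r.sample_id), breed=str(r.breed),
                   tissue=str(r.tissue), sex=str(r.sex))
        for r in df.itertuples(index=False)
    ]


def write_calls(calls: list[CnvCall], path) -> None:
    """Calls as TSV, 1-based inclusive coordinates."""
    calls_to_frame(calls).to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_calls(path) -> list[CnvCall]:
    df = pd.read_csv(path, sep="\t")
    return [
        CnvCall(
            sample_id=str(r.sample_id), chromosome=str(r.chromosome),
            start=int(r.start), end=int(r.end), n_probes=int(r.n_probes),
            mean_log2=float(r.mean_log2), direction=str(r.direction),
            zygosity=str(r.zygosity),
        )
        for r in df.itertuples(index=False)
    ]


def cnvrs_to_frame(cnvrs: list[Cnvr]) -> pd.DataFrame:
    rows = []
    for r in cnvrs:
        rows.append({
            "chromosome": r.chromosome,
            "start": r.start,
            "end": r.end,
            "size": r.length,
            "state": r.state,
            "n_samples": len(r.samples),
            "samples": ",".join(sorted(r.samples)),
            "breeds": ",".join(sorted(r.breeds)),
            "sharing": r.sharing,
            "breed_specific": r.breed_specific,
            "genic": "" if r.genic is None else bool(r.genic),
            "genes": ",".join(r.gene_ids),
            "subtelomeric": "" if r.subtelomeric is None else bool(r.subtelomeric),
        })
    return pd.DataFrame(rows)


def write_cnvrs(cnvrs: list[Cnvr], path) -> None:
    cnvrs_to_frame(cnvrs).to_csv(path, sep="\t", index=False)


def write_bed(intervals, path, names=None, extra: dict | None = None) -> None:
    """Write 1-based inclusive intervals as BED (0-based half-open).

    ``intervals`` is a sequence of objects with ``chromosome``/``start``/
    ``end`` attributes; ``names`` gives the BED name column; ``extra`` maps
    further column names to per-interval value lists.
    """
    with open(path, "w") as fh:
        for i, iv in enumerate(intervals):
            fields = [iv.chromosome, str(iv.start - 1), str(iv.end)]
            if names is not None:
                fields.append(str(names[i]))
            for values in (extra or {}).values():
                fields.append(str(values[i]))
            fh.write("\t".join(fields) + "\n")


def write_truth_bed(truth: list[TruthCnv], path) -> None:
    """Truth set as BED with sample, copy-state and expected-log2 columns."""
    write_bed(
        truth,
        path,
        names=[t.sample_id for t in truth],
        extra={
            "copy_state": [t.copy_state for t in truth],
            "expected_log2": [f"{t.expected_log2:.4f}" for t in truth],
        },
    )


_BED_GENE_COLS = ["chromosome", "start", "end", "gene_id"]


def read_gene_annotation(path, format: str = "BED", feature: str = "gene") -> list[GeneInterval]:
    """Load gene intervals from BED or GFF3, normalized to 1-based inclusive.

    For GFF3, only records of the given feature type (default ``gene``) are
    kept; the gene id comes from the ``ID`` attribute (falling back to
    ``gene_id``/``Name``). BED name columns provide the id directly.
    """
    fmt = format.upper()
    if fmt == "BED":
        try:
            df = pd.read_csv(path, sep="\t", header=None, comment="#")
        except pd.errors.EmptyDataError:
            return []
        if df.shape[1] < 3:
            raise ValueError(f"BED file {path} needs at least 3 columns")
        genes = []
        for i, row in enumerate(df.itertuples(index=False)):
            name = str(row[3]) if df.shape[1] > 3 else f"gene{i + 1}"
            genes.append(GeneInterval(name, str(row[0]), int(row[1]) + 1, int(row[2])))
        return genes
    if fmt == "GFF3":
        import gffutils

        db = gffutils.create_db(
            str(path), ":memory:", force=True, keep_order=True,
            merge_strategy="create_unique",
        )
        genes = []
        for feat in db.features_of_type(feature):
            gid = feat.id
            for key in ("gene_id", "Name"):
                if gid.startswith("autogenerated") and key in feat.attributes:
                    gid = feat.attributes[key][0]
            genes.append(GeneInterval(gid, feat.seqid, feat.start, feat.end))
        return genes
    raise ValueError(f"unknown annotation format {format!r}")
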