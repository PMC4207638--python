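"""Published reference tables for the horse (EquCab2) CNV study cohort.

Two small tables are shipped with the package so that cohort- and
chromosome-level summary statistics can be recomputed without access to the
raw hybridizations:

* :data:`INDIVIDUAL_CALLS` — per-individual CNV call counts (36 discovery
  horses; the two Thoroughbred reference animals are excluded because every
  call is, by construction, mirrored in the reference).
* :data:`CHROMOSOME_CNVRS` — chromosome-wise CNVR statistics (counts by
  state/sharing/annotation, total CNVR length, chromosome length).

Chromosome sizes follow the EquCab2 assembly (chr1–chr31, chrX and the
unplaced-contig pseudo-chromosome chrUn; chrY is absent from the assembly's
sized sequence classes and carries no CNVRs).
"""

from __future__ import annotations

import pandas as pd

# (individual, tissue, calls, gains, losses)
INDIVIDUAL_CALLS: tuple[tuple[str, str, int, int, int], ...] = (
    ("Akhal-Teke 1", "blood", 37, 12, 25),
    ("Akhal-Teke 2", "blood", 26, 13, 13),
    ("American Miniature 1", "blood", 59, 16, 43),
    ("American Miniature 2", "hair", 46, 4, 42),
    ("American Quarter Horse 1", "blood", 12, 0, 12),
    ("American Quarter Horse 2", "blood", 21, 2, 19),
    ("American Quarter Horse 3", "blood", 14, 10, 4),
    ("Arabian 1", "blood", 21, 17, 4),
    ("Arabian 2", "hair", 17, 0, 17),
    ("Belgian 1", "blood", 31, 14, 17),
    ("Belgian 2", "hair", 14, 1, 13),
    ("Caspian Pony 1", "blood", 40, 16, 24),
    ("Caspian Pony 2", "hair", 12, 1, 11),
    ("Clydesdale 1", "blood", 25, 6, 19),
    ("Clydesdale 2", "hair", 16, 1, 15),
    ("Exmoor Pony 1", "blood", 29, 15, 14),
    ("Exmoor Pony 2", "hair", 18, 8, 10),
    ("Fell Pony 1", "blood", 25, 11, 14),
    ("Fell Pony 2", "hair", 47, 11, 36),
    ("Friesian 1", "blood", 29, 6, 23),
    ("Friesian 2", "blood", 39, 10, 29),
    ("Friesian 3", "blood", 41, 9, 32),
    ("Friesian 4", "blood", 22, 12, 10),
    ("Mongolian Native 1", "hair", 22, 1, 21),
    ("Mongolian Native 2", "hair", 18, 2, 16),
    ("Percheron 1", "blood", 17, 11, 6),
    ("Percheron 2", "hair", 12, 1, 11),
    ("Przewalski 1", "fibroblast", 21, 5, 16),
    ("Przewalski 2", "fibroblast", 21, 3, 18),
    ("Sorraia 1", "blood", 36, 8, 28),
    ("Sorraia 2", "hair", 18, 1, 17),
    ("Standardbred 1", "blood", 17, 7, 10),
    ("Standardbred 2", "blood", 44, 13, 31),
    ("Swiss Warmblood 1", "blood", 23, 1, 22),
    ("Swiss Warmblood 2", "blood", 30, 6, 24),
    ("Swiss Warmblood 3", "blood", 29, 9, 20),
)

# (chrom, n_cnvr, shared, private, novel, gains, losses, complex,
#  genic, intergenic, subtelomeric, mean_size, cnvr_length, chr_size)
CHROMOSOME_CNVRS: tuple[tuple, ...] = (
    ("chr1", 21, 8, 13, 9, 2, 17, 2, 14, 7, 0, 241828, 5078379, 185838109),
    ("chr2", 13, 3, 10, 5, 5, 7, 1, 9, 4, 1, 69711, 906246, 120857687),
    ("chr3", 14, 3, 11, 3, 3, 11, 0, 11, 3, 0, 80328, 1124591, 119479920),
    ("chr4", 9, 4, 5, 3, 1, 8, 0, 7, 2, 0, 119780, 1078019, 108569075),
    ("chr5", 7, 5, 2, 2, 3, 3, 1, 4, 3, 2, 60379, 422653, 99680356),
    ("chr6", 11, 5, 6, 3, 1, 9, 1, 9, 2, 0, 206650, 2273151, 84719076),
    ("chr7", 12, 4, 8, 3, 2, 8, 2, 8, 4, 0, 119155, 1429861, 98542428),
    ("chr8", 9, 5, 4, 1, 4, 5, 0, 8, 1, 1, 170025, 1530227, 94057673),
    ("chr9", 14, 6, 8, 11, 5, 8, 1, 4, 10, 1, 45785, 640986, 83561422),
    ("chr10", 16, 7, 9, 7, 4, 12, 0, 13, 3, 1, 72954, 1167268, 83980604),
    ("chr11", 2, 0, 2, 1, 0, 2, 0, 2, 0, 0, 5235, 10470, 61308211),
    ("chr12", 6, 5, 1, 1, 0, 3, 3, 5, 1, 0, 538645, 3231871, 33091231),
    ("chr13", 5, 2, 3, 1, 1, 3, 1, 5, 0, 0, 23837, 119184, 42578167),
    ("chr14", 8, 3, 5, 3, 5, 3, 0, 5, 3, 1, 55523, 444184, 93904894),
    ("chr15", 2, 0, 2, 2, 0, 2, 0, 2, 0, 0, 80429, 160857, 91571448),
    ("chr16", 5, 3, 2, 4, 0, 5, 0, 4, 1, 0, 46120, 230599, 87365405),
    ("chr17", 6, 2, 4, 3, 1, 5, 0, 3, 3, 0, 100527, 603159, 80757907),
    ("chr18", 8, 4, 4, 4, 2, 6, 0, 5, 3, 0, 59831, 478649, 82527541),
    ("chr19", 6, 1, 5, 5, 1, 5, 0, 2, 4, 0, 69818, 418908, 59975221),
    ("chr20", 19, 11, 8, 4, 5, 14, 0, 13, 6, 0, 102575, 1948920, 64166202),
    ("chr21", 2, 1, 1, 1, 0, 1, 1, 2, 0, 1, 230842, 461684, 57723302),
    ("chr22", 4, 2, 2, 1, 1, 3, 0, 2, 2, 0, 48296, 193182, 49946797),
    ("chr23", 8, 2, 6, 4, 1, 6, 1, 5, 3, 0, 122812, 982492, 55726280),
    ("chr24", 4, 1, 3, 2, 1, 3, 0, 3, 1, 0, 104966, 419862, 46749900),
    ("chr25", 3, 2, 1, 1, 0, 2, 1, 2, 1, 0, 46573, 139720, 39536964),
    ("chr26", 6, 4, 2, 3, 1, 5, 0, 2, 4, 0, 105913, 635479, 41866177),
    ("chr27", 2, 1, 1, 0, 0, 1, 1, 2, 0, 0, 15084, 30168, 39960074),
    ("chr28", 4, 2, 2, 2, 1, 3, 0, 2, 2, 0, 37557, 150227, 46177339),
    ("chr29", 3, 2, 1, 2, 1, 2, 0, 3, 0, 0, 250105, 750316, 33672925),
    ("chr30", 4, 1, 3, 2, 2, 2, 0, 2, 2, 0, 67956, 271825, 30062385),
    ("chr31", 2, 1, 1, 2, 0, 2, 0, 0, 2, 1, 34286, 68572, 24984650),
    ("chrX", 12, 5, 7, 10, 4, 7, 1, 0, 12, 1, 87146, 1045753, 124114077),
    ("chrUn", 11, 9, 2, 11, 6, 0, 5, 0, 11, 0, 4118, 45298, 117461955),
)

_CHROM_COLUMNS = (
    "chromosome", "n_cnvr", "shared", "private", "novel", "gains", "losses",
    "complex", "genic", "intergenic", "subtelomeric", "mean_size",
    "cnvr_length", "chrom_length",
)


def individual_calls_frame() -> pd.DataFrame:
    """Per-individual call counts as a DataFrame (36 discovery horses)."""
    return pd.DataFrame(
        list(INDIVIDUAL_CALLS),
        columns=["individual", "tissue", "n_calls", "n_gains", "n_losses"],
    )


def chromosome_cnvr_frame() -> pd.DataFrame:
    """Chromosome-wise CNVR statistics as a DataFrame."""
    return pd.DataFrame(list(CHROMOSOME_CNVRS), columns=_CHROM_COLUMNS)


def equcab2_chrom_sizes() -> tuple[tuple[str, int], ...]:
    """EquCab2 chromosome sizes (chr1–chr31, chrX, chrUn), in assembly order."""
    return tuple((row[0], row[13]) for row in CHROMOSOME_CNVRS)
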