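"""Genome builds: ordered chromosomes with lengths.

A :class:`GenomeBuild` is the coordinate authority for every interval in the
pipeline. All internal coordinates are 1-based inclusive; conversion to BED's
0-based half-open convention happens only at file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from . import published

__all__ = ["GenomeBuild", "build_genome"]


@dataclass(frozen=True)
class GenomeBuild:
    """Ordered list of (chromosome name, length in bp)."""

    chromosomes: tuple[tuple[str, int], ...]
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        names = [name for name, _ in self.chromosomes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate chromosome names: {dupes}")
        for name, length in self.chromosomes:
            if length <= 0:
                raise ValueError(f"non-positive length for {name}: {length}")
        object.__setattr__(
            self, "_index", {name: i for i, (name, _) in enumerate(self.chromosomes)}
        )

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.chromosomes)

    @property
    def total_length(self) -> int:
        return sum(length for _, length in self.chromosomes)

    def length(self, name: str) -> int:
        return self.chromosomes[self._index[name]][1]

    def order(self, name: str) -> int:
        """Stable sort key of a chromosome; raises KeyError if unknown."""
        return self._index[name]

    def __contains__(self, name: str) -> bool:
        return name in self._index

    def __len__(self) -> int:
        return len(self.chromosomes)


_TOY = (("chr1", 10_000_000), ("chr2", 5_000_000), ("chr3", 2_000_000))


def build_genome(
    spec: list[tuple[str, int]] | None = None,
    preset: str | None = None,
) -> GenomeBuild:
    """Create a genome build from an explicit (name, length) list or a preset.

    Presets
    -------
    ``equcab2_table2``
        The 33 sized sequence classes of the horse EquCab2 assembly
        (chr1–chr31, chrX, chrUn), total 2,484,515,402 bp.
    ``toy``
        Three chromosomes of 10 Mb, 5 Mb and 2 Mb for tests and examples.
    """
    if (spec is None) == (preset is None):
        raise ValueError("provide exactly one of spec= or preset=")
    if preset is not None:
        if preset == "equcab2_table2":
            return GenomeBuild(published.equcab2_chrom_sizes())
        if preset == "toy":
            return GenomeBuild(_TOY)
        raise ValueError(f"unknown preset: {preset!r}")
    return GenomeBuild(tuple((str(n), int(l)) for n, l in spec))
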