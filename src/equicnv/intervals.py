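"""Single-linkage merging of 1-based inclusive intervals.

The merge relation used throughout: two intervals on the same chromosome
merge iff they overlap by at least one base or share a boundary coordinate
(previous end == next start — which, in 1-based inclusive space, is itself
a one-base overlap). Contiguous-but-not-touching intervals
(end + 1 == start) do not merge. Merging is transitive.
"""

from __future__ import annotations

from typing import Iterable, Sequence, TypeVar

T = TypeVar("T")

__all__ = ["merge_groups"]


def merge_groups(
    items: Sequence[T],
    chrom_of,
    start_of,
    end_of,
    chrom_order=None,
) -> list[tuple[str, int, int, list[T]]]:
    """Group items into merged regions.

    Returns ``(chromosome, start, end, members)`` tuples where the span is
    the union of member spans, ordered by (chromosome, start). ``chrom_order``
    maps a chromosome name to a sort key; by default chromosomes sort by
    name.
    """
    for it in items:
        if end_of(it) < start_of(it):
            raise ValueError(
                f"interval end < start: {chrom_of(it)}:{start_of(it)}-{end_of(it)}"
            )
    if chrom_order is None:
        names = sorted({chrom_of(it) for it in items})
        order = {n: i for i, n in enumerate(names)}
    else:
        order = None
    key = (lambda it: (order[chrom_of(it)], start_of(it), end_of(it))) if order is not None \
        else (lambda it: (chrom_order(chrom_of(it)), start_of(it), end_of(it)))
    out: list[tuple[str, int, int, list[T]]] = []
    cur: list[T] = []
    cur_chrom, cur_start, cur_end = None, 0, 0
    for it in sorted(items, key=key):
        c, s, e = chrom_of(it), start_of(it), end_of(it)
        if cur and c == cur_chrom and s <= cur_end:
            cur.append(it)
            cur_end = max(cur_end, e)
        else:
            if cur:
                out.append((cur_chrom, cur_start, cur_end, cur))
            cur = [it]
            cur_chrom, cur_start, cur_end = c, s, e
    if cur:
        out.append((cur_chrom, cur_start, cur_end, cur))
    return out
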