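"""Genomic interval algebra on 0-based half-open (BED convention) coordinates.

All positional inputs to the pipeline (peak calls, exons, coverage runs)
are reduced to :class:`GenomicInterval` / :class:`IntervalSet` and the
set algebra below: union-merge for pooling replicate peak calls,
intersection for chromatin pseudostates, subtraction for exon exclusion
and flank padding for peak borders.

Bookended intervals (``end == next.start``) merge, matching the union
semantics of pooled peaks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np


class IntervalError(ValueError):
    """A malformed interval or an invalid interval operation."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on ``chrom``."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise IntervalError(f"empty chromosome name in interval {self!r}")
        if self.start < 0:
            raise IntervalError(f"negative start in interval {self!r}")
        if self.end <= self.start:
            raise IntervalError(
                f"end must exceed start in interval "
                f"{self.chrom}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"


@dataclass
class IntervalSet:
    """An ordered collection of intervals, normalizable to a disjoint union.

    After :meth:`normalize` the intervals are sorted by ``(chrom, start)``
    and pairwise non-overlapping (bookended runs merged).
    """

    intervals: list[GenomicInterval] = field(default_factory=list)

    @classmethod
    def from_tuples(cls, tuples: Iterable[tuple[str, int, int]]) -> "IntervalSet":
        return cls([GenomicInterval(c, s, e) for c, s, e in tuples])

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __len__(self) -> int:
        return len(self.intervals)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    @property
    def total_bases(self) -> int:
        return sum(len(iv) for iv in self.intervals)

    def by_chrom(self) -> dict[str, np.ndarray]:
        """Per-chromosome ``(n, 2)`` start/end arrays in input order."""
        out: dict[str, list[tuple[int, int]]] = {}
        for iv in self.intervals:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
        return {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}

    def normalize(self) -> "IntervalSet":
        return merge_intervals(self)


def _from_chrom_arrays(arrays: Mapping[str, np.ndarray]) -> IntervalSet:
    ivs = []
    for chrom in sorted(arrays):
        for s, e in arrays[chrom]:
            ivs.append(GenomicInterval(chrom, int(s), int(e)))
    return IntervalSet(ivs)


def merge_intervals(intervals: IntervalSet) -> IntervalSet:
    """Minimal sorted set covering exactly the union of the input.

    Overlapping and bookended intervals coalesce; distinct chromosomes
    never interact. Idempotent.
    """
    merged: dict[str, np.ndarray] = {}
    for chrom, arr in intervals.by_chrom().items():
        arr = arr[np.lexsort((arr[:, 1], arr[:, 0]))]
        out: list[list[int]] = []
        for s, e in arr:
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], int(e))
            else:
                out.append([int(s), int(e)])
        merged[chrom] = np.asarray(out, dtype=np.int64)
    return _from_chrom_arrays(merged)


def intersect_sets(sets: Sequence[IntervalSet]) -> IntervalSet:
    """Bases present in every input set, as a normalized IntervalSet.

    Used to build chromatin pseudostates as the intersection of pooled
    histone-modification peak sets.
    """
    if len(sets) < 2:
        raise IntervalError("intersect_sets requires at least 2 interval sets")
    acc = merge_intervals(sets[0])
    for other in sets[1:]:
        acc = _intersect_pair(acc, merge_intervals(other))
    return acc


def _intersect_pair(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    a_arr, b_arr = a.by_chrom(), b.by_chrom()
    out: dict[str, np.ndarray] = {}
    for chrom in a_arr.keys() & b_arr.keys():
        pieces = []
        bi = 0
        bs = b_arr[chrom]
        for s, e in a_arr[chrom]:
            while bi < len(bs) and bs[bi, 1] <= s:
                bi += 1
            j = bi
            while j < len(bs) and bs[j, 0] < e:
                lo, hi = max(s, bs[j, 0]), min(e, bs[j, 1])
                if hi > lo:
                    pieces.append((lo, hi))
                j += 1
        if pieces:
            out[chrom] = np.asarray(pieces, dtype=np.int64)
    return _from_chrom_arrays(out)


def subtract_intervals(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    """Bases in ``a`` but not in ``b``; intervals may split.

    Implements exon exclusion from padded peak sets.
    """
    a = merge_intervals(a)
    b = merge_intervals(b)
    b_arr = b.by_chrom()
    out: dict[str, list[tuple[int, int]]] = {}
    for iv in a:
        cuts = b_arr.get(iv.chrom)
        if cuts is None:
            out.setdefault(iv.chrom, []).append((iv.start, iv.end))
            continue
        pos = iv.start
        for s, e in cuts:
            if e <= iv.start or s >= iv.end:
                continue
            if s > pos:
                out.setdefault(iv.chrom, []).append((pos, int(s)))
            pos = max(pos, int(e))
        if pos < iv.end:
            out.setdefault(iv.chrom, []).append((pos, iv.end))
    return _from_chrom_arrays(
        {c: np.asarray(v, dtype=np.int64) for c, v in out.items()}
    )


def pad_intervals(
    intervals: IntervalSet, flank: int, chrom_sizes: Mapping[str, int]
) -> IntervalSet:
    """Extend each interval by ``flank`` bases on both sides, clip to the
    chromosome, and re-normalize.

    The pipeline uses a 20 bp flank so binding motifs on peak borders are
    retained.
    """
    if flank < 0:
        raise IntervalError("flank must be non-negative")
    padded = []
    for iv in intervals:
        if iv.chrom not in chrom_sizes:
            raise IntervalError(
                f"chromosome {iv.chrom!r} absent from chrom_sizes"
            )
        padded.append(
            GenomicInterval(
                iv.chrom,
                max(0, iv.start - flank),
                min(chrom_sizes[iv.chrom], iv.end + flank),
            )
        )
    return merge_intervals(IntervalSet(padded))


@dataclass
class CoverageTrack:
    """Per-chromosome step/value runs giving per-base read depth.

    Sparse bedGraph convention: bases absent from the track have depth 0
    (the default; ``uncovered='nan'`` in :func:`mean_depth` averages over
    covered bases only, mirroring the ambiguity in bigWig summary tools).
    """

    runs: dict[str, np.ndarray] = field(default_factory=dict)
    # runs[chrom]: float array (n, 3) of (start, end, depth), sorted, disjoint

    @classmethod
    def from_records(
        cls, records: Iterable[tuple[str, int, int, float]]
    ) -> "CoverageTrack":
        per: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, s, e, d in records:
            if d < 0:
                raise IntervalError(f"negative depth {d} at {chrom}:{s}-{e}")
            if e <= s:
                raise IntervalError(f"empty coverage run at {chrom}:{s}-{e}")
            per.setdefault(chrom, []).append((s, e, d))
        runs = {}
        for chrom, rr in per.items():
            arr = np.asarray(sorted(rr), dtype=float)
            if np.any(arr[1:, 0] < arr[:-1, 1]):
                raise IntervalError(f"overlapping coverage runs on {chrom}")
            runs[chrom] = arr
        return cls(runs)


def mean_depth(
    track: CoverageTrack, iv: GenomicInterval, uncovered: str = "zero"
) -> float:
    """Arithmetic mean per-base depth of ``track`` over ``iv``.

    ``uncovered='zero'`` (default) counts bases missing from the track as
    depth 0; ``uncovered='nan'`` averages covered bases only and returns
    NaN if none are covered.
    """
    if uncovered not in ("zero", "nan"):
        raise ValueError("uncovered must be 'zero' or 'nan'")
    runs = track.runs.get(iv.chrom)
    total = 0.0
    covered = 0
    if runs is not None:
        s = np.maximum(runs[:, 0], iv.start)
        e = np.minimum(runs[:, 1], iv.end)
        w = np.maximum(e - s, 0)
        total = float(np.sum(w * runs[:, 2]))
        covered = int(np.sum(w))
    if uncovered == "zero":
        return total / len(iv)
    return total / covered if covered else float("nan")
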