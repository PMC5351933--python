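"""Genomic interval model and BED I/O.

All coordinates are 0-based half-open (BED convention). Variant positions
arriving 1-based (VCF-like input) are converted on read to single-base
intervals [pos-1, pos). Overlap means >= 1 shared base: the touching
intervals [0, 10) and [10, 20) do NOT overlap. Strand is stored but ignored
by every operation.
"""

from __future__ import annotations

import gzip
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np

from .errors import BedParseError, ValidationError

__all__ = ["GenomicInterval", "IntervalSet", "read_bed", "write_bed"]


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic span with optional label, score and annotations."""

    chrom: str
    start: int
    end: int
    name: Optional[str] = None
    score: Optional[float] = None
    strand: str = "."
    tags: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("chrom must be non-empty")
        if self.start < 0:
            raise ValidationError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValidationError(
                f"end must exceed start, got [{self.start}, {self.end})"
            )

    def __len__(self) -> int:
        return self.end - self.start


class IntervalSet:
    """An ordered collection of :class:`GenomicInterval`.

    Intervals are kept in input order; per-chromosome sorted views and merged
    (non-overlapping) views are built lazily and cached. Duplicates are
    permitted.
    """

    def __init__(self, intervals: Iterable[GenomicInterval] = ()) -> None:
        self.intervals: List[GenomicInterval] = list(intervals)
        self._merged_cache: Dict[str, Tuple[np.ndarray, np.ndarray]] = {}

    # -- basic container protocol -------------------------------------------------
    def __len__(self) -> int:
        return len(self.intervals)

    def __iter__(self) -> Iterator[GenomicInterval]:
        return iter(self.intervals)

    def __getitem__(self, i):
        return self.intervals[i]

    def __eq__(self, other) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return self.intervals == other.intervals

    def chroms(self) -> List[str]:
        seen = dict.fromkeys(iv.chrom for iv in self.intervals)
        return list(seen)

    def total_bp(self) -> int:
        """Sum of interval lengths (duplicates counted twice)."""
        return sum(len(iv) for iv in self.intervals)

    def covered_bp(self) -> int:
        """Number of distinct covered bases (union of intervals)."""
        total = 0
        for chrom in self.chroms():
            s, e = self.merged(chrom)
            total += int((e - s).sum())
        return total

    def has_duplicates(self) -> bool:
        seen = set()
        for iv in self.intervals:
            key = (iv.chrom, iv.start, iv.end)
            if key in seen:
                return True
            seen.add(key)
        return False

    # -- sorted / merged views ----------------------------------------------------
    def merged(self, chrom: str) -> Tuple[np.ndarray, np.ndarray]:
        """Sorted, merged (non-overlapping) start/end arrays for one chromosome.

        Abutting intervals are merged; with half-open coordinates this does
        not change overlap truth or covered bp.
        """
        if chrom not in self._merged_cache:
            spans = sorted(
                (iv.start, iv.end) for iv in self.intervals if iv.chrom == chrom
            )
            starts: List[int] = []
            ends: List[int] = []
            for s, e in spans:
                if starts and s <= ends[-1]:
                    ends[-1] = max(ends[-1], e)
                else:
                    starts.append(s)
                    ends.append(e)
            self._merged_cache[chrom] = (
                np.asarray(starts, dtype=np.int64),
                np.asarray(ends, dtype=np.int64),
            )
        return self._merged_cache[chrom]

    def sorted(self) -> "IntervalSet":
        return IntervalSet(
            sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))
        )

    # -- set operations -----------------------------------------------------------
    def intersect_any(self, annotation: "IntervalSet") -> np.ndarray:
        """Boolean per interval of ``self``: does it overlap ``annotation`` by >= 1 bp?"""
        out = np.zeros(len(self.intervals), dtype=bool)
        by_chrom: Dict[str, List[int]] = {}
        for i, iv in enumerate(self.intervals):
            by_chrom.setdefault(iv.chrom, []).append(i)
        for chrom, idx in by_chrom.items():
            mstarts, mends = annotation.merged(chrom)
            if mstarts.size == 0:
                continue
            qs = np.asarray([self.intervals[i].start for i in idx], dtype=np.int64)
            qe = np.asarray([self.intervals[i].end for i in idx], dtype=np.int64)
            # Merged intervals are disjoint and sorted, so the only candidate
            # overlapping a query is the last one starting before query end.
            j = np.searchsorted(mstarts, qe, side="left") - 1
            hit = (j >= 0) & (mends[np.clip(j, 0, None)] > qs)
            out[np.asarray(idx)] = hit
        return out

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Maximal sub-intervals of ``self`` not covered by ``other``.

        Labels, scores and tags of the source interval are carried onto every
        surviving fragment.
        """
        result: List[GenomicInterval] = []
        for iv in self.intervals:
            bstarts, bends = other.merged(iv.chrom)
            if bstarts.size == 0:
                result.append(iv)
                continue
            lo = np.searchsorted(bends, iv.start, side="right")
            hi = np.searchsorted(bstarts, iv.end, side="left")
            cursor = iv.start
            for k in range(lo, hi):
                if bstarts[k] > cursor:
                    result.append(replace(iv, start=cursor, end=int(bstarts[k])))
                cursor = max(cursor, int(bends[k]))
            if cursor < iv.end:
                result.append(replace(iv, start=cursor, end=iv.end))
        return IntervalSet(result)

    def intersection(self, other: "IntervalSet") -> "IntervalSet":
        """Merged intervals covering exactly the bases present in both sets."""
        out: List[GenomicInterval] = []
        for chrom in self.chroms():
            astarts, aends = self.merged(chrom)
            bstarts, bends = other.merged(chrom)
            if bstarts.size == 0:
                continue
            for s, e in zip(astarts, aends):
                lo = np.searchsorted(bends, s, side="right")
                hi = np.searchsorted(bstarts, e, side="left")
                for k in range(lo, hi):
                    out.append(
                        GenomicInterval(
                            chrom, max(s, int(bstarts[k])), min(e, int(bends[k]))
                        )
                    )
        return IntervalSet(out)

    def filter(self, predicate) -> "IntervalSet":
        return IntervalSet([iv for iv in self.intervals if predicate(iv)])

    def coverage_mask(self, chrom_lengths: Dict[str, int]) -> Dict[str, np.ndarray]:
        """Dense boolean per-base coverage, one array per chromosome."""
        masks = {c: np.zeros(n, dtype=bool) for c, n in chrom_lengths.items()}
        for chrom in self.chroms():
            if chrom not in masks:
                continue
            s, e = self.merged(chrom)
            m = masks[chrom]
            for a, b in zip(s, e):
                m[a : min(b, m.size)] = True
        return masks


# -- BED I/O ------------------------------------------------------------------


def _open_text(path) -> io.TextIOBase:
    path = Path(path)
    if path.suffix == ".gz":
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "rt")


def read_bed(path) -> IntervalSet:
    """Read BED3/BED6 (tab-separated, no header; gzip-transparent).

    Column 4 is the name, column 5 the score (kept only when numeric),
    column 6 the strand.
    """
    intervals: List[GenomicInterval] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise BedParseError(
                    f"{path}: line {lineno}: expected >= 3 tab-separated columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinate"
                ) from exc
            name = fields[3] if len(fields) > 3 and fields[3] != "." else None
            score: Optional[float] = None
            if len(fields) > 4:
                try:
                    score = float(fields[4])
                except ValueError:
                    score = None
            strand = fields[5] if len(fields) > 5 else "."
            try:
                intervals.append(
                    GenomicInterval(fields[0], start, end, name, score, strand)
                )
            except ValidationError as exc:
                raise BedParseError(f"{path}: line {lineno}: {exc}") from exc
    return IntervalSet(intervals)


def write_bed(ivs: IntervalSet, path, bed6: bool = True) -> None:
    """Write BED6 (or BED3) with '.' placeholders for missing name/score."""
    with open(path, "wt") as fh:
        for iv in ivs:
            if bed6:
                # repr gives the shortest decimal that round-trips the float
                score = "." if iv.score is None else repr(float(iv.score))
                name = iv.name if iv.name is not None else "."
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\t{score}\t{iv.strand}\n"
                )
            else:
                fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")
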