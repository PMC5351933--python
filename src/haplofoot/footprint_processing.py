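"""Footprint quality control.

Footprint calls (short DNase-protected intervals inside DHS, typically
11-22 bp) are filtered before any overlap analysis: blacklist removal,
autosome restriction, width bounds, a cut-profile artefact filter, and an
optional score-centile threshold.

The artefact filter targets PCR/alignment spikes: a footprint is removed
when a single base position contributes more than ``skew_threshold`` (default
50%) of the total DNase cut signal within +-100 bp of the footprint centre.
An alternative reading — left/right half-window imbalance — is available via
``mode="leftright"``; the spike reading is the default.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import ValidationError
from .genome_intervals import GenomicInterval, IntervalSet

__all__ = [
    "ScoredTrack",
    "filter_blacklist",
    "filter_autosomes",
    "filter_width",
    "filter_artefacts",
    "threshold_by_score",
    "footprint_centre",
    "qc_pipeline",
]


@dataclass
class ScoredTrack:
    """Per-base numeric track over named chromosomes; missing positions read 0."""

    data: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.data = {c: np.asarray(v, dtype=np.float64) for c, v in self.data.items()}

    @classmethod
    def zeros(cls, chrom_lengths: Dict[str, int]) -> "ScoredTrack":
        return cls({c: np.zeros(n) for c, n in chrom_lengths.items()})

    def chrom_lengths(self) -> Dict[str, int]:
        return {c: v.size for c, v in self.data.items()}

    def window(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Values over [start, end), zero-padded outside the defined range."""
        arr = self.data.get(chrom)
        out = np.zeros(end - start)
        if arr is None:
            return out
        lo, hi = max(start, 0), min(end, arr.size)
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def mean_over(self, chrom: str, start: int, end: int) -> float:
        if end <= start:
            raise ValidationError("zero-length span has no mean")
        return float(self.window(chrom, start, end).mean())

    # 3-column per-base text format: chrom <TAB> pos0 <TAB> value, zeros omitted.
    @classmethod
    def read(cls, path, chrom_lengths: Dict[str, int]) -> "ScoredTrack":
        track = cls.zeros(chrom_lengths)
        df = pd.read_csv(
            path, sep="\t", header=None, names=["chrom", "pos", "value"],
            dtype={"chrom": str, "pos": np.int64, "value": np.float64},
            float_precision="round_trip",
        )
        for chrom, grp in df.groupby("chrom", sort=False):
            if chrom in track.data:
                track.data[chrom][grp["pos"].to_numpy()] = grp["value"].to_numpy()
        return track

    def write(self, path) -> None:
        with open(path, "wt") as fh:
            for chrom, arr in self.data.items():
                nz = np.flatnonzero(arr)
                for p in nz:
                    # repr of a Python float is the shortest round-trip form
                    fh.write(f"{chrom}\t{p}\t{float(arr[p])!r}\n")


def footprint_centre(iv: GenomicInterval) -> int:
    """Centre of a footprint; even lengths round down: start + floor(len/2)."""
    return iv.start + len(iv) // 2


def filter_blacklist(fp: IntervalSet, blacklist: IntervalSet) -> IntervalSet:
    """Drop footprints overlapping a blacklisted region by >= 1 bp."""
    hit = fp.intersect_any(blacklist)
    return IntervalSet([iv for iv, h in zip(fp, hit) if not h])


def filter_autosomes(fp: IntervalSet, autosome_names: Sequence[str]) -> IntervalSet:
    allowed = set(autosome_names)
    return fp.filter(lambda iv: iv.chrom in allowed)


def filter_width(fp: IntervalSet, min_bp: int, max_bp: int) -> IntervalSet:
    if min_bp > max_bp:
        raise ValidationError("min_bp must be <= max_bp")
    return fp.filter(lambda iv: min_bp <= len(iv) <= max_bp)


def filter_artefacts(
    fp: IntervalSet,
    cuts: ScoredTrack,
    half_window_bp: int = 100,
    skew_threshold: float = 0.5,
    mode: str = "spike",
) -> Tuple[IntervalSet, IntervalSet]:
    """Partition footprints into (kept, removed) by cut-profile skew.

    ``mode="spike"`` (default): ratio = max single-position value / window
    total over centre +- half_window_bp; removed iff ratio > skew_threshold.
    ``mode="leftright"``: ratio = |left half sum - right half sum| / window
    total. All-zero windows are kept with ratio 0. The diagnostic ratio is
    attached to each output interval under ``tags["skew_ratio"]``.
    """
    if mode not in ("spike", "leftright"):
        raise ValidationError(f"unknown artefact mode {mode!r}")
    kept: List[GenomicInterval] = []
    removed: List[GenomicInterval] = []
    for iv in fp:
        c = footprint_centre(iv)
        w = cuts.window(iv.chrom, c - half_window_bp, c + half_window_bp + 1)
        total = w.sum()
        if total <= 0:
            ratio = 0.0
        elif mode == "spike":
            ratio = float(w.max() / total)
        else:
            half = w.size // 2
            ratio = float(abs(w[:half].sum() - w[half + 1 :].sum()) / total)
        tagged = replace(iv, tags={**iv.tags, "skew_ratio": ratio})
        (removed if ratio > skew_threshold else kept).append(tagged)
    return IntervalSet(kept), IntervalSet(removed)


def threshold_by_score(fp: IntervalSet, centile: float) -> IntervalSet:
    """Keep footprints scoring at or above the given centile of the input's scores.

    The centile is computed on the input set itself, so this filter does not
    commute with the others and is applied last in the QC pipeline.
    """
    if not 0 <= centile <= 100:
        raise ValidationError("centile must be in [0, 100]")
    scores = [iv.score for iv in fp]
    if any(s is None for s in scores):
        raise ValidationError("threshold_by_score requires every footprint scored")
    if not scores:
        return IntervalSet()
    cutoff = float(np.percentile(np.asarray(scores, dtype=np.float64), centile))
    return fp.filter(lambda iv: iv.score >= cutoff)


def qc_pipeline(
    fp: IntervalSet,
    blacklist: IntervalSet,
    autosomes: Sequence[str],
    cuts: ScoredTrack,
    min_width: int = 11,
    max_width: int = 22,
    artefact_half_window: int = 100,
    artefact_skew: float = 0.5,
    score_centile: float | None = None,
) -> Tuple[IntervalSet, Dict[str, int]]:
    """Apply the full footprint QC in order; returns kept set and stage counts."""
    counts = {"input": len(fp)}
    fp = filter_blacklist(fp, blacklist)
    counts["after_blacklist"] = len(fp)
    fp = filter_autosomes(fp, autosomes)
    counts["after_autosomes"] = len(fp)
    fp = filter_width(fp, min_width, max_width)
    counts["after_width"] = len(fp)
    fp, removed = filter_artefacts(fp, cuts, artefact_half_window, artefact_skew)
    counts["after_artefacts"] = len(fp)
    counts["artefacts_removed"] = len(removed)
    if score_centile is not None:
        fp = threshold_by_score(fp, score_centile)
    counts["after_score_threshold"] = len(fp)
    return fp, counts
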