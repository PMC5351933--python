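"""Footprint-score calibration against motif conservation and TF expression.

Footprint callers emit scores whose scale is not directly interpretable. The
calibration uses two external proxies to pick a score threshold:

* motifs of TFs highly expressed in the tissue (RPKM > 10 in every sample)
  that show central evolutionary conservation (mean log conservation within
  the motif exceeding the mean over its 50-bp flanks by > 0.1) are treated
  as likely-true binding sites;
* motifs of TFs undetectable in the tissue (RPKM = 0 in every sample) are
  treated as likely-false.

For each score centile the ratio of per-bp densities of footprint overlap
with the two motif classes is an estimated TP:FP ratio; the chosen threshold
is the smallest centile whose ratio reaches a target (default 2.0).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, NamedTuple, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ValidationError
from .footprint_processing import ScoredTrack, threshold_by_score
from .genome_intervals import GenomicInterval, IntervalSet

__all__ = [
    "ExpressionTable",
    "TFClasses",
    "CalibrationCurve",
    "classify_tfs",
    "delta_log_conservation",
    "tp_fp_ratio",
    "calibrate_threshold",
]

DEFAULT_CENTILE_GRID: List[float] = [float(c) for c in range(0, 100, 5)]


@dataclass
class ExpressionTable:
    """TF x sample RPKM matrix."""

    values: pd.DataFrame  # index: tf_id, columns: sample_id

    def __post_init__(self) -> None:
        if (self.values.to_numpy() < 0).any():
            raise ValidationError("RPKM values must be >= 0")

    @classmethod
    def read(cls, path) -> "ExpressionTable":
        """Long tab-separated format: tf_id, sample_id, rpkm (no header)."""
        df = pd.read_csv(
            path, sep="\t", header=None, names=["tf_id", "sample_id", "rpkm"],
            dtype={"tf_id": str, "sample_id": str, "rpkm": np.float64},
            float_precision="round_trip",
        )
        wide = df.pivot(index="tf_id", columns="sample_id", values="rpkm")
        return cls(wide)

    def write(self, path) -> None:
        with open(path, "wt") as fh:
            for tf, row in self.values.iterrows():
                for sample, rpkm in row.items():
                    fh.write(f"{tf}\t{sample}\t{float(rpkm)!r}\n")

    def tf_ids(self) -> List[str]:
        return list(self.values.index)


class TFClasses(NamedTuple):
    highly_expressed: Set[str]
    undetectable: Set[str]
    brain_expressed: Set[str]


def classify_tfs(expr: ExpressionTable) -> TFClasses:
    """Expression-based TF classes (they need not partition the universe).

    highly_expressed: RPKM > 10 in every sample; undetectable: RPKM = 0 in
    every sample; brain_expressed: RPKM >= 1 in at least one sample.
    """
    if expr.values.empty:
        raise ValidationError("expression table is empty")
    v = expr.values
    hi = set(v.index[(v > 10).all(axis=1)])
    und = set(v.index[(v == 0).all(axis=1)])
    expressed = set(v.index[(v >= 1).any(axis=1)])
    return TFClasses(hi, und, expressed)


def delta_log_conservation(
    motif: GenomicInterval, track: ScoredTrack, flank_bp: int = 50
) -> Optional[float]:
    """Mean log-conservation inside the motif minus the mean over its flanks.

    Flanks are ``flank_bp`` wide, abutting the motif on each side. Track
    values are taken as already log-scaled. Returns None (with a warning)
    when a flank would run off the chromosome.
    """
    if len(motif) == 0:
        raise ValidationError("zero-length motif")
    chrom_len = track.data.get(motif.chrom, np.empty(0)).size
    if motif.start - flank_bp < 0 or motif.end + flank_bp > chrom_len:
        warnings.warn(
            f"motif {motif.chrom}:{motif.start}-{motif.end} skipped: "
            f"{flank_bp} bp flanks exceed chromosome bounds"
        )
        return None
    inside = track.mean_over(motif.chrom, motif.start, motif.end)
    flank = np.concatenate(
        [
            track.window(motif.chrom, motif.start - flank_bp, motif.start),
            track.window(motif.chrom, motif.end, motif.end + flank_bp),
        ]
    )
    return float(inside - flank.mean())


def _split_motifs(
    motifs: IntervalSet,
    hi: Set[str],
    und: Set[str],
    track: Optional[ScoredTrack],
    delta_threshold: float,
    flank_bp: int,
) -> Tuple[IntervalSet, IntervalSet]:
    """(conserved hi-TF motifs, und-TF motifs). The conservation gate applies
    only to the expressed class; the undetectable side is ungated."""
    hi_set: List[GenomicInterval] = []
    und_set: List[GenomicInterval] = []
    for m in motifs:
        tf = m.tags.get("tf_id", m.name)
        if tf in und:
            und_set.append(m)
        if tf in hi:
            if track is not None:
                d = delta_log_conservation(m, track, flank_bp)
                if d is None or d <= delta_threshold:
                    continue
            hi_set.append(m)
    return IntervalSet(hi_set), IntervalSet(und_set)


def tp_fp_ratio(
    fp: IntervalSet,
    motifs: IntervalSet,
    hi: Set[str],
    und: Set[str],
    track: Optional[ScoredTrack] = None,
    delta_threshold: float = 0.1,
    flank_bp: int = 50,
) -> float:
    """Estimated TP:FP ratio for a footprint set.

    numerator   = (fraction of footprints overlapping >= 1 conserved
                   expressed-TF motif) / (bp of the expressed-TF motif track)
    denominator = (fraction overlapping >= 1 undetectable-TF motif)
                  / (bp of the undetectable-TF motif track)

    Returns math.inf when no footprint overlaps the undetectable track.
    """
    hi_motifs, und_motifs = _split_motifs(
        motifs, hi, und, track, delta_threshold, flank_bp
    )
    und_bp = und_motifs.covered_bp()
    if und_bp == 0:
        raise ConfigurationError(
            "undetectable-TF motif track is empty: ratio denominator undefined"
        )
    hi_bp = hi_motifs.covered_bp()
    if len(fp) == 0 or hi_bp == 0:
        return 0.0
    hi_frac = float(fp.intersect_any(hi_motifs).mean())
    und_frac = float(fp.intersect_any(und_motifs).mean())
    if und_frac == 0.0:
        return math.inf
    return (hi_frac / hi_bp) / (und_frac / und_bp)


@dataclass
class CalibrationCurve:
    """TP:FP ratio as a function of footprint score centile."""

    centiles: List[float]
    n_footprints: List[int]
    hi_density: List[float]
    und_density: List[float]
    ratio: List[float]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "centile": self.centiles,
                "n_footprints": self.n_footprints,
                "expressed_density": self.hi_density,
                "undetectable_density": self.und_density,
                "tp_fp_ratio": self.ratio,
            }
        )


def calibrate_threshold(
    fp: IntervalSet,
    motifs: IntervalSet,
    classes: TFClasses,
    track: Optional[ScoredTrack],
    target_ratio: float = 2.0,
    centile_grid: Optional[Sequence[float]] = None,
    delta_threshold: float = 0.1,
    flank_bp: int = 50,
) -> Tuple[Optional[float], CalibrationCurve]:
    """Pick the smallest score centile whose TP:FP ratio reaches the target.

    Returns (chosen_centile, curve); chosen_centile is None when no grid
    point reaches the target (the curve is still returned for reporting).
    """
    grid = sorted(centile_grid) if centile_grid is not None else DEFAULT_CENTILE_GRID
    hi_motifs, und_motifs = _split_motifs(
        motifs, classes.highly_expressed, classes.undetectable,
        track, delta_threshold, flank_bp,
    )
    und_bp = und_motifs.covered_bp()
    if und_bp == 0:
        raise ConfigurationError("undetectable-TF motif track is empty")
    hi_bp = hi_motifs.covered_bp()

    centiles, ns, hi_d, und_d, ratios = [], [], [], [], []
    for c in grid:
        kept = threshold_by_score(fp, c)
        n = len(kept)
        if n == 0 or hi_bp == 0:
            hd = ud = 0.0
            r = 0.0
        else:
            hf = float(kept.intersect_any(hi_motifs).mean())
            uf = float(kept.intersect_any(und_motifs).mean())
            hd = hf / hi_bp
            ud = uf / und_bp
            r = math.inf if ud == 0.0 and hd > 0 else (hd / ud if ud > 0 else 0.0)
        centiles.append(float(c))
        ns.append(n)
        hi_d.append(hd)
        und_d.append(ud)
        ratios.append(r)
    curve = CalibrationCurve(centiles, ns, hi_d, und_d, ratios)
    chosen = next(
        (c for c, r in zip(curve.centiles, curve.ratio) if r >= target_ratio), None
    )
    return chosen, curve
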