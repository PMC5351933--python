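"""The Π statistic: proportion of haplotype blocks explained by an annotation.

A haplotype block counts as "hit" when at least one member SNV's single-base
interval overlaps the annotation — a binary call, unweighted by how many
members hit or at what r². Π is reported across an ascending r² grid and
across nested annotation layers (DHS ⊇ footprints ⊇ footprint∩motif), where
it is non-increasing in the threshold and ordered across layers by nesting.

The grid evaluation avoids re-expanding blocks per threshold: for each
sentinel the maximum r² among annotation-flagged variants inside its window
is computed once, and the block hits at threshold t iff that maximum is
>= t (the sentinel itself participates at r² = 1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd

from .errors import UndefinedStatisticError, ValidationError
from .genome_intervals import IntervalSet
from .ld_haplotypes import (
    DEFAULT_WINDOW_BP,
    HaplotypeBlock,
    PhasedPanel,
    r2_many_vs_many,
)

__all__ = [
    "PiCurve",
    "pi_statistic",
    "pi_curve",
    "conditional_pi",
    "variant_annotation_flags",
]


@dataclass
class PiCurve:
    r2_grid: List[float]
    layers: List[str]
    values: Dict[str, List[float]]  # layer -> proportion per threshold
    denominators: List[int]  # haplotype-block count per threshold

    def to_dataframe(self) -> pd.DataFrame:
        rows = []
        for i, t in enumerate(self.r2_grid):
            for layer in self.layers:
                rows.append(
                    {
                        "r2_threshold": t,
                        "layer": layer,
                        "pi": self.values[layer][i],
                        "n_blocks": self.denominators[i],
                    }
                )
        return pd.DataFrame(rows)


def variant_annotation_flags(
    panel: PhasedPanel, annotation: IntervalSet
) -> np.ndarray:
    """Per panel variant: does its 1-bp interval [pos-1, pos) overlap the set?"""
    flags = np.zeros(panel.n_variants, dtype=bool)
    for chrom in np.unique(panel.chrom):
        sel = np.flatnonzero(panel.chrom == chrom)
        pos0 = panel.pos[sel] - 1
        mstarts, mends = annotation.merged(str(chrom))
        if mstarts.size == 0:
            continue
        j = np.searchsorted(mstarts, pos0, side="right") - 1
        flags[sel] = (j >= 0) & (mends[np.clip(j, 0, None)] > pos0)
    return flags


def pi_statistic(
    blocks: Sequence[HaplotypeBlock],
    annotation: IntervalSet,
    panel: PhasedPanel,
) -> float:
    """Fraction of blocks with >= 1 member SNV overlapping the annotation."""
    if len(blocks) == 0:
        raise UndefinedStatisticError("no haplotype blocks: Π undefined")
    flags = variant_annotation_flags(panel, annotation)
    hits = 0
    for block in blocks:
        if any(flags[panel.index_of(vid)] for vid, _ in block.members):
            hits += 1
    return hits / len(blocks)


def _max_flagged_r2(
    panel: PhasedPanel,
    sentinel_idx: np.ndarray,
    flags_by_layer: Dict[str, np.ndarray],
    window_bp: int,
    chunk: int = 256,
) -> Dict[str, np.ndarray]:
    """Per sentinel: max r² over annotation-flagged variants in its window.

    The sentinel itself counts at r² = 1; -inf means no flagged member at any
    threshold. Monomorphic variants are excluded (undefined LD).
    """
    out = {layer: np.full(sentinel_idx.size, -np.inf) for layer in flags_by_layer}
    for chrom in np.unique(panel.chrom[sentinel_idx]):
        chrom_vars = np.flatnonzero(panel.chrom == chrom)
        pos = panel.pos[chrom_vars]
        s_here = np.flatnonzero(panel.chrom[sentinel_idx] == chrom)
        s_idx = sentinel_idx[s_here]
        for lo in range(0, s_idx.size, chunk):
            part = s_idx[lo : lo + chunk]
            r2 = r2_many_vs_many(panel.matrix, part, chrom_vars)
            in_window = (
                np.abs(pos[None, :] - panel.pos[part][:, None]) <= window_bp
            )
            valid = in_window & ~np.isnan(r2)
            for layer, flags in flags_by_layer.items():
                use = valid & flags[chrom_vars][None, :]
                masked = np.where(use, r2, -np.inf)
                m = masked.max(axis=1)
                m = np.where(flags[part], 1.0, m)  # sentinel at r²=1
                out[layer][s_here[lo : lo + part.size]] = m
    return out


def pi_curve(
    sentinels: Sequence[str],
    panel: PhasedPanel,
    annotations: Dict[str, IntervalSet],
    r2_grid: Sequence[float],
    window_bp: int = DEFAULT_WINDOW_BP,
) -> PiCurve:
    """Π per (r² threshold, annotation layer) over an ascending grid.

    Duplicate sentinels (same variant reported for two traits) are kept as
    distinct blocks, so denominators are per reported association.
    """
    grid = list(r2_grid)
    if grid != sorted(grid):
        raise ValidationError("r2_grid must be ascending")
    if len(sentinels) == 0:
        raise UndefinedStatisticError("no sentinels: Π undefined")
    ids = list(sentinels)
    uniq = sorted(set(ids))
    uniq_idx = np.asarray([panel.index_of(s) for s in uniq])
    flags_by_layer = {
        name: variant_annotation_flags(panel, ann)
        for name, ann in annotations.items()
    }
    max_r2 = _max_flagged_r2(panel, uniq_idx, flags_by_layer, window_bp)
    pos_of = {s: i for i, s in enumerate(uniq)}
    counts = np.bincount(
        [pos_of[s] for s in ids], minlength=len(uniq)
    ).astype(np.float64)
    n = float(len(ids))
    values = {
        layer: [float(counts @ (m >= t) / n) for t in grid]
        for layer, m in max_r2.items()
    }
    return PiCurve(grid, list(annotations), values, [len(ids)] * len(grid))


def conditional_pi(
    blocks_a: Sequence[HaplotypeBlock],
    blocks_b: Sequence[HaplotypeBlock],
    annotation: IntervalSet,
    panel: PhasedPanel,
) -> Tuple[float, int]:
    """Π of the subset of blocks_a sharing >= 1 member variant with blocks_b.

    Returns (proportion, size of the conditional subset). Raises with the
    zero count when no block of a shares a member with b.
    """
    members_b: Set[str] = set()
    for b in blocks_b:
        members_b.update(b.member_ids())
    subset = [
        a for a in blocks_a if any(vid in members_b for vid in a.member_ids())
    ]
    if not subset:
        raise UndefinedStatisticError(
            "conditional Π undefined: 0 blocks share members"
        )
    return pi_statistic(subset, annotation, panel), len(subset)
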