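"""Workspace-constrained randomisation enrichment.

The observed statistic is the number of query segments overlapping an
annotation by >= 1 bp (a bp-overlap mode is available). The null is built by
re-placing each query segment independently within a workspace: a workspace
segment is chosen with probability proportional to the number of valid
placements it offers (segment_length - item_length + 1, among segments that
can contain the item), then a uniform offset inside it. Empirical p-values
use the add-one estimator p = (#{null >= observed} + 1) / (n + 1), so p is
never zero. Optional stratification (the generalisation of GC-isochore
correction) confines each item's re-placement to workspace segments sharing
the stratum label of its segment of origin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from statsmodels.stats.multitest import multipletests

from .errors import PlacementError, ValidationError
from .genome_intervals import GenomicInterval, IntervalSet

__all__ = [
    "EnrichmentResult",
    "shuffle_within_workspace",
    "fold_enrichment",
    "bh_qvalues",
    "quintile_strata",
]


@dataclass
class EnrichmentResult:
    observed_overlap: float
    null_mean: float
    null_sd: float
    fold: float
    p_empirical: float
    n_randomisations: int
    q: Optional[float] = None
    label: Optional[str] = None


class _Workspace:
    """Pre-indexed workspace segments supporting weighted placement draws."""

    def __init__(
        self, workspace: IntervalSet, strata: Optional[Sequence] = None
    ) -> None:
        self.chrom = np.asarray([iv.chrom for iv in workspace])
        self.start = np.asarray([iv.start for iv in workspace], dtype=np.int64)
        self.length = np.asarray([len(iv) for iv in workspace], dtype=np.int64)
        if strata is not None and len(strata) != len(workspace):
            raise ValidationError("strata labels must align with workspace segments")
        self.strata = None if strata is None else np.asarray(strata)
        self._groups: Dict[Tuple, Tuple[np.ndarray, np.ndarray]] = {}

    def segment_of(self, iv: GenomicInterval) -> int:
        """Index of the workspace segment fully containing ``iv``."""
        ok = np.flatnonzero(
            (self.chrom == iv.chrom)
            & (self.start <= iv.start)
            & (self.start + self.length >= iv.end)
        )
        if ok.size == 0:
            raise PlacementError(
                f"{iv.chrom}:{iv.start}-{iv.end} lies in no workspace segment"
            )
        return int(ok[0])

    def placement_table(self, length: int, stratum=None):
        """(capable segment indices, cumulative placement weights)."""
        key = (int(length), stratum)
        if key not in self._groups:
            ok = self.length >= length
            if stratum is not None:
                ok &= self.strata == stratum
            cap = np.flatnonzero(ok)
            if cap.size == 0:
                raise PlacementError(
                    f"no workspace segment can contain a {length} bp item"
                    + (f" in stratum {stratum!r}" if stratum is not None else "")
                )
            w = (self.length[cap] - length + 1).astype(np.float64)
            self._groups[key] = (cap, np.cumsum(w))
        return self._groups[key]

    def draw(self, length: int, m: int, rng, stratum=None) -> np.ndarray:
        """m placement start positions for items of the given length."""
        cap, cumw = self.placement_table(length, stratum)
        u = rng.random(m) * cumw[-1]
        seg = cap[np.searchsorted(cumw, u, side="right")]
        off = rng.integers(0, self.length[seg] - length + 1)
        return self.start[seg] + off, seg


def shuffle_within_workspace(
    items: IntervalSet,
    workspace: IntervalSet,
    rng,
    strata: Optional[Sequence] = None,
) -> IntervalSet:
    """One independent re-placement of every item inside the workspace.

    Lengths are preserved; shuffled items may overlap each other. With
    ``strata`` (labels per workspace segment) each item stays within
    segments sharing its origin segment's label.
    """
    ws = _Workspace(workspace, strata)
    out: List[Optional[GenomicInterval]] = [None] * len(items)
    labels = None
    if strata is not None:
        labels = [ws.strata[ws.segment_of(iv)] for iv in items]
    by_group: Dict[Tuple, List[int]] = {}
    for i, iv in enumerate(items):
        key = (len(iv), None if labels is None else labels[i])
        by_group.setdefault(key, []).append(i)
    for (length, stratum), idx in sorted(
        by_group.items(), key=lambda kv: (kv[0][0], repr(kv[0][1]))
    ):
        starts, segs = ws.draw(length, len(idx), rng, stratum)
        for i, s, g in zip(idx, starts, segs):
            src = items[i]
            out[i] = GenomicInterval(
                str(ws.chrom[g]), int(s), int(s) + length,
                src.name, src.score, src.strand, dict(src.tags),
            )
    return IntervalSet([iv for iv in out if iv is not None])


def _genome_layout(workspace: IntervalSet) -> Dict[str, int]:
    lengths: Dict[str, int] = {}
    for iv in workspace:
        lengths[iv.chrom] = max(lengths.get(iv.chrom, 0), iv.end)
    return lengths


def _coverage_cumsum(
    annotation: IntervalSet, chrom_lengths: Dict[str, int]
) -> Dict[str, np.ndarray]:
    out = {}
    for chrom, n in chrom_lengths.items():
        cov = np.zeros(n, dtype=np.int32)
        s, e = annotation.merged(chrom)
        for a, b in zip(s, e):
            cov[a : min(b, n)] = 1
        out[chrom] = np.concatenate([[0], np.cumsum(cov, dtype=np.int64)])
    return out


def _overlap_statistic(
    csum: Dict[str, np.ndarray],
    chroms: np.ndarray,
    starts: np.ndarray,
    ends: np.ndarray,
    mode: str,
) -> float:
    total = 0.0
    for chrom in np.unique(chroms):
        cs = csum.get(chrom)
        if cs is None:
            continue
        sel = chroms == chrom
        s = np.clip(starts[sel], 0, cs.size - 1)
        e = np.clip(ends[sel], 0, cs.size - 1)
        ov = cs[e] - cs[s]
        total += float((ov > 0).sum()) if mode == "segment" else float(ov.sum())
    return total


def fold_enrichment(
    query: IntervalSet,
    annotation: IntervalSet,
    workspace: IntervalSet,
    n: int = 10_000,
    rng_seed: int = 0,
    stratify: Optional[Sequence] = None,
    mode: str = "segment",
    alternative: str = "greater",
    label: Optional[str] = None,
) -> EnrichmentResult:
    """Randomisation test of query-vs-annotation overlap within a workspace.

    mode="segment" counts query segments overlapping >= 1 annotation bp
    (default); mode="bp" sums overlapping base pairs. The default
    alternative is enrichment; "two-sided" doubles the smaller tail.
    """
    if mode not in ("segment", "bp"):
        raise ValidationError(f"unknown overlap mode {mode!r}")
    if n < 100:
        warnings.warn(f"n={n} randomisations gives unstable empirical p-values")
    ws = _Workspace(workspace, stratify)
    chrom_lengths = _genome_layout(workspace)
    csum = _coverage_cumsum(annotation, chrom_lengths)

    q_chrom = np.asarray([iv.chrom for iv in query])
    q_start = np.asarray([iv.start for iv in query], dtype=np.int64)
    q_len = np.asarray([len(iv) for iv in query], dtype=np.int64)
    observed = _overlap_statistic(csum, q_chrom, q_start, q_start + q_len, mode)

    labels = None
    if stratify is not None:
        labels = np.asarray([ws.strata[ws.segment_of(iv)] for iv in query])
    groups: List[Tuple[int, object, np.ndarray]] = []
    if labels is None:
        for L in np.unique(q_len):
            groups.append((int(L), None, np.flatnonzero(q_len == L)))
    else:
        for L in np.unique(q_len):
            for lab in np.unique(labels[q_len == L]):
                groups.append(
                    (int(L), lab, np.flatnonzero((q_len == L) & (labels == lab)))
                )
    # warm placement tables so per-iteration work is draws only
    for L, lab, _ in groups:
        ws.placement_table(L, lab)

    rng = np.random.default_rng(rng_seed)
    null = np.zeros(n)
    for it in range(n):
        stat = 0.0
        for L, lab, idx in groups:
            starts, segs = ws.draw(L, idx.size, rng, lab)
            stat += _overlap_statistic(
                csum, ws.chrom[segs], starts, starts + L, mode
            )
        null[it] = stat

    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n > 1 else 0.0
    if len(annotation) == 0 or null_mean == 0:
        fold = float("nan")
    else:
        fold = observed / null_mean
    p_hi = (int((null >= observed).sum()) + 1) / (n + 1)
    if alternative == "greater":
        p = p_hi
    elif alternative == "two-sided":
        p_lo = (int((null <= observed).sum()) + 1) / (n + 1)
        p = min(1.0, 2.0 * min(p_hi, p_lo))
    else:
        raise ValidationError(f"unknown alternative {alternative!r}")
    return EnrichmentResult(
        observed, null_mean, null_sd, fold, p, n, label=label
    )


def bh_qvalues(p_values: Sequence[float]) -> List[float]:
    """Benjamini-Hochberg adjusted p-values, order-preserving."""
    p = np.asarray(list(p_values), dtype=np.float64)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)):
        raise ValidationError("p-values must be in (0, 1]")
    return multipletests(p, method="fdr_bh")[1].tolist()


def quintile_strata(
    workspace: IntervalSet, values: Sequence[float], bin_bp: int = 1_000_000
) -> List[int]:
    """Quintile stratum labels for workspace segments from a per-segment value.

    The per-segment value (e.g. GC fraction of the segment's 1 Mb bin) is cut
    at its quintiles; ties share a stratum. Mirrors isochore correction where
    a composition track exists.
    """
    v = np.asarray(list(values), dtype=np.float64)
    if v.size != len(workspace):
        raise ValidationError("one value per workspace segment required")
    qs = np.quantile(v, [0.2, 0.4, 0.6, 0.8])
    return np.searchsorted(qs, v, side="right").tolist()
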