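"""Linkage disequilibrium from a phased haplotype panel.

The LD measure is the classical composite-frequency r² between two biallelic
variants A and B computed directly on phased haplotypes:

    r² = (p_AB − p_A·p_B)² / (p_A(1 − p_A) · p_B(1 − p_B))

where p_A and p_B are ALT-allele frequencies and p_AB the joint ALT-ALT
haplotype frequency. A sentinel variant is expanded into a haplotype block:
the sentinel plus every panel variant on the same chromosome within a window
(default 10 Mb) whose r² with the sentinel reaches the threshold (default
0.5, inclusive at the boundary). Monomorphic variants have undefined LD and
are excluded from blocks rather than treated as r² = 0.
"""

from __future__ import annotations

import difflib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .errors import LDUndefinedError, SentinelNotFoundError, ValidationError
from .genome_intervals import GenomicInterval, IntervalSet

__all__ = [
    "PhasedPanel",
    "HaplotypeBlock",
    "compute_r2",
    "r2_one_vs_many",
    "expand_haplotype",
    "expand_blocks",
    "blocks_to_intervals",
    "read_panel",
    "write_panel",
    "read_sentinels",
    "write_sentinels",
]

DEFAULT_WINDOW_BP = 10_000_000
DEFAULT_MIN_R2 = 0.5


@dataclass
class PhasedPanel:
    """Phased biallelic haplotypes: a (haplotype x variant) 0/1 matrix."""

    ids: np.ndarray  # variant ids, shape (n_variants,)
    chrom: np.ndarray  # chromosome per variant
    pos: np.ndarray  # 1-based position per variant
    ref: np.ndarray
    alt: np.ndarray
    matrix: np.ndarray  # (n_haplotypes, n_variants) uint8, 1 = ALT
    _index: Dict[str, int] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.chrom = np.asarray(self.chrom)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.ref = np.asarray(self.ref)
        self.alt = np.asarray(self.alt)
        self.matrix = np.asarray(self.matrix, dtype=np.uint8)
        if self.matrix.ndim != 2 or self.matrix.shape[0] < 2:
            raise ValidationError("panel needs >= 2 haplotypes")
        if self.matrix.shape[1] != self.ids.size:
            raise ValidationError("matrix width must equal number of variants")
        if self.matrix.max(initial=0) > 1:
            raise ValidationError("haplotype matrix entries must be 0/1")
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if np.any(np.diff(p) < 0):
                raise ValidationError(f"positions on {c} are not sorted")
        self._index = {vid: i for i, vid in enumerate(self.ids.tolist())}

    @property
    def n_haplotypes(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_variants(self) -> int:
        return self.matrix.shape[1]

    def index_of(self, variant_id: str) -> int:
        try:
            return self._index[variant_id]
        except KeyError:
            near = difflib.get_close_matches(variant_id, self._index, n=3)
            raise SentinelNotFoundError(
                f"variant {variant_id!r} not in panel; nearest ids: {near}"
            ) from None

    def alt_freq(self) -> np.ndarray:
        return self.matrix.mean(axis=0)


@dataclass
class HaplotypeBlock:
    """A sentinel plus all panel variants linked at >= r2_threshold within a window."""

    sentinel: str
    members: List[Tuple[str, float]]  # (variant id, r2), sentinel included at 1.0
    r2_threshold: float
    window_bp: int

    def member_ids(self) -> List[str]:
        return [m[0] for m in self.members]

    def __len__(self) -> int:
        return len(self.members)


def compute_r2(col_a: Sequence[int], col_b: Sequence[int]) -> float:
    """r² between two phased 0/1 haplotype columns of equal length.

    Raises :class:`LDUndefinedError` for a monomorphic column: LD there is
    undefined, not zero.
    """
    a = np.asarray(col_a, dtype=np.float64)
    b = np.asarray(col_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValidationError("columns must be equal-length 1-D with >= 2 entries")
    n = a.size
    p_a = a.sum() / n
    p_b = b.sum() / n
    if p_a in (0.0, 1.0) or p_b in (0.0, 1.0):
        raise LDUndefinedError("monomorphic column: r2 undefined")
    p_ab = (a * b).sum() / n
    d = p_ab - p_a * p_b
    return (d * d) / (p_a * (1.0 - p_a) * p_b * (1.0 - p_b))


def r2_one_vs_many(matrix: np.ndarray, j: int, idx: np.ndarray) -> np.ndarray:
    """Vectorised r² of variant column ``j`` against columns ``idx``.

    Monomorphic targets (or a monomorphic ``j``) yield NaN.
    """
    m = matrix
    n = m.shape[0]
    a = m[:, j].astype(np.float64)
    sub = m[:, idx].astype(np.float64)
    p_a = a.sum() / n
    p_b = sub.sum(axis=0) / n
    p_ab = (a @ sub) / n
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (p_ab - p_a * p_b) ** 2
        den = p_a * (1 - p_a) * p_b * (1 - p_b)
        r2 = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    if p_a in (0.0, 1.0):
        r2[:] = np.nan
    return r2


def r2_many_vs_many(
    matrix: np.ndarray, a_idx: np.ndarray, b_idx: np.ndarray
) -> np.ndarray:
    """r² matrix (len(a_idx) x len(b_idx)); NaN where either side is monomorphic.

    Joint counts come from one 0/1 matrix product, so the cost is a single
    GEMM — this is the bulk path behind pi curves at 10^4 sentinels.
    """
    m = matrix
    n = m.shape[0]
    A = m[:, a_idx].astype(np.float32)
    B = m[:, b_idx].astype(np.float32)
    c_ab = (A.T @ B).astype(np.float64)  # exact: counts < 2^24
    p_a = A.sum(axis=0).astype(np.float64)[:, None] / n
    p_b = B.sum(axis=0).astype(np.float64)[None, :] / n
    p_ab = c_ab / n
    with np.errstate(divide="ignore", invalid="ignore"):
        num = (p_ab - p_a * p_b) ** 2
        den = p_a * (1 - p_a) * p_b * (1 - p_b)
        r2 = np.where(den > 0, num / np.where(den > 0, den, 1.0), np.nan)
    return r2


def expand_haplotype(
    panel: PhasedPanel,
    sentinel: str,
    min_r2: float = DEFAULT_MIN_R2,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> HaplotypeBlock:
    """Expand a sentinel into its haplotype block.

    Members are the sentinel itself (at r² = 1) plus every same-chromosome
    variant within ``window_bp`` whose r² with the sentinel is >= ``min_r2``.
    Monomorphic variants are skipped. A monomorphic sentinel yields a
    singleton block (its own LD with anything is undefined).
    """
    j = panel.index_of(sentinel)
    same = np.flatnonzero(
        (panel.chrom == panel.chrom[j])
        & (np.abs(panel.pos - panel.pos[j]) <= window_bp)
    )
    same = same[same != j]
    members: List[Tuple[str, float]] = [(sentinel, 1.0)]
    if same.size:
        r2 = r2_one_vs_many(panel.matrix, j, same)
        keep = np.flatnonzero(~np.isnan(r2) & (r2 >= min_r2))
        members.extend(
            (str(panel.ids[same[k]]), float(r2[k])) for k in keep
        )
    return HaplotypeBlock(sentinel, members, min_r2, window_bp)


def expand_blocks(
    panel: PhasedPanel,
    sentinels: Sequence[str],
    min_r2: float = DEFAULT_MIN_R2,
    window_bp: int = DEFAULT_WINDOW_BP,
) -> List[HaplotypeBlock]:
    """Expand many sentinels; duplicate sentinel ids yield duplicate blocks."""
    cache: Dict[str, HaplotypeBlock] = {}
    out = []
    for s in sentinels:
        if s not in cache:
            cache[s] = expand_haplotype(panel, s, min_r2, window_bp)
        out.append(cache[s])
    return out


def blocks_to_intervals(block: HaplotypeBlock, panel: PhasedPanel) -> IntervalSet:
    """One 1-bp interval per member: 1-based pos -> [pos-1, pos)."""
    out = []
    for vid, r2 in block.members:
        i = panel.index_of(vid)
        p = int(panel.pos[i])
        out.append(
            GenomicInterval(
                str(panel.chrom[i]),
                p - 1,
                p,
                name=vid,
                score=r2,
                tags={"sentinel": block.sentinel},
            )
        )
    return IntervalSet(out)


# -- panel and sentinel I/O ---------------------------------------------------
#
# Minimal VCF-like tab-separated panel: CHROM POS ID REF ALT then one phased
# column per individual, "a|b" with a, b in {0, 1}. No header line.


def read_panel(path) -> PhasedPanel:
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    if df.shape[1] < 6:
        raise ValidationError("panel file needs CHROM POS ID REF ALT + genotypes")
    n_ind = df.shape[1] - 5
    haps = np.empty((2 * n_ind, df.shape[0]), dtype=np.uint8)
    for k in range(n_ind):
        col = df.iloc[:, 5 + k].str
        haps[2 * k] = col[0].astype(np.uint8)
        haps[2 * k + 1] = col[2].astype(np.uint8)
    return PhasedPanel(
        ids=df.iloc[:, 2].to_numpy(),
        chrom=df.iloc[:, 0].to_numpy(),
        pos=df.iloc[:, 1].to_numpy(np.int64),
        ref=df.iloc[:, 3].to_numpy(),
        alt=df.iloc[:, 4].to_numpy(),
        matrix=haps,
    )


def write_panel(panel: PhasedPanel, path) -> None:
    if panel.n_haplotypes % 2:
        raise ValidationError(
            "panel file pairs haplotypes into individuals: even count required"
        )
    m = panel.matrix
    with open(path, "wt") as fh:
        for i in range(panel.n_variants):
            gts = "\t".join(
                f"{m[2 * k, i]}|{m[2 * k + 1, i]}" for k in range(m.shape[0] // 2)
            )
            fh.write(
                f"{panel.chrom[i]}\t{panel.pos[i]}\t{panel.ids[i]}"
                f"\t{panel.ref[i]}\t{panel.alt[i]}\t{gts}\n"
            )


def read_sentinels(path) -> List[Tuple[str, Optional[str]]]:
    """One variant id per line, optional second tab column (trait/gene tag)."""
    out: List[Tuple[str, Optional[str]]] = []
    with open(path, "rt") as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            out.append((parts[0], parts[1] if len(parts) > 1 else None))
    return out


def write_sentinels(sentinels: Sequence[Tuple[str, Optional[str]]], path) -> None:
    with open(path, "wt") as fh:
        for vid, tag in sentinels:
            fh.write(vid if tag is None else f"{vid}\t{tag}")
            fh.write("\n")
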