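"""PWM motif scanning with exact p-values, and ref-vs-alt disruption calls.

Scoring is the log-odds of the position weight matrix against a 0-order
background, discretised to fixed-width bins (1e-3 log-odds units). The
p-value of a score s is P(score >= s) for a k-mer drawn from the background,
computed by exact dynamic programming over the discretised score
distribution; the score threshold for a target p-value follows FIMO
semantics (smallest achievable score whose tail probability is <= p).

A variant disrupts a motif match when substituting the alternate base flips
the match status at the p threshold in either direction (loss or gain). An
empirical test compares the proportion of footprint-contained SNVs that
disrupt an overlapping match against a null built by re-placing footprints
uniformly within DHS.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np

from .errors import UndefinedStatisticError, ValidationError
from .genome_intervals import GenomicInterval, IntervalSet

__all__ = [
    "PWM",
    "MotifHit",
    "ScoreDistribution",
    "pvalue_score_threshold",
    "scan",
    "is_disruptive",
    "disruptive_snv",
    "disruption_proportion_test",
    "read_meme",
    "write_meme",
]

SCORE_BIN = 1e-3  # log-odds units per discretisation bin
ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
_COMPLEMENT = str.maketrans("ACGT", "TGCA")
UNIFORM_BG = np.full(4, 0.25)


@dataclass
class PWM:
    """Position probability matrix over ACGT with a 0-order background."""

    tf_id: str
    matrix: np.ndarray  # (length, 4) probabilities
    pseudocount: float = 0.0
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.background = np.asarray(self.background, dtype=np.float64)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != 4:
            raise ValidationError("PWM matrix must be (length, 4)")
        if self.matrix.shape[0] < 4:
            raise ValidationError("PWM length must be >= 4")
        if not np.allclose(self.matrix.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("PWM rows must sum to 1 (±1e-9)")
        if np.any(self.background <= 0):
            raise ValidationError("background frequencies must be strictly positive")

    def __len__(self) -> int:
        return self.matrix.shape[0]

    def log_odds(self) -> np.ndarray:
        """(length, 4) log2 odds with the pseudocount mixed toward background."""
        p = (self.matrix + self.pseudocount * self.background) / (
            1.0 + self.pseudocount
        )
        return np.log2(p / self.background)

    def int_scores(self) -> np.ndarray:
        """Log-odds discretised to integer SCORE_BIN units."""
        return np.rint(self.log_odds() / SCORE_BIN).astype(np.int64)

    def reverse_complement(self) -> "PWM":
        return PWM(
            self.tf_id, self.matrix[::-1, ::-1].copy(), self.pseudocount,
            self.background[::-1].copy(),
        )

    def consensus(self) -> str:
        return "".join(ALPHABET[i] for i in self.matrix.argmax(axis=1))


@dataclass
class MotifHit:
    """A scoring window passing the p-value threshold."""

    tf_id: str
    interval: GenomicInterval
    strand: str
    score: float  # log2 odds (discretised grid)
    p_value: float
    sequence: str = ""  # motif-oriented matched sequence

    def __post_init__(self) -> None:
        if not 0.0 < self.p_value <= 1.0:
            raise ValidationError("hit p-value must be in (0, 1]")


class ScoreDistribution:
    """Exact background distribution of the discretised PWM score.

    Built by convolving the per-position score distributions: O(L * range)
    dynamic programming, exact up to the discretisation grid.
    """

    def __init__(self, pwm: PWM) -> None:
        s = pwm.int_scores()
        bg = pwm.background
        lo = int(s.min(axis=1).sum())
        hi = int(s.max(axis=1).sum())
        pmf = np.zeros(hi - lo + 1)
        # running support [cur_lo, cur_lo + len(cur) - 1]
        cur = np.array([1.0])
        cur_lo = 0
        for i in range(len(pwm)):
            row = s[i]
            nxt_lo = cur_lo + int(row.min())
            nxt = np.zeros(cur.size + int(row.max() - row.min()))
            for b in range(4):
                off = int(row[b]) + cur_lo - nxt_lo
                nxt[off : off + cur.size] += bg[b] * cur
            cur, cur_lo = nxt, nxt_lo
        assert cur_lo == lo and cur.size == pmf.size
        pmf[:] = cur
        self.min_score = lo
        self.max_score = hi
        self.pmf = pmf
        # survival[s - lo] = P(score >= s)
        self.sf = np.cumsum(pmf[::-1])[::-1]

    def total(self) -> float:
        return float(self.pmf.sum())

    def p_value(self, int_score: int) -> float:
        if int_score > self.max_score:
            return 0.0
        if int_score <= self.min_score:
            return 1.0
        return float(self.sf[int_score - self.min_score])

    def threshold_for(self, p: float) -> int:
        """Smallest achievable integer score with tail probability <= p.

        When even the maximal score has tail probability > p, the maximal
        score is returned (with a warning): no stricter threshold exists.
        """
        if not 0.0 < p < 1.0 + 1e-12:
            raise ValidationError("p must be in (0, 1]")
        achievable = np.flatnonzero(self.pmf > 0) + self.min_score
        tails = self.sf[achievable - self.min_score]
        ok = achievable[tails <= p + 1e-15]
        if ok.size == 0:
            warnings.warn(
                f"p={p:g} below the minimal achievable tail "
                f"{tails[-1]:g}; using the maximal score"
            )
            return int(achievable[-1])
        return int(ok[0])


def pvalue_score_threshold(pwm: PWM, p: float) -> float:
    """Score threshold (log2 odds) at tail probability p under the background."""
    return ScoreDistribution(pwm).threshold_for(p) * SCORE_BIN


def _encode(sequence: str) -> np.ndarray:
    """Map to 0..3; anything not uppercase ACGT (N, masked lowercase) -> -1."""
    out = np.full(len(sequence), -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[np.frombuffer(sequence.encode(), dtype=np.uint8) == ord(b)] = i
    return out


def _strand_hits(
    enc: np.ndarray, pwm: PWM, dist: ScoreDistribution, thr: int,
    strand: str, sequence: str, chrom: str,
) -> List[MotifHit]:
    k = len(pwm)
    s = pwm.int_scores() if strand == "+" else pwm.reverse_complement().int_scores()
    n_win = enc.size - k + 1
    if n_win <= 0:
        return []
    valid = np.ones(n_win, dtype=bool)
    bad = enc < 0
    if bad.any():
        # window i valid iff no bad base in [i, i+k)
        cb = np.concatenate([[0], np.cumsum(bad)])
        valid = (cb[k:] - cb[:-k]) == 0
    scores = np.zeros(n_win, dtype=np.int64)
    e = np.where(enc < 0, 0, enc)
    for j in range(k):
        scores += s[j, e[j : j + n_win]]
    hits = []
    for i in np.flatnonzero(valid & (scores >= thr)):
        window = sequence[i : i + k].upper()
        seq = window if strand == "+" else window.translate(_COMPLEMENT)[::-1]
        hits.append(
            MotifHit(
                pwm.tf_id,
                GenomicInterval(chrom, int(i), int(i) + k, name=pwm.tf_id),
                strand,
                float(scores[i]) * SCORE_BIN,
                dist.p_value(int(scores[i])),
                seq,
            )
        )
    return hits


def scan(
    sequence: str, pwm: PWM, p: float = 1e-4, chrom: str = "seq"
) -> List[MotifHit]:
    """Scan both strands; windows containing N or masked (lowercase) bases skip.

    Hit coordinates are 0-based half-open offsets into the sequence. The
    reverse-strand score at offset i is the forward score of the
    reverse-complement PWM, so coordinates mirror under reverse complement.
    """
    if len(sequence) < len(pwm):
        return []
    dist = ScoreDistribution(pwm)
    thr = dist.threshold_for(p)
    enc = _encode(sequence)
    hits = _strand_hits(enc, pwm, dist, thr, "+", sequence, chrom)
    hits += _strand_hits(enc, pwm, dist, thr, "-", sequence, chrom)
    return sorted(hits, key=lambda h: (h.interval.start, h.strand))


def is_disruptive(
    hit: MotifHit,
    pwm: PWM,
    ref_base: str,
    alt_base: str,
    offset_in_motif: int,
    p: float = 1e-4,
    dist: Optional[ScoreDistribution] = None,
) -> bool:
    """Does substituting alt for ref flip match status at the p threshold?

    Bases and offset are in motif orientation (use :func:`disruptive_snv`
    for genomic coordinates/strand handling).
    """
    if not 0 <= offset_in_motif < len(pwm):
        raise ValidationError("offset outside motif")
    ref_base, alt_base = ref_base.upper(), alt_base.upper()
    if hit.sequence and hit.sequence[offset_in_motif] != ref_base:
        raise ValidationError(
            f"ref base {ref_base} does not match hit sequence "
            f"{hit.sequence!r} at offset {offset_in_motif}"
        )
    if ref_base == alt_base:
        return False
    if dist is None:
        dist = ScoreDistribution(pwm)
    thr = dist.threshold_for(p)
    s = pwm.int_scores()
    ref_score = int(np.rint(hit.score / SCORE_BIN))
    alt_score = (
        ref_score - s[offset_in_motif, _BASE_INDEX[ref_base]]
        + s[offset_in_motif, _BASE_INDEX[alt_base]]
    )
    return (ref_score >= thr) != (alt_score >= thr)


def disruptive_snv(
    hit: MotifHit,
    pwm: PWM,
    pos0: int,
    ref: str,
    alt: str,
    p: float = 1e-4,
    dist: Optional[ScoreDistribution] = None,
) -> bool:
    """Genomic-coordinate wrapper for :func:`is_disruptive`.

    pos0 is the 0-based genomic position of the SNV; ref/alt are plus-strand
    bases and are reoriented for minus-strand hits.
    """
    off = pos0 - hit.interval.start
    if not 0 <= off < len(pwm):
        raise ValidationError("SNV outside hit window")
    if hit.strand == "-":
        off = len(pwm) - 1 - off
        ref = ref.translate(_COMPLEMENT)
        alt = alt.translate(_COMPLEMENT)
    return is_disruptive(hit, pwm, ref, alt, off, p, dist)


# -- empirical disruption-proportion test -------------------------------------


def _snv_disruption_flags(
    snvs: IntervalSet,
    hits: Sequence[MotifHit],
    pwms: Dict[str, PWM],
    p: float,
) -> np.ndarray:
    """Per SNV: disruptive to >= 1 overlapping hit? SNVs carry ref/alt tags."""
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for j, h in enumerate(hits):
        by_chrom.setdefault(h.interval.chrom, []).append((h.interval.start, j))
    dists = {tf: ScoreDistribution(pwm) for tf, pwm in pwms.items()}
    flags = np.zeros(len(snvs), dtype=bool)
    for i, snv in enumerate(snvs):
        pos = snv.start
        ref, alt = snv.tags.get("ref", "N"), snv.tags.get("alt", "N")
        for start, j in by_chrom.get(snv.chrom, ()):
            h = hits[j]
            if start <= pos < h.interval.end and ref in _BASE_INDEX and alt in _BASE_INDEX:
                if disruptive_snv(h, pwms[h.tf_id], pos, ref, alt, p, dists[h.tf_id]):
                    flags[i] = True
                    break
    return flags


def _containment_counts(
    snv_pos: Dict[str, np.ndarray],
    snv_csum: Dict[str, np.ndarray],
    fp_chrom: np.ndarray,
    fp_start: np.ndarray,
    fp_end: np.ndarray,
) -> Tuple[int, int]:
    """(#distinct SNVs inside >= 1 footprint, #those that are disruptive)."""
    n_in = n_dis = 0
    for chrom in snv_pos:
        sel = fp_chrom == chrom
        if not sel.any():
            continue
        spans = np.stack([fp_start[sel], fp_end[sel]], axis=1)
        spans = spans[np.argsort(spans[:, 0])]
        # merge to count distinct SNVs once
        pos, csum = snv_pos[chrom], snv_csum[chrom]
        cur_s, cur_e = None, None
        for s, e in spans:
            if cur_e is None or s > cur_e:
                if cur_e is not None:
                    a, b = np.searchsorted(pos, (cur_s, cur_e))
                    n_in += b - a
                    n_dis += csum[b] - csum[a]
                cur_s, cur_e = s, e
            else:
                cur_e = max(cur_e, e)
        if cur_e is not None:
            a, b = np.searchsorted(pos, (cur_s, cur_e))
            n_in += b - a
            n_dis += csum[b] - csum[a]
    return int(n_in), int(n_dis)


def _capable_dhs(
    fp_len: np.ndarray, dhs_len: np.ndarray
) -> Dict[int, np.ndarray]:
    capable: Dict[int, np.ndarray] = {}
    for L in np.unique(fp_len):
        cap = np.flatnonzero(dhs_len >= L)
        if cap.size == 0:
            raise UndefinedStatisticError(f"no DHS can contain a {L} bp footprint")
        capable[int(L)] = cap
    return capable


def _draw_footprint_placements(
    fp_len: np.ndarray,
    capable: Dict[int, np.ndarray],
    dhs_start: np.ndarray,
    dhs_len: np.ndarray,
    rng,
) -> Tuple[np.ndarray, np.ndarray]:
    """(dhs index, start) per footprint: uniform capable DHS, uniform offset."""
    seg = np.empty(fp_len.size, dtype=np.int64)
    start = np.empty(fp_len.size, dtype=np.int64)
    for L, cap in capable.items():
        which = np.flatnonzero(fp_len == L)
        pick = cap[rng.integers(0, cap.size, which.size)]
        seg[which] = pick
        start[which] = dhs_start[pick] + rng.integers(0, dhs_len[pick] - L + 1)
    return seg, start


def shuffle_footprints_within_dhs(
    footprints: IntervalSet, dhs: IntervalSet, rng
) -> IntervalSet:
    """One null draw: every footprint re-placed uniformly within a uniformly
    chosen DHS large enough to contain it. Lengths are preserved."""
    fp_len = np.asarray([len(f) for f in footprints], dtype=np.int64)
    dhs_start = np.asarray([d.start for d in dhs], dtype=np.int64)
    dhs_len = np.asarray([len(d) for d in dhs], dtype=np.int64)
    dhs_chrom = [d.chrom for d in dhs]
    capable = _capable_dhs(fp_len, dhs_len)
    seg, start = _draw_footprint_placements(fp_len, capable, dhs_start, dhs_len, rng)
    return IntervalSet(
        [
            GenomicInterval(dhs_chrom[g], int(s), int(s) + int(L), name=f.name)
            for f, g, s, L in zip(footprints, seg, start, fp_len)
        ]
    )


def disruption_proportion_test(
    snvs: IntervalSet,
    footprints: IntervalSet,
    dhs: IntervalSet,
    hits: Sequence[MotifHit],
    pwms: Dict[str, PWM],
    n_shuffles: int = 1000,
    rng_seed: int = 0,
    p: float = 1e-4,
) -> Tuple[float, float, float]:
    """(observed, null_mean, empirical_p) for the motif-disruption proportion.

    observed: fraction of footprint-contained SNVs disruptive to >= 1
    overlapping motif hit. Null: each shuffle re-places every footprint at a
    uniform offset within a uniformly chosen DHS large enough to contain it;
    shuffles with no footprint-contained SNV contribute a proportion of 0.
    p = (#{null >= observed} + 1) / (n_shuffles + 1).
    """
    flags = _snv_disruption_flags(snvs, hits, pwms, p)
    snv_pos: Dict[str, np.ndarray] = {}
    snv_csum: Dict[str, np.ndarray] = {}
    for chrom in {s.chrom for s in snvs}:
        idx = [i for i, s in enumerate(snvs) if s.chrom == chrom]
        posv = np.asarray([snvs[i].start for i in idx])
        order = np.argsort(posv)
        snv_pos[chrom] = posv[order]
        snv_csum[chrom] = np.concatenate(
            [[0], np.cumsum(flags[np.asarray(idx)[order]])]
        )

    fp_chrom = np.asarray([f.chrom for f in footprints])
    fp_start = np.asarray([f.start for f in footprints])
    fp_end = np.asarray([f.end for f in footprints])
    n_in, n_dis = _containment_counts(snv_pos, snv_csum, fp_chrom, fp_start, fp_end)
    if n_in == 0:
        raise UndefinedStatisticError("no SNV falls inside a footprint")
    observed = n_dis / n_in

    dhs_chrom = np.asarray([d.chrom for d in dhs])
    dhs_start = np.asarray([d.start for d in dhs])
    dhs_len = np.asarray([len(d) for d in dhs])
    fp_len = fp_end - fp_start
    rng = np.random.default_rng(rng_seed)
    null = np.zeros(n_shuffles)
    capable = _capable_dhs(fp_len, dhs_len)
    for it in range(n_shuffles):
        seg, s_start = _draw_footprint_placements(
            fp_len, capable, dhs_start, dhs_len, rng
        )
        m_in, m_dis = _containment_counts(
            snv_pos, snv_csum, dhs_chrom[seg], s_start, s_start + fp_len
        )
        null[it] = (m_dis / m_in) if m_in else 0.0
    p_emp = (int((null >= observed).sum()) + 1) / (n_shuffles + 1)
    return observed, float(null.mean()), p_emp


# -- MEME minimal format I/O --------------------------------------------------


def read_meme(path) -> List[PWM]:
    pwms: List[PWM] = []
    background = UNIFORM_BG.copy()
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            background = np.asarray([float(parts[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if line.startswith("MOTIF"):
            tf_id = line.split()[1]
            i += 1
            while not lines[i].strip().startswith("letter-probability matrix"):
                i += 1
            header = lines[i].strip()
            w = int(header.split("w=")[1].split()[0])
            rows = []
            for k in range(1, w + 1):
                rows.append([float(x) for x in lines[i + k].split()])
            pwms.append(PWM(tf_id, np.asarray(rows), background=background.copy()))
            i += w + 1
            continue
        i += 1
    return pwms


def write_meme(pwms: Iterable[PWM], path) -> None:
    pwms = list(pwms)
    with open(path, "wt") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        if pwms:
            bg = pwms[0].background
            fh.write("Background letter frequencies\n")
            fh.write(
                f"A {bg[0]:.5f} C {bg[1]:.5f} G {bg[2]:.5f} T {bg[3]:.5f}\n\n"
            )
        for pwm in pwms:
            fh.write(f"MOTIF {pwm.tf_id}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {len(pwm)} "
                f"nsites= 20 E= 0\n"
            )
            for row in pwm.matrix:
                fh.write(" ".join(f"{x:.6f}" for x in row) + "\n")
            fh.write("\n")
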