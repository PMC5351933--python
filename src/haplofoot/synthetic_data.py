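"""Seedable synthetic datasets with planted, recoverable effects.

The generator emulates the statistical structure the analysis assumes,
without sequence realism (the genome is abstract coordinates):

* non-overlapping DHS on autosome-like chromosomes, each optionally
  containing one footprint (11-22 bp) fully inside it;
* a phased haplotype panel with block-structured LD: within each block every
  variant is an independently-flipped copy of a block "ancestral" column,
  with flip probability tuned analytically so pairwise r² targets
  ``within_block_r2`` (r² = (1-2ε)⁴ ⇒ ε = (1 - r2^{1/4})/2);
* sentinel variants drawn from DHS variants with a planted fold-enrichment
  inside footprints: each sentinel falls in a footprint with probability
  planted_fold × baseline, where baseline is the fraction of DHS variants
  inside footprints;
* per-base DNase cut counts (Poisson over DHS) with artefact footprints
  given one dominant spike near the centre, set to 10x the rest of the
  +-100 bp window total so the >50% skew filter fires on exactly the
  planted set;
* one motif occurrence per footprint — an expressed-TF motif in high-score
  footprints (top 40% of scores), an undetectable-TF motif otherwise — with
  conservation signal added only over expressed-TF occurrences, making the
  TP:FP score calibration analytically recoverable;
* SNVs inside motif occurrences are given an alternate allele with minimal
  PWM probability, so they disrupt the motif match (planted disruption).

Every quantity needed to score recovery is stored in the truth record.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .conservation_calibration import ExpressionTable
from .errors import ConfigurationError
from .footprint_processing import ScoredTrack, footprint_centre
from .genome_intervals import GenomicInterval, IntervalSet, read_bed, write_bed
from .ld_haplotypes import (
    PhasedPanel,
    read_panel,
    read_sentinels,
    write_panel,
    write_sentinels,
)
from .motif_scan import (
    ALPHABET,
    PWM,
    SCORE_BIN,
    MotifHit,
    ScoreDistribution,
    read_meme,
    write_meme,
)

__all__ = ["SyntheticConfig", "SyntheticDataset", "TruthRecord",
           "generate_dataset", "write_dataset", "read_dataset"]

# Layout constants: DHS keep 300 bp off chromosome ends (room for artefact
# windows and conservation flanks) and 250 bp between each other (so one
# footprint's +-100 bp cut window never reaches a neighbouring DHS).
CHROM_MARGIN_BP = 300
DHS_GAP_BP = 250
TRACK_MARGIN_BP = 150  # conservation baseline extends this far beyond DHS
CUT_RATE = 5.0  # Poisson mean of per-base cut counts inside DHS
CONSERVATION_NOISE_SD = 0.3
HIGH_QUALITY_FRACTION = 0.4  # fraction of footprints treated as true sites
UND_EXPRESSION_RPKM = 0.0
HI_EXPRESSION_RANGE = (11.0, 60.0)
N_EXPRESSION_SAMPLES = 3
N_BLACKLIST = 15
BLACKLIST_LENGTH_RANGE = (500, 2000)


@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic dataset."""

    n_chromosomes: int = 2
    chrom_length_bp: int = 1_000_000
    n_dhs: int = 1200
    dhs_length_bp: Tuple[int, int] = (200, 400)
    footprint_per_dhs_prob: float = 0.8
    footprint_length_bp: Tuple[int, int] = (11, 22)
    n_snvs: int = 20_000
    n_haplotypes_in_panel: int = 380
    ld_block_length_bp: int = 10_000
    within_block_r2: float = 0.8
    n_sentinels: int = 10_000
    planted_fold: float = 1.65
    n_motifs: int = 16  # number of TF motifs (PWMs)
    motif_length: int = 8
    expressed_tf_fraction: float = 0.5
    conservation_signal: float = 0.5
    artefact_spike_prob: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_chromosomes", "chrom_length_bp", "n_dhs", "n_snvs",
                     "n_haplotypes_in_panel", "ld_block_length_bp",
                     "n_sentinels", "n_motifs", "motif_length"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        for name in ("footprint_per_dhs_prob", "within_block_r2",
                     "expressed_tf_fraction", "artefact_spike_prob"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1]")
        if self.planted_fold < 0:
            raise ConfigurationError("planted_fold must be >= 0")
        if self.conservation_signal < 0:
            raise ConfigurationError("conservation_signal must be >= 0")
        lo, hi = self.dhs_length_bp
        flo, fhi = self.footprint_length_bp
        if not (1 <= lo <= hi):
            raise ConfigurationError("dhs_length_bp must be a valid (min, max)")
        if not (1 <= flo <= fhi):
            raise ConfigurationError("footprint_length_bp must be a valid (min, max)")
        if fhi > lo:
            raise ConfigurationError(
                "footprint_length_bp must fit within dhs_length_bp"
            )
        if self.motif_length > flo:
            raise ConfigurationError(
                "motif_length must fit within the smallest footprint"
            )
        if self.n_haplotypes_in_panel % 2:
            raise ConfigurationError(
                "n_haplotypes_in_panel must be even (haplotypes pair into "
                "individuals in the panel file format)"
            )


@dataclass
class TruthRecord:
    """Planted parameters, sufficient to score recovery."""

    planted_fold: float
    baseline_rate: float  # P(DHS variant inside footprint)
    realized_fold: float
    causal_sentinel_indices: List[int]  # positions in the sentinel list
    artefact_footprints: List[str]  # footprint names with planted spikes
    hq_footprints: List[str]  # high-score footprints carrying expressed motifs
    hq_score_centile: float  # centile where the quality boundary sits
    expected_chosen_centile: float  # analytic TP:FP = 2 crossing centile
    disruptive_snvs: List[str]  # variant ids planted to disrupt a motif
    chrom_lengths: Dict[str, int]
    config: Dict

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "TruthRecord":
        d = json.loads(text)
        d["chrom_lengths"] = {k: int(v) for k, v in d["chrom_lengths"].items()}
        for key in ("dhs_length_bp", "footprint_length_bp"):
            if key in d.get("config", {}):  # JSON turns tuples into lists
                d["config"][key] = tuple(d["config"][key])
        return cls(**d)


@dataclass
class SyntheticDataset:
    workspace: IntervalSet
    dhs: IntervalSet
    footprints: IntervalSet
    blacklist: IntervalSet
    cut_track: ScoredTrack
    conservation_track: ScoredTrack
    panel: PhasedPanel
    sentinels: List[str]
    motif_occurrences: IntervalSet
    pwms: List[PWM]
    expression: ExpressionTable
    truth: TruthRecord

    @property
    def autosomes(self) -> List[str]:
        return list(self.truth.chrom_lengths)

    def motif_hits(self) -> List[MotifHit]:
        """One plus-strand hit per occurrence, matching its PWM's consensus."""
        by_tf = {p.tf_id: p for p in self.pwms}
        dists = {p.tf_id: ScoreDistribution(p) for p in self.pwms}
        hits = []
        for occ in self.motif_occurrences:
            tf = occ.tags.get("tf_id", occ.name)
            pwm = by_tf[tf]
            seq = pwm.consensus()
            s = pwm.int_scores()
            score = int(sum(s[i, ALPHABET.index(b)] for i, b in enumerate(seq)))
            hits.append(
                MotifHit(
                    tf, occ, "+", score * SCORE_BIN, dists[tf].p_value(score), seq
                )
            )
        return hits

    def snv_intervals(self) -> IntervalSet:
        """All panel variants as 1-bp intervals tagged with ref/alt."""
        p = self.panel
        return IntervalSet(
            [
                GenomicInterval(
                    str(p.chrom[i]), int(p.pos[i]) - 1, int(p.pos[i]),
                    name=str(p.ids[i]),
                    tags={"ref": str(p.ref[i]), "alt": str(p.alt[i])},
                )
                for i in range(p.n_variants)
            ]
        )


def _place_spans(
    rng, span_lo: int, span_hi: int, lengths: np.ndarray, min_gap: int
) -> np.ndarray:
    """Non-overlapping start positions (sorted) in [span_lo, span_hi)."""
    n = lengths.size
    used = int(lengths.sum()) + (n - 1) * min_gap if n else 0
    free = (span_hi - span_lo) - used
    if free < 0:
        raise ConfigurationError(
            "n_dhs: requested intervals do not fit on the chromosomes"
        )
    extra = rng.multinomial(free, np.full(n + 1, 1.0 / (n + 1)))
    starts = np.empty(n, dtype=np.int64)
    cursor = span_lo
    for i in range(n):
        cursor += int(extra[i])
        starts[i] = cursor
        cursor += int(lengths[i]) + min_gap
    return starts


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Deterministically generate a dataset for the given configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    L = config.chrom_length_bp
    chrom_lengths = {c: L for c in chroms}
    workspace = IntervalSet([GenomicInterval(c, 0, L) for c in chroms])

    # -- DHS, one optional footprint each ------------------------------------
    per_chrom = np.full(len(chroms), config.n_dhs // len(chroms))
    per_chrom[: config.n_dhs % len(chroms)] += 1
    dhs_list: List[GenomicInterval] = []
    for ci, chrom in enumerate(chroms):
        n = int(per_chrom[ci])
        lens = rng.integers(
            config.dhs_length_bp[0], config.dhs_length_bp[1] + 1, n
        )
        starts = _place_spans(rng, CHROM_MARGIN_BP, L - CHROM_MARGIN_BP, lens,
                              DHS_GAP_BP)
        for k in range(n):
            dhs_list.append(
                GenomicInterval(chrom, int(starts[k]), int(starts[k] + lens[k]),
                                name=f"dhs_{len(dhs_list):05d}")
            )
    dhs = IntervalSet(dhs_list)

    fp_list: List[GenomicInterval] = []
    artefact_names: List[str] = []
    has_fp = rng.random(len(dhs_list)) < config.footprint_per_dhs_prob
    for k, d in enumerate(dhs_list):
        if not has_fp[k]:
            continue
        flen = int(rng.integers(config.footprint_length_bp[0],
                                config.footprint_length_bp[1] + 1))
        off = int(rng.integers(0, len(d) - flen + 1))
        score = float(np.round(rng.uniform(0.0, 100.0), 4))
        name = f"fp_{len(fp_list):05d}"
        fp_list.append(
            GenomicInterval(d.chrom, d.start + off, d.start + off + flen,
                            name=name, score=score)
        )
        if rng.random() < config.artefact_spike_prob:
            artefact_names.append(name)
    footprints = IntervalSet(fp_list)
    artefact_set = set(artefact_names)

    # -- blacklist (independent of everything else) ---------------------------
    bl_list = []
    for k in range(N_BLACKLIST):
        blen = int(rng.integers(*BLACKLIST_LENGTH_RANGE))
        chrom = chroms[int(rng.integers(0, len(chroms)))]
        s = int(rng.integers(0, L - blen))
        bl_list.append(GenomicInterval(chrom, s, s + blen, name=f"bl_{k:03d}"))
    blacklist = IntervalSet(bl_list)

    # -- cut-count track with planted artefact spikes -------------------------
    cut = ScoredTrack.zeros(chrom_lengths)
    for d in dhs_list:
        cut.data[d.chrom][d.start : d.end] = rng.poisson(CUT_RATE, len(d))
    for f in fp_list:
        if f.name not in artefact_set:
            continue
        c = footprint_centre(f)
        spike_pos = int(np.clip(c + rng.integers(-100, 101), 0, L - 1))
        w_lo, w_hi = max(0, c - 100), min(L, c + 101)
        arr = cut.data[f.chrom]
        rest = arr[w_lo:w_hi].sum() - arr[spike_pos]
        arr[spike_pos] = max(1.0, 10.0 * rest)

    # -- footprint quality classes and one motif occurrence per footprint ----
    n_fp = len(fp_list)
    n_hq = int(np.floor(HIGH_QUALITY_FRACTION * n_fp))
    order = np.argsort([-(f.score or 0.0) for f in fp_list], kind="stable")
    hq_idx = set(order[:n_hq].tolist())
    hq_names = [fp_list[i].name for i in sorted(hq_idx)]

    n_hi_tf = int(round(config.expressed_tf_fraction * config.n_motifs))
    n_hi_tf = min(max(n_hi_tf, 1), config.n_motifs - 1) if config.n_motifs > 1 else 1
    tf_ids = [f"tf{t:02d}" for t in range(config.n_motifs)]
    hi_tfs, und_tfs = tf_ids[:n_hi_tf], tf_ids[n_hi_tf:]
    pwms = []
    for tf in tf_ids:
        consensus = rng.integers(0, 4, config.motif_length)
        mat = np.full((config.motif_length, 4), 0.05)
        mat[np.arange(config.motif_length), consensus] = 0.85
        pwms.append(PWM(tf, mat))
    pwm_by_tf = {p.tf_id: p for p in pwms}

    occ_list: List[GenomicInterval] = []
    for k, f in enumerate(fp_list):
        pool = hi_tfs if k in hq_idx else und_tfs
        if not pool:  # degenerate expressed_tf_fraction of 0 or 1
            continue
        tf = pool[int(rng.integers(0, len(pool)))]
        off = int(rng.integers(0, len(f) - config.motif_length + 1))
        occ_list.append(
            GenomicInterval(f.chrom, f.start + off,
                            f.start + off + config.motif_length,
                            name=tf, tags={"tf_id": tf})
        )
    motifs = IntervalSet(occ_list)

    # -- conservation track: noise near DHS + signal on expressed motifs -----
    cons = ScoredTrack.zeros(chrom_lengths)
    for d in dhs_list:
        lo = max(0, d.start - TRACK_MARGIN_BP)
        hi = min(L, d.end + TRACK_MARGIN_BP)
        cons.data[d.chrom][lo:hi] = np.round(
            rng.normal(0.0, CONSERVATION_NOISE_SD, hi - lo), 4
        )
    hi_tf_set = set(hi_tfs)
    for m in occ_list:
        if m.name in hi_tf_set:
            cons.data[m.chrom][m.start : m.end] += config.conservation_signal

    # -- expression table ------------------------------------------------------
    samples = [f"s{j + 1}" for j in range(N_EXPRESSION_SAMPLES)]
    expr_rows = {}
    for tf in tf_ids:
        if tf in hi_tf_set:
            expr_rows[tf] = np.round(
                rng.uniform(*HI_EXPRESSION_RANGE, N_EXPRESSION_SAMPLES), 3
            )
        else:
            expr_rows[tf] = np.full(N_EXPRESSION_SAMPLES, UND_EXPRESSION_RPKM)
    expression = ExpressionTable(
        pd.DataFrame(expr_rows, index=samples).T.rename_axis("tf_id")
    )

    # -- phased panel with block LD -------------------------------------------
    per_chrom_snv = np.full(len(chroms), config.n_snvs // len(chroms))
    per_chrom_snv[: config.n_snvs % len(chroms)] += 1
    eps = 0.5 * (1.0 - config.within_block_r2 ** 0.25)
    n_hap = config.n_haplotypes_in_panel
    all_chrom, all_pos, cols = [], [], []
    for ci, chrom in enumerate(chroms):
        n = int(per_chrom_snv[ci])
        pos0 = np.sort(rng.choice(L, n, replace=False))
        pos1 = pos0 + 1  # 1-based
        blocks = pos0 // config.ld_block_length_bp
        mat = np.empty((n_hap, n), dtype=np.uint8)
        for b in np.unique(blocks):
            sel = np.flatnonzero(blocks == b)
            anc = (rng.random(n_hap) < 0.5).astype(np.uint8)
            flips = (rng.random((n_hap, sel.size)) < eps).astype(np.uint8)
            mat[:, sel] = anc[:, None] ^ flips
        all_chrom.append(np.full(n, chrom))
        all_pos.append(pos1)
        cols.append(mat)
    chrom_arr = np.concatenate(all_chrom)
    pos_arr = np.concatenate(all_pos)
    matrix = np.concatenate(cols, axis=1)
    ids = np.asarray([f"{c}:{p}" for c, p in zip(chrom_arr, pos_arr)])

    # ref/alt: SNVs inside a motif occurrence get the consensus base as ref
    # and a minimal-probability base as alt (planted disruption)
    ref = np.full(ids.size, "A", dtype="<U1")
    alt = np.full(ids.size, "G", dtype="<U1")
    occ_by_chrom: Dict[str, List[GenomicInterval]] = {}
    for m in occ_list:
        occ_by_chrom.setdefault(m.chrom, []).append(m)
    disruptive_ids: List[str] = []
    for chrom, occs in occ_by_chrom.items():
        sel = np.flatnonzero(chrom_arr == chrom)
        p0 = pos_arr[sel] - 1
        starts = np.asarray([m.start for m in occs])
        o_order = np.argsort(starts)
        starts = starts[o_order]
        occs = [occs[i] for i in o_order]
        j = np.searchsorted(starts, p0, side="right") - 1
        for si, jj in zip(sel, j):
            if jj < 0:
                continue
            m = occs[jj]
            pos0 = int(pos_arr[si]) - 1
            if not m.start <= pos0 < m.end:
                continue
            pwm = pwm_by_tf[m.name]
            offset = pos0 - m.start
            cons_base = int(pwm.matrix[offset].argmax())
            worst = int(pwm.matrix[offset].argmin())
            ref[si] = ALPHABET[cons_base]
            alt[si] = ALPHABET[worst]
            disruptive_ids.append(str(ids[si]))
    panel = PhasedPanel(ids, chrom_arr, pos_arr, ref, alt, matrix)

    # -- sentinels with planted footprint enrichment --------------------------
    dhs_mask = dhs.coverage_mask(chrom_lengths)
    fp_mask = footprints.coverage_mask(chrom_lengths)
    pos0_all = pos_arr - 1
    in_dhs = np.zeros(ids.size, dtype=bool)
    in_fp = np.zeros(ids.size, dtype=bool)
    for chrom in chroms:
        sel = chrom_arr == chrom
        in_dhs[sel] = dhs_mask[chrom][pos0_all[sel]]
        in_fp[sel] = fp_mask[chrom][pos0_all[sel]]
    dhs_vars = np.flatnonzero(in_dhs)
    fp_vars = np.flatnonzero(in_fp)
    bg_vars = np.flatnonzero(in_dhs & ~in_fp)
    if dhs_vars.size == 0 or fp_vars.size == 0 or bg_vars.size == 0:
        raise ConfigurationError(
            "n_snvs: too few variants fall inside DHS/footprints to plant "
            "the sentinel enrichment"
        )
    # Baseline = footprint fraction of DHS base pairs: the overlap rate of a
    # variant placed uniformly in DHS, and exactly what a within-DHS
    # permutation null recovers.
    baseline = footprints.covered_bp() / dhs.covered_bp()
    p_in = config.planted_fold * baseline
    if p_in > 1.0:
        raise ConfigurationError(
            f"planted_fold: fold x baseline rate = {p_in:.3f} exceeds 1"
        )
    causal = rng.random(config.n_sentinels) < p_in
    choice = np.empty(config.n_sentinels, dtype=np.int64)
    n_c = int(causal.sum())
    choice[causal] = fp_vars[rng.integers(0, fp_vars.size, n_c)]
    choice[~causal] = bg_vars[
        rng.integers(0, bg_vars.size, config.n_sentinels - n_c)
    ]
    sentinels = [str(ids[i]) for i in choice]
    realized_fold = (n_c / config.n_sentinels) / baseline

    n_lq = n_fp - n_hq
    # TP:FP ratio at centile c is n_lq / (#low-quality footprints kept); it
    # reaches 2.0 when half the low-quality set is filtered out:
    expected_centile = 100.0 * (1.0 - (n_hq + 0.5 * n_lq) / n_fp) if n_fp else 0.0
    truth = TruthRecord(
        planted_fold=config.planted_fold,
        baseline_rate=float(baseline),
        realized_fold=float(realized_fold),
        causal_sentinel_indices=np.flatnonzero(causal).tolist(),
        artefact_footprints=artefact_names,
        hq_footprints=hq_names,
        hq_score_centile=100.0 * (1.0 - n_hq / n_fp) if n_fp else 0.0,
        expected_chosen_centile=expected_centile,
        disruptive_snvs=disruptive_ids,
        chrom_lengths=chrom_lengths,
        config=asdict(config),
    )
    return SyntheticDataset(
        workspace, dhs, footprints, blacklist, cut, cons, panel, sentinels,
        motifs, pwms, expression, truth,
    )


# -- on-disk layout -----------------------------------------------------------

_FILES = {
    "dhs": "dhs.bed",
    "footprints": "footprints.bed",
    "blacklist": "blacklist.bed",
    "motifs": "motifs.bed",
    "cut_track": "cut_track.tsv",
    "conservation_track": "conservation_track.tsv",
    "panel": "panel.tsv",
    "sentinels": "sentinels.tsv",
    "expression": "expression.tsv",
    "pwms": "pwms.meme",
    "truth": "truth.json",
    "chrom_lengths": "chrom_lengths.tsv",
}


def write_dataset(ds: SyntheticDataset, directory) -> Dict[str, str]:
    """Write all dataset components plus a checksum manifest; returns the
    manifest as {filename: sha256}."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_bed(ds.dhs, directory / _FILES["dhs"])
    write_bed(ds.footprints, directory / _FILES["footprints"])
    write_bed(ds.blacklist, directory / _FILES["blacklist"])
    write_bed(ds.motif_occurrences, directory / _FILES["motifs"])
    ds.cut_track.write(directory / _FILES["cut_track"])
    ds.conservation_track.write(directory / _FILES["conservation_track"])
    write_panel(ds.panel, directory / _FILES["panel"])
    write_sentinels([(s, None) for s in ds.sentinels],
                    directory / _FILES["sentinels"])
    ds.expression.write(directory / _FILES["expression"])
    write_meme(ds.pwms, directory / _FILES["pwms"])
    (directory / _FILES["truth"]).write_text(ds.truth.to_json())
    with open(directory / _FILES["chrom_lengths"], "wt") as fh:
        for c, n in ds.truth.chrom_lengths.items():
            fh.write(f"{c}\t{n}\n")
    manifest = {}
    for fname in sorted(_FILES.values()):
        digest = hashlib.sha256((directory / fname).read_bytes()).hexdigest()
        manifest[fname] = digest
    with open(directory / "MANIFEST.tsv", "wt") as fh:
        for fname, digest in manifest.items():
            fh.write(f"{fname}\t{digest}\n")
    return manifest


def read_dataset(directory) -> SyntheticDataset:
    """Read a dataset written by :func:`write_dataset`."""
    directory = Path(directory)
    truth = TruthRecord.from_json((directory / _FILES["truth"]).read_text())
    chrom_lengths = truth.chrom_lengths
    workspace = IntervalSet(
        [GenomicInterval(c, 0, n) for c, n in chrom_lengths.items()]
    )
    motifs = read_bed(directory / _FILES["motifs"])
    for m in motifs:
        m.tags["tf_id"] = m.name
    sentinels = [s for s, _ in read_sentinels(directory / _FILES["sentinels"])]
    return SyntheticDataset(
        workspace=workspace,
        dhs=read_bed(directory / _FILES["dhs"]),
        footprints=read_bed(directory / _FILES["footprints"]),
        blacklist=read_bed(directory / _FILES["blacklist"]),
        cut_track=ScoredTrack.read(directory / _FILES["cut_track"], chrom_lengths),
        conservation_track=ScoredTrack.read(
            directory / _FILES["conservation_track"], chrom_lengths
        ),
        panel=read_panel(directory / _FILES["panel"]),
        sentinels=sentinels,
        motif_occurrences=motifs,
        pwms=read_meme(directory / _FILES["pwms"]),
        expression=ExpressionTable.read(directory / _FILES["expression"]),
        truth=truth,
    )
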