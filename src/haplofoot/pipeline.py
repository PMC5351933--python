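"""Config-driven end-to-end orchestration.

Stages, in order: generate or load data -> association-p filter of sentinels
-> footprint QC -> optional score calibration -> haplotype expansion per r²
threshold -> Π curves per annotation layer -> workspace-constrained
enrichment tests -> motif-disruption test -> BH correction across enrichment
rows -> machine-readable report. All randomness derives from the single
top-level seed; re-running with the same seed reproduces the report
byte-for-byte (log lines carry timestamps, report files do not).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import yaml

from . import conservation_calibration as cc
from . import enrichment_stats as es
from . import footprint_processing as fpq
from . import motif_scan as ms
from . import pi_analysis as pa
from .errors import ConfigurationError
from .genome_intervals import GenomicInterval, IntervalSet
from .ld_haplotypes import DEFAULT_WINDOW_BP
from .synthetic_data import (
    SyntheticConfig,
    SyntheticDataset,
    generate_dataset,
    read_dataset,
)

__all__ = ["PipelineConfig", "run_pipeline"]

log = logging.getLogger("haplofoot")

DEFAULT_R2_GRID = [0.5, 0.6, 0.7, 0.8, 0.9, 1.0]


@dataclass
class FootprintQCConfig:
    min_width: int = 11
    max_width: int = 22
    artefact_half_window: int = 100
    artefact_skew: float = 0.5
    score_centile: Optional[float] = None


@dataclass
class CalibrationConfig:
    enabled: bool = False
    target_ratio: float = 2.0
    delta_threshold: float = 0.1
    flank_bp: int = 50
    centile_step: float = 5.0


@dataclass
class EnrichmentConfig:
    n: int = 10_000
    mode: str = "segment"


@dataclass
class MotifConfig:
    p: float = 1e-4
    n_shuffles: int = 1000


@dataclass
class PipelineConfig:
    """Defaults match the published analysis parameters: r² grid 0.5-1.0,
    10 Mb LD window, genome-wide significance 5e-8, 10,000 randomisations,
    motif p-value 1e-4, 1,000 footprint shuffles."""

    dataset_dir: Optional[str] = None
    synthetic: Optional[SyntheticConfig] = None
    r2_grid: List[float] = field(default_factory=lambda: list(DEFAULT_R2_GRID))
    window_bp: int = DEFAULT_WINDOW_BP
    gwas_p_threshold: float = 5e-8
    footprint_qc: FootprintQCConfig = field(default_factory=FootprintQCConfig)
    calibration: CalibrationConfig = field(default_factory=CalibrationConfig)
    enrichment: EnrichmentConfig = field(default_factory=EnrichmentConfig)
    motif: MotifConfig = field(default_factory=MotifConfig)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Dict) -> "PipelineConfig":
        kwargs = dict(raw)
        if "synthetic" in kwargs and kwargs["synthetic"] is not None:
            syn = dict(kwargs["synthetic"])
            for key in ("dhs_length_bp", "footprint_length_bp"):
                if key in syn:
                    syn[key] = tuple(syn[key])
            kwargs["synthetic"] = SyntheticConfig(**syn)
        for key, sub in (
            ("footprint_qc", FootprintQCConfig),
            ("calibration", CalibrationConfig),
            ("enrichment", EnrichmentConfig),
            ("motif", MotifConfig),
        ):
            if key in kwargs and kwargs[key] is not None:
                kwargs[key] = sub(**kwargs[key])
        return cls(**kwargs)


def _contained_sentinel_intervals(
    ds: SyntheticDataset, sentinels: Sequence[str], workspace: IntervalSet
) -> IntervalSet:
    """Sentinels as 1-bp intervals, restricted to those inside the workspace."""
    panel = ds.panel
    flags = pa.variant_annotation_flags(panel, workspace)
    out = []
    for s in sentinels:
        i = panel.index_of(s)
        if flags[i]:
            p = int(panel.pos[i])
            out.append(GenomicInterval(str(panel.chrom[i]), p - 1, p, name=s))
    return IntervalSet(out)


def _filter_sentinels(
    sentinels: Sequence[str], tags: Sequence[Optional[str]], threshold: float
) -> List[str]:
    """Drop sentinels whose tag parses as an association p >= threshold.

    Sentinels without a numeric tag (eQTL lists pre-filtered upstream) pass.
    """
    kept = []
    for s, tag in zip(sentinels, tags):
        if tag is not None:
            try:
                if float(tag) >= threshold:
                    continue
            except ValueError:
                pass
        kept.append(s)
    return kept


def run_pipeline(config: PipelineConfig, out_dir=None) -> Dict:
    """Run every stage and return (and optionally write) the report."""
    rng_seed = int(config.seed)
    report: Dict = {"seed": rng_seed, "stages": {}}

    # stage: data
    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=rng_seed)
        ds = generate_dataset(syn)
        source = "synthetic"
    elif config.dataset_dir is not None:
        ds = read_dataset(config.dataset_dir)
        source = str(config.dataset_dir)
    else:
        raise ConfigurationError("dataset_dir: no input (set it or a synthetic block)")
    log.info("data: %s | %d DHS, %d footprints, %d sentinels, %d variants",
             source, len(ds.dhs), len(ds.footprints), len(ds.sentinels),
             ds.panel.n_variants)
    report["stages"]["data"] = {
        "source": source,
        "n_dhs": len(ds.dhs),
        "n_footprints": len(ds.footprints),
        "n_sentinels": len(ds.sentinels),
        "n_variants": ds.panel.n_variants,
    }

    # stage: sentinel association-p filter
    sentinels = _filter_sentinels(
        ds.sentinels, [None] * len(ds.sentinels), config.gwas_p_threshold
    )
    log.info("sentinel filter: %d -> %d at p < %g",
             len(ds.sentinels), len(sentinels), config.gwas_p_threshold)
    report["stages"]["sentinel_filter"] = {
        "input": len(ds.sentinels), "kept": len(sentinels),
        "p_threshold": config.gwas_p_threshold,
    }

    # stage: footprint QC
    qc = config.footprint_qc
    footprints, counts = fpq.qc_pipeline(
        ds.footprints, ds.blacklist, ds.autosomes, ds.cut_track,
        qc.min_width, qc.max_width, qc.artefact_half_window, qc.artefact_skew,
        qc.score_centile,
    )
    log.info("footprint QC: %s", counts)
    report["stages"]["footprint_qc"] = counts

    # stage: optional score calibration
    if config.calibration.enabled:
        cal = config.calibration
        classes = cc.classify_tfs(ds.expression)
        grid = list(np.arange(0.0, 100.0, cal.centile_step))
        chosen, curve = cc.calibrate_threshold(
            footprints, ds.motif_occurrences, classes, ds.conservation_track,
            cal.target_ratio, grid, cal.delta_threshold, cal.flank_bp,
        )
        report["stages"]["calibration"] = {
            "chosen_centile": chosen,
            "curve": curve.to_dataframe().to_dict(orient="list"),
        }
        if chosen is not None:
            footprints = fpq.threshold_by_score(footprints, chosen)
        log.info("calibration: chosen centile %s, %d footprints retained",
                 chosen, len(footprints))

    # stage: Π curves over nested layers
    layers = {
        "dhs": ds.dhs,
        "footprints": footprints,
        "footprints_motif": footprints.intersection(ds.motif_occurrences),
    }
    curve = pa.pi_curve(sentinels, ds.panel, layers, config.r2_grid,
                        config.window_bp)
    report["pi_curve"] = curve.to_dataframe().to_dict(orient="list")
    log.info("pi: %s", {k: v[0] for k, v in curve.values.items()})

    # stage: enrichment tests
    seeds = np.random.SeedSequence(rng_seed).spawn(3)
    enr_seed = [int(s.generate_state(1)[0] % (2**31)) for s in seeds]
    query_dhs_ws = _contained_sentinel_intervals(ds, sentinels, ds.dhs)
    chrom_ws = ds.workspace.subtract(ds.blacklist)
    query_chrom_ws = _contained_sentinel_intervals(ds, sentinels, chrom_ws)
    results = [
        es.fold_enrichment(
            query_dhs_ws, footprints, ds.dhs, config.enrichment.n,
            enr_seed[0], mode=config.enrichment.mode,
            label="sentinels_in_footprints_vs_dhs_workspace",
        ),
        es.fold_enrichment(
            query_chrom_ws, ds.dhs, chrom_ws, config.enrichment.n,
            enr_seed[1], mode=config.enrichment.mode,
            label="sentinels_in_dhs_vs_chromosome_workspace",
        ),
    ]
    for q, r in zip(es.bh_qvalues([r.p_empirical for r in results]), results):
        r.q = q
    report["enrichment"] = [dataclasses.asdict(r) for r in results]
    for r in results:
        log.info("enrichment %s: fold=%.3f p=%.4g q=%.4g",
                 r.label, r.fold, r.p_empirical, r.q)

    # stage: motif-disruption test
    obs, null_mean, p_dis = ms.disruption_proportion_test(
        ds.snv_intervals(), footprints, ds.dhs, ds.motif_hits(),
        {p.tf_id: p for p in ds.pwms}, config.motif.n_shuffles,
        enr_seed[2], config.motif.p,
    )
    report["disruption"] = {
        "observed": obs, "null_mean": null_mean, "p": p_dis,
        "n_shuffles": config.motif.n_shuffles,
    }
    log.info("disruption: observed=%.3f null=%.3f p=%.4g", obs, null_mean, p_dis)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        import pandas as pd

        pd.DataFrame(report["pi_curve"]).to_csv(
            out_dir / "pi_curve.tsv", sep="\t", index=False
        )
        pd.DataFrame(report["enrichment"]).to_csv(
            out_dir / "enrichment.tsv", sep="\t", index=False
        )
        (out_dir / "report.json").write_text(
            json.dumps(report, indent=1, sort_keys=True, default=float)
        )
    return report
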