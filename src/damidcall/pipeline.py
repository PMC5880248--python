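"""End-to-end DamID-seq peak calling: configuration and orchestration.

``run_pipeline`` wires the stages in their analysis order —
fragment map -> count -> abundance filter -> TMM/logCPM -> qsmooth
(-> optional quantro report) -> moderated tests -> merge -> call ->
coverage tracks — with the published default parameters (abundance
threshold 10, tol 260, max width 10,000, FDR 0.1, min logFC 0.5).
Reruns with the same config and seed are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import counting, diffbind, normalize, peaks as peaks_mod, tracks as tracks_mod
from .counting import (CountMatrix, ReadFilterPolicy, SampleSheet,
                       read_sample_sheet, write_counts)
from .fragment_map import FragmentMap, build_fragment_map, write_fragment_annotation

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "load_config", "dump_config", "run_pipeline",
           "run_from_counts", "PipelineResult"]


@dataclass
class PipelineConfig:
    """All paths and parameters of a pipeline run.

    Numeric defaults are the published analysis values; ``seed`` drives
    every stochastic step (the quantro permutations).
    """

    genome: str | None = None
    samples: str | None = None
    blacklist: str | None = None
    output_dir: str = "damidcall_out"
    min_count: float = 10.0
    prior_count: float = 2.0
    qsmooth_span: float = 0.05
    tol: int = 260
    max_width: int = 10_000
    fdr: float = 0.1
    min_logfc: float = 0.5
    trend_span: float = 0.4
    robust: bool = True
    quantro_permutations: int = 0   # 0 disables the report
    make_tracks: bool = True
    seed: int = 0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def load_config(path) -> PipelineConfig:
    """Read a YAML config; unknown keys are rejected, defaults filled."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a mapping")
    valid = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(data) - valid
    if unknown:
        raise ValueError(f"unknown config keys {sorted(unknown)}; "
                         f"valid keys: {sorted(valid)}")
    cfg = PipelineConfig(**data)
    logger.info("resolved config: %s", cfg.to_dict())
    return cfg


def dump_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


@dataclass
class PipelineResult:
    fragment_map: FragmentMap
    counts: CountMatrix
    retained: CountMatrix
    keep_mask: np.ndarray
    norm_factors: np.ndarray
    logcpm: np.ndarray
    tests: pd.DataFrame
    regions: pd.DataFrame
    quantro: object | None = None
    report: dict = field(default_factory=dict)

    @property
    def peaks(self) -> pd.DataFrame:
        return self.regions[self.regions["called"]].reset_index(drop=True)


def run_from_counts(counts: CountMatrix, fmap: FragmentMap,
                    config: PipelineConfig | None = None) -> PipelineResult:
    """Statistical pipeline from an existing count matrix to peaks."""
    config = config or PipelineConfig()
    report: dict = {"n_fragments": fmap.n_fragments,
                    "n_samples": len(counts.samples)}

    retained, keep = normalize.filter_low_abundance(
        counts, config.min_count, config.prior_count)
    report["n_retained"] = int(keep.sum())
    if retained.n_fragments < 10:
        raise ValueError("fewer than 10 fragments pass the abundance filter")

    factors = normalize.tmm_factors(retained)
    logcpm = normalize.log_cpm(retained, factors, config.prior_count)
    abundance = normalize.ave_log_cpm(retained, config.prior_count)

    quantro = None
    if config.quantro_permutations > 0:
        quantro = normalize.quantro_test(
            logcpm, retained.groups, n_perm=config.quantro_permutations,
            seed=config.seed)
        report["quantro_stat"] = quantro.statistic
        report["quantro_p"] = quantro.p_value

    smoothed = normalize.qsmooth(logcpm, retained.groups, config.qsmooth_span)

    tests = diffbind.differential_binding_tests(
        smoothed, retained.groups, abundance,
        fragment_index=retained.fragment_index,
        span=config.trend_span, robust=config.robust)

    frame = fmap.to_frame().set_index("index")
    coords = frame.loc[tests["fragment"].to_numpy()]
    tests = tests.assign(chrom=coords["chrom"].to_numpy(),
                         start=coords["start"].to_numpy(),
                         end=coords["end"].to_numpy())

    cluster = peaks_mod.merge_windows(tests, tol=config.tol,
                                      max_width=config.max_width)
    regions = peaks_mod.combine_tests(tests, cluster)
    params = peaks_mod.PeakCallParams(tol=config.tol, max_width=config.max_width,
                                      fdr=config.fdr, min_logfc=config.min_logfc)
    regions = peaks_mod.call_peaks(regions, params)
    report["n_regions"] = len(regions)
    report["n_peaks"] = int(regions["called"].sum()) if len(regions) else 0

    return PipelineResult(fmap, counts, retained, keep, factors, smoothed,
                          tests, regions, quantro, report)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Full run from genome + alignments to peaks, tracks and report files."""
    if config.genome is None or config.samples is None:
        raise ValueError("config fields 'genome' and 'samples' are required")
    for name in ("genome", "samples"):
        p = getattr(config, name)
        if not Path(p).exists():
            raise FileNotFoundError(f"config field {name!r}: no such file {p}")
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    dump_config(config, out / "config.resolved.yaml")

    logger.info("stage fragments: building GATC fragment map")
    fmap = build_fragment_map(config.genome)
    write_fragment_annotation(fmap, out / "fragments.bed", "bed")

    logger.info("stage count: filtering and counting alignments")
    sheet = read_sample_sheet(config.samples)
    policy = ReadFilterPolicy()
    if config.blacklist:
        policy.exclusion_regions = ReadFilterPolicy.load_exclusion_bed(
            config.blacklist)
    counts, stats = counting.count_samples(sheet, fmap, policy)
    write_counts(counts, out / "counts.tsv")

    result = run_from_counts(counts, fmap, config)
    result.report["filter_stats"] = {s: st.as_dict() for s, st in stats.items()}

    result.tests.to_csv(out / "fragment_tests.tsv", sep="\t", index=False)
    peaks_mod.write_peaks(result.regions, out / "peaks")

    if config.make_tracks:
        logger.info("stage tracks: scaled coverage and subtraction")
        _write_tracks(config, sheet, policy, fmap, result, out)

    with open(out / "report.json", "w") as fh:
        json.dump(result.report, fh, indent=2, default=str)
    return result


def _write_tracks(config: PipelineConfig, sheet: SampleSheet,
                  policy: ReadFilterPolicy, fmap: FragmentMap,
                  result: PipelineResult, out: Path) -> None:
    import pysam

    eff = normalize.effective_library_sizes(result.retained, result.norm_factors)
    group_tracks: dict[str, list[tracks_mod.CoverageTrack]] = {}
    for i, (sample, path) in enumerate(zip(sheet.samples, sheet.paths)):
        reads: dict[str, list[tuple[int, int]]] = {}
        with pysam.AlignmentFile(str(path), check_sq=False) as afile:
            for aln in counting.filter_alignments(afile, policy):
                reads.setdefault(aln.reference_name, []).append(
                    (aln.reference_start, aln.reference_end))
        raw = tracks_mod.genome_coverage(reads, fmap.chrom_lengths, label=sample)
        scaled = tracks_mod.scale_coverage(raw, 1e6 / eff[i])
        tracks_mod.write_bedgraph(scaled, out / f"{sample}.bedgraph")
        group_tracks.setdefault(sheet.groups[i], []).append(scaled)
    merged = {g: tracks_mod.mean_tracks(ts, label=g)
              for g, ts in group_tracks.items()}
    for g, track in merged.items():
        tracks_mod.write_bedgraph(track, out / f"group_{g}.bedgraph")
    if counting.GROUP_POI in merged and counting.GROUP_DAM in merged:
        diff = tracks_mod.subtract_tracks(merged[counting.GROUP_POI],
                                          merged[counting.GROUP_DAM])
        tracks_mod.write_bedgraph(diff, out / "subtract.bedgraph",
                                  omit_zero=False)
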