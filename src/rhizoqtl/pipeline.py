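"""End-to-end pipeline: filter -> scan -> threshold -> regions -> compare.

``PipelineConfig`` collects every stage parameter with the published values
as defaults and round-trips through YAML unchanged.  ``run_pipeline`` chains
the stages, logs parameters and counts, writes every artifact into the output
directory and records them all in a manifest.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import filtering, regions as regions_mod, scan, vcfio
from .errors import RhizoqtlError, StageError


@dataclass
class PipelineConfig:
    """All stage parameters; defaults reproduce the published analysis."""

    variants: str = ""                 # VCF or TSV of bulk allele depths
    gwas_hits: str | None = None       # optional TSV of GWAS hits
    out_dir: str = "rhizoqtl_out"

    tail_fraction: float = 0.10
    bulk_size: int = 55

    min_total_allele_freq: float = 0.25
    symmetric_freq_filter: bool = False
    depth_lower_pct: float = 25.0
    depth_upper_pct: float = 95.0
    max_missing_frac: float = 0.5
    min_maf: float = 0.05

    window: int = 100
    ed_variant: str = "between"
    window_stat: str = "sum4"
    alpha: float = 0.05
    threshold_mode: str = "genome_max"
    n_null_sims: int = 200

    gwas_flank_bp: int = 50_000
    seed: int = 0

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise StageError("config", "unknown-key",
                             f"unrecognised config keys {sorted(unknown)}")
        return cls(**data)

    def filter_params(self) -> filtering.FilterParams:
        return filtering.FilterParams(
            min_total_allele_freq=self.min_total_allele_freq,
            symmetric_freq_filter=self.symmetric_freq_filter,
            depth_lower_pct=self.depth_lower_pct,
            depth_upper_pct=self.depth_upper_pct,
            max_missing_frac=self.max_missing_frac,
            min_maf=self.min_maf,
        )


@dataclass
class PipelineResult:
    out_dir: Path
    filter_report: filtering.FilterReport
    profile: pd.DataFrame
    threshold: scan.ScanThreshold
    regions: list
    overlap: pd.DataFrame | None
    manifest: dict = field(default_factory=dict)


def _load_variants(path: str) -> pd.DataFrame:
    p = Path(path)
    if p.suffix.lower() == ".vcf":
        return vcfio.read_vcf(p)
    return vcfio.read_variants_tsv(p)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full scan; every stage failure aborts with its stage name."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []
    manifest: dict[str, str] = {}

    def log(msg: str):
        log_lines.append(msg)

    def emit(name: str, writer):
        path = out / name
        writer(path)
        manifest[name] = str(path)

    try:
        table = _load_variants(config.variants)
        log(f"input: {config.variants} ({len(table)} sites)")
    except RhizoqtlError:
        raise
    except Exception as e:  # noqa: BLE001 - wrap with stage context
        raise StageError("input", "read-failed", str(e)) from e

    try:
        filtered, report = filtering.filter_cascade(table, config.filter_params())
        for s in report.steps:
            log(f"filter {s.name}: removed {s.removed}, remaining {s.remaining}")
        log(f"filter depth bounds: {report.depth_bounds}")
        emit("filtered_variants.tsv", lambda p: vcfio.write_variants_tsv(filtered, p))
        emit("filter_report.tsv", lambda p: report.to_frame().to_csv(p, sep="\t", index=False))
    except RhizoqtlError as e:
        raise StageError("filter", "cascade-failed", str(e)) from e

    if filtered.empty:
        raise StageError("scan", "empty-input", "no sites survive the filter cascade")

    try:
        profile = scan.ed_profile(filtered, window=config.window,
                                  variant=config.ed_variant, stat=config.window_stat)
        log(f"scan: ED variant={config.ed_variant}, window={config.window}, "
            f"stat={config.window_stat}")
    except RhizoqtlError as e:
        raise StageError("scan", "profile-failed", str(e)) from e

    try:
        depth_low = (filtered["ref_depth_low"] + filtered["alt_depth_low"]).to_numpy()
        depth_high = (filtered["ref_depth_high"] + filtered["alt_depth_high"]).to_numpy()
        thr = scan.significance_threshold(
            filtered["chrom"].to_numpy(), depth_low, depth_high,
            bulk_size=config.bulk_size, n_sims=config.n_null_sims,
            alpha=config.alpha, seed=config.seed, window=config.window,
            variant=config.ed_variant, stat=config.window_stat,
            mode=config.threshold_mode,
        )
        profile = scan.mark_significant(profile, thr)
        log(f"threshold: {thr.value:.6g} (alpha={thr.alpha}, mode={thr.mode}, "
            f"n_sims={thr.n_sims}, seed={thr.seed})")
        emit("ed_profile.tsv", lambda p: profile.to_csv(p, sep="\t", index=False))
    except RhizoqtlError as e:
        raise StageError("threshold", "null-sim-failed", str(e)) from e

    try:
        called = regions_mod.call_regions(profile, window=config.window)
        log(f"regions: {len(called)} called, "
            f"{int(profile['significant'].sum())} significant markers")
        emit("regions.tsv", lambda p: regions_mod.regions_to_frame(called)
             .to_csv(p, sep="\t", index=False))
        emit("regions_mbp.tsv", lambda p: regions_mod.regions_to_frame(called, mbp=True)
             .to_csv(p, sep="\t", index=False))
        emit("regions.bed", lambda p: regions_mod.write_bed(called, p))
    except RhizoqtlError as e:
        raise StageError("regions", "calling-failed", str(e)) from e

    overlap = None
    if config.gwas_hits:
        try:
            hits = vcfio.read_gwas_hits_tsv(config.gwas_hits)
            windows = regions_mod.gwas_windows(hits, flank=config.gwas_flank_bp)
            overlap, summary = regions_mod.overlap_report(called, windows)
            log(f"compare: {summary.n_regions_overlapped}/{summary.n_regions} regions "
                f"overlap {summary.n_windows_overlapped}/{summary.n_windows} GWAS windows")
            emit("gwas_overlap.tsv", lambda p: overlap.to_csv(p, sep="\t", index=False))
        except RhizoqtlError as e:
            raise StageError("compare", "overlap-failed", str(e)) from e

    emit("run.log", lambda p: p.write_text("\n".join(log_lines) + "\n"))
    emit("config.yaml", config.to_yaml)
    manifest_path = out / "manifest.json"
    with open(manifest_path, "w") as fh:
        json.dump({"artifacts": manifest}, fh, indent=2, sort_keys=True)
    manifest["manifest.json"] = str(manifest_path)

    return PipelineResult(out_dir=out, filter_report=report, profile=profile,
                          threshold=thr, regions=called, overlap=overlap,
                          manifest=manifest)
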