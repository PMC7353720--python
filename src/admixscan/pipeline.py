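"""End-to-end scan orchestration.

``scan_cohort`` is the in-memory driver used by the CLI, the tests and the
acceptance harness: sample filtering -> within-chromosome correlations ->
per-locus decay fits -> direction-averaged residuals -> cross-chromosome
null scale -> Z-test -> effective-test Bonferroni correction -> distance
filter -> region-pair merging.  ``run_scan``/``run_meta`` wrap it with file
I/O, logging and a reproducibility manifest.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .correlation import (
    CorrelationMatrix,
    NullScale,
    estimate_null_scale,
    within_chromosome_correlations,
)
from .decay import DecayFit, ResidualMatrix, fit_all_loci, residual_correlations
from .errors import ConfigError, DataError
from .io import (
    BinManifest,
    ExclusionAnnotation,
    LocalAncestryMatrix,
    apply_exclusions,
    filter_samples,
)
from .meta import combine_scans, qq_data
from .scan import (
    EffectiveTestCount,
    RegionPair,
    annotate_significance,
    attach_beta,
    bonferroni_threshold,
    distance_filter,
    effective_bins,
    merge_region_pairs,
    region_pairs_table,
    total_independent_tests,
    z_test,
)

logger = logging.getLogger("admixscan")

_FLOAT_FMT = "%.10g"


@dataclass
class PipelineConfig:
    """Parameters of one cohort scan."""

    matrix_path: str | None = None
    manifest_path: str | None = None
    exclusion_bed: str | None = None
    cohort_label: str = "cohort"
    bin_size_bp: int = 400_000
    exclusion_radius_bp: int = 2_000_000
    low_ancestry: float = 0.05
    high_ancestry: float = 0.98
    min_distance_cM: float = 50.0
    alpha: float = 0.05
    max_null_pairs: int = 2_000_000
    gap_bins: int = 1
    seed: int = 0
    out_dir: str = "scan_out"

    def validate(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ConfigError("alpha must be in (0, 1)")
        if self.min_distance_cM < 0:
            raise ConfigError("min_distance_cM must be >= 0")


@dataclass
class ScanOutput:
    """Everything a cohort scan produces, in memory."""

    cohort_label: str
    n_samples: int
    n_samples_removed: int
    correlations: dict[str, CorrelationMatrix]
    fits: dict[str, dict[str, DecayFit]]
    residuals: dict[str, ResidualMatrix]
    null_scale: NullScale
    results: pd.DataFrame
    effective: EffectiveTestCount
    regions: dict[str, list[RegionPair]]
    stage_counts: dict = field(default_factory=dict)


def scan_cohort(
    matrix: LocalAncestryMatrix,
    manifest: BinManifest,
    *,
    exclusions: ExclusionAnnotation | None = None,
    exclusion_radius_bp: int = 2_000_000,
    low_ancestry: float = 0.05,
    high_ancestry: float = 0.98,
    min_distance_cM: float = 50.0,
    alpha: float = 0.05,
    max_null_pairs: int = 2_000_000,
    gap_bins: int = 1,
    seed: int = 0,
    scan_chroms: list[str] | None = None,
) -> ScanOutput:
    """Run the full within-chromosome epistasis scan for one cohort.

    ``scan_chroms`` restricts which chromosomes are scanned for pairs; all
    chromosomes always contribute to the cross-chromosome null scale.
    """
    manifest.validate()
    if exclusions is not None:
        kept = apply_exclusions(manifest, exclusions, exclusion_radius_bp)
        dropped_bins = manifest.n_bins - kept.n_bins
        manifest = kept
        matrix = LocalAncestryMatrix(
            matrix.dosage[manifest.bin_ids], cohort_label=matrix.cohort_label
        )
    else:
        dropped_bins = 0

    n_before = matrix.n_samples
    matrix = filter_samples(matrix, low_ancestry, high_ancestry)
    n_removed = n_before - matrix.n_samples
    logger.info("samples: %d kept, %d removed", matrix.n_samples, n_removed)

    correlations = within_chromosome_correlations(matrix, manifest)
    null_scale = estimate_null_scale(matrix, manifest, max_null_pairs, seed)
    logger.info(
        "null scale sigma_hat=%.6g from %d cross-chromosome pairs",
        null_scale.sigma_hat,
        null_scale.n_pairs_used,
    )

    chrom_list = scan_chroms if scan_chroms is not None else manifest.chroms
    fits: dict[str, dict[str, DecayFit]] = {}
    residuals: dict[str, ResidualMatrix] = {}
    tables = []
    k_per_chrom: dict[str, int] = {}
    n_nonconverged = 0
    for chrom in chrom_list:
        corr = correlations[chrom]
        chrom_fits = fit_all_loci(corr, manifest)
        n_nonconverged += sum(not f.converged for f in chrom_fits.values())
        res = residual_correlations(corr, chrom_fits, manifest)
        table = attach_beta(z_test(res, null_scale, manifest), corr)
        fits[chrom] = chrom_fits
        residuals[chrom] = res
        tables.append(table)
        k_per_chrom[chrom] = effective_bins(corr)
    results = pd.concat(tables, ignore_index=True)

    total = total_independent_tests(k_per_chrom)
    alpha_corrected = bonferroni_threshold(total, alpha)
    effective = EffectiveTestCount(
        k_per_chrom=k_per_chrom, total_tests=total, alpha_corrected=alpha_corrected
    )
    results = annotate_significance(
        distance_filter(results, min_distance_cM), alpha_corrected
    )

    regions: dict[str, list[RegionPair]] = {}
    for chrom in chrom_list:
        sig = results[(results["chrom"].astype(str) == chrom) & results["significant"]]
        regions[chrom] = merge_region_pairs(
            sig, manifest, gap_bins=gap_bins, exclusions=exclusions
        )

    stage_counts = {
        "bins_dropped_by_exclusion": dropped_bins,
        "bins_retained": manifest.n_bins,
        "samples_kept": matrix.n_samples,
        "samples_removed": n_removed,
        "fits_nonconverged": n_nonconverged,
        "pairs_tested": int(len(results)),
        "pairs_passing_distance": int(results["passes_distance_filter"].sum()),
        "pairs_significant": int(results["significant"].sum()),
        "region_pairs": int(sum(len(v) for v in regions.values())),
    }
    logger.info("stage counts: %s", stage_counts)
    return ScanOutput(
        cohort_label=matrix.cohort_label,
        n_samples=matrix.n_samples,
        n_samples_removed=n_removed,
        correlations=correlations,
        fits=fits,
        residuals=residuals,
        null_scale=null_scale,
        results=results,
        effective=effective,
        regions=regions,
        stage_counts=stage_counts,
    )


def _write_fits(fits: dict[str, dict[str, DecayFit]], path: Path) -> None:
    rows = [
        {
            "bin_id": f.locus,
            "a0": f.a0,
            "a1": f.a1,
            "a2": f.a2,
            "sse": f.sse,
            "converged": f.converged,
            "n_points": f.n_points,
        }
        for chrom_fits in fits.values()
        for f in chrom_fits.values()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def run_scan(config: PipelineConfig) -> Path:
    """File-based scan: read inputs, run scan_cohort, write every output.

    Outputs under ``config.out_dir``: scan_results.tsv, region_pairs.tsv,
    decay_fits.tsv, null_scale.json, effective_tests.json, qq.tsv and
    run_manifest.json (versions, parameters, seed, stage counts).
    """
    config.validate()
    if not config.matrix_path or not config.manifest_path:
        raise ConfigError("matrix_path and manifest_path are required")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    matrix = LocalAncestryMatrix.from_tsv(config.matrix_path, config.cohort_label)
    manifest = BinManifest.from_tsv(config.manifest_path)
    exclusions = (
        ExclusionAnnotation.from_bed(config.exclusion_bed)
        if config.exclusion_bed
        else None
    )
    scan = scan_cohort(
        matrix,
        manifest,
        exclusions=exclusions,
        exclusion_radius_bp=config.exclusion_radius_bp,
        low_ancestry=config.low_ancestry,
        high_ancestry=config.high_ancestry,
        min_distance_cM=config.min_distance_cM,
        alpha=config.alpha,
        max_null_pairs=config.max_null_pairs,
        gap_bins=config.gap_bins,
        seed=config.seed,
    )

    scan.results.to_csv(
        out / "scan_results.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    all_regions = [r for regs in scan.regions.values() for r in regs]
    region_pairs_table(all_regions).to_csv(
        out / "region_pairs.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    _write_fits(scan.fits, out / "decay_fits.tsv")
    (out / "null_scale.json").write_text(
        json.dumps(
            {
                "sigma_hat": scan.null_scale.sigma_hat,
                "n_pairs_used": scan.null_scale.n_pairs_used,
                "subsample_seed": scan.null_scale.subsample_seed,
            },
            indent=2,
        )
    )
    (out / "effective_tests.json").write_text(
        json.dumps(
            {
                "k_per_chrom": scan.effective.k_per_chrom,
                "total_tests": scan.effective.total_tests,
                "alpha_corrected": scan.effective.alpha_corrected,
            },
            indent=2,
        )
    )
    qq_data(scan.results["p"]).to_csv(
        out / "qq.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    run_manifest = {
        "tool": "admixscan",
        "version": __version__,
        "cohort_label": config.cohort_label,
        "n_samples": scan.n_samples,
        "parameters": {
            k: v for k, v in vars(config).items() if not k.startswith("_")
        },
        "stage_counts": scan.stage_counts,
    }
    (out / "run_manifest.json").write_text(json.dumps(run_manifest, indent=2, sort_keys=True))
    return out


def run_meta(scan_dirs: list[str | Path], out_dir: str | Path) -> Path:
    """Meta-analyze >= 1 completed scan output directories on a shared grid."""
    scans: dict[str, pd.DataFrame] = {}
    n_by_label: dict[str, int] = {}
    sigma_by_label: dict[str, float] = {}
    grid: list[tuple] | None = None
    for d in scan_dirs:
        d = Path(d)
        man = json.loads((d / "run_manifest.json").read_text())
        label = man["cohort_label"]
        if label in scans:
            label = f"{label}:{d.name}"
        table = pd.read_csv(d / "scan_results.tsv", sep="\t", dtype={"chrom": str})
        this_grid = list(zip(table["chrom"], table["bin_i"], table["bin_j"]))
        if grid is None:
            grid = this_grid
        elif grid != this_grid:
            divergent = next(
                (a for a, b in zip(grid, this_grid) if a != b),
                ("<length mismatch>",),
            )
            raise DataError(f"bin grid mismatch at pair {divergent} in {d}")
        scans[label] = table
        n_by_label[label] = int(man["n_samples"])
        sigma_by_label[label] = float(
            json.loads((d / "null_scale.json").read_text())["sigma_hat"]
        )

    meta_table, diagnostics = combine_scans(scans, n_by_label, sigma_by_label)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta_table.to_csv(
        out / "meta_results.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    (out / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2, sort_keys=True))
    qq_data(meta_table["p_meta"]).to_csv(
        out / "qq.tsv", sep="\t", index=False, float_format=_FLOAT_FMT
    )
    return out
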