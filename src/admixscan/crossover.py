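"""ANCAEC: average number of African/European ancestry crossovers per cM,
and the normal-approximation deficit test.

Epistatic selection between two regions preserves ancestry haplotypes
spanning them, so the inter-region interval should show fewer historical
ancestry crossovers than equal-length windows elsewhere in the genome.
Events are counted from diploid dosage as the absolute adjacent-bin dosage
difference — the minimal number of haplotype switches consistent with
unphased data (a 0->2 step counts as 2 events).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .errors import DataError
from .io import BinManifest, LocalAncestryMatrix


@dataclass
class CrossoverStats:
    """Per-interval ancestry-crossover summary."""

    chrom: str
    start_bp: int
    end_bp: int
    cm_length: float
    ancaec_per_cm: float
    events: np.ndarray  # per-individual event counts


def _interp_cm(sub, bp: float) -> float:
    """Genetic position of a bp coordinate, linear between bin midpoints
    (clamped at chromosome ends)."""
    x = sub["mid_bp"].to_numpy(dtype=float)
    y = sub["mid_cM"].to_numpy(dtype=float)
    return float(np.interp(bp, x, y))


def count_ancestry_switches(
    matrix: LocalAncestryMatrix,
    manifest: BinManifest,
    interval: tuple[str, int, int],
) -> CrossoverStats:
    """ANCAEC per cM over an interval (chrom, start_bp, end_bp).

    Per individual, events = sum over adjacent in-interval bins of
    |dosage_{b+1} - dosage_b|; the rate is the mean event count divided by
    the interval's cM length.
    """
    chrom, start_bp, end_bp = str(interval[0]), int(interval[1]), int(interval[2])
    sub = manifest.for_chrom(chrom)
    if not len(sub):
        raise DataError(f"chromosome {chrom} not in manifest")
    inside = sub[(sub["mid_bp"] >= start_bp) & (sub["mid_bp"] <= end_bp)]
    if len(inside) < 2:
        raise DataError("interval must contain >= 2 bins")
    cm_length = _interp_cm(sub, end_bp) - _interp_cm(sub, start_bp)
    if cm_length <= 0:
        raise DataError("interval has non-positive cM length")
    dosage = matrix.dosage[list(inside["bin_id"])].to_numpy(dtype=float)
    events = np.abs(np.diff(dosage, axis=1)).sum(axis=1)
    return CrossoverStats(
        chrom=chrom,
        start_bp=start_bp,
        end_bp=end_bp,
        cm_length=cm_length,
        ancaec_per_cm=float(events.mean() / cm_length),
        events=events,
    )


def reference_windows(
    manifest: BinManifest,
    cm_length: float,
    excluded: list[tuple[str, int, int]] | None = None,
) -> list[tuple[str, int, int]]:
    """Non-overlapping windows of the target's cM length tiled over the genome.

    Windows overlapping any excluded bp interval, or containing fewer than
    two bins, are dropped.
    """
    excluded = excluded or []
    windows: list[tuple[str, int, int]] = []
    for chrom in manifest.chroms:
        sub = manifest.for_chrom(chrom)
        cm = sub["mid_cM"].to_numpy(dtype=float)
        bp = sub["mid_bp"].to_numpy(dtype=float)
        lo, hi = cm.min(), cm.max()
        start = lo
        while start + cm_length <= hi + 1e-9:
            # window bp bounds via the same piecewise-linear map used for
            # the target's cM length, keeping denominators comparable
            w = (
                chrom,
                int(round(np.interp(start, cm, bp))),
                int(round(np.interp(start + cm_length, cm, bp))),
            )
            start += cm_length
            mask = (bp >= w[1]) & (bp <= w[2])
            if mask.sum() < 2:
                continue
            if any(
                c == chrom and w[1] <= e and w[2] >= s for c, s, e in excluded
            ):
                continue
            windows.append(w)
    return windows


def deficit_test(
    target: CrossoverStats,
    matrix: LocalAncestryMatrix,
    manifest: BinManifest,
    excluded: list[tuple[str, int, int]] | None = None,
) -> tuple[float, float, np.ndarray]:
    """One-sided test for a crossover deficit in the target interval.

    The null mean and SD come from the ANCAEC rates of equal-cM-length
    windows tiled over the genome minus the excluded intervals (the target
    is always excluded).  Returns (Z, p, window_rates); p is the lower tail
    of the normal approximation.
    """
    excluded = list(excluded or [])
    excluded.append((target.chrom, target.start_bp, target.end_bp))
    windows = reference_windows(manifest, target.cm_length, excluded)
    if len(windows) < 10:
        raise DataError(
            f"only {len(windows)} reference windows available (need >= 10)"
        )
    rates = np.array(
        [
            count_ancestry_switches(matrix, manifest, w).ancaec_per_cm
            for w in windows
        ]
    )
    sd = rates.std(ddof=1)
    if sd == 0:
        raise DataError("reference window rates are constant")
    z = (target.ancaec_per_cm - rates.mean()) / sd
    p = float(norm.cdf(z))
    return float(z), p, rates
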