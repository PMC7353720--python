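"""Window-based positional enrichment of trait-associated hits in a region.

The chromosome outside the target region is tiled into windows of the
target's bp length; the enrichment Z compares the target's hit count with the
mean per-window count, scaled by the SD of per-window counts (the Z compares
one region against the window distribution, not against the SE of the mean).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .errors import DataError


@dataclass
class EnrichmentResult:
    z: float
    p: float
    observed: int
    expected: float
    n_windows: int


def read_hits(path) -> pd.DataFrame:
    """Hit list TSV with columns chrom, bp, label (header optional extras kept)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    for col in ("chrom", "bp"):
        if col not in df.columns:
            raise DataError(f"hit list missing column {col!r}")
    return df


def region_enrichment(
    hits: pd.DataFrame,
    target: tuple[str, int, int],
    chrom_length: int,
) -> EnrichmentResult:
    """One-sided enrichment test of hit counts in a target interval.

    Z = (observed - mean window count) / SD of window counts over
    non-overlapping target-length windows tiling the rest of the chromosome.
    """
    chrom, start, end = str(target[0]), int(target[1]), int(target[2])
    if start < 1 or end > chrom_length or start >= end:
        raise DataError("target interval outside chromosome or empty")
    width = end - start + 1
    pos = hits.loc[hits["chrom"].astype(str) == chrom, "bp"].to_numpy(dtype=float)

    windows: list[tuple[int, int]] = []
    # full-width windows tiled left of the target, then right of it
    left_edge = start - 1
    w_end = left_edge
    while w_end - width + 1 >= 1:
        windows.append((w_end - width + 1, w_end))
        w_end -= width
    w_start = end + 1
    while w_start + width - 1 <= chrom_length:
        windows.append((w_start, w_start + width - 1))
        w_start += width
    if len(windows) < 5:
        raise DataError(f"only {len(windows)} reference windows (need >= 5)")

    counts = np.array([((pos >= a) & (pos <= b)).sum() for a, b in windows], dtype=float)
    observed = int(((pos >= start) & (pos <= end)).sum())
    sd = counts.std(ddof=1)
    if sd == 0:
        raise DataError("window hit counts have zero variance")
    z = (observed - counts.mean()) / sd
    return EnrichmentResult(
        z=float(z),
        p=float(norm.sf(z)),
        observed=observed,
        expected=float(counts.mean()),
        n_windows=len(windows),
    )
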