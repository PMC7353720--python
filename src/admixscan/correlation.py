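"""Pairwise Pearson correlation of local-ancestry dosages and the
cross-chromosome null scale.

The scan statistic divides residual within-chromosome correlations by the
standard deviation of correlations between loci on *different* chromosomes,
where genetic distance is effectively infinite and any correlation is pure
sampling noise (plus genome-wide admixture structure).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, NumericalError
from .io import BinManifest, LocalAncestryMatrix


@dataclass
class CorrelationMatrix:
    """Symmetric matrix of local-ancestry correlations for one chromosome.

    ``excluded_bins`` lists bins dropped for zero variance; they appear in
    neither ``bin_ids`` nor ``beta``.
    """

    chrom: str
    bin_ids: list[str]
    beta: np.ndarray
    n_samples: int
    excluded_bins: list[str] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.beta, index=self.bin_ids, columns=self.bin_ids).to_csv(
            path, sep="\t", float_format="%.10g"
        )


@dataclass
class NullScale:
    """Null-scale estimate: SD of cross-chromosome ancestry correlations."""

    sigma_hat: float
    n_pairs_used: int
    subsample_seed: int | None = None


def _standardize(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-standardize; returns (z, zero_variance_mask)."""
    mean = values.mean(axis=0)
    sd = values.std(axis=0)
    zero = sd == 0
    z = np.zeros_like(values, dtype=float)
    ok = ~zero
    z[:, ok] = (values[:, ok] - mean[ok]) / sd[ok]
    return z, zero


def within_chromosome_correlations(
    matrix: LocalAncestryMatrix, manifest: BinManifest
) -> dict[str, CorrelationMatrix]:
    """Pearson correlation over samples for every within-chromosome bin pair.

    Zero-variance bins are excluded (and reported on the result), never left
    as silent NaN.
    """
    matrix.check_manifest(manifest)
    if matrix.n_samples < 3:
        raise DataError("need >= 3 samples for correlations")
    out: dict[str, CorrelationMatrix] = {}
    for chrom in manifest.chroms:
        sub = manifest.for_chrom(chrom)
        ids = list(sub["bin_id"])
        if len(ids) < 2:
            raise DataError(f"chrom {chrom}: need >= 2 bins")
        values = matrix.dosage[ids].to_numpy(dtype=float)
        sd = values.std(axis=0)
        excluded = [b for b, z in zip(ids, sd == 0) if z]
        kept = [b for b in ids if b not in excluded]
        if len(kept) < 2:
            raise DataError(f"chrom {chrom}: fewer than 2 variable bins")
        beta = np.corrcoef(matrix.dosage[kept].to_numpy(dtype=float), rowvar=False)
        np.fill_diagonal(beta, 1.0)
        out[chrom] = CorrelationMatrix(
            chrom=str(chrom),
            bin_ids=kept,
            beta=beta,
            n_samples=matrix.n_samples,
            excluded_bins=excluded,
        )
    return out


def estimate_null_scale(
    matrix: LocalAncestryMatrix,
    manifest: BinManifest,
    max_pairs: int = 2_000_000,
    seed: int = 0,
) -> NullScale:
    """Sample SD of correlations over all cross-chromosome bin pairs.

    If the number of cross-chromosome pairs exceeds ``max_pairs``, a seeded
    uniform subsample of pairs is used and recorded on the result.
    """
    matrix.check_manifest(manifest)
    chroms = manifest.chroms
    if len(chroms) < 2:
        raise DataError("null scale requires >= 2 chromosomes")
    values = matrix.dosage.to_numpy(dtype=float)
    z, zero = _standardize(values)
    chrom_of = manifest.table["chrom"].astype(str).to_numpy()
    n = matrix.n_samples

    correlations: list[np.ndarray] = []
    for a in range(len(chroms)):
        cols_a = np.flatnonzero((chrom_of == chroms[a]) & ~zero)
        for b in range(a + 1, len(chroms)):
            cols_b = np.flatnonzero((chrom_of == chroms[b]) & ~zero)
            if not len(cols_a) or not len(cols_b):
                continue
            block = z[:, cols_a].T @ z[:, cols_b] / n
            correlations.append(block.ravel())
    if not correlations:
        raise DataError("no usable cross-chromosome pairs")
    pooled = np.concatenate(correlations)
    subsample_seed = None
    if pooled.size > max_pairs:
        subsample_seed = seed
        rng = np.random.default_rng(seed)
        pooled = pooled[rng.choice(pooled.size, size=max_pairs, replace=False)]
    if pooled.size < 2:
        raise DataError("need >= 2 cross-chromosome pairs")
    sigma = float(np.std(pooled, ddof=1))
    if sigma == 0.0:
        raise NumericalError("cross-chromosome correlations are constant; null scale is 0")
    return NullScale(sigma_hat=sigma, n_pairs_used=int(pooled.size), subsample_seed=subsample_seed)
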