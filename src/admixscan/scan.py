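"""Z-test of residual ancestry correlations, multiple-testing correction via
the effective number of independent tests, distance filtering and merging of
significant bin pairs into region pairs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .correlation import CorrelationMatrix, NullScale
from .decay import ResidualMatrix
from .errors import DataError, NumericalError
from .io import BinManifest, ExclusionAnnotation

P_FLOOR = 1e-300  # keep p in (0, 1] under extreme Z

SCAN_COLUMNS = [
    "chrom",
    "bin_i",
    "bin_j",
    "mid_bp_i",
    "mid_bp_j",
    "d_cM",
    "beta",
    "beta_res",
    "z",
    "p",
    "passes_distance_filter",
    "significant",
]


@dataclass
class EffectiveTestCount:
    """Per-chromosome effective bin counts and the corrected alpha."""

    k_per_chrom: dict[str, int]
    total_tests: int
    alpha_corrected: float


@dataclass
class RegionPair:
    """A merged pair of genomic regions supported by significant bin pairs."""

    chrom: str
    region1_start_bp: int
    region1_end_bp: int
    region2_start_bp: int
    region2_end_bp: int
    n_pairs: int
    min_p: float
    telomere_adjacent: bool = False


def z_test(
    residuals: ResidualMatrix, scale: NullScale, manifest: BinManifest
) -> pd.DataFrame:
    """Two-sided normal test of each valid residual against the null scale.

    Z = beta_res / sigma_hat; P = 2 * (1 - Phi(|Z|)).  Returns one row per
    unordered valid bin pair (i < j in manifest order).
    """
    if scale.sigma_hat <= 0:
        raise NumericalError("sigma_hat must be positive")
    sub = manifest.for_chrom(residuals.chrom).set_index("bin_id")
    cm = sub["mid_cM"].reindex(residuals.bin_ids).to_numpy(dtype=float)
    bp = sub["mid_bp"].reindex(residuals.bin_ids).to_numpy()
    m = len(residuals.bin_ids)
    iu, ju = np.triu_indices(m, k=1)
    valid = residuals.valid[iu, ju]
    iu, ju = iu[valid], ju[valid]
    beta_res = residuals.beta_res[iu, ju]
    z = beta_res / scale.sigma_hat
    p = np.maximum(2.0 * norm.sf(np.abs(z)), P_FLOOR)
    ids = np.asarray(residuals.bin_ids)
    # beta reconstructed from residual + prediction is not stored here; the
    # caller merges it in from the correlation matrix (see attach_beta).
    return pd.DataFrame(
        {
            "chrom": residuals.chrom,
            "bin_i": ids[iu],
            "bin_j": ids[ju],
            "mid_bp_i": bp[iu],
            "mid_bp_j": bp[ju],
            "d_cM": np.abs(cm[ju] - cm[iu]),
            "beta": np.nan,
            "beta_res": beta_res,
            "z": z,
            "p": p,
            "passes_distance_filter": False,
            "significant": False,
        }
    )


def attach_beta(results: pd.DataFrame, corr: CorrelationMatrix) -> pd.DataFrame:
    """Fill the observed-correlation column from the correlation matrix."""
    index = {b: i for i, b in enumerate(corr.bin_ids)}
    ii = results["bin_i"].map(index).to_numpy()
    jj = results["bin_j"].map(index).to_numpy()
    results = results.copy()
    results["beta"] = corr.beta[ii, jj]
    return results


def effective_bins(corr: CorrelationMatrix | np.ndarray) -> int:
    """Effective number of independent bins from the correlation eigenvalues.

    Li & Ji's estimator: each eigenvalue contributes
    I(lambda >= 1) + (lambda - floor(lambda)); the sum is floored to an
    integer.  Identity -> M; all-ones -> 1.
    """
    beta = corr.beta if isinstance(corr, CorrelationMatrix) else np.asarray(corr, dtype=float)
    if beta.ndim != 2 or beta.shape[0] != beta.shape[1]:
        raise DataError("correlation matrix must be square")
    if not np.allclose(beta, beta.T, atol=1e-8):
        raise DataError("correlation matrix must be symmetric")
    lam = np.clip(np.linalg.eigvalsh((beta + beta.T) / 2.0), 0.0, None)
    # snap eigenvalues numerically adjacent to an integer: the fractional
    # term lambda - floor(lambda) is discontinuous there and a 6 - 1e-15
    # eigenvalue must count as 6, not as 5 + (1 - eps)
    near = np.round(lam)
    lam = np.where(np.abs(lam - near) < 1e-9 * max(beta.shape[0], 1), near, lam)
    contrib = (lam >= 1.0).astype(float) + (lam - np.floor(lam))
    k = int(np.floor(contrib.sum() + 1e-9))
    return max(k, 1)


def total_independent_tests(k_per_chrom: dict[str, int] | list[int]) -> int:
    """Sum over chromosomes of k_i * (k_i - 1) / 2 within-chromosome pairs."""
    ks = list(k_per_chrom.values()) if isinstance(k_per_chrom, dict) else list(k_per_chrom)
    if any(k < 1 for k in ks):
        raise DataError("all k_i must be >= 1")
    return int(sum(k * (k - 1) // 2 for k in ks))


def bonferroni_threshold(n_independent: int, alpha: float = 0.05) -> float:
    """Bonferroni-corrected significance level alpha / n_independent."""
    if n_independent < 1:
        raise DataError("n_independent must be >= 1")
    return alpha / n_independent


def distance_filter(results: pd.DataFrame, min_cM: float = 50.0) -> pd.DataFrame:
    """Flag pairs at genetic distance >= min_cM; closer pairs are retained
    for audit but excluded from significance declaration."""
    out = results.copy()
    out["passes_distance_filter"] = out["d_cM"].to_numpy() >= min_cM
    return out


def annotate_significance(results: pd.DataFrame, alpha_corrected: float) -> pd.DataFrame:
    """Mark pairs significant when they pass the distance filter and
    p < alpha_corrected."""
    out = results.copy()
    out["significant"] = out["passes_distance_filter"] & (out["p"] < alpha_corrected)
    return out


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def merge_region_pairs(
    significant: pd.DataFrame,
    manifest: BinManifest,
    gap_bins: int = 1,
    exclusions: ExclusionAnnotation | None = None,
    telomere_radius_bp: int = 2_000_000,
) -> list[RegionPair]:
    """Merge significant bin pairs into region pairs by connected components.

    Pairs are oriented (i < j in manifest bin order); two pairs connect when
    both endpoints are within ``gap_bins`` bins of each other.  Each
    component's bounding bp intervals form the RegionPair.  Components whose
    regions fall within ``telomere_radius_bp`` of an annotated interval are
    flagged, not dropped.
    """
    if significant.empty:
        return []
    chroms = significant["chrom"].astype(str).unique()
    if len(chroms) != 1:
        raise DataError("merge_region_pairs expects pairs from a single chromosome")
    chrom = chroms[0]
    sub = manifest.for_chrom(chrom)
    order = {b: i for i, b in enumerate(sub["bin_id"])}
    start_bp = sub["start_bp"].to_numpy()
    end_bp = sub["end_bp"].to_numpy()

    ii = significant["bin_i"].map(order).to_numpy()
    jj = significant["bin_j"].map(order).to_numpy()
    lo = np.minimum(ii, jj)
    hi = np.maximum(ii, jj)
    pvals = significant["p"].to_numpy()

    n = len(lo)
    uf = _UnionFind(n)
    for a in range(n):
        near = (np.abs(lo - lo[a]) <= gap_bins) & (np.abs(hi - hi[a]) <= gap_bins)
        for b in np.flatnonzero(near):
            uf.union(a, int(b))
    roots = np.array([uf.find(a) for a in range(n)])

    regions: list[RegionPair] = []
    for root in np.unique(roots):
        members = roots == root
        r1_lo, r1_hi = int(lo[members].min()), int(lo[members].max())
        r2_lo, r2_hi = int(hi[members].min()), int(hi[members].max())
        pair = RegionPair(
            chrom=chrom,
            region1_start_bp=int(start_bp[r1_lo]),
            region1_end_bp=int(end_bp[r1_hi]),
            region2_start_bp=int(start_bp[r2_lo]),
            region2_end_bp=int(end_bp[r2_hi]),
            n_pairs=int(members.sum()),
            min_p=float(pvals[members].min()),
        )
        if exclusions is not None:
            pair.telomere_adjacent = _near_exclusion(pair, exclusions, telomere_radius_bp)
        regions.append(pair)
    regions.sort(key=lambda r: (r.region1_start_bp, r.region2_start_bp))
    return regions


def _near_exclusion(
    pair: RegionPair, exclusions: ExclusionAnnotation, radius_bp: int
) -> bool:
    iv = exclusions.for_chrom(pair.chrom)
    for _, row in iv.iterrows():
        lo, hi = row["start_bp"] - radius_bp, row["end_bp"] + radius_bp
        for s, e in (
            (pair.region1_start_bp, pair.region1_end_bp),
            (pair.region2_start_bp, pair.region2_end_bp),
        ):
            if s <= hi and e >= lo:
                return True
    return False


def region_pairs_table(regions: list[RegionPair]) -> pd.DataFrame:
    """Region pairs as a table with Mb coordinates for reporting."""
    rows = [
        {
            "chrom": r.chrom,
            "region1_start_Mb": r.region1_start_bp / 1e6,
            "region1_end_Mb": r.region1_end_bp / 1e6,
            "region2_start_Mb": r.region2_start_bp / 1e6,
            "region2_end_Mb": r.region2_end_bp / 1e6,
            "n_pairs": r.n_pairs,
            "min_p": r.min_p,
            "telomere_adjacent": r.telomere_adjacent,
        }
        for r in regions
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "region1_start_Mb",
            "region1_end_Mb",
            "region2_start_Mb",
            "region2_end_Mb",
            "n_pairs",
            "min_p",
            "telomere_adjacent",
        ],
    )


def heatmap_matrix(
    results: pd.DataFrame, manifest: BinManifest, cap: float = 6.0
) -> pd.DataFrame:
    """-log10(p) matrix for one chromosome, capped for plotting."""
    chroms = results["chrom"].astype(str).unique()
    if len(chroms) != 1:
        raise DataError("heatmap_matrix expects one chromosome")
    ids = [
        b
        for b in manifest.for_chrom(chroms[0])["bin_id"]
        if b in set(results["bin_i"]) | set(results["bin_j"])
    ]
    index = {b: i for i, b in enumerate(ids)}
    mat = np.zeros((len(ids), len(ids)))
    ii = results["bin_i"].map(index).to_numpy()
    jj = results["bin_j"].map(index).to_numpy()
    vals = np.minimum(-np.log10(results["p"].to_numpy()), cap)
    mat[ii, jj] = vals
    mat[jj, ii] = vals
    return pd.DataFrame(mat, index=ids, columns=ids)
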