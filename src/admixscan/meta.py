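"""Cross-cohort combination of scan results and calibration diagnostics.

Per-pair Z-scores are combined with the sample-size-weighted Z method
(as in METAL): z_meta = sum(sqrt(n_k) z_k) / sqrt(sum n_k).  Heterogeneity is
quantified with Cochran's Q on the residual-correlation scale with variance
sigma_hat_k^2 per cohort.  Diagnostics: genomic-control lambda, per-cohort
residual skewness, and pairwise cohort Z correlations.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import chi2, norm, skew

from .errors import DataError, NumericalError
from .scan import P_FLOOR

CHI2_1_MEDIAN = float(chi2.ppf(0.5, 1))  # 0.4549364...

PAIR_KEY = ["chrom", "bin_i", "bin_j"]


def weighted_z_meta(z_by_cohort, n_by_cohort) -> tuple[np.ndarray, np.ndarray]:
    """Sample-size-weighted Z combination with two-sided normal p-values.

    ``z_by_cohort``: array (K,) or (K, P) of Z-scores; ``n_by_cohort``:
    length-K sample sizes.  Returns (z_meta, p_meta) with shapes (P,) or
    scalars for 1-D input.
    """
    z = np.asarray(z_by_cohort, dtype=float)
    if z.ndim == 1:
        z = z[:, None]
    n = np.asarray(n_by_cohort, dtype=float)
    if z.shape[0] != n.shape[0]:
        raise DataError("z and n cohort counts differ")
    if np.any(n <= 0):
        raise DataError("sample sizes must be positive")
    w = np.sqrt(n)
    z_meta = (w[:, None] * z).sum(axis=0) / np.sqrt(n.sum())
    p_meta = np.maximum(2.0 * norm.sf(np.abs(z_meta)), P_FLOOR)
    if np.ndim(z_by_cohort) == 1:
        return float(z_meta[0]), float(p_meta[0])
    return z_meta, p_meta


def cochran_q(effects, variances) -> tuple[np.ndarray, np.ndarray]:
    """Cochran's Q heterogeneity test across K >= 2 cohorts.

    ``effects``: (K,) or (K, P) residual correlations; ``variances``:
    length-K sigma_hat^2.  Q = sum_k (b_k - b_bar)^2 / v_k with the
    inverse-variance weighted mean b_bar; p from chi-square with K-1 df.
    """
    b = np.asarray(effects, dtype=float)
    if b.ndim == 1:
        b = b[:, None]
    v = np.asarray(variances, dtype=float)
    K = b.shape[0]
    if K < 2:
        raise DataError("Cochran's Q requires >= 2 cohorts")
    if np.any(v <= 0):
        raise NumericalError("cohort variances must be positive")
    w = 1.0 / v
    b_bar = (w[:, None] * b).sum(axis=0) / w.sum()
    q = ((b - b_bar) ** 2 * w[:, None]).sum(axis=0)
    p = chi2.sf(q, df=K - 1)
    if np.ndim(effects) == 1:
        return float(q[0]), float(p[0])
    return q, p


def genomic_control_lambda(z_values) -> float:
    """lambda_GC = median(Z^2) / median of chi-square_1 (0.4549...)."""
    z = np.asarray(z_values, dtype=float)
    if z.size < 1:
        raise DataError("need >= 1 Z value")
    return float(np.median(z**2) / CHI2_1_MEDIAN)


def residual_skewness(residuals) -> float:
    """Adjusted Fisher-Pearson sample skewness of the residual distribution."""
    x = np.asarray(residuals, dtype=float)
    if x.size < 3:
        raise DataError("need >= 3 values for skewness")
    if np.std(x) == 0:
        raise NumericalError("zero variance: skewness undefined")
    return float(skew(x, bias=False))


def cohort_z_correlation(z_by_label: dict[str, pd.Series | np.ndarray]) -> pd.DataFrame:
    """Pearson correlation of aligned Z vectors for every cohort pair."""
    labels = list(z_by_label)
    if len(labels) < 2:
        raise DataError("need >= 2 cohorts")
    mat = np.column_stack([np.asarray(z_by_label[l], dtype=float) for l in labels])
    if mat.shape[0] < 2:
        raise DataError("need >= 2 shared pairs")
    corr = np.corrcoef(mat, rowvar=False)
    return pd.DataFrame(corr, index=labels, columns=labels)


def combine_scans(
    scans: dict[str, pd.DataFrame],
    n_by_label: dict[str, int],
    sigma_by_label: dict[str, float],
) -> tuple[pd.DataFrame, dict]:
    """Meta-analyze per-pair scan tables sharing an identical bin grid.

    Returns the meta table (pair keys + z_meta, p_meta, q, q_p, d_cM, flags)
    and a diagnostics dict (lambda_gc, skewness and sigma per cohort,
    pairwise cohort Z correlations).  Pairs absent from any cohort are
    skipped.
    """
    labels = list(scans)
    if not labels:
        raise DataError("no cohorts supplied")
    base = scans[labels[0]][PAIR_KEY + ["d_cM", "mid_bp_i", "mid_bp_j", "passes_distance_filter"]]
    merged = base.copy()
    for label in labels:
        sub = scans[label][PAIR_KEY + ["z", "beta_res"]].rename(
            columns={"z": f"z_{label}", "beta_res": f"b_{label}"}
        )
        merged = merged.merge(sub, on=PAIR_KEY, how="inner")
    if merged.empty:
        raise DataError("no pairs shared across all cohorts")

    z_mat = np.vstack([merged[f"z_{l}"].to_numpy() for l in labels])
    n = np.array([n_by_label[l] for l in labels], dtype=float)
    z_meta, p_meta = weighted_z_meta(z_mat, n)
    out = merged[PAIR_KEY + ["mid_bp_i", "mid_bp_j", "d_cM", "passes_distance_filter"]].copy()
    out["z_meta"] = z_meta
    out["p_meta"] = p_meta
    if len(labels) >= 2:
        b_mat = np.vstack([merged[f"b_{l}"].to_numpy() for l in labels])
        v = np.array([sigma_by_label[l] ** 2 for l in labels])
        q, q_p = cochran_q(b_mat, v)
        out["q_statistic"] = q
        out["q_pvalue"] = q_p
        cohort_corr = cohort_z_correlation(
            {l: merged[f"z_{l}"].to_numpy() for l in labels}
        )
    else:
        out["q_statistic"] = np.nan
        out["q_pvalue"] = np.nan
        cohort_corr = None

    diagnostics = {
        "lambda_gc": genomic_control_lambda(z_meta),
        "skewness": {l: residual_skewness(merged[f"b_{l}"].to_numpy()) for l in labels},
        "sigma_hat": dict(sigma_by_label),
        "cohort_z_correlation": None
        if cohort_corr is None
        else cohort_corr.to_dict(),
        "n_pairs": int(len(out)),
    }
    return out, diagnostics


def qq_data(p_values) -> pd.DataFrame:
    """Expected vs observed -log10(p) for QQ plotting (export as TSV)."""
    p = np.sort(np.asarray(p_values, dtype=float))
    n = p.size
    expected = -np.log10((np.arange(1, n + 1) - 0.5) / n)
    return pd.DataFrame({"expected": expected, "observed": -np.log10(p)})
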