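"""Per-locus exponential admixture-LD decay fit and residual correlations.

For each locus i, the observed ancestry correlations beta_ij against all
other loci j on the same chromosome are fit with

    f(d) = a0 + a1 * exp(-a2 * d),

d in cM, by nonlinear least squares with a1, a2 >= 0.  a0 captures the
background correlation between effectively unlinked loci; a1 * exp(-a2 * d)
is the admixture-LD decay itself, whose rate a2 approximates t/100 per cM for
a population admixed t generations ago.  The residual (beta - f(d)) computed
from each endpoint's own fit is averaged over the two directions to give the
final per-pair departure from the null decay.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .correlation import CorrelationMatrix
from .errors import DataError
from .io import BinManifest

MAX_NFEV = 500
FTOL = 1e-10


@dataclass
class DecayFit:
    """Fitted decay-curve parameters for one locus."""

    locus: str
    a0: float
    a1: float
    a2: float
    sse: float
    converged: bool
    n_points: int


@dataclass
class ResidualMatrix:
    """Direction-averaged residual correlations for one chromosome.

    ``per_direction[i, j]`` is beta[i, j] - f_i(d_ij) using locus i's fit;
    ``beta_res`` is the symmetric average of the two directions; ``valid``
    masks pairs where both endpoint fits converged.
    """

    chrom: str
    bin_ids: list[str]
    beta_res: np.ndarray
    per_direction: np.ndarray
    valid: np.ndarray


def _initial_guess(betas: np.ndarray, distances: np.ndarray) -> tuple[float, float, float]:
    """Deterministic start: background from the low quantile, decay slope from
    a log-linear regression of the positive excess on distance."""
    a0 = float(np.percentile(betas, 5))
    a1 = max(float(betas.max() - a0), 1e-6)
    excess = betas - a0
    usable = excess > 1e-8
    if usable.sum() >= 2 and len(np.unique(distances[usable])) >= 2:
        slope = np.polyfit(distances[usable], np.log(excess[usable]), 1)[0]
        a2 = max(-float(slope), 1e-6)
    else:
        a2 = 0.01
    return a0, a1, a2


def fit_locus_decay(locus: str, betas: np.ndarray, distances: np.ndarray) -> DecayFit:
    """Least-squares fit of f(d) = a0 + a1*exp(-a2*d) to one locus's correlations.

    Requires >= 10 points with >= 3 distinct distances.  Non-convergence is
    flagged on the result, not raised.
    """
    betas = np.asarray(betas, dtype=float)
    distances = np.asarray(distances, dtype=float)
    if betas.shape != distances.shape:
        raise DataError("betas and distances must have equal length")
    if len(betas) < 4:
        raise DataError("fewer points than parameters")
    if len(betas) < 10 or len(np.unique(distances)) < 3:
        raise DataError("need >= 10 points with >= 3 distinct distances")

    # f(d) is itself a correlation, so the background and amplitude are
    # bounded by the correlation scale; this also removes the degenerate
    # near-linear valley a0 -> -inf, a1 -> +inf, a2 -> 0
    lower = np.array([-1.0, 0.0, 0.0])
    upper = np.array([1.0, 2.0, np.inf])
    x0 = np.clip(np.array(_initial_guess(betas, distances)), lower, upper)

    def resid(a):
        return a[0] + a[1] * np.exp(-a[2] * distances) - betas

    def jac(a):
        e = np.exp(-a[2] * distances)
        return np.column_stack([np.ones_like(distances), e, -a[1] * distances * e])

    sol = least_squares(
        resid,
        x0,
        jac=jac,
        bounds=(lower, upper),
        ftol=FTOL,
        xtol=1e-12,
        max_nfev=MAX_NFEV,
    )
    a0, a1, a2 = sol.x
    return DecayFit(
        locus=locus,
        a0=float(a0),
        a1=float(a1),
        a2=float(a2),
        sse=float(np.sum(sol.fun**2)),
        converged=bool(sol.success),
        n_points=len(betas),
    )


def predict_null_ld(fit: DecayFit, d) -> np.ndarray | float:
    """Predicted admixture LD under no epistasis: a0 + a1*exp(-a2*d)."""
    d = np.asarray(d, dtype=float)
    value = fit.a0 + fit.a1 * np.exp(-fit.a2 * d)
    return float(value) if value.ndim == 0 else value


def fit_all_loci(corr: CorrelationMatrix, manifest: BinManifest) -> dict[str, DecayFit]:
    """Fit the decay curve at every retained locus of one chromosome.

    Every j != i on the retained-bin set enters each locus fit, including
    pairs that a later distance filter flags: the argmin runs over all pairs.
    """
    sub = manifest.for_chrom(corr.chrom)
    cm = sub.set_index("bin_id")["mid_cM"].reindex(corr.bin_ids).to_numpy(dtype=float)
    fits: dict[str, DecayFit] = {}
    m = len(corr.bin_ids)
    for i, locus in enumerate(corr.bin_ids):
        others = np.arange(m) != i
        fits[locus] = fit_locus_decay(
            locus, corr.beta[i, others], np.abs(cm[others] - cm[i])
        )
    return fits


def residual_correlations(
    corr: CorrelationMatrix, fits: dict[str, DecayFit], manifest: BinManifest
) -> ResidualMatrix:
    """Direction-averaged departures of beta from each endpoint's fitted curve.

    Pairs with a missing or non-converged endpoint fit are masked invalid.
    """
    sub = manifest.for_chrom(corr.chrom)
    cm = sub.set_index("bin_id")["mid_cM"].reindex(corr.bin_ids).to_numpy(dtype=float)
    m = len(corr.bin_ids)
    d = np.abs(cm[:, None] - cm[None, :])

    ok = np.array(
        [locus in fits and fits[locus].converged for locus in corr.bin_ids]
    )
    a0 = np.array([fits[l].a0 if l in fits else np.nan for l in corr.bin_ids])
    a1 = np.array([fits[l].a1 if l in fits else np.nan for l in corr.bin_ids])
    a2 = np.array([fits[l].a2 if l in fits else np.nan for l in corr.bin_ids])

    # per_direction[i, j]: residual of pair (i, j) under locus i's fit
    predicted = a0[:, None] + a1[:, None] * np.exp(-a2[:, None] * d)
    per_direction = corr.beta - predicted
    beta_res = (per_direction + per_direction.T) / 2.0
    valid = ok[:, None] & ok[None, :]
    np.fill_diagonal(valid, False)
    beta_res = np.where(valid, beta_res, np.nan)
    np.fill_diagonal(beta_res, 0.0)
    return ResidualMatrix(
        chrom=corr.chrom,
        bin_ids=list(corr.bin_ids),
        beta_res=beta_res,
        per_direction=per_direction,
        valid=valid,
    )
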