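"""Shared fixtures: small simulated cohorts for unit tests and the large
session-scoped simulation studies consumed by the acceptance tests.

Study conditions follow the package's synthetic defaults: cohorts of 2000
diploids admixed 8 generations ago with African fraction 0.8, a scanned
2-Morgan / 80-Mb chromosome in 400-kb bins, and an auxiliary 1-Morgan /
40-Mb chromosome that supplies cross-chromosome pairs for the null scale.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pytest

from admixscan import (
    estimate_null_scale,
    fit_all_loci,
    fit_locus_decay,
    residual_correlations,
    scan_cohort,
    within_chromosome_correlations,
    z_test,
)
from admixscan.crossover import count_ancestry_switches, deficit_test
from admixscan.meta import genomic_control_lambda
from admixscan.simulate import EpistasisConfig, SimulationConfig, simulate_population

# scanned chromosome: 2 Morgans / 80 Mb; auxiliary chromosome for sigma_hat
STUDY_CHROMS = ((2.0, 80_000_000), (1.0, 40_000_000))
STUDY_N = 2000
STUDY_T = 8
STUDY_M = 0.8
EPI_LOCI_CM = (70.0, 130.0)  # d = 60 cM, beyond the 50-cM filter
S_LARGE = 2.0

N_NULL_REPLICATES = 200
N_POWER_SEEDS = 50
POWER_S_GRID = (0.0, 0.05, 0.1, 0.2)
N_E2E_SEEDS = 20


def oracle_switch_events(tracts, chrom_idx: int, mids_cM: np.ndarray) -> np.ndarray:
    """Per-individual ancestry-switch counts recomputed from ground-truth
    tracts at bin midpoints, independently of the simulator's dosage path
    (np.digitize over tract ends instead of the library's searchsorted)."""
    n = tracts.n_individuals
    events = np.zeros(n)
    for i in range(n):
        dosage = np.zeros(len(mids_cM), dtype=int)
        for h in (2 * i, 2 * i + 1):
            ends, anc = tracts.haplotypes[chrom_idx][h]
            idx = np.digitize(mids_cM, np.asarray(ends), right=False)
            idx = np.minimum(idx, len(ends) - 1)
            dosage += np.asarray(anc, dtype=int)[idx]
        events[i] = np.abs(np.diff(dosage)).sum()
    return events


@pytest.fixture(scope="session")
def small_null_sim():
    """A small null cohort reused across unit tests (n=300, t=6, two chroms)."""
    cfg = SimulationConfig(
        n_individuals=300,
        t_generations=6,
        m_admixture=0.8,
        chromosomes=((1.0, 20_000_000), (1.0, 20_000_000)),
        seed=42,
    )
    return simulate_population(cfg), cfg


@pytest.fixture(scope="session")
def study_null_sim():
    """One full-size null cohort for moderately heavy unit checks."""
    cfg = SimulationConfig(
        n_individuals=STUDY_N,
        t_generations=STUDY_T,
        m_admixture=STUDY_M,
        chromosomes=STUDY_CHROMS,
        seed=7,
    )
    return simulate_population(cfg), cfg


@dataclass
class NullStudy:
    """Streamed summaries of the 200-replicate null simulation study."""

    n_replicates: int = 0
    n_pairs: int = 0
    n_rejected: int = 0
    z_pooled: list = field(default_factory=list)
    a2_values: list = field(default_factory=list)
    switch_equal: list = field(default_factory=list)
    deficit_p: list = field(default_factory=list)
    region_pair_counts: list = field(default_factory=list)
    switch_rates: list = field(default_factory=list)  # per Morgan, chr1

    @property
    def rejection_rate(self) -> float:
        return self.n_rejected / self.n_pairs

    @property
    def lambda_gc(self) -> float:
        return genomic_control_lambda(np.concatenate(self.z_pooled))


def run_null_replicate(seed: int, study: NullStudy) -> None:
    cfg = SimulationConfig(
        n_individuals=STUDY_N,
        t_generations=STUDY_T,
        m_admixture=STUDY_M,
        chromosomes=STUDY_CHROMS,
        seed=seed,
    )
    matrix, manifest, tracts = simulate_population(cfg)

    # ancestry-switch consistency: dosage-difference counts vs tract truth
    sub = manifest.for_chrom("1")
    mids = sub["mid_cM"].to_numpy(dtype=float)
    stats = count_ancestry_switches(
        matrix, manifest, ("1", int(sub["start_bp"].iloc[0]), int(sub["end_bp"].iloc[-1]))
    )
    oracle = oracle_switch_events(tracts, 0, mids)
    study.switch_equal.append(bool(np.array_equal(stats.events, oracle)))
    study.switch_rates.append(tracts.switch_counts(0).mean() / 2.0)

    correlations = within_chromosome_correlations(matrix, manifest)
    scale = estimate_null_scale(matrix, manifest, seed=seed)
    corr = correlations["1"]
    fits = fit_all_loci(corr, manifest)
    res = residual_correlations(corr, fits, manifest)
    table = z_test(res, scale, manifest)

    study.n_replicates += 1
    study.n_pairs += len(table)
    study.n_rejected += int((table["p"] < 0.05).sum())
    study.z_pooled.append(table["z"].to_numpy())
    study.a2_values.extend(f.a2 for f in fits.values() if f.converged)

    # crossover-deficit calibration: arbitrary 20-cM interval with bounds on
    # bin midpoints, matching the reference-window semantics
    target = count_ancestry_switches(matrix, manifest, ("1", 15_800_000, 23_800_000))
    _, p, _ = deficit_test(target, matrix, manifest)
    study.deficit_p.append(p)

    # corrected-alpha region pairs for the first 20 replicates (null scan)
    if len(study.region_pair_counts) < 20:
        from admixscan.scan import (
            annotate_significance,
            bonferroni_threshold,
            distance_filter,
            effective_bins,
            merge_region_pairs,
            total_independent_tests,
        )

        k = effective_bins(corr)
        alpha_c = bonferroni_threshold(total_independent_tests([k]))
        flagged = annotate_significance(distance_filter(table), alpha_c)
        regions = merge_region_pairs(
            flagged[flagged["significant"]], manifest
        )
        study.region_pair_counts.append(len(regions))


@pytest.fixture(scope="session")
def null_study() -> NullStudy:
    study = NullStudy()
    for r in range(N_NULL_REPLICATES):
        run_null_replicate(20_000 + r, study)
    return study


def injected_pair_pvalue(seed: int, s: float) -> float:
    """Uncorrected two-sided p at the injected locus pair for one replicate."""
    epi = EpistasisConfig("1", EPI_LOCI_CM[0], EPI_LOCI_CM[1], s) if s > 0 else None
    cfg = SimulationConfig(
        n_individuals=STUDY_N,
        t_generations=STUDY_T,
        m_admixture=STUDY_M,
        chromosomes=STUDY_CHROMS,
        epistasis=epi,
        seed=seed,
    )
    matrix, manifest, _ = simulate_population(cfg)
    correlations = within_chromosome_correlations(matrix, manifest)
    scale = estimate_null_scale(matrix, manifest, seed=seed)
    corr = correlations["1"]
    sub = manifest.for_chrom("1").set_index("bin_id")
    cm = sub["mid_cM"].reindex(corr.bin_ids).to_numpy(dtype=float)
    idx_i = int(np.argmin(np.abs(cm - EPI_LOCI_CM[0])))
    idx_j = int(np.argmin(np.abs(cm - EPI_LOCI_CM[1])))

    residual = 0.0
    for a, b in ((idx_i, idx_j), (idx_j, idx_i)):
        others = np.arange(len(cm)) != a
        fit = fit_locus_decay(
            corr.bin_ids[a], corr.beta[a, others], np.abs(cm[others] - cm[a])
        )
        d_ab = abs(cm[b] - cm[a])
        residual += corr.beta[a, b] - (fit.a0 + fit.a1 * np.exp(-fit.a2 * d_ab))
    residual /= 2.0
    z = residual / scale.sigma_hat
    from scipy.stats import norm

    return float(2.0 * norm.sf(abs(z)))


@pytest.fixture(scope="session")
def power_study() -> dict[float, float]:
    """Rejection rate at the injected pair per selection coefficient."""
    rates = {}
    for s in POWER_S_GRID:
        hits = sum(
            injected_pair_pvalue(40_000 + r, s) < 0.05 for r in range(N_POWER_SEEDS)
        )
        rates[s] = hits / N_POWER_SEEDS
    return rates


@pytest.fixture(scope="session")
def e2e_study():
    """Full scans of 20 strongly epistatic cohorts (s = 2, d = 60 cM)."""
    outputs = []
    for r in range(N_E2E_SEEDS):
        epi = EpistasisConfig("1", EPI_LOCI_CM[0], EPI_LOCI_CM[1], S_LARGE)
        cfg = SimulationConfig(
            n_individuals=STUDY_N,
            t_generations=STUDY_T,
            m_admixture=STUDY_M,
            chromosomes=STUDY_CHROMS,
            epistasis=epi,
            seed=60_000 + r,
        )
        matrix, manifest, _ = simulate_population(cfg)
        out = scan_cohort(matrix, manifest, seed=60_000 + r, scan_chroms=["1"])
        outputs.append((out, manifest))
    return outputs
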