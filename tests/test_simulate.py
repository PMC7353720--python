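"""Simulator behaviour: fixation cases, tract invariants, determinism,
admixture-LD decay against closed-form expectations, and the selection knob.
"""
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from admixscan.errors import ConfigError
from admixscan.simulate import (
    EpistasisConfig,
    SimulationConfig,
    expected_null_correlation,
    simulate_population,
)


def haldane_null_correlation(t: int, d_cM: float) -> float:
    """Ancestry correlation under Haldane crossovers: (1 - r)^t with
    recombination fraction r = (1 - exp(-2 d_M)) / 2.  Independent oracle for
    the simulated decay (the exponential form approximates this at small d)."""
    r = 0.5 * (1.0 - np.exp(-2.0 * d_cM / 100.0))
    return (1.0 - r) ** t


class TestExpectedNullCorrelation:
    @pytest.mark.parametrize(
        "t,d,expected",
        [
            (5, 0.0, 1.0),  # zero distance
            (0, 37.5, 1.0),  # no decay before any recombination
            (8, 10.0, 0.9**8),  # 0.43046721, direct arithmetic
            (3, 150.0, 0.0),  # beyond 1 Morgan the (1-d) form floors at 0
        ],
    )
    def test_values(self, t, d, expected):
        assert expected_null_correlation(t, d) == pytest.approx(expected, abs=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ConfigError):
            expected_null_correlation(-1, 10.0)
        with pytest.raises(ConfigError):
            expected_null_correlation(2, -0.5)


class TestDegenerateCases:
    def test_full_african_founding_fixes_dosage(self):
        cfg = SimulationConfig(50, 5, 1.0, ((1.0, 10_000_000),), seed=1)
        matrix, _, _ = simulate_population(cfg)
        assert (matrix.dosage.to_numpy() == 2).all()

    def test_no_generations_means_single_ancestry_haplotypes(self):
        cfg = SimulationConfig(80, 0, 0.6, ((1.5, 30_000_000),), seed=2)
        matrix, manifest, tracts = simulate_population(cfg)
        for ends, anc in tracts.haplotypes[0]:
            assert len(anc) == 1  # no post-admixture recombination
        # dosage constant along each individual's genome
        values = matrix.dosage.to_numpy()
        assert (values == values[:, [0]]).all()

    def test_config_errors(self):
        with pytest.raises(ConfigError):
            SimulationConfig(1, 5, 0.5, ((1.0, 10_000_000),)).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(
                10, 5, 0.5, ((1.0, 10_000_000),),
                epistasis=EpistasisConfig("1", 20.0, 150.0, 0.5),
            ).validate()
        with pytest.raises(ConfigError):
            SimulationConfig(
                10, 5, 0.5, ((1.0, 10_000_000),),
                epistasis=EpistasisConfig("2", 10.0, 50.0, 0.5),
            ).validate()


def test_identical_seed_and_config_reproduce_bitwise():
    cfg = SimulationConfig(40, 4, 0.7, ((1.0, 10_000_000), (0.5, 5_000_000)), seed=11)
    m1, man1, t1 = simulate_population(cfg)
    m2, man2, t2 = simulate_population(cfg)
    assert m1.dosage.equals(m2.dosage)
    assert man1.table.equals(man2.table)
    for c in range(2):
        for h1, h2 in zip(t1.haplotypes[c], t2.haplotypes[c]):
            assert h1 == h2


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    n=st.integers(2, 6),
    t=st.integers(0, 5),
    m=st.floats(0.0, 1.0),
    morgans=st.floats(0.2, 2.0),
    seed=st.integers(0, 10_000),
)
def test_tracts_tile_chromosome_and_alternate(n, t, m, morgans, seed):
    """Tracts always tile [0, L] without gaps/overlap and adjacent tracts
    differ in ancestry."""
    cfg = SimulationConfig(n, t, m, ((morgans, 10_000_000),), seed=seed)
    _, _, tracts = simulate_population(cfg)
    L = morgans * 100.0
    for ends, anc in tracts.haplotypes[0]:
        assert len(ends) == len(anc) >= 1
        assert ends[-1] == pytest.approx(L)
        assert all(a < b for a, b in zip(ends, ends[1:]))
        assert all(x != y for x, y in zip(anc, anc[1:]))
        assert all(a in (0, 1) for a in anc)


class TestStudyScaleExpectations:
    """Monte-Carlo checks on the full-size null cohort (n=2000, t=8, m=0.8)."""

    def test_mean_ancestry_matches_admixture_fraction(self, study_null_sim):
        (matrix, _, _), cfg = study_null_sim
        prop = matrix.ancestry_proportions().to_numpy()
        # founder proportion is Binomial(2n, m)/2n; individual proportions are
        # strongly correlated, so allow 3 SE of the founding draw
        se = np.sqrt(cfg.m_admixture * (1 - cfg.m_admixture) / (2 * cfg.n_individuals))
        assert abs(prop.mean() - cfg.m_admixture) < 6 * se

    def test_switch_rate_matches_thinned_poisson(self, study_null_sim):
        """Ancestry junctions accumulate at 2m(1-m)t per Morgan: crossovers
        (rate t per Morgan along a lineage) thinned by the probability the
        two homologous ancestries differ."""
        (_, _, tracts), cfg = study_null_sim
        m, t = cfg.m_admixture, cfg.t_generations
        expected = 2 * m * (1 - m) * t
        for c, (morgans, _) in enumerate(cfg.chromosomes):
            per_morgan = tracts.switch_counts(c) / morgans
            # haplotypes share founders, so the effective sample is far below
            # the haplotype count; a single cohort needs a wide MC band (the
            # multi-replicate study pins the rate tightly)
            assert abs(per_morgan.mean() - expected) < 0.12 * expected

    def test_binned_decay_matches_null_curve(self, study_null_sim):
        """Binned ancestry correlations follow the closed-form decay: the
        Haldane oracle everywhere, and the exponential approximation
        (1-d)^t at short range where it is accurate."""
        (matrix, manifest, _), cfg = study_null_sim
        sub = manifest.for_chrom("1")
        cm = sub["mid_cM"].to_numpy(dtype=float)
        values = matrix.dosage[list(sub["bin_id"])].to_numpy(dtype=float)
        beta = np.corrcoef(values, rowvar=False)
        iu, ju = np.triu_indices(len(cm), k=1)
        d = np.abs(cm[ju] - cm[iu])
        b = beta[iu, ju]
        edges = np.linspace(0.0, 150.0, 61)  # 60 distance bins
        for lo, hi in zip(edges[:-1], edges[1:]):
            mask = (d >= lo) & (d < hi)
            if mask.sum() < 10:
                continue
            mid = 0.5 * (lo + hi)
            observed = b[mask].mean()
            assert observed == pytest.approx(
                haldane_null_correlation(cfg.t_generations, mid), abs=0.03
            )
            # the (1-d)^t form approximates the Haldane curve only at short
            # range; beyond ~10 cM the approximation gap exceeds MC noise
            if mid <= 7.5:
                assert observed == pytest.approx(
                    expected_null_correlation(cfg.t_generations, mid), abs=0.04
                )

    def test_dosage_consistent_with_tracts(self, study_null_sim, request):
        """The reported dosage equals the tract ground truth at bin midpoints."""
        from conftest import oracle_switch_events

        (matrix, manifest, tracts), _ = study_null_sim
        sub = manifest.for_chrom("2")
        mids = sub["mid_cM"].to_numpy(dtype=float)
        dosage = matrix.dosage[list(sub["bin_id"])].to_numpy(dtype=int)
        events = np.abs(np.diff(dosage, axis=1)).sum(axis=1)
        assert np.array_equal(events, oracle_switch_events(tracts, 1, mids))


def test_selection_increases_correlation_at_target_pair():
    """With s > 0 the correlation at the selected pair exceeds the matched
    null correlation (one-sided MC at shared seeds)."""
    loci = (30.0, 70.0)
    diffs = []
    for seed in (101, 102, 103):
        corrs = {}
        for s in (0.0, 1.0):
            epi = EpistasisConfig("1", *loci, s) if s else None
            cfg = SimulationConfig(
                600, 6, 0.8, ((1.0, 20_000_000),), epistasis=epi, seed=seed
            )
            matrix, manifest, _ = simulate_population(cfg)
            sub = manifest.for_chrom("1")
            cm = sub["mid_cM"].to_numpy(dtype=float)
            i = int(np.argmin(np.abs(cm - loci[0])))
            j = int(np.argmin(np.abs(cm - loci[1])))
            x = matrix.dosage[sub["bin_id"].iloc[i]]
            y = matrix.dosage[sub["bin_id"].iloc[j]]
            corrs[s] = np.corrcoef(x, y)[0, 1]
        diffs.append(corrs[1.0] - corrs[0.0])
    assert np.mean(diffs) > 0.1
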