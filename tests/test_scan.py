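"""Z-test, effective independent tests, distance filter and region merging."""
import math

import numpy as np
import pandas as pd
import pytest

from admixscan.correlation import CorrelationMatrix, NullScale
from admixscan.decay import DecayFit, residual_correlations
from admixscan.errors import DataError, NumericalError
from admixscan.io import BinManifest
from admixscan.scan import (
    annotate_significance,
    bonferroni_threshold,
    distance_filter,
    effective_bins,
    heatmap_matrix,
    merge_region_pairs,
    total_independent_tests,
    z_test,
)


def grid_manifest(n_bins, chrom="1", cm_step=1.0):
    rows = [
        {"bin_id": f"{chrom}:b{k}", "chrom": chrom, "start_bp": 1 + k * 1000,
         "end_bp": 1000 + k * 1000, "mid_bp": 500 + k * 1000, "mid_cM": k * cm_step}
        for k in range(n_bins)
    ]
    return BinManifest(pd.DataFrame(rows))


def residuals_from_values(manifest, values):
    """Build a ResidualMatrix-like input via flat fits with a0=a1=0 so that
    beta_res equals the supplied correlation values exactly."""
    ids = manifest.bin_ids
    beta = np.array(values, dtype=float)
    corr = CorrelationMatrix("1", ids, beta, n_samples=500)
    fits = {b: DecayFit(b, 0.0, 0.0, 0.0, 0.0, True, 10) for b in ids}
    return residual_correlations(corr, fits, manifest)


class TestZTest:
    def test_null_point_and_quantile(self):
        manifest = grid_manifest(3)
        sigma = 0.02
        values = np.eye(3)
        values[0, 1] = values[1, 0] = 0.0
        values[0, 2] = values[2, 0] = 1.959964 * sigma
        values[1, 2] = values[2, 1] = -0.05
        table = z_test(residuals_from_values(manifest, values), NullScale(sigma, 10), manifest)
        row01 = table[(table.bin_i == "1:b0") & (table.bin_j == "1:b1")].iloc[0]
        assert row01.z == 0.0 and row01.p == 1.0
        row02 = table[(table.bin_i == "1:b0") & (table.bin_j == "1:b2")].iloc[0]
        assert row02.p == pytest.approx(0.05, abs=1e-6)

    def test_matches_independent_cdf_evaluation(self):
        """Arbitrary (beta_res, sigma) grid: p equals erfc(|z|/sqrt(2))."""
        manifest = grid_manifest(6)
        rng = np.random.default_rng(1)
        values = rng.normal(0, 0.03, (6, 6))
        values = (values + values.T) / 2
        np.fill_diagonal(values, 1.0)
        for sigma in (0.01, 0.025, 0.2):
            table = z_test(residuals_from_values(manifest, values), NullScale(sigma, 10), manifest)
            for _, row in table.iterrows():
                assert row.z == row.beta_res / sigma  # exact by construction
                assert row.p == pytest.approx(math.erfc(abs(row.z) / math.sqrt(2)), rel=1e-10)

    def test_zero_sigma_rejected(self):
        manifest = grid_manifest(3)
        res = residuals_from_values(manifest, np.eye(3))
        with pytest.raises(NumericalError):
            z_test(res, NullScale(0.0, 10), manifest)


class TestEffectiveBins:
    def test_identity_counts_all_bins(self):
        assert effective_bins(np.eye(17)) == 17

    def test_perfect_correlation_counts_one(self):
        assert effective_bins(np.ones((9, 9))) == 1

    def test_two_perfect_pairs_counts_two(self):
        # eigenvalues 2, 2, 0, 0 by hand
        m = np.array(
            [[1, 1, 0, 0], [1, 1, 0, 0], [0, 0, 1, 1], [0, 0, 1, 1]], dtype=float
        )
        assert effective_bins(m) == 2

    def test_non_symmetric_rejected(self):
        m = np.eye(3)
        m[0, 1] = 0.5
        with pytest.raises(DataError):
            effective_bins(m)

    def test_bounded_by_bin_count(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((60, 12))
        k = effective_bins(np.corrcoef(x, rowvar=False))
        assert 1 <= k <= 12


class TestTestCounts:
    @pytest.mark.parametrize("ks,expected", [([3], 3), ([2, 2], 2), ([1], 0)])
    def test_small_cases(self, ks, expected):
        assert total_independent_tests(ks) == expected

    def test_matches_pair_enumeration(self):
        rng = np.random.default_rng(4)
        ks = list(rng.integers(1, 40, size=10))
        brute = 0
        for k in ks:
            brute += sum(1 for a in range(k) for b in range(a + 1, k))
        assert total_independent_tests(ks) == brute

    @pytest.mark.parametrize("n,alpha,expected", [(1, 0.05, 0.05), (10, 0.05, 0.005)])
    def test_bonferroni(self, n, alpha, expected):
        assert bonferroni_threshold(n, alpha) == pytest.approx(expected)


class TestDistanceFilter:
    def test_strict_less_than_boundary(self):
        table = pd.DataFrame({"d_cM": [49.9, 50.0, 120.0]})
        out = distance_filter(table, 50.0)
        assert out.passes_distance_filter.tolist() == [False, True, True]

    def test_zero_threshold_is_identity(self):
        table = pd.DataFrame({"d_cM": [0.0, 1.0]})
        assert distance_filter(table, 0.0).passes_distance_filter.all()

    def test_significance_requires_both_conditions(self):
        table = pd.DataFrame(
            {"d_cM": [60.0, 10.0, 70.0], "p": [1e-9, 1e-9, 0.5]}
        )
        out = annotate_significance(distance_filter(table), 1e-6)
        assert out.significant.tolist() == [True, False, False]


def brute_force_components(lo, hi, gap):
    """Transitive closure over the pair-adjacency relation (independent of
    the union-find in the implementation)."""
    n = len(lo)
    adj = [
        [abs(lo[a] - lo[b]) <= gap and abs(hi[a] - hi[b]) <= gap for b in range(n)]
        for a in range(n)
    ]
    labels = list(range(n))
    changed = True
    while changed:
        changed = False
        for a in range(n):
            for b in range(n):
                if adj[a][b] and labels[b] != labels[a]:
                    tgt = min(labels[a], labels[b])
                    labels[a] = labels[b] = tgt
                    changed = True
    return labels


class TestMergeRegionPairs:
    def significant_table(self, manifest, pairs):
        ids = manifest.bin_ids
        return pd.DataFrame(
            {
                "chrom": "1",
                "bin_i": [ids[i] for i, _ in pairs],
                "bin_j": [ids[j] for _, j in pairs],
                "p": [1e-9] * len(pairs),
            }
        )

    def test_single_pair_single_bin_regions(self):
        manifest = grid_manifest(10)
        regions = merge_region_pairs(self.significant_table(manifest, [(2, 7)]), manifest)
        assert len(regions) == 1
        r = regions[0]
        assert (r.region1_start_bp, r.region1_end_bp) == (2001, 3000)
        assert (r.region2_start_bp, r.region2_end_bp) == (7001, 8000)
        assert r.n_pairs == 1

    def test_adjacent_pairs_merge(self):
        manifest = grid_manifest(10)
        regions = merge_region_pairs(
            self.significant_table(manifest, [(2, 7), (2, 8)]), manifest, gap_bins=1
        )
        assert len(regions) == 1
        assert regions[0].n_pairs == 2
        assert regions[0].region2_end_bp == 9000

    def test_empty_input(self):
        manifest = grid_manifest(5)
        assert merge_region_pairs(self.significant_table(manifest, []), manifest) == []

    def test_matches_transitive_closure_oracle(self):
        manifest = grid_manifest(30)
        rng = np.random.default_rng(11)
        pairs = sorted(
            {tuple(sorted(p)) for p in rng.integers(0, 30, size=(25, 2)) if p[0] != p[1]}
        )
        regions = merge_region_pairs(
            self.significant_table(manifest, pairs), manifest, gap_bins=2
        )
        lo = [p[0] for p in pairs]
        hi = [p[1] for p in pairs]
        labels = brute_force_components(lo, hi, gap=2)
        assert len(regions) == len(set(labels))
        assert sorted(r.n_pairs for r in regions) == sorted(
            np.bincount(np.unique(labels, return_inverse=True)[1]).tolist()
        )


def test_heatmap_capped_at_six():
    manifest = grid_manifest(4)
    table = pd.DataFrame(
        {
            "chrom": "1",
            "bin_i": ["1:b0", "1:b1"],
            "bin_j": ["1:b2", "1:b3"],
            "p": [1e-12, 0.01],
        }
    )
    hm = heatmap_matrix(table, manifest, cap=6.0)
    assert hm.loc["1:b0", "1:b2"] == 6.0
    assert hm.loc["1:b3", "1:b1"] == pytest.approx(2.0)
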