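"""caQTL detection: scan, segment fits, DP optimality, pi0, sweep."""

import itertools

import numpy as np
import pytest
from scipy import stats

from allelescan.caqtl import (
    DEFAULT_LAMBDA1_GRID,
    DEFAULT_LAMBDA2_GRID,
    CaQTLSegmenter,
    CorrelationScanner,
    _window_fits,
    dependent_bp,
    estimate_pi0,
    fit_segment,
    lambda_sweep,
    scan_correlation,
    segment_caqtl,
    sweep_stability,
)

from conftest import planted_intensity


def brute_force_cost(D, g, lambda1, lambda2):
    """Exhaustive minimum of the segmentation cost over all 2^I labelings."""
    c_ind, c_dep, *_ = _window_fits(D, g)
    c_dep = lambda1 * c_dep
    I = D.shape[0]
    best = np.inf
    for labels in itertools.product([0, 1], repeat=I):
        arr = np.asarray(labels)
        n_segments = 1 + int((np.diff(arr) != 0).sum())
        cost = float(np.where(arr == 1, c_dep, c_ind).sum()) + n_segments * lambda2
        best = min(best, cost)
    return best


class TestScan:
    def test_perfect_linearity_gives_r_one(self):
        g = np.array([0, 1, 2, 0, 1, 2, 1, 0], float)
        D = np.vstack([2 * g + 5, np.random.default_rng(0).normal(size=8)])
        out = scan_correlation(D, g)
        assert out.loc[0, "r"] == pytest.approx(1.0)
        assert out.loc[0, "p"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_genotype_all_undefined(self):
        D = np.random.default_rng(1).normal(size=(4, 6))
        out = scan_correlation(D, np.ones(6))
        assert out["r"].isna().all()
        assert out["q"].isna().all()

    def test_constant_window_flagged_and_excluded_from_bh(self):
        rng = np.random.default_rng(2)
        g = np.array([0, 0, 1, 1, 2, 2], float)
        D = np.vstack([rng.normal(size=6), np.full(6, 3.0), g + rng.normal(0, 0.1, 6)])
        out = scan_correlation(D, g)
        assert np.isnan(out.loc[1, "r"]) and np.isnan(out.loc[1, "q"])
        valid_p = out["p"].dropna()
        from statsmodels.stats.multitest import multipletests

        expected_q = multipletests(valid_p.to_numpy(), method="fdr_bh")[1]
        assert out["q"].dropna().to_numpy() == pytest.approx(expected_q)

    def test_fixture_matches_textbook_formula(self, rng):
        """r and p on a 5-window x 8-sample fixture equal the covariance-formula
        and t-transform recomputation."""
        D = rng.normal(size=(5, 8))
        g = rng.integers(0, 3, 8).astype(float)
        out = scan_correlation(D, g)
        for i in range(5):
            x, y = D[i], g
            r_oracle = (
                ((x - x.mean()) * (y - y.mean())).sum()
                / np.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
            )
            t = r_oracle * np.sqrt(6 / (1 - r_oracle**2))
            p_oracle = 2 * stats.t.sf(abs(t), 6)
            assert out.loc[i, "r"] == pytest.approx(r_oracle)
            assert out.loc[i, "p"] == pytest.approx(p_oracle)

    def test_scanner_needs_enough_samples(self):
        with pytest.raises(ValueError):
            CorrelationScanner().fit(np.zeros((2, 4)), np.array([0, 1]))


class TestSegmentFit:
    def test_zero_residual_tie_goes_independent(self):
        """Windows constant across samples cost nothing under either model;
        the segmentation then prefers a single allele-independent segment."""
        D = np.tile(np.array([[1.0], [2.0], [3.0]]), (1, 6))
        g = np.array([0, 1, 2, 0, 1, 2], float)
        _, c_ind = fit_segment(D, g, "independent")
        _, c_dep = fit_segment(D, g, "dependent", lambda1=1.075)
        assert c_ind == pytest.approx(0.0) and c_dep == pytest.approx(0.0)
        seg = segment_caqtl(D, g, 1.075, 0.5)
        assert seg.n_segments == 1
        assert seg.segments[0].label == "allele-independent"
        assert seg.total_cost == pytest.approx(0.5)

    def test_exact_linear_model_residuals(self):
        g = np.array([0, 1, 2, 1, 0, 2], float)
        a, b = 1.5, 0.8
        D = (a + b * g)[None, :].repeat(2, axis=0)
        _, dep_cost = fit_segment(D, g, "dependent", lambda1=1.2)
        assert dep_cost == pytest.approx(0.0, abs=1e-20)
        _, ind_cost = fit_segment(D, g, "independent")
        # independent residual per window = b^2 * sum_j (g - mean g)^2 / J
        expected = 2 * b**2 * ((g - g.mean()) ** 2).sum() / len(g)
        assert ind_cost == pytest.approx(expected)

    def test_ols_matches_closed_form_oracle(self, rng):
        D = rng.normal(size=(4, 10))
        g = rng.integers(0, 3, 10).astype(float)
        fitted, _ = fit_segment(D, g, "dependent", lambda1=1.075)
        for i in range(4):
            cov = ((D[i] - D[i].mean()) * (g - g.mean())).mean()
            var = ((g - g.mean()) ** 2).mean()
            slope = cov / var
            intercept = D[i].mean() - slope * g.mean()
            assert fitted[i] == pytest.approx(intercept + slope * g)

    def test_constant_genotype_degenerates_to_mean(self):
        D = np.random.default_rng(3).normal(size=(3, 5))
        g = np.full(5, 1.0)
        fitted, _ = fit_segment(D, g, "dependent", lambda1=1.075)
        assert fitted == pytest.approx(
            np.broadcast_to(D.mean(axis=1)[:, None], D.shape)
        )


class TestSegmentationDP:
    def test_matches_exhaustive_enumeration(self, rng):
        """DP total cost equals brute force over all 2^I labelings."""
        for _ in range(5):
            D = rng.normal(size=(8, 12))
            g = rng.integers(0, 3, 12).astype(float)
            for lambda1, lambda2 in [(1.075, 10**-1.5), (1.2, 0.5), (1.03, 1e-4)]:
                seg = segment_caqtl(D, g, lambda1, lambda2)
                assert seg.total_cost == pytest.approx(
                    brute_force_cost(D, g, lambda1, lambda2)
                )

    def test_planted_block_matches_exhaustive(self, rng):
        """12-window fixture with a dosage effect in windows 5-8."""
        g = rng.integers(0, 3, 50).astype(float)
        D = rng.normal(0, 1.0, size=(12, 50))
        D[5:9] += np.outer(np.full(4, 1.5), g)
        seg = segment_caqtl(D, g, 1.075, 10**-1.5)
        assert seg.total_cost == pytest.approx(
            brute_force_cost(D, g, 1.075, 10**-1.5)
        )
        assert np.array_equal(np.flatnonzero(seg.dependent_mask), [5, 6, 7, 8])

    def test_alternating_labels_partition(self, rng):
        D = rng.normal(size=(30, 10))
        g = rng.integers(0, 3, 10).astype(float)
        seg = segment_caqtl(D, g, 1.03, 1e-3)
        spans = [(s.i0, s.i1) for s in seg.segments]
        assert spans[0][0] == 0 and spans[-1][1] == 29
        for (a, b), (c, d) in zip(spans, spans[1:]):
            assert c == b + 1
        for s1, s2 in zip(seg.segments, seg.segments[1:]):
            assert s1.label != s2.label

    def test_total_cost_identity(self, rng):
        """Total cost re-derives from per-window model costs plus the
        per-segment penalty (the additive form of the objective)."""
        D = rng.normal(size=(20, 8))
        g = rng.integers(0, 3, 8).astype(float)
        seg = segment_caqtl(D, g, 1.1, 0.05)
        c_ind, c_dep, *_ = _window_fits(D, g)
        expected = (
            np.where(seg.labels == 1, 1.1 * c_dep, c_ind).sum()
            + seg.n_segments * 0.05
        )
        assert seg.total_cost == pytest.approx(expected)

    def test_huge_lambda2_forces_single_segment(self, rng):
        D = rng.normal(size=(15, 10))
        D[5:10] += np.outer(np.ones(5), np.arange(10, dtype=float))
        g = np.arange(10, dtype=float) % 3
        seg = segment_caqtl(D, g, 1.075, 1e6)
        assert seg.n_segments == 1

    def test_lambda2_monotone_segment_count(self):
        matrix, g = planted_intensity(3, n_samples=40, region_length=2000,
                                      planted=(800, 1200))
        counts = [
            segment_caqtl(matrix.values, g, 1.075, l2).n_segments
            for l2 in (1e-5, 1e-4, 1e-3, 1e-2, 1e-1, 1.0)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_lambda1_monotone_dependent_residual_mass(self):
        matrix, g = planted_intensity(4, n_samples=40, region_length=2000,
                                      planted=(800, 1200))
        c_ind, c_dep, *_ = _window_fits(matrix.values, g)
        masses = []
        for l1 in (1.025, 1.05, 1.075, 1.1, 1.15, 1.2):
            seg = segment_caqtl(matrix.values, g, l1, 1e-3)
            masses.append(c_dep[seg.dependent_mask].sum())
        assert all(a >= b - 1e-12 for a, b in zip(masses, masses[1:]))

    def test_invalid_lambdas_rejected(self):
        D = np.zeros((3, 4))
        g = np.array([0, 1, 2, 1], float)
        with pytest.raises(ValueError):
            segment_caqtl(D, g, 1.0, 0.1)
        with pytest.raises(ValueError):
            segment_caqtl(D, g, 1.1, 0.0)

    def test_joint_sample_permutation_invariance(self, rng):
        matrix, g = planted_intensity(5, n_samples=30, region_length=2000,
                                      planted=(800, 1200))
        order = rng.permutation(30)
        seg_a = segment_caqtl(matrix.values, g, 1.075, 10**-1.5)
        seg_b = segment_caqtl(matrix.values[:, order], g[order], 1.075, 10**-1.5)
        assert np.array_equal(seg_a.labels, seg_b.labels)
        assert seg_a.total_cost == pytest.approx(seg_b.total_cost)


class TestDependentBp:
    def test_union_of_overlapping_windows(self):
        # one run of 3 windows at step 10 covers 2*10 + 150 bp
        mask = np.array([0, 1, 1, 1, 0, 1], bool)
        assert dependent_bp(mask, 150, 10) == (2 * 10 + 150) + 150

    def test_empty_mask(self):
        assert dependent_bp(np.zeros(5, bool), 150, 10) == 0


class TestPi0:
    def test_nothing_called_gives_pi0_one(self):
        D = np.ones((10, 8))  # constant intensity: no dependent calls ever
        g = np.array([0, 1, 2, 0, 1, 2, 0, 1], float)
        result = estimate_pi0(D, g, n_permutations=5, seed=0)
        assert result.n1 == 0 and result.pi0 == 1.0

    def test_cap_when_null_calls_exceed_true_calls(self):
        """Signal tracking a non-genotype sample pattern: permutations align
        with it more often than the true dosages do, so n0 > n1 and pi0 caps
        at 1."""
        g = np.array([0, 1, 0, 1, 0, 1, 2, 2], float)
        v = np.array([1, -1, 1, -1, -1, 1, -1, 1], float)
        D = np.vstack([
            np.outer(np.full(2, 10.0), g),   # true-dosage block (n1 > 0)
            np.outer(np.full(20, 10.0), v),  # decoy block, uncorrelated with g
        ])
        result = estimate_pi0(D, g, 1.075, 1e-3, n_permutations=100, seed=0)
        assert result.n1 > 0
        assert result.n0 > result.n1
        assert result.pi0 == 1.0

    def test_strong_planted_effect_low_pi0(self):
        matrix, g = planted_intensity(1)
        result = estimate_pi0(matrix.values, g, n_permutations=30, seed=1)
        assert result.n1 >= 400
        assert result.pi0 < 0.1

    def test_reproducible_given_seed(self):
        matrix, g = planted_intensity(2, n_samples=30, region_length=2000,
                                      planted=(800, 1200))
        a = estimate_pi0(matrix.values, g, n_permutations=20, seed=5)
        b = estimate_pi0(matrix.values, g, n_permutations=20, seed=5)
        assert a == b


class TestSweep:
    def test_default_grids_span_stated_ranges(self):
        assert min(DEFAULT_LAMBDA1_GRID) == 1.025 and max(DEFAULT_LAMBDA1_GRID) == 1.20
        assert min(DEFAULT_LAMBDA2_GRID) == 1e-5 and max(DEFAULT_LAMBDA2_GRID) == 1e-1

    def test_single_point_reduces_to_segmentation(self):
        matrix, g = planted_intensity(6, n_samples=30, region_length=2000,
                                      planted=(800, 1200))
        sweep = lambda_sweep(matrix.values, g, [1.075], [10**-1.5])
        seg = segment_caqtl(matrix.values, g, 1.075, 10**-1.5)
        row = sweep.iloc[0]
        assert row["n_segments"] == seg.n_segments
        assert np.array_equal(row["dependent_windows"],
                              np.flatnonzero(seg.dependent_mask))
        assert row["total_cost"] == pytest.approx(seg.total_cost)

    def test_stability_metric_bounds_and_conventions(self):
        import pandas as pd

        sweep = pd.DataFrame({"dependent_windows": [(1, 2, 3), (2, 3, 4)]})
        j = sweep_stability(sweep, n_windows=10, window_length=150, step=10)
        # runs cover [10,180) and [20,190): intersection 160, union 180
        assert j == pytest.approx(160 / 180)
        empty = pd.DataFrame({"dependent_windows": [(), ()]})
        assert sweep_stability(empty, 10) == 1.0
        mixed = pd.DataFrame({"dependent_windows": [(), (1,)]})
        assert sweep_stability(mixed, 10) == 0.0


class TestEstimatorApi:
    def test_segmenter_fit_predict_and_clone(self):
        from sklearn.base import clone

        matrix, g = planted_intensity(7, n_samples=30, region_length=2000,
                                      planted=(800, 1200))
        est = CaQTLSegmenter(lambda1=1.1, lambda2=0.01)
        assert clone(est).get_params() == est.get_params()
        est.fit(matrix.values.T, g)
        assert est.labels_.shape == (matrix.values.shape[0],)
        assert np.array_equal(est.predict(), est.labels_)
        ref = segment_caqtl(matrix.values, g, 1.1, 0.01)
        assert np.array_equal(est.labels_, ref.labels)
        assert est.cost_ == pytest.approx(ref.total_cost)

    def test_scanner_matches_function_wrapper(self):
        matrix, g = planted_intensity(8, n_samples=30, region_length=2000,
                                      planted=(800, 1200))
        est = CorrelationScanner().fit(matrix.values.T, g)
        out = scan_correlation(matrix, g)
        assert est.r_ == pytest.approx(out["r"].to_numpy(), nan_ok=True)
        assert est.q_ == pytest.approx(out["q"].to_numpy(), nan_ok=True)
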