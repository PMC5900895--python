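"""Shim computation, strategy comparison, LOOCV and the Wilcoxon test."""

from itertools import product

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from b0shim.errors import ConfigurationError
from b0shim.evaluation import (EvalConfig, averaged_fixed_shim, compute_shim,
                               loocv_evaluate, random_shims, residual_std,
                               shim_ranges, wilcoxon_paired)
from b0shim.grids import VoxelGrid
from b0shim.harmonics import ShimSetting, build_basis
from b0shim.processing import FieldMap
from b0shim.synthetic import CohortConfig, sample_cohort
from tests.conftest import SMALL_GRID_KW


def make_field(values, grid, mask=None):
    if mask is None:
        mask = np.ones(grid.shape, bool)
    return FieldMap(values, grid, mask, provenance="measured")


class TestComputeShim:
    def test_exact_cancellation_of_basis_member(self, grid16):
        basis = build_basis(grid16, 2)
        mask = np.ones(grid16.shape, bool)
        field = make_field(-2.5 * basis.basis_volumes[basis.index("XZ")], grid16)
        shim = compute_shim(field, basis, mask, max_order=2)
        assert shim["XZ"] == pytest.approx(2.5, abs=1e-9)
        assert residual_std(field, shim, basis, mask) < 1e-9

    def test_sign_convention_shim_adds_to_field(self, grid16):
        """Canonical sign check: a +Z field needs a −Z shim."""
        basis = build_basis(grid16, 1)
        mask = np.ones(grid16.shape, bool)
        field = make_field(basis.basis_volumes[basis.index("Z")].copy(), grid16)
        shim = compute_shim(field, basis, mask, max_order=1)
        assert shim["Z"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_pseudo_inverse_oracle(self, rng):
        grid = VoxelGrid.centered(12, 8.0)
        basis = build_basis(grid, 2)
        for _ in range(5):
            mask = rng.random(grid.shape) < 0.6
            field = make_field(rng.normal(0, 20, grid.shape), grid, mask)
            shim = compute_shim(field, basis, mask, max_order=2)
            A = basis.design_matrix(mask)
            oracle = -np.linalg.pinv(A) @ field.values[mask]
            np.testing.assert_allclose(shim.coefficients, oracle, atol=1e-8)

    def test_residual_monotone_in_order(self, rng):
        grid = VoxelGrid.centered(12, 8.0)
        basis = build_basis(grid, 3)
        mask = rng.random(grid.shape) < 0.7
        field = make_field(rng.normal(0, 20, grid.shape), grid, mask)
        stds = [residual_std(field, compute_shim(field, basis, mask, k),
                             basis, mask) for k in (1, 2, 3)]
        assert stds[0] >= stds[1] - 1e-9 >= stds[2] - 2e-9

    def test_invalid_order_rejected(self, grid16):
        basis = build_basis(grid16, 2)
        field = make_field(np.zeros(grid16.shape), grid16)
        with pytest.raises(ValueError):
            compute_shim(field, basis, np.ones(grid16.shape, bool), max_order=4)

    def test_rms_objective_equals_std_objective(self, rng, grid16):
        """With DC in the design, minimizing RMS equals minimizing std:
        the non-constant coefficients match a fit to the demeaned field."""
        basis = build_basis(grid16, 2)
        mask = rng.random(grid16.shape) < 0.5
        vals = rng.normal(5, 20, grid16.shape)
        shim = compute_shim(make_field(vals, grid16, mask), basis, mask, 2)
        demeaned = vals - vals[mask].mean()
        shim2 = compute_shim(make_field(demeaned, grid16, mask), basis, mask, 2)
        for t in shim.terms:
            if t != "DC":
                assert shim[t] == pytest.approx(shim2[t], abs=1e-9)


class TestResidualStd:
    def test_constant_residual_is_zero(self, grid16):
        basis = build_basis(grid16, 1)
        field = make_field(np.full(grid16.shape, 7.0), grid16)
        assert residual_std(field, ShimSetting.zero(1), basis,
                            field.brain_mask) == 0.0

    def test_two_voxel_hand_calculation(self, grid16):
        basis = build_basis(grid16, 1)
        vals = np.zeros(grid16.shape)
        mask = np.zeros(grid16.shape, bool)
        vals[0, 0, 0], vals[1, 1, 1] = -1.0, 1.0
        mask[0, 0, 0] = mask[1, 1, 1] = True
        field = FieldMap(vals, grid16, mask)
        assert residual_std(field, ShimSetting.zero(1), basis, mask) == 1.0

    def test_optimal_shim_beats_random_candidates(self, rng, grid16):
        basis = build_basis(grid16, 2)
        mask = rng.random(grid16.shape) < 0.6
        field = make_field(rng.normal(0, 30, grid16.shape), grid16, mask)
        best = compute_shim(field, basis, mask, 2)
        r_best = residual_std(field, best, basis, mask)
        ranges = {t: (-1.0, 1.0) for t in best.terms}
        for shim in random_shims(100, ranges, seed=4):
            assert r_best <= residual_std(field, shim, basis, mask) + 1e-12

    def test_empty_mask_rejected(self, grid16):
        basis = build_basis(grid16, 1)
        field = make_field(np.zeros(grid16.shape), grid16)
        with pytest.raises(ConfigurationError):
            residual_std(field, ShimSetting.zero(1), basis,
                         np.zeros(grid16.shape, bool))


class TestRandomShims:
    def test_degenerate_range_all_identical(self):
        shims = random_shims(5, {"Z": (1.5, 1.5), "X": (0.0, 0.0)}, seed=0)
        for s in shims:
            assert s["Z"] == 1.5 and s["X"] == 0.0

    def test_bounds_and_reproducibility(self, rng):
        ranges = {"X": (-2.0, 1.0), "Z": (0.5, 3.0)}
        a = random_shims(50, ranges, seed=9)
        b = random_shims(50, ranges, seed=9)
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa.coefficients, sb.coefficients)
            for t, (lo, hi) in ranges.items():
                assert lo <= sa[t] <= hi

    def test_uniformity_kolmogorov_smirnov(self):
        ranges = {"Z": (-1.0, 3.0)}
        draws = np.array([s["Z"] for s in random_shims(10000, ranges, seed=1)])
        d = stats.kstest(draws, stats.uniform(loc=-1.0, scale=4.0).cdf).statistic
        critical = 1.628 / np.sqrt(10000)  # alpha = 0.01
        assert d < critical

    def test_nonpositive_count_rejected(self):
        with pytest.raises(ValueError):
            random_shims(0, {"Z": (0, 1)})


class TestAveragedFixedShim:
    def test_single_shim_is_itself(self):
        s = ShimSetting.from_dict({"Z": 2.0}, 1)
        out = averaged_fixed_shim([s])
        np.testing.assert_array_equal(out.coefficients, s.coefficients)

    def test_two_shim_mean(self):
        a = ShimSetting.from_dict({"Z": 1.0}, 1)
        b = ShimSetting.from_dict({"Z": 3.0}, 1)
        assert averaged_fixed_shim([a, b])["Z"] == 2.0

    def test_matches_arithmetic_oracle(self, rng):
        shims = [ShimSetting(("DC", "X", "Y", "Z"), rng.normal(0, 1, 4), 1)
                 for _ in range(50)]
        out = averaged_fixed_shim(shims)
        oracle = np.mean([s.coefficients for s in shims], axis=0)
        np.testing.assert_allclose(out.coefficients, oracle, atol=1e-12)

    def test_mismatched_terms_rejected(self):
        a = ShimSetting.from_dict({"Z": 1.0}, 1)
        b = ShimSetting.from_dict({"Z2": 1.0}, 2)
        with pytest.raises(ValueError):
            averaged_fixed_shim([a, b])


def brute_force_wilcoxon(d):
    """Independent oracle: enumerate all 2^n sign patterns."""
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    n = d.size
    expect = n * (n + 1) / 4.0
    count = 0
    for signs in product([1, -1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s > 0)
        if abs(w - expect) >= abs(w_obs - expect) - 1e-12:
            count += 1
    return w_obs, count / 2 ** n


class TestWilcoxon:
    def test_identical_samples_p_one(self):
        a = np.arange(6.0)
        assert wilcoxon_paired(a, a) == (0.0, 1.0)

    def test_all_positive_n6_exact(self):
        a = np.array([1.0, 2, 3, 4, 5, 6])
        w, p = wilcoxon_paired(a, np.zeros(6))
        assert w == 21.0
        assert p == pytest.approx(2 / 2 ** 6)

    def test_matches_enumeration_oracle_n8(self, rng):
        for _ in range(10):
            a = rng.normal(0.3, 1.0, 8)
            b = rng.normal(0.0, 1.0, 8)
            w, p = wilcoxon_paired(a, b)
            w_o, p_o = brute_force_wilcoxon(a - b)
            assert w == w_o
            assert p == pytest.approx(p_o, abs=1e-12)

    def test_large_sample_matches_scipy_approximation(self, rng):
        a = rng.normal(0.5, 1.0, 40)
        b = rng.normal(0.0, 1.0, 40)
        _, p = wilcoxon_paired(a, b)
        ref = stats.wilcoxon(a, b, alternative="two-sided",
                             mode="approx", correction=False)
        assert p == pytest.approx(ref.pvalue, rel=1e-6)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_paired(np.ones(3), np.zeros(3))


class TestLOOCV:
    @pytest.fixture(scope="class")
    def tiny_eval(self):
        cfg = CohortConfig(n_subjects=5, seed=3, **SMALL_GRID_KW)
        cohort = sample_cohort(cfg)
        ev = loocv_evaluate(cohort, EvalConfig(seed=0, n_random=20))
        return cohort, ev

    def test_identical_subjects_make_all_strategies_equal(self):
        cfg = CohortConfig(n_subjects=3, seed=2, rotation_sd_deg=(0, 0, 0),
                           scale_sd_frac=(0, 0, 0),
                           translation_sd_mm=(0, 0, 0),
                           cavity_scale_sd_frac=0.0, sinus_amp_hz=0.0,
                           ear_amp_hz=0.0, noise_sd_hz=0.0, **SMALL_GRID_KW)
        cohort = sample_cohort(cfg)
        ev = loocv_evaluate(cohort, EvalConfig(
            strategies=("measured", "averaged_registered", "averaged_fixed")))
        per = ev.per_subject()
        np.testing.assert_allclose(per["averaged_registered"], per["measured"],
                                   atol=1e-6)
        np.testing.assert_allclose(per["averaged_fixed"], per["measured"],
                                   atol=1e-6)

    def test_measured_is_lower_bound_for_every_subject(self, tiny_eval):
        cohort, ev = tiny_eval
        per_min = (ev.results.groupby(["subject", "strategy"])
                   ["residual_std_hz"].min().unstack("strategy"))
        for strat in per_min.columns:
            if strat != "measured":
                assert np.all(per_min["measured"]
                              <= per_min[strat] + 1e-9), strat

    def test_tuneup_is_worst_on_average(self, tiny_eval):
        _, ev = tiny_eval
        means = ev.strategy_means()
        assert means["tuneup"] == means.max()
        assert means["averaged_registered"] <= means["tuneup"]

    def test_no_leakage_training_quantities_recomputed_by_hand(self, tiny_eval):
        """Fold results for a subject must equal quantities computed from
        the other subjects only."""
        cohort, ev = tiny_eval
        held, training = cohort[0], cohort[1:]
        basis = build_basis(held.grid, 2)
        fixed = [compute_shim(t.field_true, build_basis(t.grid, 2),
                              t.brain_mask, 2) for t in training]
        avg = averaged_fixed_shim(fixed)
        expect = residual_std(held.field_true, avg, basis, held.brain_mask)
        got = ev.per_subject().loc[held.id, "averaged_fixed"]
        assert got == pytest.approx(expect, abs=1e-9)

    def test_distribution_strategies_have_one_row_per_sample(self, tiny_eval):
        cohort, ev = tiny_eval
        counts = ev.results.groupby(["subject", "strategy"]).size()
        n_train = len(cohort) - 1
        for sid in (s.id for s in cohort):
            assert counts[(sid, "individual_fixed")] == n_train
            assert counts[(sid, "individual_registered")] == n_train
            assert counts[(sid, "random")] == 20
            assert counts[(sid, "measured")] == 1

    def test_cohort_too_small_rejected(self, small_cohort):
        with pytest.raises(ConfigurationError):
            loocv_evaluate(small_cohort[:2])
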