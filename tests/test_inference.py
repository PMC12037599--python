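import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from covnet.exceptions import ValidationError
from covnet.inference import (
    auc,
    bh_fdr,
    global_permutation_test,
    nodal_permutation_test_fdr,
    permute_groups,
)
from covnet.networks import sparsity_grid
from covnet.preprocess import residualize
from covnet.simulate import SyntheticSpec, generate_cohort


class TestAUC:
    def test_constant_curve_is_rectangle(self):
        grid = sparsity_grid()
        assert auc(np.ones(31), grid) == pytest.approx(0.30)

    def test_linear_ramp_is_triangle(self):
        grid = sparsity_grid()
        assert auc(np.linspace(0, 1, 31), grid) == pytest.approx(0.15)

    def test_matches_fine_grid_riemann_sum(self):
        rng = np.random.default_rng(1)
        grid = sparsity_grid()
        vals = rng.random(31)
        # midpoint rule at 10x resolution on the piecewise-linear interpolant
        fine = np.linspace(0.10, 0.40, 3001)
        mid = (fine[:-1] + fine[1:]) / 2
        riemann = float(np.sum(np.interp(mid, grid, vals) * np.diff(fine)))
        assert auc(vals, grid) == pytest.approx(riemann, abs=1e-9)

    def test_decreasing_grid_rejected(self):
        with pytest.raises(ValidationError):
            auc([1.0, 2.0], [0.4, 0.1])


class TestPermuteGroups:
    def test_group_sizes_preserved(self):
        labels = np.array(["A"] * 50 + ["B"] * 49)
        out = permute_groups(labels, np.random.default_rng(0))
        assert (out == "A").sum() == 50 and (out == "B").sum() == 49

    def test_deterministic_per_seed(self):
        labels = np.array(["A"] * 10 + ["B"] * 8)
        out1 = permute_groups(labels, np.random.default_rng(42))
        out2 = permute_groups(labels, np.random.default_rng(42))
        assert np.array_equal(out1, out2)

    def test_subject_set_partition_preserved(self):
        labels = np.array(["A", "A", "B", "B", "B"])
        out = permute_groups(labels, np.random.default_rng(3))
        assert sorted(out) == sorted(labels)


@pytest.fixture(scope="module")
def corrected(regions6):
    cohort = generate_cohort(
        SyntheticSpec(n_per_group=(12, 10), regions=regions6, n_blocks=2, seed=5))
    return residualize(cohort)


class TestGlobalPermutationTest:

    def test_null_reproducible_bit_for_bit(self, corrected):
        kw = dict(grid=sparsity_grid(0.2, 0.4, 0.1), repetitions=120, seed=9)
        with pytest.warns(UserWarning, match="permutations"):
            r1 = global_permutation_test(corrected, "Eglob", **kw)
            r2 = global_permutation_test(corrected, "Eglob", **kw)
        assert np.array_equal(r1.null, r2.null)
        assert r1.p == r2.p and r1.observed == r2.observed

    def test_p_value_never_zero_and_band_covers_median(self, corrected):
        with pytest.warns(UserWarning, match="permutations"):
            r = global_permutation_test(corrected, "Cp",
                                        grid=sparsity_grid(0.2, 0.4, 0.1),
                                        repetitions=120, seed=1)
        assert 0 < r.p <= 1
        assert r.band[0] <= np.median(r.null) <= r.band[1]

    def test_observed_invariant_to_subject_row_order(self, corrected):
        kw = dict(grid=sparsity_grid(0.2, 0.4, 0.1), repetitions=120, seed=2)
        with pytest.warns(UserWarning, match="permutations"):
            r1 = global_permutation_test(corrected, "Eglob", **kw)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(corrected.subjects))
        shuffled = corrected.with_values(corrected.values.to_numpy()[perm])
        shuffled.meta = corrected.meta.iloc[perm]
        shuffled.values.index = corrected.values.index[perm]
        with pytest.warns(UserWarning, match="permutations"):
            r2 = global_permutation_test(shuffled, "Eglob", **kw)
        assert r1.observed == pytest.approx(r2.observed, abs=1e-12)

    def test_unknown_metric_rejected(self, corrected):
        with pytest.raises(ValidationError):
            global_permutation_test(corrected, "EglobX", repetitions=100)

    def test_too_few_repetitions_rejected(self, corrected):
        with pytest.raises(ValidationError):
            global_permutation_test(corrected, "Eglob", repetitions=50)

    def test_degenerate_zero_observed_gives_p_one(self):
        null = np.array([0.1, -0.2, 0.0, 0.3])
        from covnet.inference import _permutation_p
        assert _permutation_p(0.0, null) == 1.0


class TestNodalPermutationTest:
    def test_null_cohort_reports_frame_with_bh_columns(self, regions6):
        cohort = generate_cohort(
            SyntheticSpec(n_per_group=(12, 10), regions=regions6, n_blocks=2, seed=5))
        corrected = residualize(cohort)
        out = nodal_permutation_test_fdr(corrected, "degree", sparsity=0.4,
                                         repetitions=150, seed=3)
        assert list(out.index) == list(regions6.labels)
        assert ((0 < out.p_raw) & (out.p_raw <= 1)).all()
        assert (out.p_bh >= out.p_raw - 1e-12).all()

    def test_single_region_bh_is_identity(self):
        assert bh_fdr([0.037]) == pytest.approx([0.037])


class TestBenjaminiHochberg:
    def test_hand_evaluated_step_up(self):
        adj = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_equal_pvalues_unchanged(self):
        assert np.allclose(bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        p = rng.random(25)
        adj = bh_fdr(p)
        assert np.allclose(adj[::-1], bh_fdr(p[::-1]))

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_statsmodels_reference(self, seed):
        p = np.random.default_rng(seed).random(40)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_fdr(p), expected, atol=1e-12)

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValidationError):
            bh_fdr([0.5, 1.2])


class TestNullCalibrationReducedScale:
    def test_pvalues_roughly_uniform_under_h0(self, regions6):
        """Under identical group distributions the p-values should be ~uniform.

        Quick 40-replicate screen; the full 200-replicate binomial check
        lives in the acceptance suite.
        """
        pvals = []
        for rep in range(40):
            cohort = generate_cohort(
                SyntheticSpec(n_per_group=(15, 15), regions=regions6, n_blocks=2,
                              seed=400 + rep))
            corrected = residualize(cohort)
            with pytest.warns(UserWarning, match="permutations"):
                r = global_permutation_test(corrected, "Eglob", repetitions=199,
                                            seed=rep)
            pvals.append(r.p)
        from scipy import stats
        assert stats.kstest(pvals, "uniform").pvalue > 0.001
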