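"""MSI/PPR indices, peak statistics, curve alignment, fitting, and the
nested-curve comparison."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tectalmsi.tuning import (
    MSITuning,
    MSITuningCurve,
    UndefinedIndexError,
    align_curves,
    aligned_points,
    cell_tuning_curve,
    compare_curves_f_test,
    fit_tuning_curve,
    group_summary,
    msin,
    preferred_isi,
)
from .conftest import make_cell


def curve(values, cell_id="c", stage="st44_46"):
    return MSITuningCurve(cell_id, "MSIn", values, sm=1.0, stage_group=stage)


class TestMsin:
    def test_doubling_gives_unity(self):
        assert msin(4, 2) == pytest.approx(1.0)

    def test_equal_means_give_zero(self):
        assert msin(3.7, 3.7) == 0.0

    def test_zero_paired_response_floors_at_minus_one(self):
        assert msin(0, 3) == -1.0

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedIndexError):
            msin(1, 0)

    @given(st.floats(0, 50), st.floats(0.1, 50), st.floats(0.1, 10))
    def test_scale_invariance_and_lower_bound(self, cm, sm, k):
        """MSIn is invariant when counts scale together, and >= -1 for
        non-negative counts."""
        v = msin(cm, sm)
        assert v >= -1.0
        assert msin(k * cm, k * sm) == pytest.approx(v, rel=1e-9, abs=1e-12)


class TestCellTuningCurve:
    def test_sm_is_max_single_modality_mean(self):
        # V mean 3, HB mean 2, paired mean 6 -> (6-3)/3 = 1
        cell = make_cell([3, 3], [2, 2], {100.0: [6, 6]})
        c = cell_tuning_curve(cell)
        assert c.sm == 3.0
        assert c.values[100.0] == pytest.approx(1.0)

    def test_flat_curve_when_paired_equals_max_single(self):
        cell = make_cell([3, 3], [2, 2], {100.0: [3, 3], 250.0: [3, 3]})
        c = cell_tuning_curve(cell)
        assert all(v == 0.0 for v in c.values.values())

    def test_ppr_uses_repeated_modality_denominator(self):
        cell = make_cell([2, 2], [5, 5], {100.0: [6, 6]}, pair=("V", "V"))
        c = cell_tuning_curve(cell, index_kind="PPR", ppr_modality="V")
        assert c.values[100.0] == pytest.approx(2.0)

    def test_zero_single_response_excludes_cell(self):
        cell = make_cell([0, 0], [0, 0], {100.0: [3]})
        with pytest.raises(UndefinedIndexError):
            cell_tuning_curve(cell)

    def test_order_pooling_merges_signed_isis(self):
        vh = make_cell([2, 2], [2, 2], {100.0: [4, 4]}, pair=("V", "HB"))
        hv_trials = make_cell([2, 2], [2, 2], {100.0: [8, 8]}, pair=("HB", "V"))
        cell = vh
        cell.trials += [t for t in hv_trials.trials if t.condition.kind == "paired"]
        pooled = cell_tuning_curve(cell, pool_order=True)
        assert set(pooled.values) == {100.0}
        assert pooled.values[100.0] == pytest.approx((6 - 2) / 2)
        split = cell_tuning_curve(cell, pool_order=False)
        assert set(split.values) == {100.0, -100.0}


class TestPreferredIsi:
    def test_argmax(self):
        assert preferred_isi(curve({100: 0.1, 200: 0.9, 500: 0.3})) == (200, 0.9)

    def test_tie_breaks_toward_smallest_abs_isi(self):
        assert preferred_isi(curve({100: 0.5, 500: 0.5})) == (100, 0.5)
        assert preferred_isi(curve({-100: 0.5, 500: 0.5})) == (-100, 0.5)

    def test_single_entry(self):
        assert preferred_isi(curve({250: -0.2})) == (250, -0.2)

    def test_empty_curve_raises(self):
        with pytest.raises(ValueError):
            preferred_isi(curve({}))


class TestAlignCurves:
    def test_single_cell_rekeyed_with_zero_sem(self):
        al = align_curves([curve({100: 0.1, 200: 0.9, 500: 0.3})])
        assert al.offsets[0.0] == (0.9, 0.0, 1)
        assert al.offsets[-100.0] == (pytest.approx(0.1), 0.0, 1)
        assert al.offsets[300.0] == (pytest.approx(0.3), 0.0, 1)

    def test_two_identical_cells_zero_sem(self):
        c1 = curve({100: 0.2, 200: 0.8}, "a")
        c2 = curve({100: 0.2, 200: 0.8}, "b")
        al = align_curves([c1, c2])
        assert al.offsets[0.0] == (pytest.approx(0.8), 0.0, 2)

    def test_three_cell_hand_oracle(self):
        """Means match plain-loop averaging of hand-aligned values."""
        c1 = curve({100: 0.1, 200: 1.0, 300: 0.4}, "a")  # peak 200
        c2 = curve({100: 0.9, 200: 0.5, 300: 0.2}, "b")  # peak 100
        c3 = curve({100: 0.3, 200: 0.6, 300: 0.7}, "c")  # peak 300
        al = align_curves([c1, c2, c3])
        # offset 0: peaks 1.0, 0.9, 0.7
        assert al.offsets[0.0][0] == pytest.approx((1.0 + 0.9 + 0.7) / 3)
        assert al.offsets[0.0][2] == 3
        # offset +100: c1 300->0.4, c2 200->0.5
        assert al.offsets[100.0][0] == pytest.approx((0.4 + 0.5) / 2)
        # offset -200: only c3 100->0.3
        assert al.offsets[-200.0] == (pytest.approx(0.3), 0.0, 1)

    def test_conserves_data_points(self, young_population):
        res = MSITuning(young_population).fit()
        n_points = sum(len(c.values) for c in res.curves)
        al = align_curves(res.curves)
        assert sum(n for _, _, n in al.offsets.values()) == n_points
        assert aligned_points(res.curves).shape == (n_points, 2)


class TestFitTuningCurve:
    @staticmethod
    def model(x, amp, width, floor):
        return floor + amp * np.exp(-0.5 * (x / width) ** 2)

    def test_exact_recovery_of_noise_free_points(self):
        x = np.linspace(-400, 400, 9)
        pts = np.column_stack([x, self.model(x, 1.2, 150.0, -0.3)])
        fit = fit_tuning_curve(pts)
        assert fit.converged
        assert fit.rss <= 1e-9
        assert fit.amplitude == pytest.approx(1.2, rel=1e-4)
        assert fit.width_ms == pytest.approx(150.0, rel=1e-4)
        assert fit.floor == pytest.approx(-0.3, abs=1e-4)

    def test_constant_data_fits_flat(self):
        x = np.linspace(-300, 300, 7)
        fit = fit_tuning_curve(np.column_stack([x, np.full(7, 0.42)]))
        assert fit.amplitude == pytest.approx(0.0, abs=1e-6)
        assert fit.floor + fit.amplitude * 1.0 == pytest.approx(0.42, abs=1e-3)

    def test_noisy_points_recover_parameters(self, rng):
        x = np.tile(np.linspace(-400, 400, 9), 20)
        y = self.model(x, 1.0, 120.0, -0.2) + rng.normal(0, 0.05, x.size)
        fit = fit_tuning_curve(np.column_stack([x, y]))
        assert fit.amplitude == pytest.approx(1.0, abs=0.1)
        assert fit.width_ms == pytest.approx(120.0, abs=15.0)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_tuning_curve(np.array([[0, 1], [1, 2], [2, 3]]))


class TestCompareCurves:
    def test_identical_groups_give_zero_f(self):
        x = np.linspace(-300, 300, 8)
        pts = np.column_stack([x, TestFitTuningCurve.model(x, 1.0, 150.0, -0.2)])
        F, df1, df2, p = compare_curves_f_test(pts, pts)
        assert F == pytest.approx(0.0, abs=1e-6)
        assert p > 0.999
        assert df1 == 3

    def test_width_contrast_detected(self, rng):
        x = np.tile(np.linspace(-400, 400, 9), 8)
        a = TestFitTuningCurve.model(x, 1.0, 250.0, -0.2) + rng.normal(0, 0.03, x.size)
        b = TestFitTuningCurve.model(x, 1.0, 80.0, -0.2) + rng.normal(0, 0.03, x.size)
        F, _, _, p = compare_curves_f_test(
            np.column_stack([x, a]), np.column_stack([x, b])
        )
        assert p < 1e-6

    @given(st.integers(0, 2**31 - 1))
    def test_f_statistic_non_negative(self, seed):
        r = np.random.default_rng(seed)
        x = np.linspace(-300, 300, 6)
        a = np.column_stack([x, r.normal(0, 1, 6)])
        b = np.column_stack([x, r.normal(0, 1, 6)])
        F, _, _, p = compare_curves_f_test(a, b)
        assert F >= 0.0 and 0.0 <= p <= 1.0

    def test_matches_refit_oracle(self, rng):
        """F recomputed from independently refit RSS values (lmfit) agrees
        to 6 decimals on small low-noise datasets."""
        lmfit = pytest.importorskip("lmfit")
        from scipy import stats as sps

        def lm_rss(pts):
            model = lmfit.Model(TestFitTuningCurve.model)
            x, y = pts[:, 0], pts[:, 1]
            pars = model.make_params(
                amp=y.max() - y.min(), width=(x.max() - x.min()) / 2, floor=y.min()
            )
            out = model.fit(y, pars, x=x)
            return float(np.sum(out.residual**2))

        for _ in range(5):
            x = np.tile(np.linspace(-400, 400, 9), 3)
            a = np.column_stack(
                [x, TestFitTuningCurve.model(x, 1.0, 200.0, -0.1)
                 + rng.normal(0, 0.02, x.size)]
            )
            b = np.column_stack(
                [x, TestFitTuningCurve.model(x, 0.7, 120.0, -0.1)
                 + rng.normal(0, 0.02, x.size)]
            )
            F, df1, df2, p = compare_curves_f_test(a, b)
            rss1 = lm_rss(np.vstack([a, b]))
            rss2 = lm_rss(a) + lm_rss(b)
            F_oracle = (rss1 - rss2) / df1 / (rss2 / df2)
            assert F == pytest.approx(F_oracle, abs=1e-6)
            assert p == pytest.approx(float(sps.f.sf(F_oracle, df1, df2)), abs=1e-6)


class TestGroupSummary:
    def test_identical_cells_zero_sem_and_iqr(self):
        curves = [curve({100: 0.5, 200: 1.0}, f"c{i}") for i in range(5)]
        out = group_summary(curves)
        g = out["groups"]["st44_46"]
        assert g["max_index_sem"] == 0.0
        assert g["preferred_isi_iqr"] == 0.0
        assert g["preferred_isi_median"] == 200.0

    def test_known_median_contrast_detected(self):
        """Generative medians 100 vs 400 ms at n=30/group -> Mann-Whitney
        p < 0.05."""
        r = np.random.default_rng(1)
        a = [curve({float(i): 1.0 + 0.01 * j}, f"a{j}", "st44_46")
             for j, i in enumerate(r.normal(100, 40, 30).clip(25))]
        b = [curve({float(i): 1.0 + 0.01 * j}, f"b{j}", "st48_49")
             for j, i in enumerate(r.normal(400, 80, 30).clip(25))]
        out = group_summary(a + b)
        assert out["comparisons"][0]["preferred_isi_p"] < 0.05

    def test_single_cell_group_refused(self):
        a = curve({100: 0.5}, "a", "st44_46")
        b = curve({100: 0.5}, "b", "st48_49")
        with pytest.raises(ValueError, match=">= 2 cells"):
            group_summary([a, b])
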