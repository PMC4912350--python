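"""Current-to-conductance conversion, response magnitudes, conductance MSI,
and the E/I group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tectalmsi.conductance import (
    ConductanceAnalysis,
    ConductanceMSI,
    CurrentTrace,
    conductance_msin,
    current_to_conductance,
    decompose_trial,
    ei_scatter_stats,
    ei_stage_comparison,
    response_magnitude,
)
from tectalmsi.synthetic import (
    ConductanceParams,
    EnhancementProfile,
    enhancement_at,
    generate_conductance_population,
    generate_conductance_trials,
    preset,
)

FS = 2000.0


def trace(samples, hold_mv, stims=None):
    return CurrentTrace(np.asarray(samples, float), FS, hold_mv,
                        stimulus_times_ms=stims or [])


class TestCurrentToConductance:
    def test_worked_two_nanosiemens_case(self):
        # -100 pA at -45 mV against E_rev = +5 mV: g = -100 / -50 = 2 nS
        g = current_to_conductance(trace(np.full(100, -100.0), -45.0), 5.0)
        np.testing.assert_allclose(g, 2.0)

    def test_zero_current_zero_conductance(self):
        g = current_to_conductance(trace(np.zeros(100), -45.0), 5.0)
        np.testing.assert_allclose(g, 0.0)

    def test_degenerate_driving_force_rejected(self):
        with pytest.raises(ValueError, match="driving force"):
            current_to_conductance(trace(np.zeros(10), 2.0), 5.0)

    def test_baseline_subtracted_before_division(self):
        x = np.full(400, -20.0)  # 50 pA offset throughout
        x[240:] = -120.0  # response after the stimulus at 120 ms
        g = current_to_conductance(trace(x, -45.0, stims=[120.0]), 5.0)
        np.testing.assert_allclose(g[:240], 0.0)
        np.testing.assert_allclose(g[240:], 2.0)

    @given(st.integers(0, 2**31 - 1), st.floats(0.25, 4.0))
    def test_exact_linearity_in_current(self, seed, a):
        r = np.random.default_rng(seed)
        x = r.normal(0, 30, 300)
        t1 = trace(x, -45.0, stims=[100.0])
        t2 = trace(a * x, -45.0, stims=[100.0])
        g1 = current_to_conductance(t1, 5.0)
        g2 = current_to_conductance(t2, 5.0)
        np.testing.assert_allclose(g2, a * g1, rtol=1e-12, atol=1e-12)


class TestResponseMagnitude:
    def test_peak_of_triangular_bump(self):
        g = np.concatenate([np.linspace(0, 3, 50), np.linspace(3, 0, 50)])
        assert response_magnitude(g, FS, (0.0, 50.0)) == pytest.approx(3.0)

    def test_scaling(self):
        g = np.concatenate([np.linspace(0, 3, 50), np.linspace(3, 0, 50)])
        m1 = response_magnitude(g, FS, (0.0, 50.0))
        m2 = response_magnitude(2 * g, FS, (0.0, 50.0))
        assert m2 == pytest.approx(2 * m1)

    def test_integral_of_rectangular_pulse(self):
        # amplitude 2 nS for 10 ms -> 20 nS*ms
        g = np.zeros(100)
        g[20:40] = 2.0  # 20 samples at 0.5 ms/sample = 10 ms
        assert response_magnitude(g, FS, (0.0, 50.0), mode="integral") == (
            pytest.approx(20.0)
        )

    def test_negative_magnitude_clamped_with_warning(self):
        with pytest.warns(UserWarning, match="clamped"):
            out = response_magnitude(np.full(50, -1.0), FS, (0.0, 10.0))
        assert out == 0.0


def _noiseless_cell(profile_exc, profile_inh, isis=(100.0, 500.0)):
    cfg = preset(
        "st44_46", n_cells=1, seed=0, n_paired_trials=1, isi_grid_ms=isis,
        conductance_params=ConductanceParams(noise_sd_pa=0.0, sampling_rate_hz=FS),
    )
    return cfg, generate_conductance_trials(cfg, profile_exc, profile_inh)


class TestConductanceRoundTrip:
    def test_noise_free_recovery_is_exact(self):
        """Generated single-transient conductances come back exactly after
        synthesising currents at both holding potentials and converting."""
        prof = EnhancementProfile(0.8, 100.0, 80.0, -0.2)
        cfg, cell = _noiseless_cell(prof, prof)
        p = cfg.conductance_params
        single = next(t for t in cell.trials if t.condition.kind == "single")
        pair = decompose_trial(*single.trace)
        t = np.arange(pair.g_exc.size) / FS * 1000.0
        # reconstruct the generated transient independently
        from tectalmsi.synthetic import _transient

        g_e = _transient(t, p.pre_stimulus_ms, p.amp_exc_ns,
                         p.tau_rise_exc_ms, p.tau_decay_exc_ms)
        g_i = _transient(t, p.pre_stimulus_ms, p.amp_inh_ns,
                         p.tau_rise_inh_ms, p.tau_decay_inh_ms)
        np.testing.assert_allclose(pair.g_exc, g_e, atol=1e-10)
        np.testing.assert_allclose(pair.g_inh, g_i, atol=1e-10)

    def test_default_noise_magnitudes_within_ten_percent(self):
        prof = EnhancementProfile(0.8, 100.0, 80.0, -0.2)
        cfg = preset(
            "st44_46", n_cells=1, seed=1, n_paired_trials=1,
            isi_grid_ms=(100.0,),
            conductance_params=ConductanceParams(sampling_rate_hz=FS),
        )
        cell = generate_conductance_trials(cfg, prof, prof)
        p = cfg.conductance_params
        for trial in cell.trials:
            if trial.condition.kind != "single":
                continue
            pair = decompose_trial(*trial.trace)
            m_e = response_magnitude(pair.g_exc, FS,
                                     (p.pre_stimulus_ms, p.pre_stimulus_ms + 500))
            m_i = response_magnitude(pair.g_inh, FS,
                                     (p.pre_stimulus_ms, p.pre_stimulus_ms + 500))
            assert m_e == pytest.approx(p.amp_exc_ns, rel=0.10)
            assert m_i == pytest.approx(p.amp_inh_ns, rel=0.10)


class TestConductanceMSI:
    def test_additive_pair_in_integral_mode_gives_unity(self):
        """Paired = sum of two equal transients: integral doubles, so the
        conductance MSI index is 1 regardless of overlap."""
        flat = EnhancementProfile(0.0, 200.0, 100.0, 0.0)
        _, cell = _noiseless_cell(flat, flat)
        m = conductance_msin(cell, "excitatory", mode="integral")
        for v in m.values.values():
            assert v == pytest.approx(1.0, abs=1e-3)

    def test_known_gain_recovered_in_integral_mode(self):
        prof_e = EnhancementProfile(1.0, 100.0, 80.0, -0.2)
        prof_i = EnhancementProfile(0.4, 100.0, 80.0, -0.2)
        _, cell = _noiseless_cell(prof_e, prof_i)
        m_e = conductance_msin(cell, "excitatory", mode="integral")
        m_i = conductance_msin(cell, "inhibitory", mode="integral")
        for isi in m_e.values:
            ge = enhancement_at(prof_e, isi)
            gi = enhancement_at(prof_i, isi)
            # integral of paired = 2*(1+G) x single integral -> MSIn = 1+2G,
            # up to the first transient's extra tail inside the longer
            # paired window (< 1% of charge at tau_decay <= 80 ms)
            assert m_e.values[isi] == pytest.approx(2 * (1 + ge) - 1, abs=0.01)
            assert m_i.values[isi] == pytest.approx(2 * (1 + gi) - 1, abs=0.01)

    def test_paired_equal_to_larger_single_gives_zero(self):
        msi = ConductanceMSI("c", "excitatory", "st44_46", {}, sm=3.0)
        # direct formula check through the shared index definition
        from tectalmsi.tuning import msin

        assert msin(3.0, 3.0) == 0.0


class TestEIStatistics:
    @staticmethod
    def _msis(stage_effect_exc):
        msis = {"excitatory": [], "inhibitory": []}
        r = np.random.default_rng(3)
        for stage, bump in (("st44_46", stage_effect_exc), ("st48_49", 0.0)):
            for i in range(10):
                vals_e = {isi: 1.0 + bump + r.normal(0, 0.15)
                          for isi in (50.0, 100.0, 200.0)}
                vals_i = {isi: 1.0 + r.normal(0, 0.15)
                          for isi in (50.0, 100.0, 200.0)}
                msis["excitatory"].append(
                    ConductanceMSI(f"{stage}{i}", "excitatory", stage, vals_e, 1.0))
                msis["inhibitory"].append(
                    ConductanceMSI(f"{stage}{i}", "inhibitory", stage, vals_i, 1.0))
        return msis

    def test_anova_df_identity(self):
        table = ei_stage_comparison(self._msis(0.5)["excitatory"])
        n_obs = 20 * 3
        assert table["df"].sum() == n_obs - 1

    def test_stage_effect_detected_only_for_affected_component(self):
        msis = self._msis(0.6)
        p_e = ei_stage_comparison(msis["excitatory"]).loc["C(stage)", "PR(>F)"]
        p_i = ei_stage_comparison(msis["inhibitory"]).loc["C(stage)", "PR(>F)"]
        assert p_e < 0.05 < p_i

    def test_identical_groups_give_zero_stage_f(self):
        vals = {50.0: 1.0, 100.0: 1.4, 200.0: 0.8}
        msis = [
            ConductanceMSI(f"{st}{i}", "excitatory", st,
                           {k: v + 0.1 * i for k, v in vals.items()}, 1.0)
            for st in ("st44_46", "st48_49")
            for i in range(4)
        ]
        table = ei_stage_comparison(msis)
        assert table.loc["C(stage)", "F"] == pytest.approx(0.0, abs=1e-10)

    def test_collinear_scatter_r_is_one(self):
        df = pd.DataFrame({
            "stage": ["a"] * 5 + ["b"] * 5,
            "max_inh_msin": list(range(5)) + list(range(5)),
            "max_exc_msin": [2.0 * v + 1 for v in range(5)] * 2,
        })
        out = ei_scatter_stats(df)
        assert out["per_stage"]["a"]["r"] == pytest.approx(1.0)
        assert out["slope_test"]["F"] == pytest.approx(0.0, abs=1e-9)

    def test_slope_contrast_detected(self, rng):
        x = rng.uniform(0, 3, 25)
        df = pd.DataFrame({
            "stage": ["a"] * 25 + ["b"] * 25,
            "max_inh_msin": np.concatenate([x, x]),
            "max_exc_msin": np.concatenate([
                2.0 * x + rng.normal(0, 0.1, 25),
                1.0 * x + rng.normal(0, 0.1, 25),
            ]),
        })
        out = ei_scatter_stats(df)
        assert out["slope_test"]["p"] < 0.01
        assert out["slope_test"]["df2"] == 50 - 4


class TestConductanceAnalysisEndToEnd:
    def test_stage_contrast_in_excitation_not_inhibition(self):
        """Generator with stage-dependent excitatory gain and shared
        inhibitory gain: the ANOVA localises the developmental change to
        the excitatory component, and E-I maxima correlate per stage."""
        from tectalmsi.synthetic import ProfileDistribution

        shared = ProfileDistribution(width_mean_ms=80.0, width_sd_ms=15.0,
                                     preferred_isi_choices=(50.0, 100.0, 200.0))
        kw = dict(isi_grid_ms=(50.0, 100.0, 200.0, 500.0), n_paired_trials=2,
                  profile_distribution=shared,
                  conductance_params=ConductanceParams(sampling_rate_hz=FS))
        young = generate_conductance_population(
            preset("st44_46", n_cells=14, seed=0, **kw),
            exc_gain_mean=1.6, inh_gain_mean=1.0)
        old = generate_conductance_population(
            preset("st48_49", n_cells=14, seed=1, **kw),
            exc_gain_mean=0.5, inh_gain_mean=1.0)
        res = ConductanceAnalysis(young + old).fit()
        assert res.stage_effect_p("excitatory") < 0.05
        assert res.stage_effect_p("inhibitory") > 0.05
        for st_, d in res.scatter_stats["per_stage"].items():
            assert d["r"] > 0.0
        assert res.scatter_stats["slope_test"]["df2"] == 28 - 4
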