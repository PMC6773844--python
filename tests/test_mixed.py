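import warnings

import numpy as np
import pytest

import topospect as ts
from topospect.mixed import (ConvergenceError, ModelError, ModelSpec,
                             default_ladder, design_matrix, effect_test,
                             fit_all_channels, fit_channel,
                             fit_random_intercept, lrt_pvalue, select_model)


class TestModelSpec:
    def test_interaction_requires_lower_order_terms(self):
        with pytest.raises(ModelError):
            ModelSpec(("HY_NC:NDE_AUTOBIO",))
        ModelSpec(("HY_NC", "NDE_AUTOBIO", "HY_NC:NDE_AUTOBIO"))  # ok

    def test_drop_removes_dependents(self):
        spec = ModelSpec(("HY_NC", "NDE_AUTOBIO", "HY_NC:NDE_AUTOBIO"))
        assert spec.drop("NDE_AUTOBIO").fixed_terms == ("HY_NC",)

    def test_unknown_term_rejected(self):
        with pytest.raises(ModelError):
            ModelSpec(("BANANA",))


class TestEngineAgreesWithStatsmodels:
    """The concentrated-ML fitter against MixedLM as independent oracle."""

    def _data(self, tau=0.6, seed=0):
        rng = np.random.default_rng(seed)
        n_part, per = 6, 40
        codes = np.repeat(np.arange(n_part), per)
        n = len(codes)
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n),
                             rng.normal(size=n)])
        beta = np.array([1.0, 0.5, -0.3])
        y = X @ beta + rng.normal(0, tau, n_part)[codes] + rng.normal(0, 1, n)
        return y, X, codes

    def test_loglik_coefficients_and_tvalues_match(self):
        from statsmodels.regression.mixed_linear_model import MixedLM

        y, X, codes = self._data()
        mine = fit_random_intercept(y, X, codes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sm = MixedLM(y, X, groups=codes).fit(reml=False)
        assert mine.llf == pytest.approx(sm.llf, abs=1e-5)
        np.testing.assert_allclose(mine.beta, sm.params[:3], atol=1e-5)
        np.testing.assert_allclose(mine.tvalues, np.asarray(sm.tvalues)[:3],
                                   atol=1e-3)
        assert mine.sigma2 == pytest.approx(sm.scale, rel=1e-3)
        assert mine.tau2 == pytest.approx(float(np.asarray(sm.cov_re)[0, 0]),
                                          rel=1e-2, abs=1e-4)

    def test_boundary_variance_handled(self):
        y, X, codes = self._data(tau=0.0, seed=3)
        fit = fit_random_intercept(y, X, codes)
        assert fit.converged
        assert fit.tau2 < 0.05


class TestFitChannel:
    def test_injected_coefficient_recovered(self, effect_table, full_spec,
                                            frontal_patch):
        fit = fit_channel(effect_table, frontal_patch[0], "alpha", full_spec)
        est = fit.fit.coef("NDE_AUTOBIO")
        se = fit.fit.bse[fit.fit.exog_names.index("NDE_AUTOBIO")]
        assert abs(est - 0.8) < 3 * se

    def test_null_pvalues_calibrated(self, small_layout):
        """Over 200 null single-channel fits the memory-effect LRT rejects
        at the nominal 5% rate."""
        lay = ts.build_layout(2)
        design = ts.scaled_design(block_minutes=1.0)
        spec = ModelSpec(("NDE_AUTOBIO",))
        rejections = 0
        for s in range(200):
            t = ts.simulate_window_table(
                design, lay, ts.SimulationParams(seed=5000 + s,
                                                 artifact_rate=0.0))
            fit = fit_channel(t, "E1", "alpha", spec)
            _, _, p = effect_test(fit, "NDE_AUTOBIO")
            rejections += p < 0.05
        assert 0.02 <= rejections / 200 <= 0.09

    def test_single_participant_rejected(self, small_layout):
        design = ts.StudyDesign((ts.Participant("P1", 50, 5),),
                                (ts.BlockDef("NC", "NDE", "PE", 120.0),
                                 ts.BlockDef("NC", "AUTOBIO", "KS", 120.0)))
        t = ts.simulate_window_table(design, small_layout,
                                     ts.SimulationParams(seed=0))
        with pytest.raises(ModelError):
            fit_channel(t, "E1", "alpha", ModelSpec(("NDE_AUTOBIO",)))

    def test_row_order_invariance(self, effect_table, full_spec):
        shuffled = effect_table.sample(frac=1.0, random_state=0)
        a = fit_channel(effect_table, "E1", "alpha", full_spec)
        b = fit_channel(shuffled, "E1", "alpha", full_spec)
        np.testing.assert_allclose(np.sort(a.fit.tvalues),
                                   np.sort(b.fit.tvalues), atol=1e-6)
        assert a.fit.llf == pytest.approx(b.fit.llf, abs=1e-6)


class TestEffectTest:
    def test_chi2_nonnegative_and_df_matches_param_difference(
            self, null_table, full_spec):
        fit = fit_channel(null_table, "E1", "alpha", full_spec)
        chi2, dof, p = effect_test(fit, "HY_NC:NDE_AUTOBIO:OBE_PE")
        assert chi2 >= 0 and dof == 1 and 0 < p <= 1

    def test_nesting_never_hurts_likelihood(self, null_table, full_spec):
        full = fit_channel(null_table, "E1", "alpha", full_spec)
        nested = fit_channel(null_table, "E1", "alpha",
                             full_spec.drop("HY_NC:NDE_AUTOBIO:OBE_PE"))
        assert full.fit.llf >= nested.fit.llf - 1e-8

    def test_identical_likelihoods_give_unit_p(self):
        assert lrt_pvalue(0.0, 1) == 1.0

    @pytest.mark.parametrize("chi2,dof,expected", [(8.318, 1, 0.004),
                                                   (4.959, 1, 0.026)])
    def test_upper_tail_mapping(self, chi2, dof, expected):
        assert round(lrt_pvalue(chi2, dof), 3) == expected

    def test_absent_term_rejected(self, null_table):
        fit = fit_channel(null_table, "E1", "alpha", ModelSpec(("HY_NC",)))
        with pytest.raises(ModelError):
            effect_test(fit, "NDE_AUTOBIO")


class TestModelSelection:
    def test_strong_interaction_data_selects_full_model(self, small_layout):
        effects = (
            ts.EffectSpec("alpha", 1.0, {"memory": "NDE"}),
            ts.EffectSpec("alpha", 1.0, {"state": "HY"}),
            ts.EffectSpec("alpha", 1.0, {"phase": "PE"}),
            # strong three-way structure: an extra shift only for HY-NDE-PE
            ts.EffectSpec("alpha", 1.5, {"state": "HY", "memory": "NDE",
                                         "phase": "PE"}),
        )
        t = ts.simulate_window_table(
            ts.scaled_design(), small_layout,
            ts.SimulationParams(seed=31, band_effects=effects,
                                window_noise_sd=0.3, artifact_rate=0.0))
        spec = select_model(t, "E1", "alpha", default_ladder(covariates=False))
        assert "HY_NC:NDE_AUTOBIO:OBE_PE" in spec.fixed_terms

    def test_null_data_selects_baseline(self, small_layout):
        t = ts.simulate_window_table(
            ts.scaled_design(), small_layout,
            ts.SimulationParams(seed=32, artifact_rate=0.0))
        spec = select_model(t, "E1", "alpha", default_ladder(covariates=False))
        assert spec.fixed_terms == ()

    def test_aic_tie_prefers_simpler(self, monkeypatch, null_table):
        import topospect.mixed as mixed

        ladder = [ModelSpec(()), ModelSpec(("HY_NC",))]
        calls = {}

        class Dummy:
            aic = 100.0

        def fake_fit(table, ch, band, spec):
            calls[spec.fixed_terms] = True
            return Dummy()

        monkeypatch.setattr(mixed, "fit_channel", fake_fit)
        chosen = mixed.select_model(null_table, "E1", "alpha", ladder)
        assert chosen.fixed_terms == ()


class TestFitAllChannels:
    def test_effect_channels_carry_largest_t(self, effect_table, full_spec,
                                             frontal_patch):
        fits = fit_all_channels(effect_table, "alpha", full_spec)
        tmap = fits.tmap("NDE_AUTOBIO")
        top4 = [tmap.channels[i]
                for i in np.argsort(np.abs(tmap.values))[-4:]]
        assert set(top4) == set(frontal_patch)

    def test_null_tmap_roughly_symmetric(self, small_layout, full_spec):
        vals = []
        for s in range(30):
            t = ts.simulate_window_table(
                ts.scaled_design(), small_layout,
                ts.SimulationParams(seed=6000 + s, artifact_rate=0.0))
            fits = fit_all_channels(t, "alpha", full_spec)
            vals.extend(fits.tmap("NDE_AUTOBIO").values)
        vals = np.asarray(vals)
        assert abs(np.mean(vals)) < 3 * np.std(vals) / np.sqrt(len(vals))

    def test_zero_variance_outcome_is_hard_error(self, null_table, full_spec):
        t = null_table.copy()
        t["power"] = 1.0
        with pytest.raises(ConvergenceError):
            fit_all_channels(t, "alpha", full_spec)


def test_design_matrix_codes_factors_as_indicators(null_table):
    df = null_table[(null_table.channel == "E1")
                    & (null_table.band == "alpha")]
    X, names = design_matrix(df, ModelSpec(("HY_NC", "NDE_AUTOBIO",
                                            "OBE_PE", "age", "shss")))
    assert names[0] == "Intercept"
    hy = X[:, names.index("HY_NC")]
    assert set(np.unique(hy)) == {0.0, 1.0}
    np.testing.assert_allclose(hy, (df["state"] == "HY").to_numpy(float))
    # covariates are z-scored
    assert abs(X[:, names.index("age")].mean()) < 1e-9
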