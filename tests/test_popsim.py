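import numpy as np
import pytest

from pilotbe.popsim import (
    DEFAULT_SAMPLING_TIMES,
    PopulationModel,
    TrialDesign,
    apply_residual_error,
    cv_to_log_sd,
    draw_individual_parameters,
    predict_concentration,
    randomize_sequences,
    simulate_trial,
)

from conftest import analytic_auc_0_to_t, make_noise_free_trial, ode_concentrations


class TestPredictConcentration:
    def test_zero_at_dose_time(self):
        c = predict_concentration(1.22, 58.8, 0.15, 0.9, 50, [0.0])
        assert c[0] == 0.0

    def test_matches_stiff_ode_oracle_at_reference_peak(self):
        # continuous peak time ln(ka/ke)/(ka-ke)
        tpk = np.log(1.22 / 0.15) / (1.22 - 0.15)
        c = predict_concentration(1.22, 58.8, 0.15, 0.9, 50, [tpk])
        c_ode, _ = ode_concentrations(1.22, 58.8, 0.15, 0.9, 50, [0.0, tpk])
        assert c[0] == pytest.approx(c_ode[-1], rel=1e-6)
        assert c[0] == pytest.approx(570.4, rel=1e-3)

    def test_slow_absorption_peak_ratio(self):
        # test product with ka scaled to 0.3x peaks later and ~28% lower
        ka_t = 0.3 * 1.22
        tpk = np.log(ka_t / 0.15) / (ka_t - 0.15)
        c_test = predict_concentration(ka_t, 58.8, 0.15, 0.9, 50, [tpk])[0]
        c_ode, _ = ode_concentrations(ka_t, 58.8, 0.15, 0.9, 50, [0.0, tpk])
        assert c_test == pytest.approx(c_ode[-1], rel=1e-6)
        assert c_test == pytest.approx(411.9, rel=1e-3)
        assert c_test / 570.4 == pytest.approx(0.722, abs=5e-3)

    def test_agrees_with_ode_over_random_parameter_sets(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            ka = rng.uniform(0.2, 3.0)
            ke = rng.uniform(0.05, 0.5)
            if abs(ka - ke) < 1e-3:
                continue
            v = rng.uniform(20, 200)
            f = rng.uniform(0.3, 1.0)
            closed = predict_concentration(ka, v, ke, f, 50, DEFAULT_SAMPLING_TIMES)
            ode, _ = ode_concentrations(ka, v, ke, f, 50, DEFAULT_SAMPLING_TIMES)
            np.testing.assert_allclose(closed[1:], ode[1:], rtol=1e-6)

    def test_ode_oracle_mass_balance(self):
        _, y = ode_concentrations(1.22, 58.8, 0.15, 0.9, 50, DEFAULT_SAMPLING_TIMES)
        total = y.sum(axis=0)
        np.testing.assert_allclose(total, 0.9 * 50_000.0, rtol=1e-8)

    def test_ka_equals_ke_analytic_limit(self):
        t = np.array([0.5, 1.0, 2.0])
        c = predict_concentration(0.5, 50.0, 0.5, 1.0, 50, t)
        expected = 50_000.0 * 0.5 * t * np.exp(-0.5 * t) / 50.0
        np.testing.assert_allclose(c, expected, rtol=1e-12)
        # and it is the continuous limit of nearby ka
        near = predict_concentration(0.5 + 1e-9, 50.0, 0.5, 1.0, 50, t)
        np.testing.assert_allclose(c, near, rtol=1e-6)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            predict_concentration(1.0, 50, 0.1, 0.9, 50, [-1.0])


class TestRandomEffects:
    def test_degenerate_variability_returns_means(self):
        model = PopulationModel(test_ka_multiplier=0.3, varying_parameter="ka")
        design = TrialDesign(n_subjects=4)
        rng = np.random.default_rng(0)
        params = draw_individual_parameters(model, design, ["TR", "RT", "TR", "RT"], rng)
        for p in params:
            mult = 0.3 if p.treatment == "test" else 1.0
            assert p.ka == pytest.approx(model.ka_mean * mult)
            assert p.v == model.v_mean and p.ke == model.ke_mean and p.f == model.f_mean

    def test_iiv_moment_recovery_and_occasion_constancy(self):
        model = PopulationModel(iiv_cv=30, varying_parameter="V")
        design = TrialDesign(n_subjects=10_000)
        rng = np.random.default_rng(1)
        seqs = ["TR", "RT"] * 5_000
        params = draw_individual_parameters(model, design, seqs, rng)
        logv_occ1 = np.array([np.log(p.v) for p in params if p.occasion == 1])
        logv_occ2 = np.array([np.log(p.v) for p in params if p.occasion == 2])
        np.testing.assert_allclose(logv_occ1, logv_occ2)  # eta only, no kappa
        assert logv_occ1.std(ddof=1) == pytest.approx(0.30, abs=0.01)

    def test_iov_draws_independent_across_occasions(self):
        model = PopulationModel(iov_cv=45, varying_parameter="V")
        design = TrialDesign(n_subjects=10_000)
        rng = np.random.default_rng(2)
        seqs = ["TR", "RT"] * 5_000
        params = draw_individual_parameters(model, design, seqs, rng)
        logv1 = np.array([np.log(p.v) for p in params if p.occasion == 1])
        logv2 = np.array([np.log(p.v) for p in params if p.occasion == 2])
        assert abs(np.corrcoef(logv1, logv2)[0, 1]) < 0.03
        assert logv1.std(ddof=1) == pytest.approx(0.45, abs=0.02)

    def test_cv_mapping_conventions(self):
        assert cv_to_log_sd(30) == 0.30
        assert cv_to_log_sd(30, exact=True) == pytest.approx(np.sqrt(np.log(1.09)))
        with pytest.raises(ValueError):
            cv_to_log_sd(-1)


class TestResidualError:
    def test_zero_cv_is_identity(self):
        rng = np.random.default_rng(0)
        c = np.array([0.0, 10.0, 20.0])
        np.testing.assert_array_equal(apply_residual_error(c, 0.0, rng), c)

    def test_zero_concentration_stays_zero(self):
        rng = np.random.default_rng(0)
        out = apply_residual_error([0.0, 5.0], 25.0, rng)
        assert out[0] == 0.0 and out[1] != 5.0

    def test_lognormal_moment_recovery(self):
        rng = np.random.default_rng(3)
        out = apply_residual_error(np.full(100_000, 100.0), 10.0, rng)
        logs = np.log(out)
        assert logs.std(ddof=1) == pytest.approx(0.10, abs=0.002)
        assert np.exp(logs.mean()) == pytest.approx(100.0, rel=0.005)


class TestRandomization:
    def test_balanced_allocation(self):
        seqs = randomize_sequences(12, np.random.default_rng(0))
        assert seqs.count("TR") == seqs.count("RT") == 6

    def test_deterministic_given_seed(self):
        a = randomize_sequences(12, np.random.default_rng(11))
        b = randomize_sequences(12, np.random.default_rng(11))
        assert a == b

    def test_block_orders_equifrequent(self):
        rng = np.random.default_rng(4)
        firsts = [randomize_sequences(12, rng)[0] for _ in range(1000)]
        frac_tr = firsts.count("TR") / 1000
        assert 0.45 < frac_tr < 0.55

    def test_odd_n_rejected(self):
        with pytest.raises(ValueError):
            randomize_sequences(11, np.random.default_rng(0))


class TestSimulateTrial:
    def test_bookkeeping(self, baseline_trial):
        data = baseline_trial.data
        assert len(data) == 12 * 2 * 20
        assert (data.loc[data.time_h == 0.0, "conc_ug_L"] == 0.0).all()
        per_subject = data.groupby("subject_id").size()
        assert (per_subject == 40).all()
        assert set(data["sequence"]) == {"TR", "RT"}

    def test_noise_free_be_trial_has_identical_treatments(self, noise_free_be_trial):
        data = noise_free_be_trial.data
        wide = data.pivot_table(
            index=["subject_id", "time_h"], columns="treatment", values="conc_ug_L"
        )
        np.testing.assert_allclose(wide["test"], wide["reference"], rtol=1e-12)

    def test_truth_label_follows_multiplier(self, noise_free_bie_trial):
        assert noise_free_bie_trial.truth_label == "truly-bioinequivalent"

    def test_bie_auc_infinity_preserved_in_closed_form(self):
        # F, V, ke equal for both products, so AUC(0, inf) = F*D/(V*ke) for each
        auc_inf = 0.9 * 50_000.0 / (58.8 * 0.15)
        for ka in (1.22, 0.3 * 1.22):
            big_t = 400.0
            approx = analytic_auc_0_to_t(ka, 58.8, 0.15, 0.9, 50, big_t)
            assert approx == pytest.approx(auc_inf, rel=1e-9)

    def test_reproducible_for_fixed_seed(self, baseline_model, design12):
        t1 = simulate_trial(baseline_model, design12, 99)
        t2 = simulate_trial(baseline_model, design12, 99)
        np.testing.assert_array_equal(t1.data["conc_ug_L"], t2.data["conc_ug_L"])

    def test_csv_round_trip(self, baseline_trial, tmp_path):
        from pilotbe.popsim import TrialDataset

        path = tmp_path / "trial.csv"
        baseline_trial.to_csv(path)
        back = TrialDataset.from_csv(path, truth_label=baseline_trial.truth_label)
        np.testing.assert_allclose(back.data["conc_ug_L"], baseline_trial.data["conc_ug_L"])
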