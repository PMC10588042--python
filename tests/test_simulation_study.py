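import numpy as np
import pandas as pd
import pytest

from emaxdesign import (EmaxParams, EnsembleGenConfig, ParamEnsemble,
                        Scenario, efficient_rounding, equidistant_design,
                        eval_emax, filter_ensemble, fit_sigmoid_emax,
                        generate_parameter_ensemble, nrmse, rmse_curve,
                        run_study, simulate_responses, theta7_ensemble)
from emaxdesign.simulation_study import GridCell, vpa_default_cells


class TestEnsembleGenerator:
    def test_reproducible_from_seed(self):
        cfg = EnsembleGenConfig(n_curves=50, seed=42)
        assert generate_parameter_ensemble(cfg) == \
            generate_parameter_ensemble(cfg)

    def test_degenerate_cells_hit_representative_values_exactly(self):
        from emaxdesign.optimal_design import THETA7_TABLE
        total = sum(r[3] for r in THETA7_TABLE)
        cells = tuple(GridCell(ec50, ec50, h, h, pi / total)
                      for _, ec50, h, pi in THETA7_TABLE)
        ens = generate_parameter_ensemble(
            EnsembleGenConfig(n_curves=7, cells=cells, seed=3))
        table = {(r[1], r[2]) for r in THETA7_TABLE}
        for theta in ens.thetas:
            assert (theta.ec50, theta.h) in table
            assert theta.e0 == 1.0 and theta.emax == -1.0

    def test_cell_frequencies_follow_probabilities(self):
        cfg = EnsembleGenConfig(n_curves=10000, seed=9)
        ens = generate_parameter_ensemble(cfg)
        pts = np.array([(t.ec50, t.h) for t in ens.thetas])
        for cell in cfg.cells:
            inside = ((pts[:, 0] >= cell.ec50_lo) &
                      (pts[:, 0] <= cell.ec50_hi) &
                      (pts[:, 1] >= cell.h_lo) & (pts[:, 1] <= cell.h_hi))
            assert abs(inside.mean() - cell.prob) < 0.02

    def test_slope_point_mass_near_target_share(self):
        ens = generate_parameter_ensemble(
            EnsembleGenConfig(n_curves=5000, seed=11))
        share = np.mean([t.h == 10.0 for t in ens.thetas])
        assert 0.25 < share < 0.40      # empirical boundary share ~32%

    def test_default_cells_are_a_probability_table(self):
        assert sum(c.prob for c in vpa_default_cells()) == \
            pytest.approx(1.0, abs=1e-12)


class TestFilterEnsemble:
    def test_inadmissible_ec50_removed_and_prior_renormalized(self):
        thetas = (EmaxParams(1, -1, 500, 4), EmaxParams(1, -1, 1200, 4),
                  EmaxParams(1, -1, 300, 2))
        ens = ParamEnsemble(("a", "b", "c"), thetas, (0.5, 0.25, 0.25))
        out = filter_ensemble(ens)
        assert out.labels == ("a", "c")
        assert sum(out.prior) == pytest.approx(1.0)
        assert out.prior[0] == pytest.approx(2 / 3)

    def test_admissible_ensemble_unchanged(self, theta7):
        assert filter_ensemble(theta7) == theta7

    def test_all_removed_is_an_error(self):
        ens = ParamEnsemble.singleton(EmaxParams(1, -1, 1200, 4))
        with pytest.raises(ValueError):
            filter_ensemble(ens)


class TestSimulateResponses:
    def test_zero_noise_lies_on_curve(self, theta4):
        ex = efficient_rounding(equidistant_design(9), 27)
        data = simulate_responses(ex, theta4, 0.0, 1)
        assert len(data) == 27
        expected = eval_emax(data["concentration"].to_numpy(), theta4)
        assert np.allclose(data["response"], expected)

    def test_sample_mean_concentrates_on_curve(self, theta4):
        from emaxdesign import ExactDesign
        ex = ExactDesign((0.0, 500.0, 700.0, 1000.0), (10000, 1, 1, 1))
        data = simulate_responses(ex, theta4, 1.0, 7)
        at0 = data.loc[data["concentration"] == 0, "response"]
        assert abs(at0.mean() - theta4.e0) < 3 / 100

    def test_reproducible(self, theta4):
        ex = efficient_rounding(equidistant_design(9), 27)
        a = simulate_responses(ex, theta4, 0.3, 5)
        b = simulate_responses(ex, theta4, 0.3, 5)
        pd.testing.assert_frame_equal(a, b)


class TestFit:
    def test_noiseless_recovery(self, theta4):
        ex = efficient_rounding(equidistant_design(9), 27)
        fit = fit_sigmoid_emax(simulate_responses(ex, theta4, 0.0, 1))
        assert abs(fit.ec50 - theta4.ec50) / theta4.ec50 < 1e-3
        assert abs(fit.h - theta4.h) / theta4.h < 1e-3
        assert fit.e0 == pytest.approx(theta4.e0, abs=1e-4)
        assert fit.emax == pytest.approx(theta4.emax, abs=1e-4)

    def test_slope_clipped_at_upper_bound(self):
        steep = EmaxParams(1, -1, 469.36, 12.0)
        ex = efficient_rounding(equidistant_design(9), 27)
        fit = fit_sigmoid_emax(simulate_responses(ex, steep, 0.0, 1))
        assert fit.h == pytest.approx(10.0)

    def test_constant_data_gives_flat_curve(self):
        data = pd.DataFrame({"concentration": [0, 100, 500, 1000] * 3,
                             "response": [2.0] * 12})
        fit = fit_sigmoid_emax(data)
        assert eval_emax(0.0, fit) == pytest.approx(2.0, abs=1e-6)
        assert abs(fit.emax) < 1e-6 or np.allclose(
            eval_emax(np.linspace(0, 1000, 20), fit), 2.0, atol=1e-5)

    def test_too_few_concentrations_rejected(self):
        data = pd.DataFrame({"concentration": [0, 100, 500] * 3,
                             "response": np.arange(9.0)})
        with pytest.raises(ValueError):
            fit_sigmoid_emax(data)


class TestErrorMeasures:
    def test_identical_curves_have_zero_rmse(self, theta4):
        assert rmse_curve(theta4, theta4) == 0.0

    def test_baseline_shift_gives_exact_rmse(self, theta4):
        shifted = EmaxParams(theta4.e0 + 0.37, theta4.emax, theta4.ec50,
                             theta4.h)
        assert rmse_curve(shifted, theta4) == pytest.approx(0.37, abs=1e-12)

    def test_matches_loop_summation_oracle(self, theta4, theta5):
        total = 0.0
        for x in range(1001):
            total += (eval_emax(float(x), theta5)
                      - eval_emax(float(x), theta4)) ** 2
        oracle = (total / 1001) ** 0.5
        assert rmse_curve(theta5, theta4) == pytest.approx(oracle, rel=1e-12)

    def test_nrmse_standardizes_by_response_range(self):
        assert nrmse(2.0, EmaxParams(0, 4, 100, 2)) == pytest.approx(0.5)
        assert nrmse(2.0, EmaxParams(0, 10, 100, 2)) == pytest.approx(0.2)
        assert nrmse(0.2, EmaxParams(0, -1, 100, 2)) == pytest.approx(0.2)
        with pytest.raises(ValueError):
            nrmse(1.0, EmaxParams(0, 0.0, 100, 2))


class TestRunStudy:
    def test_noise_free_study_recovers_all_curves(self, theta7):
        sc = Scenario("equi", equidistant_design(9), 27, n_sim=1,
                      sigma_factor=0.0, seed=1)
        res = run_study([sc], theta7)[0]
        assert max(res.nrmse_values) < 1e-4

    def test_bit_reproducible(self, theta7):
        sc = Scenario("equi", equidistant_design(9), 27, n_sim=5, seed=2)
        a = run_study([sc], theta7)[0]
        b = run_study([sc], theta7)[0]
        assert a.nrmse_values == b.nrmse_values

    def test_summary_and_outlier_trimming(self, theta7):
        sc = Scenario("equi", equidistant_design(9), 27, n_sim=5, seed=2)
        res = run_study([sc], theta7)[0]
        s = res.summary()
        assert s["min"] <= s["q25"] <= s["median"] <= s["q75"] <= s["max"]
        trimmed = res.summary(drop_outliers=True)
        assert trimmed["max"] <= s["max"]

    def test_scenario_validation(self):
        with pytest.raises(ValueError):
            Scenario("bad", equidistant_design(9), 8, n_sim=1)
        with pytest.raises(ValueError):
            Scenario("bad", equidistant_design(9), 27, n_sim=0)
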