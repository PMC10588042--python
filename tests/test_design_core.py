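import numpy as np
import pytest

from emaxdesign import (Design, EmaxParams, SingularDesignError, d_criterion,
                        d_efficiency, grad_emax, info_matrix, sensitivity_d,
                        sensitivity_s)
from emaxdesign.optimal_design import ParamEnsemble

from conftest import random_admissible_theta


def four_point_design():
    return Design((0.0, 200.0, 500.0, 1000.0), (0.25,) * 4)


class TestDesignContainer:
    def test_validation(self):
        with pytest.raises(ValueError):
            Design((0.0, 100.0), (0.5, 0.6))            # weights not normed
        with pytest.raises(ValueError):
            Design((100.0, 100.0), (0.5, 0.5))          # not increasing
        with pytest.raises(ValueError):
            Design((0.0, 2000.0), (0.5, 0.5))           # outside range
        with pytest.raises(ValueError):
            Design((0.0, 100.0), (1.1, -0.1))           # negative weight

    def test_create_merges_and_renormalizes(self):
        xi = Design.create([500.0, 0.0, 500.0 + 1e-9], [0.2, 0.2, 0.2])
        assert xi.n_points == 2
        assert xi.weights == pytest.approx((1 / 3, 2 / 3))

    def test_cleaned_prunes_small_weights(self):
        xi = Design((0.0, 500.0, 1000.0), (0.49995, 5e-5, 0.5))
        out = xi.cleaned(prune_tol=1e-4)
        assert out.n_points == 2
        assert sum(out.weights) == pytest.approx(1.0)

    def test_csv_roundtrip(self, tmp_path):
        xi = four_point_design()
        path = tmp_path / "design.csv"
        xi.to_csv(path)
        back = Design.from_csv(path)
        assert back.support == pytest.approx(xi.support)
        assert back.weights == pytest.approx(xi.weights)

    def test_csv_rejects_unnormalized_weights(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("concentration,weight\n0,0.5\n100,0.6\n")
        with pytest.raises(ValueError):
            Design.from_csv(path)

    def test_json_roundtrip(self, tmp_path):
        xi = four_point_design()
        path = tmp_path / "design.json"
        xi.to_json(path)
        assert Design.from_json(path) == xi


class TestInfoMatrix:
    def test_one_point_design_is_rank_one(self, theta4):
        xi = Design((300.0,), (1.0,))
        m = info_matrix(xi, theta4)
        assert np.linalg.matrix_rank(m, tol=1e-10) == 1
        assert np.linalg.det(m) == pytest.approx(0.0, abs=1e-15)

    def test_matches_outer_product_summation_oracle(self, theta4):
        xi = four_point_design()
        m = info_matrix(xi, theta4)
        oracle = np.zeros((4, 4))
        for x, w in zip(xi.support, xi.weights):
            g = grad_emax(x, theta4)
            for a in range(4):
                for b in range(4):
                    oracle[a, b] += w * g[a] * g[b]
        assert np.allclose(m, oracle, rtol=1e-12)

    def test_always_psd(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            theta = random_admissible_theta(rng)
            n = rng.integers(1, 7)
            sup = np.sort(rng.uniform(0, 1000, n))
            sup += np.arange(n) * 1e-6          # enforce strict increase
            w = rng.dirichlet(np.ones(n))
            xi = Design.create(sup, w)
            eig = np.linalg.eigvalsh(info_matrix(xi, theta))
            assert eig.min() >= -1e-10

    def test_emax_scaling_multiplies_det_by_c4(self, theta4):
        xi = four_point_design()
        c = 2.7
        scaled = EmaxParams(theta4.e0, c * theta4.emax, theta4.ec50, theta4.h)
        d1 = np.linalg.det(info_matrix(xi, theta4))
        d2 = np.linalg.det(info_matrix(xi, scaled))
        assert d2 == pytest.approx(c ** 4 * d1, rel=1e-9)


class TestDCriterion:
    def test_rank_deficient_designs_score_zero(self, theta4):
        xi3 = Design((0.0, 300.0, 1000.0), (1 / 3,) * 3)
        assert d_criterion(xi3, theta4) == 0.0

    def test_emax_scaling_is_linear(self, theta4):
        xi = four_point_design()
        scaled = EmaxParams(theta4.e0, 3.0 * theta4.emax, theta4.ec50,
                            theta4.h)
        assert d_criterion(xi, scaled) == pytest.approx(
            3.0 * d_criterion(xi, theta4), rel=1e-9)

    def test_determinant_log_concavity(self):
        # det((M1+M2)/2) >= sqrt(det M1 * det M2) for PSD matrices
        rng = np.random.default_rng(23)
        for _ in range(20):
            theta = random_admissible_theta(rng)
            xs = np.sort(rng.uniform(0, 1000, (2, 5)), axis=1)
            xs += np.arange(5) * 1e-6
            m = [info_matrix(Design.create(x, rng.dirichlet(np.ones(5))),
                             theta) for x in xs]
            lhs = np.linalg.det((m[0] + m[1]) / 2)
            # determinants of PSD matrices: clip roundoff negatives
            d0, d1 = (max(np.linalg.det(mi), 0.0) for mi in m)
            rhs = np.sqrt(d0 * d1)
            assert lhs >= rhs - 1e-12 * max(abs(lhs), 1.0)


class TestSensitivity:
    def test_weighted_average_over_support_is_zero(self, theta4):
        # sum_i w_i d(x_i) = tr(M^-1 M) - p = 0 for any nonsingular design
        xi = Design((0.0, 150.0, 400.0, 700.0, 1000.0), (0.2,) * 5)
        vals = sensitivity_d(xi.support_array(), xi, theta4)
        assert float(np.dot(xi.weights_array(), vals)) == pytest.approx(
            0.0, abs=1e-8)

    def test_singular_design_raises(self, theta4):
        xi3 = Design((0.0, 300.0, 1000.0), (1 / 3,) * 3)
        with pytest.raises(SingularDesignError):
            sensitivity_d(500.0, xi3, theta4)

    def test_singleton_ensemble_reduces_to_weighted_local(self, theta4,
                                                          local_opts7):
        ens = ParamEnsemble.singleton(theta4, "t")
        xi = four_point_design()
        ref = {"t": local_opts7["theta4"]}
        x = np.array([0.0, 123.0, 456.0, 789.0])
        eff = d_efficiency(xi, theta4, ref["t"])
        expected = eff * sensitivity_d(x, xi, theta4)
        assert np.allclose(sensitivity_s(x, xi, ens, ref), expected)

    def test_ensemble_sensitivity_names_singular_member(self, theta7,
                                                        local_opts7):
        xi3 = Design((0.0, 300.0, 1000.0), (1 / 3,) * 3)
        with pytest.raises(SingularDesignError, match="theta1"):
            sensitivity_s(500.0, xi3, theta7, local_opts7)


class TestEfficiency:
    def test_self_efficiency_is_one(self, theta4, local_opts7):
        opt = local_opts7["theta4"]
        assert d_efficiency(opt, theta4, opt) == pytest.approx(1.0)

    def test_singular_design_has_zero_efficiency(self, theta4, local_opts7):
        xi3 = Design((0.0, 300.0, 1000.0), (1 / 3,) * 3)
        assert d_efficiency(xi3, theta4, local_opts7["theta4"]) == 0.0

    def test_invariant_to_linear_parameters(self, local_opts7):
        rng = np.random.default_rng(31)
        xi = four_point_design()
        opt = local_opts7["theta4"]
        for _ in range(10):
            e0, emax = rng.uniform(-5, 5), rng.choice([-1, 1]) * \
                rng.uniform(0.1, 10)
            theta = EmaxParams(e0, emax, 469.36, 4.0)
            base = d_efficiency(xi, EmaxParams(1, -1, 469.36, 4.0), opt)
            assert d_efficiency(xi, theta, opt) == pytest.approx(
                base, rel=1e-9)

    def test_zero_reference_rejected(self, theta4):
        xi3 = Design((0.0, 300.0, 1000.0), (1 / 3,) * 3)
        with pytest.raises(ValueError):
            d_efficiency(four_point_design(), theta4, xi3)
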