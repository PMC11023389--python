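"""The variance decomposition chain: regression Jacobian, null space,
projection, variance components, synergy index and summaries."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ucmthrow import (
    ArmModel,
    SynergyDecomposition,
    TrialEnsemble,
    estimate_jacobian,
    group_synergy,
    index_of_synergy,
    mean_free,
    null_space_basis,
    position_jacobian_fd,
    project_deviations,
    proportion_above,
    pv_timeseries,
    variance_components,
)
from ucmthrow.ucm import ALL_PERFORMANCE_VARIABLES, VarianceProfile, get_pv_spec


class TestMeanFree:
    def test_identical_trials_zero_deviations(self):
        angles = np.tile(np.linspace(0, 50, 700).reshape(100, 7), (5, 1, 1))
        theta0, dev = mean_free(TrialEnsemble(angles))
        assert np.allclose(dev, 0)
        assert np.allclose(theta0, angles[0])

    def test_two_symmetric_trials(self):
        base = np.zeros((2, 10, 7))
        a = 3.0
        base[0] += a
        base[1] -= a
        _, dev = mean_free(TrialEnsemble(base))
        assert np.allclose(dev[0], a) and np.allclose(dev[1], -a)

    def test_reconstruction_identity(self, small_ensemble):
        theta0, dev = mean_free(small_ensemble)
        assert np.allclose(theta0 + dev, small_ensemble.angles)
        assert np.abs(dev.sum(axis=0)).max() < 1e-10


class TestJacobianRegression:
    def test_exact_on_noiseless_linear_map_e1(self, rng):
        dev = rng.normal(size=(20, 7))
        dev -= dev.mean(axis=0)
        w = np.array([[1.0, 0, 0, 0, 0, 0, 0]])
        J = estimate_jacobian(dev, dev @ w.T)
        assert np.allclose(J, w, atol=1e-10)

    def test_zero_pv_gives_zero_jacobian(self, rng):
        dev = rng.normal(size=(15, 7))
        J = estimate_jacobian(dev, np.zeros((15, 2)))
        assert np.allclose(J, 0)

    def test_sum_of_angles_gives_row_of_ones(self, rng):
        dev = rng.normal(size=(25, 7))
        dev -= dev.mean(axis=0)
        J = estimate_jacobian(dev, dev.sum(axis=1, keepdims=True))
        assert np.allclose(J, 1.0, atol=1e-10)

    def test_underdetermined_rejected(self, rng):
        with pytest.raises(ValueError):
            estimate_jacobian(rng.normal(size=(7, 7)), rng.normal(size=(7, 1)))

    def test_rank_deficient_warns_minimum_norm(self, rng):
        dev = rng.normal(size=(20, 7))
        dev[:, 6] = dev[:, 0]  # collinear predictors
        with pytest.warns(UserWarning, match="rank-deficient"):
            estimate_jacobian(dev, dev[:, :1])


class TestNullSpace:
    def test_hand_checkable_row(self):
        J = np.array([[1.0, 1, 0, 0, 0, 0, 0]])
        basis = null_space_basis(J)
        assert basis.shape == (7, 6)
        assert np.abs(J @ basis).max() < 1e-12
        assert np.allclose(basis.T @ basis, np.eye(6), atol=1e-10)
        # the (1,-1)/sqrt(2) direction lies in the span
        v = np.zeros(7)
        v[0], v[1] = 1 / np.sqrt(2), -1 / np.sqrt(2)
        assert np.allclose(basis @ (basis.T @ v), v, atol=1e-12)

    def test_orthonormal_rows_leave_remaining_axes(self):
        J = np.eye(3, 7)
        basis = null_space_basis(J)
        assert basis.shape == (7, 4)
        assert np.allclose(np.abs(basis[:3]).max(), 0, atol=1e-12)

    def test_random_full_rank(self, rng):
        J = rng.normal(size=(3, 7))
        basis = null_space_basis(J)
        assert basis.shape == (7, 4)
        assert np.abs(J @ basis).max() < 1e-10
        assert np.allclose(basis.T @ basis, np.eye(4), atol=1e-10)

    def test_rank_deficient_widens_basis(self):
        J = np.vstack([np.ones(7), np.ones(7), np.zeros(7)])
        assert null_space_basis(J).shape == (7, 6)

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            null_space_basis(np.full((1, 7), np.nan))


class TestProjection:
    def test_in_span_has_zero_perp(self, rng):
        basis = null_space_basis(rng.normal(size=(1, 7)))
        dev = rng.normal(size=(10, 6)) @ basis.T
        par, perp = project_deviations(dev, basis)
        assert np.abs(perp).max() < 1e-10
        assert np.allclose(par, dev)

    def test_orthogonal_has_zero_par(self, rng):
        J = rng.normal(size=(1, 7))
        basis = null_space_basis(J)
        dev = np.outer(rng.normal(size=8), J[0])
        par, _ = project_deviations(dev, basis)
        assert np.abs(par).max() < 1e-10

    def test_two_dof_hand_projection(self):
        basis = np.array([[1.0], [-1.0]]) / np.sqrt(2)
        par, perp = project_deviations(np.array([[1.0, 0.0]]), basis)
        assert np.allclose(par, [[0.5, -0.5]])
        assert np.allclose(perp, [[0.5, 0.5]])

    def test_idempotent_and_orthogonal(self, rng):
        basis = null_space_basis(rng.normal(size=(3, 7)))
        dev = rng.normal(size=(20, 7))
        par, perp = project_deviations(dev, basis)
        par2, perp2 = project_deviations(par, basis)
        assert np.allclose(par2, par) and np.abs(perp2).max() < 1e-10
        assert np.abs(np.sum(par * perp, axis=1)).max() < 1e-10

    def test_non_orthonormal_basis_rejected(self, rng):
        with pytest.raises(ValueError):
            project_deviations(rng.normal(size=(5, 7)), 2 * np.eye(7, 3))


class TestVarianceComponents:
    def test_hand_computation_toy(self):
        par = np.array([[1.0, -1.0], [-1.0, 1.0]])
        perp = np.zeros((2, 2))
        v_ucm, v_ort = variance_components(par, perp, n=2, d=1)
        assert v_ucm == pytest.approx(2.0)
        assert v_ort == 0.0

    def test_zero_deviations(self):
        v_ucm, v_ort = variance_components(np.zeros((4, 7)), np.zeros((4, 7)), d=3)
        assert (v_ucm, v_ort) == (0.0, 0.0)

    @given(st.floats(0.1, 10.0))
    def test_quadratic_scaling(self, c):
        rng = np.random.default_rng(9)
        par = rng.normal(size=(10, 7))
        perp = rng.normal(size=(10, 7))
        v1 = variance_components(par, perp, d=2)
        v2 = variance_components(c * par, c * perp, d=2)
        assert np.allclose(v2, (c**2 * v1[0], c**2 * v1[1]))

    def test_ddof_compat_uses_n_minus_one(self):
        par = np.array([[1.0, -1.0], [-1.0, 1.0]])
        v_ucm, _ = variance_components(par, np.zeros((2, 2)), n=2, d=1, ddof_compat=True)
        assert v_ucm == pytest.approx(4.0)  # divisor N-1 = 1


class TestIndexOfSynergy:
    def test_continues_toy_example(self):
        v_tot, dv = index_of_synergy(2.0, 0.0, n=2, d=1)
        assert v_tot == pytest.approx(1.0)
        assert dv == pytest.approx(2.0)  # the n/(n-d) upper bound

    def test_equal_components_give_zero(self):
        _, dv = index_of_synergy(1.7, 1.7, n=7, d=3)
        assert dv == pytest.approx(0.0)

    def test_lower_bound_minus_n_over_d(self):
        _, dv = index_of_synergy(0.0, 5.0, n=7, d=1)
        assert dv == pytest.approx(-7.0)

    def test_degenerate_total_gives_nan(self):
        v_tot, dv = index_of_synergy(0.0, 0.0)
        assert v_tot == 0.0 and np.isnan(dv)

    @given(st.floats(0.0, 50.0), st.floats(0.0, 50.0), st.integers(1, 6))
    def test_bounds_always_hold(self, v_ucm, v_ort, d):
        n = 7
        _, dv = index_of_synergy(v_ucm, v_ort, n=n, d=d)
        if not np.isnan(dv):
            assert -n / d - 1e-9 <= dv <= n / (n - d) + 1e-9


class TestGroupSynergy:
    def _profile(self, v_ucm, v_ort, n=2, d=1):
        v_ucm = np.asarray(v_ucm, float)
        v_ort = np.asarray(v_ort, float)
        v_tot, dv = index_of_synergy(v_ucm, v_ort, n, d)
        return VarianceProfile(v_ucm=v_ucm, v_ort=v_ort, v_tot=v_tot, delta_v=dv, n=n, d=d)

    def test_single_participant_identity(self):
        p = self._profile([2.0, 3.0], [0.5, 1.0])
        g = group_synergy([p])
        assert np.allclose(g.delta_v, p.delta_v)

    def test_averaging_before_ratio_is_observable(self):
        # (2,0) and (0,2): averaged components (1,1) -> dV = 0, whereas the
        # mean of per-participant dV values would be (2 + (-2))/2 via
        # different totals; the scheme averages components first
        g = group_synergy([self._profile([2.0], [0.0]), self._profile([0.0], [2.0])])
        assert np.allclose(g.v_ucm, 1.0) and np.allclose(g.v_ort, 1.0)
        assert np.allclose(g.delta_v, 0.0)

    def test_identical_profiles_unchanged(self):
        p = self._profile([4.0, 4.0], [1.0, 1.0], n=7, d=1)
        g = group_synergy([p, p, p])
        assert np.allclose(g.delta_v, p.delta_v)

    def test_mismatched_time_bases_rejected(self):
        with pytest.raises(ValueError):
            group_synergy([self._profile([1.0], [1.0]), self._profile([1.0, 2.0], [1.0, 1.0])])


class TestProportionAbove:
    def test_all_above(self):
        assert proportion_above(np.ones(100)) == 1.0

    def test_strict_inequality_at_threshold(self):
        assert proportion_above(np.full(100, 0.5)) == 0.0

    def test_quarter_above(self):
        x = np.zeros(100)
        x[:25] = 1.0
        assert proportion_above(x) == 0.25

    def test_missing_excluded_from_both_sides(self):
        x = np.array([1.0, np.nan, 0.0, 1.0])
        assert proportion_above(x) == pytest.approx(2 / 3)

    def test_all_missing_is_nan(self):
        assert np.isnan(proportion_above(np.full(5, np.nan)))


class TestPerformanceVariables:
    def test_registry_has_nine(self):
        assert len(ALL_PERFORMANCE_VARIABLES) == 9
        assert sum(pv.d == 3 for pv in ALL_PERFORMANCE_VARIABLES) == 6
        assert sum(pv.d == 1 for pv in ALL_PERFORMANCE_VARIABLES) == 3

    def test_internal_external_position_differ_by_shoulder_offset(self, arm_model, rng):
        angles = rng.uniform(-30, 30, size=(4, 10, 7))
        ens = TrialEnsemble(angles)
        internal = pv_timeseries(ens, arm_model, get_pv_spec("hand_position", "internal"))
        external = pv_timeseries(ens, arm_model, get_pv_spec("hand_position", "external"))
        # identity thorax: external = shoulder offset + internal everywhere
        assert np.allclose(external - internal, arm_model.shoulder_position_lab, atol=1e-12)

    def test_static_posture_zero_speed_analogue(self, arm_model):
        angles = np.tile(np.array([5.0, -3, 8, 40, 10, 20, -15]), (3, 12, 1))
        out = pv_timeseries(TrialEnsemble(angles), arm_model, get_pv_spec("release_speed"))
        assert np.allclose(out, 0, atol=1e-12)

    def test_scripted_elbow_path_speed_analogue(self, arm_model):
        # elbow-only flexion moves the hand in the sagittal (y-z) plane, so
        # the sagittal speed analogue equals the full hand speed
        fs, rate, T = 250.0, 2.0, 50
        t = np.arange(T) / fs
        q_deg = np.zeros((2, T, 7))
        q_deg[:, :, 3] = np.degrees(0.3 + rate * t)
        out = pv_timeseries(
            TrialEnsemble(q_deg), arm_model, get_pv_spec("release_speed"), fs_equivalent=fs
        )
        l2 = arm_model.forearm_length + arm_model.hand_length
        assert np.allclose(out[:, 1:-1, 0], l2 * rate, atol=1e-3)

    def test_release_height_is_lab_z(self, arm_model, rng):
        angles = rng.uniform(-30, 30, size=(3, 8, 7))
        ens = TrialEnsemble(angles)
        height = pv_timeseries(ens, arm_model, get_pv_spec("release_height"))
        pos = pv_timeseries(ens, arm_model, get_pv_spec("hand_position", "external"))
        assert np.allclose(height[..., 0], pos[..., 2])

    def test_constant_release_mode_holds_final_sample(self, arm_model, rng):
        angles = rng.uniform(-30, 30, size=(4, 12, 7))
        ens = TrialEnsemble(angles)
        const = pv_timeseries(
            ens, arm_model, get_pv_spec("release_height"), release_mode="constant"
        )
        inst = pv_timeseries(ens, arm_model, get_pv_spec("release_height"))
        assert np.allclose(const, inst[:, -1:, :])


class TestDecompositionProperties:
    def test_pythagoras_and_total_variance_identity(self, rng):
        # conservation and the closed-form total: both routes to V_TOT agree
        for _ in range(20):
            d = int(rng.integers(1, 4))
            dev = rng.normal(size=(15, 7))
            dev -= dev.mean(axis=0)
            basis = null_space_basis(rng.normal(size=(d, 7)))
            par, perp = project_deviations(dev, basis)
            total_direct = np.sum(dev**2)
            assert np.isclose(np.sum(par**2) + np.sum(perp**2), total_direct, rtol=1e-8)
            v_ucm, v_ort = variance_components(par, perp, d=d)
            v_tot, _ = index_of_synergy(v_ucm, v_ort, d=d)
            assert np.isclose(v_tot, total_direct / (7 * 15), rtol=1e-10)

    def test_delta_v_invariant_to_rebasing(self, rng):
        from scipy.stats import ortho_group

        dev = rng.normal(size=(20, 7))
        dev -= dev.mean(axis=0)
        basis = null_space_basis(rng.normal(size=(3, 7)))
        Q = ortho_group.rvs(4, random_state=5)
        for b in (basis, basis @ Q):
            par, perp = project_deviations(dev, b)
            v = variance_components(par, perp, d=3)
            _, dv = index_of_synergy(*v, d=3)
            if "first" not in locals():
                first = dv
        assert np.isclose(first, dv, atol=1e-10)

    def test_estimator_matches_brute_force_least_squares(self, rng):
        # independent oracle: decompose each deviation by explicit least
        # squares onto span(eps) instead of the projection matrix
        w = rng.normal(size=(1, 7))
        mean = rng.uniform(-20, 20, size=(6, 7))
        dev = rng.normal(0, 2, size=(30, 6, 7))
        dev -= dev.mean(axis=0)
        ens = TrialEnsemble(mean + dev)
        pv = np.einsum("atn,dn->atd", ens.angles, w)
        est = SynergyDecomposition(pv="release_height").fit(ens, pv_values=pv)
        for i in range(6):
            J = estimate_jacobian(dev[:, i], (dev[:, i] @ w.T))
            assert np.allclose(J, w, atol=1e-8)
            basis = null_space_basis(J)
            coef, *_ = np.linalg.lstsq(basis, dev[:, i].T, rcond=None)
            par = (basis @ coef).T
            perp = dev[:, i] - par
            v_ucm, v_ort = variance_components(par, perp, d=1)
            _, dv = index_of_synergy(v_ucm, v_ort, d=1)
            assert np.isclose(est.delta_v_[i], dv, atol=1e-8)

    @pytest.mark.parametrize("v_ucm,v_ort,dv_tol", [(4.0, 1.0, 0.1), (1.0, 3.0, 0.2)])
    def test_injected_structure_recovery(self, v_ucm, v_ort, dv_tol):
        # per-DOF variance at d=1 carries ~sqrt(2/N) relative sampling sd, so
        # the 15% bound is checked at a trial count where it holds with wide
        # margin rather than by seed luck
        from ucmthrow.synthetic import SyntheticSpec, generate_ensemble

        spec = SyntheticSpec(n_trials=2000, n_samples=4, v_ucm_target=v_ucm,
                             v_ort_target=v_ort, pv_dim=1, seed=77)
        w = np.ones((1, 7)) / np.sqrt(7)
        basis = null_space_basis(w)
        bf = np.broadcast_to(basis, (4, 7, 6)).copy()
        mean = np.zeros((4, 7))
        ens = generate_ensemble(mean, bf, spec)
        pv = np.einsum("atn,dn->atd", ens.angles, w)
        est = SynergyDecomposition(pv="release_height").fit(ens, pv_values=pv)
        assert np.all(np.abs(est.v_ucm_ / v_ucm - 1) < 0.15)
        assert np.all(np.abs(est.v_ort_ / v_ort - 1) < 0.15)
        # dV tolerance scales with its sampling sd, which grows as V_TOT
        # shrinks; 0.2 is ~3 sigma for the low-synergy pair
        analytic = (v_ucm - v_ort) / ((1 / 7) * (1 * v_ort + 6 * v_ucm))
        assert np.abs(est.delta_v_ - analytic).max() < dv_tol

    def test_regression_jacobian_converges_to_fd_jacobian(self, arm_model):
        # for the nonlinear hand-position map, the regression estimate
        # approaches the analytic (finite-difference) Jacobian as the
        # deviation magnitude shrinks
        rng = np.random.default_rng(4)
        q0_deg = np.array([5.0, -10, 15, 50, 20, 30, -10])
        J_true = position_jacobian_fd(arm_model, np.radians(q0_deg)) * np.pi / 180
        z = rng.normal(size=(400, 7))
        z -= z.mean(axis=0)
        errors = []
        for scale in (2.0, 1.0, 0.5):
            angles = q0_deg + scale * z
            spec = get_pv_spec("hand_position", "external")
            ens = TrialEnsemble(angles[:, None, :].repeat(2, axis=1))
            pv = pv_timeseries(ens, arm_model, spec)
            dev_pv = pv - pv.mean(axis=0)
            J_est = estimate_jacobian(scale * z, dev_pv[:, 0, :])
            errors.append(np.abs(J_est - J_true).max())
        assert errors[0] > errors[1] > errors[2]


class TestSynergyDecompositionEstimator:
    def test_fit_on_raw_array_sets_attributes(self, rng):
        X = rng.uniform(-20, 20, size=(12, 8, 7))
        est = SynergyDecomposition(pv="hand_position", frame="external").fit(X)
        assert est.delta_v_.shape == (8,)
        assert est.jacobians_.shape == (8, 3, 7)
        assert np.all(est.v_ucm_ >= 0) and np.all(est.v_ort_ >= 0)
        assert 0 <= est.proportion_above() <= 1

    def test_sklearn_clone_compatible(self):
        from sklearn.base import clone

        est = SynergyDecomposition(pv="release_speed", threshold=0.3)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()

    def test_unknown_pv_rejected(self, rng):
        with pytest.raises(KeyError):
            SynergyDecomposition(pv="grip_force").fit(rng.normal(size=(10, 5, 7)))
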