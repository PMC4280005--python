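"""Objective/criterion arithmetic, subproblem solver, incremental algorithm."""

from dataclasses import replace

import numpy as np
import pytest

from splineflux.bspline import FreeFluxSet, SplineFunction, constant_spline
from splineflux.dynamics import DynamicModel, OutputMap
from splineflux.estimation import (MeasurementSet, SolverSettings, aic_c,
                                   chi_square_gof, count_parameters,
                                   incremental_estimate, initial_guess,
                                   min_start_timepoints, solve_subproblem,
                                   weighted_sse)
from splineflux.io import load_small_fixture
from splineflux.network import (NullSpaceBasis, check_basis, orthonormal_basis,
                                rational_basis)
from splineflux.synthetic import (ExperimentProtocol, builtin_protocol,
                                  sample_measurements, simulate_truth)


def toy_measurements(n_time=3, n_out=2, seed=0):
    rng = np.random.default_rng(seed)
    return MeasurementSet(times=np.arange(n_time, dtype=float),
                          output_ids=tuple(f"y{j}" for j in range(n_out)),
                          means=rng.normal(size=(n_time, n_out)),
                          sds=rng.uniform(0.5, 2.0, size=(n_time, n_out)))


class TestWeightedSSE:
    def test_zero_at_means(self):
        ms = toy_measurements()
        assert weighted_sse(ms, ms.means) == 0.0

    def test_single_two_sigma_residual(self):
        ms = MeasurementSet(times=[0.0, 1.0], output_ids=("y",),
                            means=np.array([[1.0], [1.0]]),
                            sds=np.array([[0.5], [0.5]]))
        pred = np.array([[1.0], [2.0]])  # residual = 2 sigma at one point
        assert weighted_sse(ms, pred) == pytest.approx(4.0)

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        ms = toy_measurements(n_time=5, n_out=4, seed=1)
        pred = rng.normal(size=ms.means.shape)
        expected = 0.0
        for i in range(ms.n_time):
            for j in range(ms.n_out):
                expected += ((pred[i, j] - ms.means[i, j]) / ms.sds[i, j]) ** 2
        assert weighted_sse(ms, pred) == pytest.approx(expected, rel=1e-12)

    def test_zero_sd_rejected_at_construction(self):
        with pytest.raises(ValueError, match="> 0"):
            MeasurementSet(times=[0.0, 1.0], output_ids=("y",),
                           means=np.zeros((2, 1)), sds=np.zeros((2, 1)))


class TestAICc:
    def test_zero_parameters(self):
        assert aic_c(0.0, 0, 10) == 0.0

    @pytest.mark.parametrize("f,n_p,n_meas,printed", [
        (49.50, 33, 84, 160.4),   # within SSE-rounding slack
        (14.41, 33, 84, 125.3),
    ])
    def test_published_values(self, f, n_p, n_meas, printed):
        assert aic_c(f, n_p, n_meas) == pytest.approx(printed, abs=0.05)

    def test_infeasible_denominator(self):
        with pytest.raises(ValueError):
            aic_c(1.0, 9, 10)


class TestMinStartTimepoints:
    def test_small_scale_case(self):
        assert min_start_timepoints(4, 3, 3) == 4

    def test_many_outputs_need_one_point(self):
        assert min_start_timepoints(15, 3, 3) == 1

    def test_matches_linear_scan_oracle(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            n_out = int(rng.integers(1, 12))
            d = int(rng.integers(1, 8))
            m_ext = int(rng.integers(0, 10))
            l = 1
            while l * n_out < 3 * d + m_ext + 3:
                l += 1
            assert min_start_timepoints(n_out, d, m_ext) == l


class TestCountParameters:
    @pytest.mark.parametrize("g_vec,optimal,n_p", [
        ((4, 0, 2), False, 25),
        ((3, 3, 4), False, 33),
        ((4, 0, 2), True, 28),
    ])
    def test_published_rows(self, g_vec, optimal, n_p):
        assert count_parameters(g_vec, d=3, k=2, m_ext=3,
                                optimal_K=optimal) == n_p

    def test_optimal_basis_adds_rotational_dof(self):
        for d in (2, 3, 5):
            base = count_parameters((0,) * d, d, 2, 3, optimal_K=False)
            opt = count_parameters((0,) * d, d, 2, 3, optimal_K=True)
            assert opt - base == d * (d - 1) // 2


class TestChiSquare:
    def test_perfect_fit_passes(self):
        ok, crit, dof = chi_square_gof(0.0, 20, 5)
        assert ok and dof == 15

    def test_quantile_matches_incomplete_gamma_oracle(self):
        from scipy.special import gammaincinv
        _, crit, dof = chi_square_gof(1.0, 64, 5, confidence=0.95)
        assert dof == 59
        oracle = 2.0 * gammaincinv(59 / 2.0, 0.95)
        assert crit == pytest.approx(oracle, abs=1e-8)

    def test_boundary_behavior(self):
        _, crit, _ = chi_square_gof(0.0, 20, 5)
        ok, _, _ = chi_square_gof(crit + 1e-9, 20, 5)
        assert not ok

    def test_nonpositive_dof_rejected(self):
        with pytest.raises(ValueError):
            chi_square_gof(1.0, 5, 5)


# ---------------------------------------------------------------------------
# solver-level tests
# ---------------------------------------------------------------------------

@pytest.fixture(scope="module")
def small_setup():
    net, basis, kin, proto = builtin_protocol("small_low_noise")
    return net, basis, kin, proto


def test_subproblem_recovers_spline_truth(small_setup):
    """Noiseless data generated from knotless quadratic fluxes is recovered
    exactly (the model class contains the truth)."""
    net, basis, _, proto = small_setup
    model = DynamicModel(net=net, basis=basis)
    times = np.linspace(0, 6, 7)
    true_cp = [np.array([0.8, 0.6, 0.5]), np.array([0.15, 0.18, 0.16]),
               np.array([1.0, 0.7, 0.6])]
    fs_true = FreeFluxSet(tuple(
        SplineFunction(k=2, t0=0.0, t_end=6.0, internal_knots=np.empty(0),
                       control_points=cp) for cp in true_cp))
    x0_true = np.array([10.0, 15.0, 0.0, 0.1])
    from splineflux.collocation import discretize, radau_grid
    disc = discretize(model, fs_true, radau_grid(times))
    p_x, _ = disc.solve_states(fs_true, x0_true)
    y = np.vstack([p_x[0, 0][None, :], p_x[:, -1, :]])
    ms = MeasurementSet(times=times, output_ids=net.state_ids, means=y,
                        sds=np.full_like(y, 1e-4))
    guess = FreeFluxSet(tuple(
        SplineFunction(k=2, t0=0.0, t_end=6.0, internal_knots=np.empty(0),
                       control_points=cp + 0.05) for cp in true_cp))
    fit = solve_subproblem(model, OutputMap.states_only(4), ms, guess,
                           x0_true + 0.02,
                           settings=SolverSettings(tol=1e-12))
    assert fit.converged
    # recovery to the precision achievable with finite-difference gradients
    for s_fit, cp in zip(fit.flux_set.splines, true_cp):
        np.testing.assert_allclose(s_fit.control_points, cp, atol=1e-5)
    np.testing.assert_allclose(fit.x0, x0_true, atol=1e-5)


def test_subproblem_parameter_recovery_within_noise(small_setup):
    """On self-generated noisy data the fitted x0 stays within a few standard
    errors of the truth."""
    net, basis, kin, proto = small_setup
    p = replace(proto, sampling_times=np.linspace(0, 20, 6),
                noise=0.01)
    truth = simulate_truth(net, basis, kin, p)
    ms = sample_measurements(truth, p, seed=11)
    model = DynamicModel(net=net, basis=basis)
    fs, x0g = initial_guess(model, p.output_map, ms)
    fit = solve_subproblem(model, p.output_map, ms, fs, x0g)
    assert fit.converged
    # sd of each x0 entry is at most the measurement sd (0.1)
    assert np.all(np.abs(fit.x0 - p.x0) < 3 * 0.1 + 1e-6)


def test_optimal_K_point_is_feasible(small_setup, realistic_measurements):
    net, basis, _, proto = small_setup
    bon = orthonormal_basis(net)
    model = DynamicModel(net=net, basis=bon)
    ms = realistic_measurements.truncate(4)
    fs, x0g = initial_guess(model, proto.output_map, ms)
    fit = solve_subproblem(model, proto.output_map, ms, fs, x0g,
                           optimal_K=True)
    assert fit.converged
    rep = check_basis(net, fit.K, orthonormal_required=True)
    assert rep.nullspace_residual < 1e-6
    assert rep.orthonormality_residual < 1e-6


def test_optimal_K_sse_no_worse_than_fixed_orthonormal(
        small_setup, realistic_measurements):
    """The optimized-basis feasible set contains every fixed orthonormal
    basis, so its optimum cannot be worse."""
    net, _, _, proto = small_setup
    bon = orthonormal_basis(net)
    model = DynamicModel(net=net, basis=bon)
    ms = realistic_measurements.truncate(5)
    fs, x0g = initial_guess(model, proto.output_map, ms)
    fixed = solve_subproblem(model, proto.output_map, ms, fs, x0g)
    opt = solve_subproblem(model, proto.output_map, ms, fixed.flux_set,
                           fixed.x0, K_guess=fixed.K, optimal_K=True)
    assert opt.converged and fixed.converged
    assert opt.f <= fixed.f + 1e-6


def test_basis_rotation_invariance(small_setup, realistic_measurements):
    """Fixed orthonormal bases K and K Q parameterize the same flux space:
    optimal objectives agree and reconstructed v = K u profiles agree."""
    net, _, _, proto = small_setup
    bon = orthonormal_basis(net)
    rng = np.random.default_rng(7)
    Q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    brot = NullSpaceBasis(K=bon.K @ Q, mode="orthonormal")
    ms = realistic_measurements.truncate(5)
    fits = []
    for basis in (bon, brot):
        model = DynamicModel(net=net, basis=basis)
        fs, x0g = initial_guess(model, proto.output_map, ms)
        fit = solve_subproblem(model, proto.output_map, ms, fs, x0g,
                               settings=SolverSettings(tol=1e-12,
                                                       maxiter=1000))
        assert fit.converged
        fits.append(fit)
    assert fits[0].f == pytest.approx(fits[1].f, rel=1e-6, abs=1e-8)
    t = np.linspace(0, ms.times[-1], 50)
    V0 = fits[0].flux_profiles(t)
    V1 = fits[1].flux_profiles(t)
    np.testing.assert_allclose(V0, V1, atol=5e-4)


def test_knot_windows_honored(small_setup, realistic_measurements):
    net, basis, _, proto = small_setup
    model = DynamicModel(net=net, basis=basis)
    ms = realistic_measurements.truncate(6)
    from splineflux.bspline import constrain_knot, insert_knot
    fs, x0g = initial_guess(model, proto.output_map, ms)
    s0 = constrain_knot(insert_knot(fs.splines[0], 2.5), 0, (2.0, 3.0))
    fs = FreeFluxSet((s0,) + fs.splines[1:])
    fit = solve_subproblem(model, proto.output_map, ms, fs, x0g)
    assert fit.converged
    knot = fit.flux_set.splines[0].internal_knots[0]
    assert 2.0 - 1e-9 <= knot <= 3.0 + 1e-9


def test_continuous_reactor_subproblem():
    """Dilution-controlled medium-scale case: one short-horizon subproblem
    converges and recovers the measured initial concentrations."""
    net, basis, kin, proto = builtin_protocol("medium")
    truth = simulate_truth(net, basis, kin, proto, rtol=1e-8)
    ms = sample_measurements(truth, proto, seed=2).truncate(4)
    model = DynamicModel(net=net, basis=basis, mode="continuous",
                         dilution=proto.dilution, x_in=proto.x_in)
    fs, x0g = initial_guess(model, proto.output_map, ms)
    fit = solve_subproblem(model, proto.output_map, ms, fs, x0g)
    assert fit.converged
    # measured states: initial values within 3 measurement sd of the truth
    sel = proto.output_map.state_selection
    meas_truth = sel @ proto.x0
    meas_fit = sel @ fit.x0
    assert np.all(np.abs(meas_fit - meas_truth) <= 3 * ms.sds[0, :8] + 1e-9)


# ---------------------------------------------------------------------------
# incremental algorithm
# ---------------------------------------------------------------------------

def test_first_iteration_insertion_blocked(small_setup, realistic_measurements):
    """At the smallest feasible horizon (l=4, 16 measurements, n_p=13) a knot
    insertion would break the AICc denominator condition."""
    net, basis, _, proto = small_setup
    model = DynamicModel(net=net, basis=basis)
    fit = incremental_estimate(realistic_measurements, model,
                               proto.output_map, max_timepoints=4)
    first = fit.history[0]
    assert first.n_time == 4
    assert first.n_p == 13
    assert first.action == "No new knot possible"


def test_noiseless_quadratic_truth_keeps_zero_knots(small_setup):
    """Data generated from knotless quadratic fluxes: AICc strictly penalizes
    any added knot at (near) zero residual gain, so none are inserted."""
    net, basis, _, _ = small_setup
    model = DynamicModel(net=net, basis=basis)
    times = np.linspace(0, 7, 8)
    cps = [np.array([0.8, 0.6, 0.5]), np.array([0.15, 0.18, 0.16]),
           np.array([1.0, 0.7, 0.6])]
    fs_true = FreeFluxSet(tuple(
        SplineFunction(k=2, t0=0.0, t_end=7.0, internal_knots=np.empty(0),
                       control_points=cp) for cp in cps))
    from splineflux.collocation import discretize, radau_grid
    disc = discretize(model, fs_true, radau_grid(times))
    p_x, _ = disc.solve_states(fs_true, np.array([10.0, 15.0, 0.0, 0.1]))
    y = np.vstack([p_x[0, 0][None, :], p_x[:, -1, :]])
    ms = MeasurementSet(times=times, output_ids=net.state_ids, means=y,
                        sds=np.full_like(y, 1e-2))
    fit = incremental_estimate(ms, model, OutputMap.states_only(4))
    assert fit.n_meas == 32
    np.testing.assert_array_equal(fit.g_vec, [0, 0, 0])


def test_monotone_acceptance_along_run(lownoise_recovery_run):
    """Every accepted AIC* is strictly below the preceding F at the same
    horizon, and F is updated to it."""
    hist = lownoise_recovery_run["fit"].history
    accepted = [h for h in hist if h.action.startswith("Knot inserted")]
    assert accepted, "run should accept at least one knot"
    for h in accepted:
        assert h.min_aic < h.aic_before


def test_history_mirrors_iteration_structure(lownoise_recovery_run):
    hist = lownoise_recovery_run["fit"].history
    n_times = [h.n_time for h in hist]
    assert n_times == sorted(n_times)
    assert hist[-1].n_time == lownoise_recovery_run["measurements"].n_time
    for h in hist:
        if h.action == "No better minimum":
            assert h.min_aic >= h.aic_before


def test_lownoise_recovery_within_five_percent(lownoise_recovery_run):
    """Low-noise parameter recovery: flux-wise integrated absolute deviation
    from the reference stays within 5% of the reference flux magnitude."""
    run = lownoise_recovery_run
    fit, truth, basis = run["fit"], run["truth"], run["basis"]
    t = np.linspace(0.0, 20.0, 201)
    _, us = truth.at(t)
    V_hat = fit.flux_profiles(t)
    V_ref = basis.K @ us
    for j in range(V_ref.shape[0]):
        num = np.trapezoid(np.abs(V_hat[j] - V_ref[j]), t)
        den = np.trapezoid(np.abs(V_ref[j]), t)
        assert num <= 0.05 * den, f"flux {j+1}: {100*num/den:.2f}% deviation"


def test_chi_square_verdict_attached(lownoise_recovery_run):
    fit = lownoise_recovery_run["fit"]
    assert fit.chi2_critical is not None
    assert fit.chi2_dof == fit.n_meas - fit.n_p
    assert fit.chi2_pass == (fit.f < fit.chi2_critical)


def test_aicc_recomputable_from_parts(lownoise_recovery_run):
    fit = lownoise_recovery_run["fit"]
    assert fit.aicc == pytest.approx(
        aic_c(fit.f, fit.n_p, fit.n_meas), abs=1e-9)
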