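"""Trifilar-pendulum model: damped fits, period -> MoI, offset correction."""

import numpy as np
import pytest

from ctinertia.errors import DomainError, InsufficientDataError, NoOscillationError
from ctinertia.pendulum import (
    DampedFit,
    OscillationTrace,
    PendulumRig,
    analytic_block_moi,
    fit_damped_oscillator,
    period_estimate,
    read_trace_csv,
    rig_moi,
    specimen_moi_corrected,
)
from ctinertia.synthetic import simulate_pendulum_trace, small_angle_period

RIG = PendulumRig(m_p=1.5, R=0.25, L=1.2)


def synthetic_trace(X=0.05, phi=0.4, zeta=0.01, omega_d=2.0, duration=180.0, rate=70.0,
                    noise=0.0, seed=0):
    t = np.arange(0.0, duration, 1.0 / rate)
    omega_n = omega_d / np.sqrt(1 - zeta**2)
    env = X * np.exp(-zeta * omega_n * t)
    arg = omega_d * t + phi
    v = env * (omega_d * np.cos(arg) - zeta * omega_n * np.sin(arg))
    if noise:
        v = v + np.random.default_rng(seed).normal(0, noise, t.size)
    return OscillationTrace(t=t, omega=v)


class TestDampedFit:
    def test_noiseless_parameters_recovered_to_1e6(self):
        zeta, omega_d = 0.01, 2.0
        trace = synthetic_trace(zeta=zeta, omega_d=omega_d)
        fit = fit_damped_oscillator(trace, fit_window=60.0)
        assert fit.omega_d == pytest.approx(omega_d, rel=1e-6)
        assert fit.zeta == pytest.approx(zeta, rel=1e-6)
        # amplitude/phase are referenced to the window start
        t0 = trace.t[trace.t >= trace.t[-1] - 60.0][0]
        omega_n = omega_d / np.sqrt(1 - zeta**2)
        x_at_window = 0.05 * np.exp(-zeta * omega_n * t0)
        assert fit.X == pytest.approx(x_at_window, rel=1e-6)
        assert fit.residual_rms < 1e-9

    def test_undamped_trace_gives_equal_frequencies(self):
        fit = fit_damped_oscillator(synthetic_trace(zeta=0.0), fit_window=60.0)
        assert fit.zeta == pytest.approx(0.0, abs=1e-9)
        assert fit.omega_n == pytest.approx(fit.omega_d, rel=1e-12)

    def test_noisy_frequency_recovered_within_0p1_percent(self):
        # 2% amplitude noise at 70 Hz, three independent repeats
        for seed in (1, 2, 3):
            trace = synthetic_trace(noise=0.02 * 0.05 * 2.0, seed=seed)
            fit = fit_damped_oscillator(trace, fit_window=60.0)
            assert fit.omega_d == pytest.approx(2.0, rel=1e-3)

    def test_flat_trace_rejected(self):
        t = np.arange(0, 120, 1 / 70)
        rng = np.random.default_rng(0)
        trace = OscillationTrace(t=t, omega=rng.normal(0, 1e-3, t.size))
        with pytest.raises(NoOscillationError):
            fit_damped_oscillator(trace, fit_window=60.0)

    def test_short_trace_rejected(self):
        trace = synthetic_trace(duration=30.0)
        with pytest.raises(InsufficientDataError):
            fit_damped_oscillator(trace, fit_window=60.0)

    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            DampedFit(zeta=0.1, omega_n=2.0, omega_d=2.0, X=1, phi=0, tau=np.pi,
                      residual_rms=0)


class TestPeriodEstimate:
    def _fit(self, tau):
        omega_d = 2 * np.pi / tau
        return DampedFit(zeta=0.0, omega_n=omega_d, omega_d=omega_d, X=0.05, phi=0.0,
                         tau=tau, residual_rms=0.0)

    def test_mean_of_identical_fits(self):
        est = period_estimate([self._fit(1.3)] * 3)
        assert est.tau == pytest.approx(1.3) and est.std == 0.0

    def test_arithmetic_mean(self):
        est = period_estimate([self._fit(t) for t in (1.0, 1.1, 1.2)])
        assert est.tau == pytest.approx(1.1, rel=1e-12)
        assert est.n == 3

    def test_empty_rejected(self):
        with pytest.raises(InsufficientDataError):
            period_estimate([])

    def test_simulated_repeats_near_truth(self):
        i_true = 0.03
        tau_true = small_angle_period(i_true, RIG.m_p, RIG)
        fits = []
        for seed in range(3):
            trace = simulate_pendulum_trace(
                i_true, RIG, zeta=0.01, amplitude=np.deg2rad(2), duration=120,
                noise_sigma=1e-3, seed=seed,
            )
            fits.append(fit_damped_oscillator(trace, fit_window=60.0))
        est = period_estimate(fits)
        assert est.tau == pytest.approx(tau_true, rel=2e-3)


class TestRigMoi:
    def test_period_squared_scaling(self):
        base = rig_moi(1.0, 9.81, 0.2, 1.0, 1.0)
        assert rig_moi(1.0, 9.81, 0.2, 2.0, 1.0) == pytest.approx(4 * base, rel=1e-12)

    def test_nonpositive_arguments_rejected(self):
        with pytest.raises(DomainError):
            rig_moi(1.0, 9.81, 0.0, 1.0, 1.0)

    def test_ode_oracle_round_trip_small_amplitude(self):
        """Exact trifilar dynamics -> damped fit -> period formula: <0.1%."""
        i_true = 0.028
        trace = simulate_pendulum_trace(
            i_true, RIG, zeta=0.0, amplitude=np.deg2rad(2), duration=180
        )
        fit = fit_damped_oscillator(trace, fit_window=60.0)
        got = rig_moi(RIG.m_p, RIG.g, RIG.R, fit.tau, RIG.L)
        assert got == pytest.approx(i_true, rel=1e-3)

    def test_additivity_of_centred_block_under_ode_oracle(self):
        i_rig = 0.028
        block = analytic_block_moi(0.1, 0.2, 0.05, 1.0, axis=0)
        fits = []
        for i_tot, m in ((i_rig, RIG.m_p), (i_rig + block, RIG.m_p + 1.0)):
            trace = simulate_pendulum_trace(
                i_tot, RIG, zeta=0.005, amplitude=np.deg2rad(2), duration=180,
                suspended_mass=m,
            )
            fits.append(fit_damped_oscillator(trace, fit_window=60.0))
        i_rig_est = rig_moi(RIG.m_p, RIG.g, RIG.R, fits[0].tau, RIG.L)
        i_tot_est = rig_moi(RIG.m_p + 1.0, RIG.g, RIG.R, fits[1].tau, RIG.L)
        assert i_tot_est - i_rig_est == pytest.approx(block, rel=1e-3)

    def test_small_angle_error_grows_with_amplitude(self):
        i_true = 0.028
        errors = []
        for amp_deg in (2.0, 10.0, 25.0):
            trace = simulate_pendulum_trace(
                i_true, RIG, zeta=0.0, amplitude=np.deg2rad(amp_deg), duration=180
            )
            fit = fit_damped_oscillator(trace, fit_window=60.0)
            got = rig_moi(RIG.m_p, RIG.g, RIG.R, fit.tau, RIG.L)
            errors.append(abs(got / i_true - 1))
        assert errors[0] < errors[1] < errors[2]


class TestOffsetCorrection:
    def test_zero_offset_reduces_to_uncorrected_difference(self):
        m_b, i_p, tau = 0.55, 0.03, 1.2
        combined = rig_moi(m_b + RIG.m_p, RIG.g, RIG.R, tau, RIG.L)
        corrected = specimen_moi_corrected(m_b, RIG.m_p, i_p, tau, RIG, 0.0)
        assert corrected == combined - i_p

    @pytest.mark.parametrize("d_mm", [8.0, 20.0, 31.0])
    def test_offset_block_recovered_within_1_percent(self, d_mm):
        """Composite rig + offset block: corrected MoI matches the block's
        own-CoM analytic value; the uncorrected estimate is biased high by
        the parallel-axis term m_b D^2."""
        d = d_mm * 1e-3
        m_b = 0.55
        i_rig = 0.028
        i_block = analytic_block_moi(0.09, 0.12, 0.04, m_b, axis=0)
        i_combined = i_rig + i_block + m_b * d**2
        trace = simulate_pendulum_trace(
            i_combined, RIG, zeta=0.01, amplitude=np.deg2rad(2), duration=180,
            suspended_mass=RIG.m_p + m_b,
        )
        fit = fit_damped_oscillator(trace, fit_window=60.0)
        corrected = specimen_moi_corrected(m_b, RIG.m_p, i_rig, fit.tau, RIG, d)
        uncorrected = specimen_moi_corrected(m_b, RIG.m_p, i_rig, fit.tau, RIG, 0.0)
        assert corrected == pytest.approx(i_block, rel=0.01)
        assert uncorrected - corrected == pytest.approx(m_b * d**2, rel=1e-12)

    def test_correction_monotone_in_offset(self):
        vals = [
            specimen_moi_corrected(0.55, RIG.m_p, 0.03, 1.2, RIG, d)
            for d in (0.0, 0.01, 0.02, 0.03)
        ]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_negative_offset_rejected(self):
        with pytest.raises(DomainError):
            specimen_moi_corrected(0.5, 1.5, 0.03, 1.2, RIG, -0.01)


class TestAnalyticBlock:
    def test_cube_symmetry(self):
        for axis in range(3):
            assert analytic_block_moi(0.1, 0.1, 0.1, 2.0, axis) == pytest.approx(
                2.0 / 6.0 * 0.01, rel=1e-12
            )

    def test_printed_closed_form(self):
        assert analytic_block_moi(0.1, 0.2, 0.3, 1.0, axis=2) == pytest.approx(
            (0.01 + 0.04) / 12.0, rel=1e-12
        )

    def test_matches_voxelized_cuboid(self):
        from ctinertia.calibration import DensityCalibration, apply_calibration
        from ctinertia.inertial import (
            AxisSpec,
            build_mass_model,
            centre_of_mass,
            moi_about_axis,
        )
        from ctinertia.synthetic import SceneSpec, Shape, rasterize_scene

        s = Shape("cuboid", (0.032, 0.032, 0.032), (0.024, 0.018, 0.012), 1000.0, 1, "c")
        scene = SceneSpec(shapes=[s], noise_sigma=0.0, spacing=(1, 1, 1),
                          volume_shape=(64, 64, 64))
        grid, labels, truth = rasterize_scene(scene)
        cal = DensityCalibration(slope=1.0, intercept=-1000.0, r_squared=1.0)
        model = build_mass_model(apply_calibration(grid, cal), labels.labels > 0)
        want = analytic_block_moi(0.024, 0.018, 0.012, truth.total_mass, axis=0)
        axis = AxisSpec.through(centre_of_mass(model), [1, 0, 0])
        assert moi_about_axis(model, axis) == pytest.approx(want, rel=0.01)


class TestTraceCsv:
    @pytest.mark.parametrize(
        "t_col, w_col", [("time_s", "omega_rad_s"), ("Time", "gyro_z"), ("t", "omega")]
    )
    def test_header_variants(self, tmp_path, t_col, w_col):
        import pandas as pd

        trace = synthetic_trace(duration=20.0)
        pd.DataFrame({t_col: trace.t, w_col: trace.omega}).to_csv(
            tmp_path / "log.csv", index=False
        )
        back = read_trace_csv(tmp_path / "log.csv")
        assert np.allclose(back.omega, trace.omega)

    def test_unrecognised_headers_rejected(self, tmp_path):
        import pandas as pd

        pd.DataFrame({"foo": [1, 2], "bar": [3, 4]}).to_csv(
            tmp_path / "log.csv", index=False
        )
        with pytest.raises(ValueError, match="could not identify"):
            read_trace_csv(tmp_path / "log.csv")
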