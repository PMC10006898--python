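import numpy as np
import pytest

from dipolefit import (
    DipoleParameters,
    EEGRecording,
    HeadModel,
    NoiseModel,
    SensorArray,
    SolverConfig,
    cost,
    fit,
    localization_error,
    make_fixture,
    match_dipoles,
    predict,
    sample_uniform_sensors,
    simulate_recording,
)


def _random_dipole(rng, head):
    loc = rng.uniform(-0.5, 0.5, 3) * head.radius_cm
    loc[2] = rng.uniform(0.3, 0.8) * head.radius_cm
    norm = np.linalg.norm(loc)
    if norm > 0.85 * head.radius_cm:
        loc *= 0.85 * head.radius_cm / norm
    mu = rng.normal(size=3)
    mu /= np.linalg.norm(mu)
    return DipoleParameters(loc, mu, rng.uniform(0.1, 0.5))


class TestPredict:
    def test_matches_stored_noiseless_in_clairvoyant_model(self, head):
        sens = sample_uniform_sensors(head, 20, seed=1)
        dip = DipoleParameters((2.0, 1.0, 5.0), (0.36, 0.48, 0.80), 0.2)
        rec = simulate_recording([dip], sens, head, 5, NoiseModel(sigma=0.1), seed=2)
        pred = predict([dip], sens, head, rec.truth.conductivity)
        assert np.allclose(pred, rec.truth.noiseless, rtol=1e-12)

    def test_zero_strength_predicts_zero(self, head):
        sens = sample_uniform_sensors(head, 5, seed=1)
        params = np.array([[1, 1, 5, 0, 0, 1, 0.0]])
        assert np.allclose(predict(params, sens, head, 0.5), 0.0)

    def test_linear_in_strength(self, head):
        sens = sample_uniform_sensors(head, 5, seed=1)
        p1 = np.array([[1, 1, 5, 0, 0, 1, 0.2]])
        p2 = p1.copy()
        p2[0, 6] = 0.4
        assert np.allclose(
            predict(p2, sens, head, 0.5), 2 * predict(p1, sens, head, 0.5), rtol=1e-14
        )


class TestCost:
    def test_zero_at_truth_without_noise(self, head):
        fx = make_fixture("single-dipole-noiseless", seed=3)
        rec = fx.simulate()
        truth = np.stack([d.as_vector() for d in fx.dipoles])
        J = cost(truth, rec, SolverConfig(mode="clairvoyant"))
        assert J == pytest.approx(0.0, abs=1e-18)

    def test_half_squared_residual_single_cell(self, head):
        sens = SensorArray(positions=[[0, 0, 10.0]])
        dip = DipoleParameters((0, 0, 5.0), (0, 0, 1.0), 0.2)
        rec = simulate_recording([dip], sens, head, 1, NoiseModel(sigma=0.0), seed=0)
        # shift the candidate strength so the prediction misses by exactly 2
        pred = rec.truth.noiseless[0]
        params = np.array([[0, 0, 5, 0, 0, 1, 0.2 * (pred + 2) / pred]])
        J = cost(params, rec, SolverConfig(mode="clairvoyant"))
        assert J == pytest.approx(2.0, rel=1e-9)

    def test_invariant_to_sensor_relabeling(self, head):
        sens = sample_uniform_sensors(head, 10, seed=2)
        dip = DipoleParameters((1.5, 0.5, 6.0), (0, 0, 1.0), 0.2)
        rec = simulate_recording([dip], sens, head, 20, NoiseModel(target_snr=20), seed=3)
        params = np.array([[1.0, 0.0, 5.0, 0, 0, 1, 0.25]])
        J1 = cost(params, rec, SolverConfig(mode="clairvoyant"))
        perm = np.random.default_rng(0).permutation(10)
        rec2 = EEGRecording(
            signals=rec.signals[perm],
            sensors=SensorArray(positions=sens.positions[perm]),
            head=head,
            truth=None,
        )
        zeta = rec.truth.conductivity[perm]
        from dipolefit.inverse_solver import _mean_and_jac, _residual_offsets

        fbar, const = _residual_offsets(rec2, None)
        mean, _ = _mean_and_jac(params.ravel(), rec2.sensors.positions, head, zeta, False)
        r = fbar - mean
        J2 = const + 0.5 * rec2.n_samples * float(r @ r)
        assert J2 == pytest.approx(J1, rel=1e-12)


class TestFit:
    def test_noiseless_recovery_from_perturbed_guess(self, head):
        failures = []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            dip = _random_dipole(rng, head)
            sens = sample_uniform_sensors(head, 24, seed=seed + 100)
            rec = simulate_recording([dip], sens, head, 5, NoiseModel(sigma=0.0), seed=seed)
            guess = dip.as_vector() + np.concatenate([rng.normal(0, 0.5, 3), rng.normal(0, 0.1, 3), [0.05]])
            guess[2] = abs(guess[2])
            res = fit(rec, 1, SolverConfig(initial_guess=guess, mode="clairvoyant"))
            loc_err = np.linalg.norm(res.estimate[0, :3] - dip.location)
            ori_err = np.max(np.abs(res.estimate[0, 3:6] - dip.orientation))
            if loc_err > 1e-4 or ori_err > 1e-4:
                failures.append((seed, loc_err, ori_err))
        assert not failures, failures

    def test_truth_guess_stays_at_truth(self):
        fx = make_fixture("single-dipole-noiseless", seed=4)
        rec = fx.simulate()
        truth = np.stack([d.as_vector() for d in fx.dipoles])
        res = fit(rec, 1, SolverConfig(initial_guess=truth, mode="clairvoyant"))
        assert res.final_cost <= 1e-12
        assert np.allclose(res.estimate, truth, atol=1e-5)

    def test_unit_norm_constraint_holds(self):
        fx = make_fixture("single-dipole-noiseless", seed=5)
        rec = fx.simulate()
        res = fit(rec, 1, SolverConfig(initial_guess=fx.initial_guess, mode="clairvoyant"))
        assert np.all(res.constraint_residuals <= 1e-6)

    def test_cost_history_monotone(self, head):
        fx = make_fixture("table1", seed=2)
        rec = fx.simulate()
        res = fit(rec, 3, SolverConfig(initial_guess=fx.initial_guess, mode="clairvoyant"))
        hist = np.array(res.cost_history)
        assert len(hist) >= 1
        assert np.all(np.diff(hist) <= 0)

    def test_nonconvergence_is_flagged_not_raised(self):
        fx = make_fixture("table1", seed=2)
        rec = fx.simulate()
        res = fit(
            rec,
            3,
            SolverConfig(
                initial_guess=fx.initial_guess,
                mode="clairvoyant",
                max_iterations=1,
                scan_initialization=False,
            ),
        )
        assert res.converged is False

    def test_guess_outside_head_rejected(self):
        fx = make_fixture("single-dipole-noiseless", seed=4)
        rec = fx.simulate()
        bad = np.array([[11.0, 0, 4, 0, 0, 1, 0.1]])
        with pytest.raises(ValueError, match="outside"):
            fit(rec, 1, SolverConfig(initial_guess=bad))

    def test_underdetermined_warns(self, head):
        sens = sample_uniform_sensors(head, 5, seed=6)
        dip = DipoleParameters((1, 1, 5), (0, 0, 1), 0.2)
        rec = simulate_recording([dip], sens, head, 10, NoiseModel(sigma=0.0), seed=6)
        with pytest.warns(UserWarning, match="under-determined"):
            fit(
                rec,
                1,
                SolverConfig(
                    initial_guess=np.array([[1, 1, 5, 0, 0, 1, 0.2]]),
                    mode="clairvoyant",
                    max_iterations=5,
                    scan_initialization=False,
                ),
            )

    def test_grid_oracle_equivalence(self, head):
        # independent oracle: exhaustive location grid with the moment solved
        # by linear least squares, refined twice around the incumbent
        rng = np.random.default_rng(12)
        dip = _random_dipole(rng, head)
        sens = sample_uniform_sensors(head, 30, seed=42)
        rec = simulate_recording([dip], sens, head, 100, NoiseModel(target_snr=20), seed=13)
        w = sens.positions
        zeta = rec.truth.conductivity[:, 0]
        fbar = rec.signals.mean(axis=1)

        def resid(loc):
            u = w - loc
            d = np.linalg.norm(u, axis=1)
            rho = 1.0 - (0.99 / 20.0) * d
            A = (rho / (4 * np.pi * zeta * d**3))[:, None] * u
            q, *_ = np.linalg.lstsq(A, fbar, rcond=None)
            return float(np.sum((fbar - A @ q) ** 2))

        center, span = np.array([0.0, 0.0, 5.0]), 5.0
        for _ in range(6):
            axes = [np.linspace(c - span, c + span, 5) for c in center]
            best = None
            for x in axes[0]:
                for y in axes[1]:
                    for z in axes[2]:
                        loc = np.array([x, y, max(z, 0.1)])
                        if np.linalg.norm(loc) >= 0.95 * head.radius_cm:
                            continue
                        v = resid(loc)
                        if best is None or v < best[0]:
                            best = (v, loc)
            center, span = best[1], span / 2
        res = fit(
            rec,
            1,
            SolverConfig(initial_guess=np.array([[1, 0, 5, 0, 0, 1, 0.2]]), mode="clairvoyant"),
        )
        # final grid resolution is span/2 per axis
        assert np.linalg.norm(res.estimate[0, :3] - center) <= 2 * span


class TestLocalizationError:
    def test_published_sub_millimetre_case(self):
        err = localization_error(
            np.array([[9.11, 32.07, 38.54]]), np.array([[9.13, 32.06, 38.52]])
        )
        assert err[0] == pytest.approx(0.03, abs=0.005)

    def test_published_centimetre_case(self):
        err = localization_error(
            np.array([[-15.01, -29.78, 59.42]]), np.array([[-34.0, -17.0, 69.0]])
        )
        assert err[0] == pytest.approx(24.81, abs=0.005)

    def test_zero_for_identical(self):
        x = np.array([[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert np.allclose(localization_error(x, x), 0.0)

    def test_invariant_to_estimate_order(self):
        truth = np.array([[0, 0, 5.0], [3, 3, 5.0]])
        est = np.array([[3.1, 3.0, 5.0], [0.1, 0, 5.0]])
        err = localization_error(truth, est)
        assert err == pytest.approx([0.1, 0.1], abs=1e-12)

    def test_count_mismatch(self):
        with pytest.raises(ValueError, match="differ"):
            match_dipoles(np.zeros((2, 3)), np.zeros((3, 3)))
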