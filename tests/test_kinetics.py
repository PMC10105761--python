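"""Rate laws, calibration, stability screening and perturbation runs."""

import numpy as np
import pytest
from dataclasses import replace
from scipy import stats

from pyrosc import kinetics as K
from pyrosc.io import load_oscillating_fixture

from conftest import random_state

F_GLC = K.glucose_uptake_flux()


class TestReactionRates:
    def test_unit_state_neutral_params(self, neutral_params):
        # all concentrations 1, a = 0, n = 1, k = Km = 1, Vmax = 4
        r = K.reaction_rates(K.UNIT_STATE, neutral_params)
        assert r.pts == pytest.approx(1.0)       # 4 / (1+1+1+1)
        assert r.pfk == r.fba == r.pyk == r.pdh == pytest.approx(2.0)
        assert r.fbpase == pytest.approx(2.0)    # 4 * 1/(1+1)

    def test_unit_state_independent_of_exponents(self, neutral_params):
        # x^a = 1 at x = 1: all 8 feedback structures agree at the unit state
        rates = []
        for s in K.FeedbackStructure.all_structures():
            p = replace(
                neutral_params,
                a1=2.0 if s.pfk_inhibition_active else 0.0,
                a2=3.0 if s.fbpase_activation_active else 0.0,
                a3=1.5 if s.pyk_activation_active else 0.0,
            )
            rates.append(K.reaction_rates(K.UNIT_STATE, p).as_array())
        assert np.allclose(rates, rates[0])

    def test_calibrated_unit_state_fluxes_solve_balance(self, calibrated_sets):
        # oracle: solve the 4 linear balance equations with the 6 fluxes as
        # unknowns (stoichiometry fixed, net flux pinned); least-norm solution
        # is unique once PTS, FBA, PYK, PDH are pinned by the balances
        for p in calibrated_sets[:5]:
            r = K.reaction_rates(K.UNIT_STATE, p)
            assert r.pts == pytest.approx(F_GLC, rel=1e-12)
            assert r.fba == pytest.approx(F_GLC, rel=1e-12)
            assert r.pyk == pytest.approx(F_GLC, rel=1e-12)
            assert r.pdh == pytest.approx(2 * F_GLC, rel=1e-12)
            assert r.pfk - r.fbpase == pytest.approx(F_GLC, rel=1e-9)

    def test_rates_nonnegative_on_random_states(self, calibrated_sets):
        rng = np.random.default_rng(5)
        for _ in range(50):
            p = calibrated_sets[rng.integers(len(calibrated_sets))]
            r = K.reaction_rates(random_state(rng), p)
            assert np.all(r.as_array() >= 0)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(K.InvalidStateError):
            K.MetaboliteState(1.0, 0.0, 1.0, 1.0)
        with pytest.raises(K.InvalidStateError):
            K.MetaboliteState(1.0, 1.0, -0.5, 1.0)


class TestMassBalance:
    def test_stoichiometric_arithmetic(self, neutral_params):
        # rates (1,2,2,2,2,2) -> derivatives (1, -2, 1, 1)
        r = K.reaction_rates(K.UNIT_STATE, neutral_params).as_array()
        assert np.allclose(r, [1, 2, 2, 2, 2, 2])
        assert np.allclose(
            K.mass_balance(K.UNIT_STATE, neutral_params), [1, -2, 1, 1]
        )

    def test_calibrated_unit_state_is_steady(self, calibrated_sets):
        for p in calibrated_sets:
            assert np.abs(K.mass_balance(K.UNIT_STATE, p)).max() < 1e-9

    def test_matches_euler_microstep(self, calibrated_sets):
        # derivative agrees with a finite difference of one explicit-Euler step
        rng = np.random.default_rng(11)
        h = 1e-8
        for p in calibrated_sets[:5]:
            s = random_state(rng)
            dx = K.mass_balance(s, p)
            x1 = s.as_array() + h * dx
            # second evaluation at the stepped state: derivative of the flow
            mid = 0.5 * (dx + K.mass_balance(K.MetaboliteState(*x1), p))
            assert np.allclose(mid, dx, rtol=1e-4)


class TestJacobian:
    def test_matches_finite_differences(self, calibrated_sets):
        rng = np.random.default_rng(2)
        worst = 0.0
        sets = (K.calibrate_vmax(K.sample_parameter_set(K.FULL_STRUCTURE, rng))
                for _ in range(100))
        for p in sets:
            s = random_state(rng)
            x0 = s.as_array()
            J = K.jacobian(s, p)
            Jfd = np.empty((4, 4))
            for j in range(4):
                h = 1e-6 * x0[j]
                xp, xm = x0.copy(), x0.copy()
                xp[j] += h
                xm[j] -= h
                Jfd[:, j] = (
                    K.mass_balance(K.MetaboliteState(*xp), p)
                    - K.mass_balance(K.MetaboliteState(*xm), p)
                ) / (2 * h)
            scale = np.abs(J).max()
            worst = max(worst, np.abs(J - Jfd).max() / scale)
        assert worst < 1e-4

    def test_structural_zero_without_pep_feedbacks(self, neutral_params):
        # a1 = a2 = 0: dFBP/dt has no PEP dependence
        J = K.jacobian(K.UNIT_STATE, neutral_params)
        assert J[1, 2] == 0.0

    def test_pyr_diagonal_negative(self, calibrated_sets):
        # PDH rises and PTS falls with PYR, so d(dPYR/dt)/dPYR < 0
        for p in calibrated_sets:
            assert K.jacobian(K.UNIT_STATE, p)[3, 3] < 0


class TestSampling:
    def test_ranges_and_loguniformity(self):
        rng = np.random.default_rng(0)
        draws = [K.sample_parameter_set(K.FULL_STRUCTURE, rng) for _ in range(4000)]
        for name in ("k1", "k2", "k3", "Km1", "Km2", "Km3", "Km4", "Km5"):
            v = np.array([getattr(d, name) for d in draws])
            assert v.min() >= 0.1 and v.max() <= 10.0
            u = (np.log(v) - np.log(0.1)) / (np.log(10) - np.log(0.1))
            assert stats.kstest(u, "uniform").pvalue > 1e-3
        for name in ("n1", "n2", "n3", "a1", "a2", "a3"):
            v = np.array([getattr(d, name) for d in draws])
            assert v.min() >= 1.0 and v.max() <= 4.0

    def test_inactive_exponents_zero(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = K.sample_parameter_set(K.NO_FEEDBACK_STRUCTURE, rng)
            assert p.a1 == p.a2 == p.a3 == 0.0

    def test_seed_reproducibility(self):
        a = K.sample_parameter_set(K.FULL_STRUCTURE, 42)
        b = K.sample_parameter_set(K.FULL_STRUCTURE, 42)
        assert a == b


class TestCalibration:
    def test_uptake_flux_value(self):
        assert K.glucose_uptake_flux() == pytest.approx(8 / 0.002 / 60)
        assert K.glucose_uptake_flux() == pytest.approx(66.6666666, abs=1e-4)

    def test_vmax1_substitution(self):
        p = K.ModelParameters(
            k1=1, k2=1, k3=1, Km1=1, Km2=1, Km3=1, Km4=1, Km5=1,
            n1=1, n2=1, n3=1, a1=0, a2=0, a3=0, flux_ratio=0.5,
        )
        c = K.calibrate_vmax(p)
        assert c.Vmax1 == pytest.approx(F_GLC * 4)

    def test_steady_state_by_construction(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = K.calibrate_vmax(K.sample_parameter_set(K.FULL_STRUCTURE, rng))
            assert np.abs(K.mass_balance(K.UNIT_STATE, p)).max() < 1e-9

    def test_degenerate_flux_ratio_rejected(self):
        p = K.sample_parameter_set(K.FULL_STRUCTURE, 0)
        with pytest.raises(K.CalibrationError):
            K.calibrate_vmax(replace(p, flux_ratio=1.0))
        with pytest.raises(K.CalibrationError):
            K.calibrate_vmax(replace(p, flux_ratio=1.2))


class TestStability:
    def test_diagonally_dominant_negative_is_stable(self, neutral_params):
        # neutral set: Jacobian at unit state should be comfortably stable
        J = K.jacobian(K.UNIT_STATE, neutral_params)
        assert np.all(np.linalg.eigvals(J).real < 0)
        assert K.is_stable(neutral_params)

    def test_threshold_is_strict(self, neutral_params):
        # scale the whole vector field so the leading eigenvalue real part
        # lands between -1e-5 and 0: must classify unstable
        lead = np.linalg.eigvals(K.jacobian(K.UNIT_STATE, neutral_params)).real.max()
        scale = 1e-6 / abs(lead)
        shrunk = replace(
            neutral_params,
            **{f: getattr(neutral_params, f) * scale for f in K.VMAX_FIELDS},
        )
        new_lead = np.linalg.eigvals(K.jacobian(K.UNIT_STATE, shrunk)).real.max()
        assert -1e-5 < new_lead < 0
        assert not K.is_stable(shrunk)

    def test_agrees_with_nudged_ode_behaviour(self):
        # stable-classified sets relax back to the unit state after a small nudge
        rng = np.random.default_rng(7)
        checked = 0
        while checked < 10:
            p = K.calibrate_vmax(K.sample_parameter_set(K.FULL_STRUCTURE, rng))
            if not K.is_stable(p):
                continue
            nudged = K.MetaboliteState(*(1.0 + 1e-4 * rng.standard_normal(4) / 10))
            traj = K.simulate_perturbation(
                p, factor=1.0, t_perturb=1.0, t_end=30.0, dt_out=0.5,
                initial_state=nudged,
            )
            assert np.abs(traj.states[-1] - 1.0).max() < 1e-3
            checked += 1


class TestEnsembleSampling:
    def test_postconditions(self):
        sets, rejected = K.sample_stable_ensemble(K.FULL_STRUCTURE, 10, rng=9)
        assert len(sets) == 10
        assert all(p.calibrated and K.is_stable(p) for p in sets)
        assert rejected >= 0

    def test_reproducible(self):
        a, ra = K.sample_stable_ensemble(K.FULL_STRUCTURE, 5, rng=4)
        b, rb = K.sample_stable_ensemble(K.FULL_STRUCTURE, 5, rng=4)
        assert a == b and ra == rb

    def test_both_outcomes_occur(self):
        sets, rejected = K.sample_stable_ensemble(K.FULL_STRUCTURE, 200, rng=8)
        assert rejected > 0  # some draws are unstable

    def test_rejection_cap(self):
        with pytest.raises(K.EnsembleExhaustedError):
            K.sample_stable_ensemble(K.FULL_STRUCTURE, 1000, rng=0, max_rejections=1)


class TestPerturbation:
    def test_unperturbed_stays_at_steady_state(self, calibrated_sets):
        traj = K.simulate_perturbation(calibrated_sets[0], factor=1.0, t_end=250.0)
        assert np.abs(traj.pyruvate - 1.0).max() < 1e-6
        assert np.allclose(traj.states[0], 1.0)

    def test_downshift_on_damped_set_settles(self, calibrated_sets):
        # pick a set whose eigenvalues are far from the imaginary axis
        damped = max(
            calibrated_sets,
            key=lambda p: -np.linalg.eigvals(K.jacobian(K.UNIT_STATE, p)).real.max(),
        )
        traj = K.simulate_perturbation(damped, factor=0.95)
        tail = traj.pyruvate[traj.times >= 225.0]
        assert tail.std() < 1e-4
        assert abs(tail.mean() - 1.0) > 1e-6  # moved to a new level

    def test_oscillating_fixture_sets_sustain(self):
        for p in load_oscillating_fixture():
            traj = K.simulate_perturbation(p, factor=0.95)
            tail = traj.pyruvate[traj.times >= 225.0]
            head = traj.pyruvate[(traj.times >= 60.0) & (traj.times < 85.0)]
            assert tail.max() - tail.min() > 0.01          # still swinging late
            assert tail.std() > 0.3 * head.std()           # not decaying away
            assert np.all(traj.states > 0)

    def test_positivity_under_shift(self, calibrated_sets):
        for p in calibrated_sets[:10]:
            traj = K.simulate_perturbation(p, factor=0.95, t_end=100.0)
            assert np.all(traj.states > 0)

    def test_invalid_window(self, calibrated_sets):
        with pytest.raises(ValueError):
            K.simulate_perturbation(calibrated_sets[0], t_perturb=300.0, t_end=250.0)
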