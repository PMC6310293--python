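"""Musculo-tendon strain stage: path polynomials, slack-length handling,
force balance and the condition-level strain simulations."""

import numpy as np
import pytest

import tendonheal.kinematics_strain as ks


@pytest.fixture(scope="module")
def units_rep():
    return ks.load_default_units(repaired=True)


@pytest.fixture(scope="module")
def units_unrep():
    return ks.load_default_units(repaired=False)


@pytest.fixture(scope="module")
def gait():
    return ks.JointTrajectory.rat_gait()


@pytest.fixture(scope="module")
def schedule():
    return ks.ActivationSchedule()


# --------------------------------------------------------------------------
# path length
# --------------------------------------------------------------------------

class TestMtLength:
    def test_reference_posture_is_constant_term(self, units_rep):
        for u in units_rep:
            zero = {"hip": 0.0, "knee": 0.0, "ankle": 0.0}
            assert ks.mt_length(zero, u) == pytest.approx(
                u.mt_length_coefficients["const"])

    def test_dorsiflexion_lengthens_every_unit(self, units_rep):
        for u in units_rep:
            dorsi = ks.mt_length({"hip": 0, "knee": -30, "ankle": 10}, u)
            plantar = ks.mt_length({"hip": 0, "knee": -30, "ankle": -10}, u)
            assert dorsi > plantar

    def test_matches_direct_polynomial_evaluation(self, units_rep, gait):
        # independent oracle: evaluate the polynomial directly at 100 points
        idx = np.linspace(0, gait.times.size - 1, 100).astype(int)
        for u in units_rep:
            c = u.mt_length_coefficients
            for i in idx:
                a = gait.angles_at(i)
                expected = (c["const"] + c["hip"] * a["hip"]
                            + c["knee"] * a["knee"] + c["ankle"] * a["ankle"]
                            + c.get("ankle2", 0.0) * a["ankle"] ** 2)
                assert ks.mt_length(a, u) == pytest.approx(expected, abs=1e-12)

    def test_angle_outside_calibrated_range_raises(self, units_rep):
        with pytest.raises(ValueError, match="outside calibrated range"):
            ks.mt_length({"hip": 0, "knee": 0, "ankle": 60}, units_rep[0])


# --------------------------------------------------------------------------
# transection gap and callus stiffness
# --------------------------------------------------------------------------

@pytest.mark.parametrize("tsl, gap, expected",
                         [(20.0, 7.0, 27.0), (20.0, 0.0, 20.0),
                          (12.5, 7.0, 19.5)])
def test_transection_gap_shifts_slack_length_exactly(tsl, gap, expected):
    assert ks.apply_transection_gap(tsl, gap) == expected


def test_negative_gap_rejected():
    with pytest.raises(ValueError):
        ks.apply_transection_gap(20.0, -1.0)


class TestCallusScaling:
    def test_printed_modulus_scaling(self):
        curve = ks.TendonForceCurve(linear_slope=175.0)
        assert ks.scale_callus_stiffness(curve, 5.0).linear_slope == 35.0

    def test_factor_one_is_identity(self):
        curve = ks.TendonForceCurve(linear_slope=20.0, toe_strain=0.03)
        assert ks.scale_callus_stiffness(curve, 1.0) == curve

    def test_force_divided_pointwise(self):
        curve = ks.TendonForceCurve(linear_slope=20.0, toe_strain=0.03)
        soft = ks.scale_callus_stiffness(curve, 5.0)
        for eps in np.linspace(0.001, 0.2, 20):
            assert soft.force(eps) == pytest.approx(curve.force(eps) / 5.0)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            ks.scale_callus_stiffness(ks.TendonForceCurve(), 0.5)


# --------------------------------------------------------------------------
# tendon slack length estimation
# --------------------------------------------------------------------------

def _sweep_for(unit, tsl_true, angles_list):
    """Forward-generate target normalized fiber lengths for a known TSL."""
    return [(a, (ks.mt_length(a, unit) - tsl_true) / unit.optimal_fiber_length)
            for a in angles_list]


ANGLES = [{"hip": 0, "knee": -40 + 5 * i, "ankle": -30 + 5 * i}
          for i in range(8)]


def _feasible_tsl(unit):
    """A ground-truth TSL whose implied fiber-length targets lie in (0, 2)."""
    lengths = [ks.mt_length(a, unit) for a in ANGLES]
    return min(lengths) - 0.5 * unit.optimal_fiber_length


class TestTslEstimation:
    def test_recovers_known_slack_length(self, units_rep):
        unit = units_rep[0]
        tsl_true = _feasible_tsl(unit)
        sweep = _sweep_for(unit, tsl_true, ANGLES)
        assert ks.estimate_tendon_slack_length(unit, sweep) == pytest.approx(
            tsl_true, abs=1e-6)

    def test_consistent_sweep_is_fixed_point(self, units_rep):
        unit = units_rep[0]
        sweep = _sweep_for(unit, unit.tendon_slack_length, ANGLES)
        assert ks.estimate_tendon_slack_length(unit, sweep) == pytest.approx(
            unit.tendon_slack_length, abs=1e-6)

    def test_single_posture_underdetermined(self, units_rep):
        sweep = _sweep_for(units_rep[0], 12.0, ANGLES[:1])
        with pytest.raises(ValueError):
            ks.estimate_tendon_slack_length(units_rep[0], sweep)

    def test_recovery_on_random_synthetic_units(self):
        # parameter recovery across 20 randomized fixture units
        rng = np.random.default_rng(42)
        for _ in range(20):
            unit = ks.MusculoTendonUnit(
                name="synthetic",
                optimal_fiber_length=rng.uniform(8, 25),
                tendon_slack_length=1.0,
                mt_length_coefficients={
                    "const": rng.uniform(35, 55),
                    "ankle": rng.uniform(0.05, 0.15),
                    "knee": rng.uniform(0.0, 0.05), "hip": 0.0})
            tsl_true = _feasible_tsl(unit) - rng.uniform(
                0.0, 0.5 * unit.optimal_fiber_length)
            sweep = _sweep_for(unit, tsl_true, ANGLES)
            est = ks.estimate_tendon_slack_length(unit, sweep)
            assert est == pytest.approx(tsl_true, abs=1e-4)


# --------------------------------------------------------------------------
# force balance
# --------------------------------------------------------------------------

class TestEquilibrium:
    def test_slack_tendon_carries_no_force(self, units_rep):
        unit = units_rep[0]
        assert ks.equilibrium_tendon_strain(
            unit, unit.tendon_slack_length * 0.9, 0.05) == 0.0

    def test_constant_force_muscle_matches_curve_inversion(self):
        # with an (effectively) length-independent muscle, the equilibrium
        # strain is the analytic inverse of the tendon force-strain curve
        curve = ks.TendonForceCurve(linear_slope=4.0, toe_strain=0.02)
        unit = ks.MusculoTendonUnit(
            name="flat", optimal_fiber_length=10.0, tendon_slack_length=20.0,
            mt_length_coefficients={"const": 40.0},
            tendon_curve=curve, fl_width=1e6, kpe=4.0, e0=1e6)
        for a in (0.05, 0.3, 1.0):
            eps = ks.equilibrium_tendon_strain(unit, 40.0, a)
            expected = a / 4.0 + 0.01  # linear-region inversion f = k(e - toe/2)
            assert eps == pytest.approx(expected, abs=1e-7)

    def test_activation_bounds_enforced(self, units_rep):
        with pytest.raises(ValueError):
            ks.equilibrium_tendon_strain(units_rep[0], 40.0, 0.01)

    def test_residual_is_closed_at_root(self, units_rep, gait):
        unit = units_rep[0]
        length = ks.mt_length(gait.angles_at(50), unit)
        eps = ks.equilibrium_tendon_strain(unit, length, 1.0)
        lt = unit.tendon_slack_length * (1 + eps)
        lnorm = (length - lt) / unit.optimal_fiber_length
        resid = unit.tendon_curve.force(eps) - unit.muscle_force(lnorm, 1.0)
        assert abs(resid) < 1e-8


# --------------------------------------------------------------------------
# condition simulations and operating points
# --------------------------------------------------------------------------

class TestOperatingPoints:
    """The four printed cell-strain operating points, +-15% fixture band."""

    def test_unrepaired_immobilized_static(self, units_unrep):
        cell = ks.to_cell_strain(ks.simulate_immobilized_strain(units_unrep))
        assert cell.strain[0] == pytest.approx(0.002, rel=0.15)
        assert cell.amplitude == 0.0

    def test_repaired_immobilized_static(self, units_rep):
        cell = ks.to_cell_strain(ks.simulate_immobilized_strain(units_rep))
        assert cell.strain[0] == pytest.approx(0.012, rel=0.15)

    def test_unrepaired_gait_oscillation(self, units_unrep, gait, schedule):
        cell = ks.to_cell_strain(
            ks.simulate_gait_strain(gait, schedule, units_unrep))
        assert cell.min == pytest.approx(0.009, rel=0.15)
        assert cell.max == pytest.approx(0.043, rel=0.15)

    def test_repaired_gait_oscillation(self, units_rep, gait, schedule):
        cell = ks.to_cell_strain(
            ks.simulate_gait_strain(gait, schedule, units_rep))
        assert cell.min == pytest.approx(0.011, rel=0.15)
        assert cell.max == pytest.approx(0.075, rel=0.15)


class TestSimulationStructure:
    def test_three_identical_units_average_to_one(self, units_rep, gait,
                                                  schedule):
        u = units_rep[0]
        single = ks.simulate_gait_strain(gait, schedule, [u])
        triple = ks.simulate_gait_strain(gait, schedule, [u, u, u])
        np.testing.assert_allclose(triple.strain, single.strain, atol=1e-12)

    def test_constant_posture_gait_equals_immobilized(self, units_rep):
        # swing-only activation at a fixed posture reduces to the
        # immobilized solution
        sched = ks.ActivationSchedule(stance_activation=0.05,
                                      swing_activation=0.05)
        t = np.linspace(0, 1, 21)
        traj = ks.JointTrajectory(
            t, np.zeros_like(t), np.full_like(t, -50.0),
            np.full_like(t, -30.0))
        gait_profile = ks.simulate_gait_strain(traj, sched, units_rep)
        immob = ks.simulate_immobilized_strain(units_rep)
        np.testing.assert_allclose(gait_profile.strain,
                                   immob.strain[0], atol=1e-10)

    def test_peak_strain_during_stance(self, units_rep, gait, schedule):
        profile = ks.simulate_gait_strain(gait, schedule, units_rep)
        t_peak = profile.times[np.argmax(profile.strain)]
        assert t_peak < gait.stance_fraction * gait.period

    def test_profile_periodicity(self, units_rep, gait, schedule):
        profile = ks.simulate_gait_strain(gait, schedule, units_rep)
        assert profile.strain[0] == pytest.approx(profile.strain[-1], abs=1e-6)


class TestCellScaling:
    def test_printed_factor(self):
        p = ks.StrainProfile(np.array([0.0, 1.0]), np.array([1.0, 1.0]))
        cell = ks.to_cell_strain(p)
        np.testing.assert_allclose(cell.strain, 0.28)
        assert cell.level == "cell"

    def test_zero_maps_to_zero_and_identity_factor(self):
        p = ks.StrainProfile(np.array([0.0, 1.0]), np.array([0.0, 0.5]))
        assert ks.to_cell_strain(p, factor=1.0).strain == pytest.approx(
            [0.0, 0.5])

    def test_double_application_rejected(self):
        p = ks.StrainProfile(np.array([0.0, 1.0]), np.array([0.1, 0.1]))
        with pytest.raises(ValueError):
            ks.to_cell_strain(ks.to_cell_strain(p))

    def test_linearity(self, units_rep, gait, schedule):
        profile = ks.simulate_gait_strain(gait, schedule, units_rep)
        scaled = ks.StrainProfile(profile.times, 3.0 * profile.strain)
        np.testing.assert_allclose(ks.to_cell_strain(scaled).strain,
                                   3.0 * ks.to_cell_strain(profile).strain)


# --------------------------------------------------------------------------
# invariants
# --------------------------------------------------------------------------

def _perturbed_units(repaired, factor):
    """Moment-arm coefficients scaled by +-20% around the fixtures."""
    units = ks.load_default_units(repaired=repaired)
    out = []
    for u in units:
        c = dict(u.mt_length_coefficients)
        for key in ("ankle", "knee", "ankle2"):
            if key in c:
                c[key] = c[key] * factor
        u2 = ks.MusculoTendonUnit(
            name=u.name, optimal_fiber_length=u.optimal_fiber_length,
            tendon_slack_length=u.tendon_slack_length,
            mt_length_coefficients=c, tendon_curve=u.tendon_curve,
            fl_width=u.fl_width, kpe=u.kpe, e0=u.e0)
        out.append(u2)
    return out


class TestConditionOrdering:
    @pytest.mark.parametrize("factor", [1.0, 0.8, 1.2])
    def test_repaired_strain_dominates_unrepaired(self, gait, schedule,
                                                  factor):
        rep = ks.simulate_gait_strain(gait, schedule,
                                      _perturbed_units(True, factor))
        unrep = ks.simulate_gait_strain(gait, schedule,
                                        _perturbed_units(False, factor))
        assert np.all(rep.strain >= unrep.strain - 1e-10)
        im_rep = ks.simulate_immobilized_strain(_perturbed_units(True, factor))
        im_unrep = ks.simulate_immobilized_strain(
            _perturbed_units(False, factor))
        assert im_rep.strain[0] >= im_unrep.strain[0] - 1e-10

    @pytest.mark.parametrize("repaired", [True, False])
    def test_gait_mean_exceeds_immobilized(self, gait, schedule, repaired):
        units = ks.load_default_units(repaired=repaired)
        assert (ks.simulate_gait_strain(gait, schedule, units).mean
                > ks.simulate_immobilized_strain(units).strain[0])

    def test_growing_gap_never_increases_strain(self, gait, schedule):
        base = ks.load_default_units(repaired=True)
        prev_gait = ks.simulate_gait_strain(gait, schedule, base).strain
        prev_im = ks.simulate_immobilized_strain(base).strain[0]
        for gap in (7.0, 10.0):
            units = [u.with_gap(gap) for u in base]
            cur_gait = ks.simulate_gait_strain(gait, schedule, units).strain
            cur_im = ks.simulate_immobilized_strain(units).strain[0]
            assert np.all(cur_gait <= prev_gait + 1e-10)
            assert cur_im <= prev_im + 1e-10
            prev_gait, prev_im = cur_gait, cur_im

    def test_strain_never_negative(self, gait, schedule, units_unrep):
        profile = ks.simulate_gait_strain(gait, schedule, units_unrep)
        assert np.all(profile.strain >= 0.0)

    def test_amplitude_identity(self, gait, schedule, units_rep):
        profile = ks.simulate_gait_strain(gait, schedule, units_rep)
        assert profile.amplitude == profile.max - profile.min


class TestActivationSchedule:
    def test_phase_values_and_ramp(self):
        s = ks.ActivationSchedule()
        assert s.activation(0.3, 1.0, 0.75) == 1.0
        assert s.activation(0.9, 1.0, 0.75) == 0.05
        mid_ramp = s.activation(0.755, 1.0, 0.75)
        assert 0.05 < mid_ramp < 1.0

    def test_invalid_ordering_rejected(self):
        with pytest.raises(ValueError):
            ks.ActivationSchedule(stance_activation=0.05,
                                  swing_activation=0.5)
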