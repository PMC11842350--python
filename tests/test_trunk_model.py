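import math
from importlib import resources

import numpy as np
import pandas as pd
import pytest

from liftrisk.signals import TimeSeries
from liftrisk.trunk_model import (
    G,
    MtuGroup,
    MtuParams,
    Role,
    SlackConfigurationError,
    Subject,
    activation,
    default_groups,
    emg_driven_moment,
    excitation_for_activation,
    flag_exceedance,
    force_length_active,
    force_length_passive,
    inverse_dynamics_moment,
    joint_reaction,
    mtu_force,
    mtu_geometry,
    normalize_loads,
)

FS = 340.0


def const_series(value, n=400, fs=FS):
    return TimeSeries(values=np.full(n, float(value)), fs=fs)


def make_subject(body_mass=80.0, trunk_mass=35.0, trunk_com=0.25,
                 arms_head_mass=0.0, arms_head_lever=0.0, load_lever=0.45):
    return Subject(
        subject_id="T", body_mass=body_mass, height=1.75,
        trunk_mass=trunk_mass, trunk_com_distance=trunk_com,
        trunk_inertia=trunk_mass * 0.3**2,
        arms_head_mass=arms_head_mass, arms_head_lever=arms_head_lever,
        load_lever=load_lever,
    )


def simple_group(role=Role.EXTENSOR, r0=0.05, f_max=1000.0, l_opt=0.1,
                 l_ts=0.2, l_ref=0.3, shape_A=-1.5, **kw):
    return MtuGroup(
        name=kw.pop("name", "g"), emg_channel=kw.pop("emg_channel", "ch"),
        role=role, n_units=1,
        params=MtuParams(f_max=f_max, l_opt=l_opt, l_ts=l_ts, shape_A=shape_A),
        moment_arm_coeffs=(r0,), l_ref=l_ref, **kw,
    )


class TestInverseDynamics:
    def test_static_stoop_hand_statics(self):
        # trunk 35 kg at 0.25 m and a 20 kg load at 0.45 m, fully flexed:
        # M = 35*9.81*0.25 + 20*9.81*0.45 = 174.1 N m
        subject = make_subject()
        angle = const_series(np.pi / 2)
        load = const_series(20.0 * G)
        m = inverse_dynamics_moment(angle, subject, load).values
        assert m[50] == pytest.approx(174.1, abs=0.1)

    def test_upright_static_no_load_zero_moment(self):
        m = inverse_dynamics_moment(const_series(0.0), make_subject()).values
        assert np.allclose(m, 0.0, atol=1e-9)

    def test_linearity_in_external_force(self):
        subject = make_subject()
        angle = const_series(np.pi / 2)
        m1 = inverse_dynamics_moment(angle, subject, const_series(20.0 * G)).values
        m2 = inverse_dynamics_moment(angle, subject, const_series(40.0 * G)).values
        load_term = 20.0 * G * subject.load_lever
        assert m2 - m1 == pytest.approx(np.full_like(m1, load_term))


class TestActivation:
    def test_endpoints(self):
        for A in (-3.0, -1.5, -0.01):
            assert activation(0.0, A) == pytest.approx(0.0)
            assert activation(1.0, A) == pytest.approx(1.0)

    def test_linear_limit(self):
        u = np.linspace(0, 1, 11)
        assert activation(u, -1e-6) == pytest.approx(u, abs=1e-5)
        assert activation(u, 0.0) == pytest.approx(u)

    def test_shape_minus_three_midpoint(self):
        expected = (math.exp(-1.5) - 1) / (math.exp(-3.0) - 1)
        assert activation(0.5, -3.0) == pytest.approx(expected)
        assert activation(0.5, -3.0) == pytest.approx(0.818, abs=1e-3)

    def test_monotone_and_invertible(self):
        u = np.linspace(0, 1, 51)
        a = activation(u, -2.2)
        assert np.all(np.diff(a) > 0)
        assert excitation_for_activation(a, -2.2) == pytest.approx(u, abs=1e-12)


class TestHillForce:
    def params(self, **kw):
        return MtuParams(f_max=kw.get("f_max", 500.0), l_opt=0.1, l_ts=0.2,
                         shape_A=-1.5)

    def test_optimal_isometric_gives_f_max(self):
        p = self.params()
        assert mtu_force(1.0, 0.3, 0.0, p) == pytest.approx(p.f_max)

    def test_inactive_below_optimal_no_force(self):
        p = self.params()
        assert mtu_force(0.0, 0.29, 0.0, p) == 0.0

    def test_stretched_isometric_active_plus_passive(self):
        p = self.params()
        l_mt = 0.2 + 1.2 * 0.1  # normalized fibre length 1.2
        expected = p.f_max * (force_length_active(1.2) + force_length_passive(1.2))
        assert mtu_force(1.0, l_mt, 0.0, p) == pytest.approx(expected)

    def test_slack_configuration_rejected(self):
        with pytest.raises(SlackConfigurationError):
            mtu_force(1.0, 0.15, 0.0, self.params())


class TestGeometry:
    def test_constant_arm_gives_linear_length(self):
        ext = simple_group(Role.EXTENSOR, r0=0.05)
        theta = np.linspace(-0.2, 1.6, 50)
        l_mt, r = mtu_geometry(theta, ext)
        assert r == pytest.approx(np.full_like(theta, 0.05))
        assert l_mt == pytest.approx(0.3 + 0.05 * theta)
        flex = simple_group(Role.FLEXOR, r0=0.05)
        l_f, _ = mtu_geometry(theta, flex)
        assert l_f == pytest.approx(0.3 - 0.05 * theta)

    def test_reference_posture_length(self):
        for g in default_groups():
            l_mt, _ = mtu_geometry(0.0, g)
            assert l_mt == pytest.approx(g.l_ref)

    def test_moment_arm_length_consistency_all_groups(self):
        # |dl/dtheta - role*r| < 1e-4 m across the model's angle range
        theta = np.linspace(-0.2, 1.6, 2001)
        h = theta[1] - theta[0]
        for g in default_groups():
            l_mt, r = mtu_geometry(theta, g)
            dl = np.gradient(l_mt, h)
            assert np.max(np.abs(dl - int(g.role) * r)) < 1e-4

    def test_mapping_totals_238_units(self):
        assert sum(g.n_units for g in default_groups()) == 238
        with resources.files("liftrisk.data").joinpath("emg_mtu_mapping.csv").open() as fh:
            table = pd.read_csv(fh, comment="#")
        assert len(table) == 11
        assert table["n_units"].sum() == 238


class TestEmgDrivenMoment:
    def test_zero_activation_short_fibres_zero_moment(self):
        g = simple_group()  # normalized fibre length 1.0 at theta=0
        angle = const_series(0.0)
        m = emg_driven_moment([g], {"g": np.zeros(angle.n_samples)}, angle)
        assert np.allclose(m.values, 0.0)

    def test_single_extensor_constant_moment(self):
        g = simple_group(r0=0.05, f_max=1000.0)
        angle = const_series(0.0)
        u = np.ones(angle.n_samples)
        m = emg_driven_moment([g], {"g": u}, angle)
        assert m.values == pytest.approx(np.full(angle.n_samples, 0.05 * 1000.0))

    def test_missing_channel_raises(self):
        g = simple_group()
        with pytest.raises(KeyError):
            emg_driven_moment([g], {}, const_series(0.0))


class TestJointReaction:
    def test_static_upright_compression_equals_weight(self):
        subject = make_subject(arms_head_mass=8.0, arms_head_lever=0.3)
        angle = const_series(0.0)
        loads = joint_reaction(angle, subject, np.zeros(angle.n_samples),
                               None, const_series(20.0 * G))
        total = (subject.trunk_mass + subject.arms_head_mass) * G + 20.0 * G
        assert loads.compression == pytest.approx(np.full(angle.n_samples, total))
        assert loads.shear == pytest.approx(np.zeros(angle.n_samples), abs=1e-9)

    def test_static_force_balance_residual(self):
        # independent 2D vector balance of the trunk free body
        subject = make_subject(arms_head_mass=8.0, arms_head_lever=0.3)
        theta0 = 0.7
        f_ext, f_flex = 850.0, 230.0
        angle = const_series(theta0)
        n = angle.n_samples
        loads = joint_reaction(
            angle, subject, np.zeros(n),
            {"e": np.full(n, f_ext), "f": np.full(n, f_flex)},
            const_series(20.0 * G),
        )
        axis = np.array([np.sin(theta0), np.cos(theta0)])    # trunk axis, up
        normal = np.array([np.cos(theta0), -np.sin(theta0)])  # anterior
        weight = ((subject.trunk_mass + subject.arms_head_mass) * G + 20.0 * G)
        j_vec = weight * np.array([0.0, 1.0]) + (f_ext + f_flex) * axis
        assert abs(loads.compression[n // 2] - j_vec @ axis) < 1e-6
        # anterior shear is the negative of the joint force's normal component
        assert abs(loads.shear[n // 2] + j_vec @ normal) < 1e-6

    def test_antagonist_pair_adds_to_compression_only(self):
        subject = make_subject()
        angle = const_series(0.4)
        n = angle.n_samples
        base = joint_reaction(angle, subject, np.zeros(n), None, 0.0)
        f = 300.0
        with_pair = joint_reaction(
            angle, subject, np.zeros(n),
            {"ext": np.full(n, f), "flex": np.full(n, f)}, 0.0,
        )
        assert with_pair.compression - base.compression == pytest.approx(np.full(n, 2 * f))
        assert with_pair.shear == pytest.approx(base.shear)

    def test_zero_gravity_zero_everything(self):
        # no external force, no motion, no muscle: loads scale with weight only
        subject = make_subject()
        angle = const_series(0.0)
        loads = joint_reaction(angle, subject, np.zeros(angle.n_samples), {}, 0.0)
        assert loads.compression == pytest.approx(
            np.full(angle.n_samples, subject.trunk_mass * G)
        )


class TestNormalizationAndLimits:
    def test_compression_equal_body_weight_is_one(self):
        subject = make_subject(body_mass=80.0)
        loads = joint_reaction(const_series(0.0), subject, np.zeros(400), None, 0.0)
        norm = normalize_loads(loads, subject)
        ratio = loads.compression / subject.body_weight
        assert norm.compression_bw == pytest.approx(ratio)

    def test_worked_magnitudes(self):
        subject = make_subject(body_mass=80.0)
        # 8.46 x BW for an 80 kg person is ~6.6 kN
        assert 8.46 * subject.body_weight == pytest.approx(6639, abs=5)
        # 174.1 N m over 80 kg body mass
        assert 174.1 / subject.body_mass == pytest.approx(2.18, abs=0.01)

    def test_flag_exceedance(self):
        subject = make_subject()
        loads = joint_reaction(const_series(0.0), subject, np.zeros(400),
                               {"m": np.full(400, 6000.0)}, 0.0)
        above, fraction = flag_exceedance(loads)
        assert fraction == 1.0
        low = joint_reaction(const_series(0.0), subject, np.zeros(400), None, 0.0)
        _, frac_low = flag_exceedance(low)
        assert frac_low == 0.0
        _, frac_override = flag_exceedance(low, limit=100.0)
        assert frac_override == 1.0


def test_coactivation_never_decreases_compression():
    """With the net moment held fixed, adding antagonist force (balanced by
    extra agonist force) strictly increases compression."""
    subject = make_subject()
    angle = const_series(0.5)
    n = angle.n_samples
    r_e, r_f = 0.05, 0.09
    comps = []
    for f_flex in (0.0, 100.0, 300.0, 600.0):
        f_ext = (100.0 * r_e + f_flex * r_f) / r_e  # moment fixed at 5 N m
        loads = joint_reaction(angle, subject, np.full(n, 5.0),
                               {"e": np.full(n, f_ext), "f": np.full(n, f_flex)}, 0.0)
        comps.append(loads.compression[n // 2])
    assert np.all(np.diff(comps) > 0)
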