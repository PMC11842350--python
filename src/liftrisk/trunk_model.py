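"""Planar EMG-driven lumbosacral trunk model.

A sagittal two-body reduction of a full lifting trunk model: a single rigid
trunk (with lumped arms + head) articulating on the pelvis at L5-S1, plus a
hand-held external load.  The trunk musculature is lumped into six active
muscle-tendon unit (MTU) groups driven by the six bilateral surface-EMG
channels (longissimus, iliocostalis, rectus abdominis, left/right) and one
passive pool for the unmeasured deep muscles.  Each group is a rigid-tendon
Hill-type actuator:

    F = f_max * [ a * f_l(l~) * f_v(v~) + f_p(l~) ]

with a Gaussian active force-length curve, a hyperbolic force-velocity curve
(eccentric plateau 1.4) and an exponential passive curve, where
l~ = (l_mt - l_ts) / l_opt is the normalised fibre length.

Sign conventions
----------------
The lumbosacral angle theta is FLEXION-positive (forward bending);
joint moments are EXTENSION-positive.  Extensor groups lengthen with
flexion (dl/dtheta = +r), flexors shorten (dl/dtheta = -r), where r >= 0 is
the moment-arm magnitude; equivalently r = -dl/dtheta in the
extension-angle coordinate.  A group's extension moment is role * r * F
with role = +1 for extensors and -1 for flexors.

The net L5-S1 load is obtained from a planar Newton-Euler balance of the
trunk free body with all muscle lines of action taken parallel to the trunk
longitudinal axis, decomposed into compression (along the trunk axis) and
anteroposterior shear.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np

from .signals import TimeSeries

G = 9.81  # m/s^2

__all__ = [
    "G",
    "Role",
    "Subject",
    "MtuParams",
    "MtuGroup",
    "JointLoadSeries",
    "SlackConfigurationError",
    "default_groups",
    "mtu_geometry",
    "activation",
    "excitation_for_activation",
    "force_length_active",
    "force_velocity",
    "force_length_passive",
    "mtu_force",
    "inverse_dynamics_moment",
    "emg_driven_moment",
    "joint_reaction",
    "normalize_loads",
    "flag_exceedance",
    "NIOSH_COMPRESSION_LIMIT_N",
    "THETA_RANGE",
]

NIOSH_COMPRESSION_LIMIT_N = 3400.0
THETA_RANGE = (-0.2, 1.6)  # rad, model validity range in flexion

# Hill curve constants (dimensionless)
FL_WIDTH = 0.45            # Gaussian active force-length width
FV_SHAPE = 0.25            # concentric hyperbola curvature
FV_ECC_PLATEAU = 1.4       # eccentric asymptote
FV_ECC_SHAPE = 0.2
FP_EXP_RATE = 10.0         # passive exponential rate
FP_EXP_NORM = math.exp(5.0) - 1.0
VMAX_LOPT_PER_S = 10.0     # maximal shortening velocity, optimal lengths/s


class SlackConfigurationError(ValueError):
    """Fibre length is non-positive under the rigid-tendon assumption."""


class Role(enum.IntEnum):
    """Sagittal action of a group: +1 extensor, -1 flexor."""

    EXTENSOR = 1
    FLEXOR = -1


@dataclass(frozen=True)
class Subject:
    """Anthropometry of one participant for the planar trunk model.

    Segment parameters are expressed relative to the L5-S1 joint: the trunk
    centre of mass, the lumped arms+head mass, and the hand (knuckle) lever
    through which the external load acts.
    """

    subject_id: str
    body_mass: float          # kg
    height: float             # m
    trunk_mass: float         # kg
    trunk_com_distance: float  # m, along trunk axis from L5-S1
    trunk_inertia: float      # kg m^2 about L5-S1
    arms_head_mass: float     # kg
    arms_head_lever: float    # m
    load_lever: float         # m, hands from L5-S1 along trunk axis

    def __post_init__(self) -> None:
        if self.body_mass <= 0 or self.trunk_mass <= 0:
            raise ValueError("masses must be positive")
        if self.trunk_mass >= self.body_mass:
            raise ValueError("trunk_mass must be smaller than body_mass")

    @property
    def body_weight(self) -> float:
        """N."""
        return self.body_mass * G


@dataclass(frozen=True)
class MtuParams:
    """Hill-type parameters of one lumped MTU group."""

    f_max: float    # N, maximal isometric force
    l_opt: float    # m, optimal fibre length
    l_ts: float     # m, tendon slack length
    shape_A: float  # activation nonlinearity shape factor, [-3, 0)

    def __post_init__(self) -> None:
        if min(self.f_max, self.l_opt, self.l_ts) <= 0:
            raise ValueError("f_max, l_opt and l_ts must be positive")
        if not (-3.0 <= self.shape_A < 0.0) and self.shape_A != 0.0:
            raise ValueError("shape_A must lie in [-3, 0) (0 = linear limit)")


@dataclass(frozen=True)
class MtuGroup:
    """One lumped muscle-tendon group of the planar model.

    ``moment_arm_coeffs`` are ascending polynomial coefficients of the
    moment-arm magnitude r(theta) in metres; ``l_ref`` is the MTU length at
    theta = 0.  ``n_units`` records how many MTUs of the full model the
    group lumps (the published channel->MTU mapping totals 238).
    """

    name: str
    emg_channel: str | None   # None for the passive pool
    role: Role
    n_units: int
    params: MtuParams
    moment_arm_coeffs: tuple[float, ...]
    l_ref: float
    passive_excitation: float = 0.0  # constant drive for unmeasured groups

    def __post_init__(self) -> None:
        if self.n_units <= 0:
            raise ValueError("n_units must be positive")
        if self.l_ref <= 0:
            raise ValueError("l_ref must be positive")


@dataclass(frozen=True)
class JointLoadSeries:
    """L5-S1 loads over one trial: raw and body-normalized."""

    fs: float
    t0: float
    moment: np.ndarray        # N m, extension positive
    compression: np.ndarray   # N, along trunk axis, positive compressive
    shear: np.ndarray         # N, anteroposterior, positive anterior
    moment_norm: np.ndarray | None = None      # N m / kg body mass
    compression_bw: np.ndarray | None = None   # multiples of body weight
    shear_bw: np.ndarray | None = None

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.moment.size) / self.fs


# --------------------------------------------------------------------------
# default lumped groups

_EXT_ARM = {"longissimus": (0.055, 0.005), "iliocostalis": (0.050, 0.004)}


def default_groups(shape_A: float = -1.5) -> list[MtuGroup]:
    """Six bilateral active groups plus one passive pool.

    Moment arms and lengths are generic adult values; per-subject strength
    differences are absorbed by calibration of the f_max scales.  Unit
    counts follow the published channel->MTU mapping (238 MTUs total).
    """
    groups: list[MtuGroup] = []
    for side in ("left", "right"):
        groups.append(
            MtuGroup(
                name=f"longissimus_{side}",
                emg_channel=f"erector_spinae_longissimus_{side}",
                role=Role.EXTENSOR,
                n_units=9,
                params=MtuParams(f_max=2200.0, l_opt=0.18, l_ts=0.25, shape_A=shape_A),
                moment_arm_coeffs=(0.055, 0.005),
                l_ref=0.403,
            )
        )
        groups.append(
            MtuGroup(
                name=f"iliocostalis_{side}",
                emg_channel=f"erector_spinae_iliocostalis_{side}",
                role=Role.EXTENSOR,
                n_units=29,
                params=MtuParams(f_max=2600.0, l_opt=0.18, l_ts=0.22, shape_A=shape_A),
                moment_arm_coeffs=(0.050, 0.004),
                l_ref=0.373,
            )
        )
        groups.append(
            MtuGroup(
                name=f"rectus_abdominis_{side}",
                emg_channel=f"rectus_abdominis_middle_{side}",
                role=Role.FLEXOR,
                n_units=13,
                params=MtuParams(f_max=1000.0, l_opt=0.30, l_ts=0.15, shape_A=shape_A),
                moment_arm_coeffs=(0.090, -0.010),
                l_ref=0.495,
            )
        )
    groups.append(
        MtuGroup(
            name="deep_passive",
            emg_channel=None,
            role=Role.EXTENSOR,
            n_units=136,
            params=MtuParams(f_max=1500.0, l_opt=0.16, l_ts=0.20, shape_A=shape_A),
            moment_arm_coeffs=(0.045,),
            l_ref=0.352,
            passive_excitation=0.01,
        )
    )
    assert sum(g.n_units for g in groups) == 238
    return groups


# --------------------------------------------------------------------------
# geometry and Hill curves


def mtu_geometry(theta, group: MtuGroup):
    """Moment-arm magnitude r(theta) and MTU length l_mt(theta).

    l_mt(theta) = l_ref + role * integral_0^theta r, so that
    role * r = dl/dtheta (extensors lengthen with flexion).
    """
    theta = np.asarray(theta, dtype=float)
    c = np.asarray(group.moment_arm_coeffs, dtype=float)
    r = np.polynomial.polynomial.polyval(theta, c)
    # antiderivative of the moment-arm polynomial, zero at theta = 0
    anti = np.concatenate(([0.0], c / np.arange(1, c.size + 1)))
    l_mt = group.l_ref + int(group.role) * np.polynomial.polynomial.polyval(theta, anti)
    return l_mt, r


def activation(excitation, shape_A: float):
    """Nonlinear excitation-to-activation mapping.

    a(u) = (exp(A u) - 1) / (exp(A) - 1), monotone with a(0) = 0, a(1) = 1;
    shape_A = 0 is the linear limit a = u.
    """
    u = np.clip(np.asarray(excitation, dtype=float), 0.0, 1.0)
    if shape_A == 0.0:
        return u
    return np.expm1(shape_A * u) / np.expm1(shape_A)


def excitation_for_activation(a, shape_A: float):
    """Inverse of :func:`activation` on [0, 1]."""
    a = np.clip(np.asarray(a, dtype=float), 0.0, 1.0)
    if shape_A == 0.0:
        return a
    return np.log1p(a * np.expm1(shape_A)) / shape_A


def force_length_active(l_norm):
    """Gaussian active force-length curve, peak 1 at optimal length."""
    l_norm = np.asarray(l_norm, dtype=float)
    return np.exp(-(((l_norm - 1.0) / FL_WIDTH) ** 2))


def force_velocity(v_norm):
    """Hyperbolic force-velocity curve; v_norm = fibre velocity / v_max,
    positive lengthening.  f_v(0) = 1, f_v(-1) = 0, eccentric plateau 1.4."""
    v = np.asarray(v_norm, dtype=float)
    v_c = np.clip(v, -1.0, None)
    con = (1.0 + v_c) / (1.0 - v_c / FV_SHAPE)
    ecc = (FV_ECC_PLATEAU * v_c + FV_ECC_SHAPE) / (v_c + FV_ECC_SHAPE)
    return np.where(v_c < 0.0, con, ecc)


def force_length_passive(l_norm):
    """Exponential passive curve: zero at or below optimal length, capped at 1."""
    l_norm = np.asarray(l_norm, dtype=float)
    stretched = np.clip(l_norm - 1.0, 0.0, None)
    return np.minimum(np.expm1(FP_EXP_RATE * stretched) / FP_EXP_NORM, 1.0)


def mtu_force(a, l_mt, v_mt, params: MtuParams):
    """Rigid-tendon Hill-type MTU force (N), always >= 0.

    ``v_mt`` is the MTU lengthening velocity in m/s; with a rigid tendon it
    equals the fibre velocity.
    """
    l_fib = np.asarray(l_mt, dtype=float) - params.l_ts
    if np.any(l_fib <= 0.0):
        raise SlackConfigurationError(
            "fibre length <= 0: MTU shorter than its tendon slack length"
        )
    l_norm = l_fib / params.l_opt
    v_norm = np.asarray(v_mt, dtype=float) / (VMAX_LOPT_PER_S * params.l_opt)
    a = np.clip(np.asarray(a, dtype=float), 0.0, 1.0)
    f = params.f_max * (
        a * force_length_active(l_norm) * force_velocity(v_norm)
        + force_length_passive(l_norm)
    )
    return np.clip(f, 0.0, None)


# --------------------------------------------------------------------------
# dynamics


def _derivatives(theta: np.ndarray, fs: float):
    """Angular velocity and acceleration by central differences
    (one-sided at the endpoints)."""
    dt = 1.0 / fs
    omega = np.gradient(theta, dt)
    alpha = np.gradient(omega, dt)
    return omega, alpha


def inverse_dynamics_moment(
    angle: TimeSeries,
    subject: Subject,
    load_force: TimeSeries | float = 0.0,
) -> TimeSeries:
    """Net sagittal L5-S1 moment (extension positive) by inverse dynamics.

    M(t) = I theta'' + (m_t d_t + m_ah d_ah) g sin(theta)
           + F_load(t) d_load sin(theta)

    where F_load is the vertical hand force from the external load
    (including the load's inertial contribution if the caller provides it).
    The angle series is expected low-pass filtered.
    """
    theta = np.squeeze(angle.values)
    if isinstance(load_force, TimeSeries):
        f_load = np.squeeze(load_force.values)
        if f_load.shape != theta.shape:
            raise ValueError("load force series is not aligned with the angle series")
    else:
        f_load = np.full_like(theta, float(load_force))
    _, alpha = _derivatives(theta, angle.fs)
    grav_lever = (
        subject.trunk_mass * subject.trunk_com_distance
        + subject.arms_head_mass * subject.arms_head_lever
    )
    moment = (
        subject.trunk_inertia * alpha
        + grav_lever * G * np.sin(theta)
        + f_load * subject.load_lever * np.sin(theta)
    )
    return angle.with_values(moment)


def emg_driven_moment(
    groups: list[MtuGroup],
    excitations: dict[str, np.ndarray],
    angle: TimeSeries,
    return_forces: bool = False,
):
    """EMG-driven net extension moment M(t) = sum_i role_i r_i(theta) F_i(t).

    ``excitations`` maps group name -> normalized envelope (0..1) on the
    angle time base; groups with a ``passive_excitation`` fall back to that
    constant when no entry is present.  Raises ``KeyError`` for a missing
    non-passive channel.
    """
    theta = np.squeeze(angle.values)
    omega, _ = _derivatives(theta, angle.fs)
    total = np.zeros_like(theta)
    forces: dict[str, np.ndarray] = {}
    for g in groups:
        if g.name in excitations:
            u = excitations[g.name]
        elif g.emg_channel is None:
            u = np.full_like(theta, g.passive_excitation)
        else:
            raise KeyError(f"no excitation provided for measured group {g.name!r}")
        a = activation(u, g.params.shape_A)
        l_mt, r = mtu_geometry(theta, g)
        v_mt = int(g.role) * r * omega  # dl/dt = role * r * theta_dot
        f = mtu_force(a, l_mt, v_mt, g.params)
        forces[g.name] = f
        total = total + int(g.role) * r * f
    if return_forces:
        return angle.with_values(total), forces
    return angle.with_values(total)


def joint_reaction(
    angle: TimeSeries,
    subject: Subject,
    moment: np.ndarray,
    muscle_forces: dict[str, np.ndarray] | None = None,
    load_force: TimeSeries | float = 0.0,
) -> JointLoadSeries:
    """L5-S1 joint load from a planar Newton-Euler balance of the trunk.

    All muscle lines of action are taken parallel to the trunk longitudinal
    axis, so muscle tension loads the joint in pure compression:

    compression = [(m_t + m_ah) g + F_load] cos(theta) + sum_i F_i
                  - (m_t d_t + m_ah d_ah) theta_dot^2
    shear       = [(m_t + m_ah) g + F_load] sin(theta)
                  + (m_t d_t + m_ah d_ah) theta_ddot

    The centripetal and tangential terms are the trunk's own inertial
    contributions; the external load's inertia enters through F_load.
    """
    theta = np.squeeze(angle.values)
    if isinstance(load_force, TimeSeries):
        f_load = np.squeeze(load_force.values)
    else:
        f_load = np.full_like(theta, float(load_force))
    omega, alpha = _derivatives(theta, angle.fs)
    m_seg = subject.trunk_mass + subject.arms_head_mass
    first_moment = (
        subject.trunk_mass * subject.trunk_com_distance
        + subject.arms_head_mass * subject.arms_head_lever
    )
    axial_grav = (m_seg * G + f_load) * np.cos(theta)
    muscle_sum = np.zeros_like(theta)
    if muscle_forces:
        for f in muscle_forces.values():
            muscle_sum = muscle_sum + f
    compression = axial_grav + muscle_sum - first_moment * omega**2
    shear = (m_seg * G + f_load) * np.sin(theta) + first_moment * alpha
    return JointLoadSeries(
        fs=angle.fs,
        t0=angle.t0,
        moment=np.asarray(moment, dtype=float),
        compression=compression,
        shear=shear,
    )


def normalize_loads(loads: JointLoadSeries, subject: Subject) -> JointLoadSeries:
    """Body-normalize: moment per kg body mass, forces per body weight (N)."""
    return replace(
        loads,
        moment_norm=loads.moment / subject.body_mass,
        compression_bw=loads.compression / subject.body_weight,
        shear_bw=loads.shear / subject.body_weight,
    )


def flag_exceedance(loads: JointLoadSeries, limit: float = NIOSH_COMPRESSION_LIMIT_N):
    """Samples whose compression exceeds ``limit`` (default 3.4 kN) and the
    fraction of the series above it."""
    above = loads.compression > limit
    return above, float(above.mean())
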