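"""Subject-specific calibration of the lumped trunk MTU parameters.

The EMG-driven moment depends on each group's Hill parameters; calibration
personalises them by minimising the mismatch between the EMG-driven and
the inverse-dynamics lumbosacral moments over designated calibration
trials (the low- and high-risk conditions, so the model generalises across
the intermediate one):

    J(p) = mean over trials of  RMSE(M_emg(p) - M_id) / max|M_id|

Left/right homologous groups share parameters (symmetric lifting), so the
default adjustable set is 7-dimensional: an f_max scale and an activation
shape factor per group type (longissimus, iliocostalis, rectus abdominis)
plus one shared optimal-fibre-length scale.  The optimiser is a bounded
derivative-free local search (Powell) with seeded random restarts, which
is deterministic for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize

from . import trunk_model as tm
from .signals import TimeSeries
from .trunk_model import MtuGroup, default_groups

__all__ = [
    "GROUP_TYPES",
    "CalTrial",
    "CalibrationConfig",
    "CalibrationResult",
    "CalibrationError",
    "DegenerateTrialError",
    "build_groups",
    "objective",
    "calibrate",
    "validate",
]

GROUP_TYPES = ("longissimus", "iliocostalis", "rectus_abdominis")

# (kind, group_type-or-None); None = shared across all groups
DEFAULT_ADJUSTABLE: tuple[tuple[str, str | None], ...] = (
    ("f_max_scale", "longissimus"),
    ("f_max_scale", "iliocostalis"),
    ("f_max_scale", "rectus_abdominis"),
    ("shape_A", "longissimus"),
    ("shape_A", "iliocostalis"),
    ("shape_A", "rectus_abdominis"),
    ("l_opt_scale", None),
)

_BOUNDS = {
    "f_max_scale": (0.5, 2.5),
    "l_opt_scale": (0.5, 1.5),
    "l_ts_scale": (0.5, 1.5),
    "shape_A": (-3.0, -0.001),
}

_NEUTRAL = {"f_max_scale": 1.0, "l_opt_scale": 1.0, "l_ts_scale": 1.0, "shape_A": -1.5}


class CalibrationError(RuntimeError):
    """Optimisation failed on every restart."""


class DegenerateTrialError(ValueError):
    """A calibration trial has a zero-variance inverse-dynamics moment."""


@dataclass
class CalTrial:
    """Processed inputs of one trial as the calibration consumes them."""

    name: str
    condition: int                        # designed LI level
    angle: TimeSeries                     # rad, motion rate
    m_id: np.ndarray                      # inverse-dynamics moment, N m
    excitations: dict[str, np.ndarray]    # per group name, motion rate

    def __post_init__(self) -> None:
        peak = float(np.max(np.abs(self.m_id)))
        if peak <= 0:
            raise DegenerateTrialError(f"trial {self.name}: flat ID moment")
        self.peak_m_id = peak


@dataclass(frozen=True)
class CalibrationConfig:
    adjustable: tuple[tuple[str, str | None], ...] = DEFAULT_ADJUSTABLE
    calibration_conditions: tuple[int, ...] = (1, 3)
    seed: int = 0
    restarts: int = 5
    max_evaluations: int = 4000   # per restart; 0 returns the initial point
    xtol: float = 1e-6

    def __post_init__(self) -> None:
        if not self.adjustable:
            raise ValueError("adjustable parameter set must be non-empty")
        if not self.calibration_conditions:
            raise ValueError("calibration_conditions must be non-empty")

    @property
    def bounds(self) -> list[tuple[float, float]]:
        return [_BOUNDS[kind] for kind, _ in self.adjustable]

    @property
    def neutral_point(self) -> np.ndarray:
        return np.array([_NEUTRAL[kind] for kind, _ in self.adjustable])


@dataclass
class CalibrationResult:
    params: dict[str, float]
    groups: list[MtuGroup]
    objective: float
    per_trial_rmse: dict[str, float]          # N m
    per_trial_rmse_norm: dict[str, float]     # fraction of peak |M_id|
    converged: bool
    n_evaluations: int
    config: CalibrationConfig
    x: np.ndarray = field(repr=False, default=None)


def build_groups(
    x: np.ndarray,
    adjustable: tuple[tuple[str, str | None], ...],
    base: list[MtuGroup] | None = None,
) -> list[MtuGroup]:
    """Apply a calibration vector to the base groups (left/right shared)."""
    base = base if base is not None else default_groups()
    out = []
    for g in base:
        params = g.params
        for value, (kind, gtype) in zip(x, adjustable):
            if gtype is not None and not g.name.startswith(gtype):
                continue
            if kind == "f_max_scale":
                params = replace(params, f_max=g.params.f_max * value)
            elif kind == "l_opt_scale":
                params = replace(params, l_opt=g.params.l_opt * value)
            elif kind == "l_ts_scale":
                params = replace(params, l_ts=g.params.l_ts * value)
            elif kind == "shape_A":
                params = replace(params, shape_A=value)
            else:
                raise ValueError(f"unknown adjustable kind {kind!r}")
        out.append(replace(g, params=params))
    return out


def _prepare_cache(trials: list[CalTrial], base: list[MtuGroup]):
    """Precompute geometry and excitations per (trial, group) so repeated
    objective evaluations only redo the parameter-dependent arithmetic."""
    cache = []
    for trial in trials:
        theta = np.squeeze(trial.angle.values)
        omega, _ = tm._derivatives(theta, trial.angle.fs)
        entries = []
        for g in base:
            if g.name in trial.excitations:
                u = trial.excitations[g.name]
            elif g.emg_channel is None:
                u = np.full_like(theta, g.passive_excitation)
            else:
                raise KeyError(f"no excitation for measured group {g.name!r}")
            l_mt, r = tm.mtu_geometry(theta, g)
            v_mt = int(g.role) * r * omega
            entries.append((g, u, l_mt, r, v_mt))
        cache.append((trial, entries))
    return cache


def _cached_objective(x, adjustable, cache):
    scales = {"f_max_scale": 1.0, "l_opt_scale": 1.0, "l_ts_scale": 1.0}
    errs = []
    for trial, entries in cache:
        m = None
        for g, u, l_mt, r, v_mt in entries:
            s = dict(scales)
            shape_A = g.params.shape_A
            for value, (kind, gtype) in zip(x, adjustable):
                if gtype is not None and not g.name.startswith(gtype):
                    continue
                if kind == "shape_A":
                    shape_A = value
                else:
                    s[kind] = value
            l_opt = g.params.l_opt * s["l_opt_scale"]
            l_fib = l_mt - g.params.l_ts * s["l_ts_scale"]
            l_norm = np.clip(l_fib, 1e-6, None) / l_opt
            a = tm.activation(u, shape_A)
            f = g.params.f_max * s["f_max_scale"] * (
                a
                * tm.force_length_active(l_norm)
                * tm.force_velocity(v_mt / (tm.VMAX_LOPT_PER_S * l_opt))
                + tm.force_length_passive(l_norm)
            )
            contrib = int(g.role) * r * np.clip(f, 0.0, None)
            m = contrib if m is None else m + contrib
        errs.append(np.sqrt(np.mean((m - trial.m_id) ** 2)) / trial.peak_m_id)
    return float(np.mean(errs))


def _moment_errors(groups: list[MtuGroup], trials: list[CalTrial]):
    rmse, rmse_norm = {}, {}
    for trial in trials:
        m_emg = np.squeeze(
            tm.emg_driven_moment(groups, trial.excitations, trial.angle).values
        )
        e = float(np.sqrt(np.mean((m_emg - trial.m_id) ** 2)))
        rmse[trial.name] = e
        rmse_norm[trial.name] = e / trial.peak_m_id
    return rmse, rmse_norm


def objective(groups: list[MtuGroup], trials: list[CalTrial]) -> float:
    """Mean over trials of moment-tracking RMSE normalised by peak |M_id|."""
    if not trials:
        raise ValueError("no calibration trials")
    _, rmse_norm = _moment_errors(groups, trials)
    return float(np.mean(list(rmse_norm.values())))


def calibrate(
    trials: list[CalTrial],
    cfg: CalibrationConfig | None = None,
    base: list[MtuGroup] | None = None,
) -> CalibrationResult:
    """Personalise MTU parameters on the calibration-condition trials.

    Multi-start bounded Powell search: the first start is the neutral
    point, the rest are seeded uniform draws within bounds.  Deterministic
    for a given seed; the final objective never exceeds the initial one.
    """
    cfg = cfg or CalibrationConfig()
    cal_trials = [t for t in trials if t.condition in cfg.calibration_conditions]
    have = {t.condition for t in cal_trials}
    missing = set(cfg.calibration_conditions) - have
    if missing:
        raise CalibrationError(f"no trials for calibration condition(s) {sorted(missing)}")

    bounds = cfg.bounds
    base = base if base is not None else default_groups()

    cache = _prepare_cache(cal_trials, base)

    def f(x: np.ndarray) -> float:
        return _cached_objective(x, cfg.adjustable, cache)

    rng = np.random.default_rng(cfg.seed)
    starts = [cfg.neutral_point]
    for _ in range(max(cfg.restarts - 1, 0)):
        starts.append(np.array([rng.uniform(lo, hi) for lo, hi in bounds]))

    best_x = starts[0]
    best_f = f(best_x)
    n_eval = 1
    converged = False
    if cfg.max_evaluations > 0:
        any_success = False
        any_result = False
        for x0 in starts:
            try:
                res = minimize(
                    f,
                    x0,
                    method="Powell",
                    bounds=bounds,
                    options={
                        "maxfev": cfg.max_evaluations,
                        "xtol": cfg.xtol,
                        "ftol": cfg.xtol,
                    },
                )
            except Exception:
                continue
            any_result = True
            n_eval += int(res.nfev)
            any_success = any_success or bool(res.success)
            if res.fun < best_f:
                best_f = float(res.fun)
                best_x = np.clip(res.x, [b[0] for b in bounds], [b[1] for b in bounds])
        converged = any_success
        if not any_result:
            raise CalibrationError(
                f"optimiser failed on all {len(starts)} restarts "
                f"(best objective so far {best_f:.4f})"
            )
    groups = build_groups(best_x, cfg.adjustable, base)
    rmse, rmse_norm = _moment_errors(groups, cal_trials)
    names = [f"{kind}:{gtype or 'shared'}" for kind, gtype in cfg.adjustable]
    return CalibrationResult(
        params=dict(zip(names, best_x.tolist())),
        groups=groups,
        objective=best_f,
        per_trial_rmse=rmse,
        per_trial_rmse_norm=rmse_norm,
        converged=converged,
        n_evaluations=n_eval,
        config=cfg,
        x=best_x,
    )


def validate(result: CalibrationResult, held_out: list[CalTrial]) -> dict[str, dict[str, float]]:
    """Moment-tracking errors of the calibrated model on held-out trials.

    Pure evaluation (no parameter updates): per-trial RMSE in N m and as a
    fraction of that trial's peak |M_id|.
    """
    rmse, rmse_norm = _moment_errors(result.groups, held_out)
    return {
        name: {"rmse_nm": rmse[name], "rmse_norm": rmse_norm[name]}
        for name in rmse
    }
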