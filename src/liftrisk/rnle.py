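"""Revised NIOSH Lifting Equation (RNLE).

The RNLE estimates the recommended weight limit (RWL) for a two-handed
manual lifting task as the product of a 23 kg load constant and six
attenuating multipliers derived from the task geometry and organisation::

    RWL = LC * HM * VM * DM * AM * FM * CM
    LI  = load_mass / RWL

with the horizontal (HM), vertical (VM), travel-distance (DM), asymmetry
(AM), frequency (FM) and coupling (CM) multipliers.  The lifting index LI
expresses the actual load as a fraction of the recommended limit; LI <= 1
is considered low risk and LI > 3 extremely stressful.

Multiplier definitions follow the metric Applications-Manual conventions:

==========  =====================  ===========================================
multiplier  formula                admissible range (outside -> multiplier 0)
==========  =====================  ===========================================
HM          25 / H                 H in [25, 63] cm (H < 25 clamped to 25)
VM          1 - 0.003 |V - 75|     V in [0, 175] cm
DM          0.82 + 4.5 / D         D in [25, 175] cm (D < 25 clamped to 25)
AM          1 - 0.0032 A           A in [0, 135] degrees
FM          lookup table           F in [0.2, 15] lifts/min, by duration and V
CM          lookup table           coupling quality by V band
==========  =====================  ===========================================

This module also inverts the equation (:func:`design_task_for_li`) to
construct task geometries that realise a prescribed lifting index for a
given load, which is how the three study risk conditions (LI = 1, 2, 3)
are built.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from importlib import resources

import numpy as np
import pandas as pd
from scipy.optimize import brentq

LOAD_CONSTANT_KG = 23.0

__all__ = [
    "LOAD_CONSTANT_KG",
    "DurationClass",
    "Coupling",
    "RiskLevel",
    "LiftingTask",
    "RnleResult",
    "InvalidTaskError",
    "DegenerateTaskError",
    "InfeasibleDesignError",
    "compute_multipliers",
    "compute_rwl",
    "compute_li",
    "design_task_for_li",
]


class DurationClass(str, enum.Enum):
    """Work-duration category of the lifting job."""

    ONE_HOUR = "<=1h"
    TWO_HOURS = "<=2h"
    EIGHT_HOURS = "<=8h"


class Coupling(str, enum.Enum):
    """Hand-to-object coupling quality."""

    GOOD = "good"
    FAIR = "fair"
    POOR = "poor"


class RiskLevel(str, enum.Enum):
    """Risk band derived from the lifting index.

    low <= 1.0 < medium <= 2.0 < high <= 3.0 < very_high, matching the three
    study conditions designed at LI = 1 (low), 2 (medium) and 3 (high).
    """

    LOW = "low"
    MEDIUM = "medium"
    HIGH = "high"
    VERY_HIGH = "very_high"


class InvalidTaskError(ValueError):
    """A task variable is non-finite or violates a hard invariant."""


class DegenerateTaskError(ValueError):
    """RWL is zero (some multiplier annihilated); LI is undefined."""


class InfeasibleDesignError(ValueError):
    """No admissible geometry reaches the requested lifting index."""


@dataclass(frozen=True)
class LiftingTask:
    """One lifting condition described by the RNLE task variables.

    Parameters
    ----------
    load_mass : float
        Mass of the lifted object, kg.
    H : float
        Horizontal location of the hands from the ankle midpoint, cm.
    V : float
        Vertical location of the hands at lift origin, cm.
    D : float
        Vertical travel distance of the lift, cm.
    A : float
        Asymmetry angle, degrees.
    F : float
        Lifting frequency, lifts/min.
    duration_class : DurationClass
    coupling : Coupling
    """

    load_mass: float
    H: float = 25.0
    V: float = 75.0
    D: float = 25.0
    A: float = 0.0
    F: float = 0.2
    duration_class: DurationClass = DurationClass.ONE_HOUR
    coupling: Coupling = Coupling.GOOD

    def __post_init__(self) -> None:
        numeric = {
            "load_mass": self.load_mass,
            "H": self.H,
            "V": self.V,
            "D": self.D,
            "A": self.A,
            "F": self.F,
        }
        for name, value in numeric.items():
            if not math.isfinite(value):
                raise InvalidTaskError(f"task variable {name} is not finite: {value!r}")
        if self.load_mass <= 0:
            raise InvalidTaskError("load_mass must be positive")
        for name in ("H", "V", "D", "A", "F"):
            if numeric[name] < 0:
                raise InvalidTaskError(f"task variable {name} must be >= 0")
        object.__setattr__(self, "duration_class", DurationClass(self.duration_class))
        object.__setattr__(self, "coupling", Coupling(self.coupling))


@dataclass(frozen=True)
class RnleResult:
    """Multipliers, RWL, LI and risk band for one task."""

    LC: float
    HM: float
    VM: float
    DM: float
    AM: float
    FM: float
    CM: float
    RWL: float
    LI: float | None = None
    risk_level: RiskLevel | None = None
    clamped: tuple[str, ...] = field(default_factory=tuple)
    zeroed: tuple[str, ...] = field(default_factory=tuple)

    @property
    def multipliers(self) -> dict[str, float]:
        return {m: getattr(self, m) for m in ("HM", "VM", "DM", "AM", "FM", "CM")}


def _load_table(name: str) -> pd.DataFrame:
    with resources.files("liftrisk.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


_FM_TABLE = _load_table("fm_table.csv")
_CM_TABLE = _load_table("cm_table.csv").set_index("coupling")

_DURATION_COL = {
    DurationClass.ONE_HOUR: "le1h",
    DurationClass.TWO_HOURS: "le2h",
    DurationClass.EIGHT_HOURS: "le8h",
}


def frequency_multiplier(F: float, duration_class: DurationClass, V: float) -> float:
    """FM from the lookup table; frequency rounded up to the next tabulated row."""
    if F > _FM_TABLE["frequency"].iloc[-1]:
        return 0.0
    F = max(F, _FM_TABLE["frequency"].iloc[0])
    row = _FM_TABLE[_FM_TABLE["frequency"] >= F - 1e-12].iloc[0]
    band = "vlt75" if V < 75.0 else "vge75"
    return float(row[f"{_DURATION_COL[DurationClass(duration_class)]}_{band}"])


def coupling_multiplier(coupling: Coupling, V: float) -> float:
    band = "vlt75" if V < 75.0 else "vge75"
    return float(_CM_TABLE.loc[Coupling(coupling).value, band])


def compute_multipliers(task: LiftingTask) -> RnleResult:
    """Evaluate the six RNLE multipliers for ``task``.

    Variables below the near-body/short-lift clamp (H < 25 cm, D < 25 cm)
    are clamped so their multiplier caps at 1; variables beyond the
    admissible range zero their multiplier (task not recommended), and both
    events are recorded in the result's ``clamped`` / ``zeroed`` fields.
    """
    clamped: list[str] = []
    zeroed: list[str] = []

    H = task.H
    if H < 25.0:
        H = 25.0
        clamped.append("H")
    if H > 63.0:
        HM = 0.0
        zeroed.append("H")
    else:
        HM = 25.0 / H

    if task.V > 175.0:
        VM = 0.0
        zeroed.append("V")
    else:
        VM = 1.0 - 0.003 * abs(task.V - 75.0)

    D = task.D
    if D < 25.0:
        D = 25.0
        clamped.append("D")
    if D > 175.0:
        DM = 0.0
        zeroed.append("D")
    else:
        DM = 0.82 + 4.5 / D

    if task.A > 135.0:
        AM = 0.0
        zeroed.append("A")
    else:
        AM = 1.0 - 0.0032 * task.A

    FM = frequency_multiplier(task.F, task.duration_class, task.V)
    if FM == 0.0:
        zeroed.append("F")
    CM = coupling_multiplier(task.coupling, task.V)

    mult = dict(HM=HM, VM=VM, DM=min(DM, 1.0), AM=AM, FM=FM, CM=CM)
    rwl = LOAD_CONSTANT_KG * float(np.prod(list(mult.values())))
    return RnleResult(
        LC=LOAD_CONSTANT_KG,
        **mult,
        RWL=rwl,
        clamped=tuple(clamped),
        zeroed=tuple(zeroed),
    )


def compute_rwl(task: LiftingTask) -> RnleResult:
    """Recommended weight limit: RWL = LC * HM * VM * DM * AM * FM * CM."""
    return compute_multipliers(task)


def compute_li(task: LiftingTask) -> RnleResult:
    """Lifting index LI = load_mass / RWL with the derived risk band."""
    result = compute_rwl(task)
    if result.RWL == 0.0:
        raise DegenerateTaskError(
            f"RWL is zero (multipliers zeroed for {result.zeroed}); LI undefined"
        )
    li = task.load_mass / result.RWL
    eps = 1e-9  # keep designed boundary indices (LI exactly 1, 2, 3) in-band
    if li <= 1.0 + eps:
        level = RiskLevel.LOW
    elif li <= 2.0 + eps:
        level = RiskLevel.MEDIUM
    elif li <= 3.0 + eps:
        level = RiskLevel.HIGH
    else:
        level = RiskLevel.VERY_HIGH
    return replace(result, LI=li, risk_level=level)


# Inverse design: move the free geometry variables along a single severity
# coordinate s in [0, 1], from their neutral values (multiplier = 1) to the
# worst admissible values, and root-solve RWL(s) = load / target_li.
_NEUTRAL = {"H": 25.0, "V": 75.0, "D": 25.0}
_WORST = {"H": 63.0, "V": 0.0, "D": 175.0}


def design_task_for_li(
    target_li: float,
    load_mass: float,
    free_vars: tuple[str, ...] = ("H", "V", "D"),
    fixed: LiftingTask | None = None,
    rel_tol: float = 1e-6,
) -> LiftingTask:
    """Construct a task whose computed LI equals ``target_li``.

    Only the geometry variables named in ``free_vars`` (subset of H, V, D)
    are moved; A, F, coupling and duration are taken from the ``fixed``
    template, so AM, FM and CM are identical across tasks designed from the
    same template — the construction used for the three study risk
    conditions.
    """
    if target_li <= 0:
        raise InfeasibleDesignError("target_li must be positive")
    if not free_vars:
        raise InfeasibleDesignError("at least one free variable is required")
    bad = set(free_vars) - {"H", "V", "D"}
    if bad:
        raise InfeasibleDesignError(f"free_vars must be a subset of H, V, D; got {bad}")
    template = fixed if fixed is not None else LiftingTask(load_mass=load_mass)
    template = replace(template, load_mass=load_mass)

    current = compute_li(template)
    if abs(current.LI - target_li) <= rel_tol * target_li:
        return template

    def task_at(s: float) -> LiftingTask:
        values = {
            v: _NEUTRAL[v] + s * (_WORST[v] - _NEUTRAL[v]) for v in free_vars
        }
        return replace(template, **values)

    def gap(s: float) -> float:
        return compute_li(task_at(s)).LI - target_li

    lo, hi = gap(0.0), gap(1.0)
    if not (min(lo, hi) <= 0.0 <= max(lo, hi)):
        raise InfeasibleDesignError(
            f"target LI {target_li} for load {load_mass} kg is outside the range "
            f"reachable by varying {free_vars} "
            f"(LI in [{min(lo, hi) + target_li:.3f}, {max(lo, hi) + target_li:.3f}])"
        )
    s_star = brentq(gap, 0.0, 1.0, xtol=1e-12, rtol=1e-14)
    designed = task_at(s_star)
    achieved = compute_li(designed).LI
    if abs(achieved - target_li) > 0.01 * target_li:
        raise InfeasibleDesignError(
            f"design converged to LI {achieved:.4f}, not within 1% of {target_li}"
        )
    return designed
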