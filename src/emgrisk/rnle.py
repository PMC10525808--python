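"""Revised NIOSH Lifting Equation (RNLE).

The recommended weight limit of a lifting task is the product

    RWL = LC * HM * VM * DM * AM * FM * GM

of a load constant LC and six dimensionless multipliers in [0, 1]:
horizontal (HM), vertical (VM), travel-distance (DM), asymmetry (AM),
frequency (FM) and coupling/grab (GM).  The lifting index LI = load / RWL
classifies the task: LI <= 1 acceptable (NO-RISK), LI > 1 risky (RISK).

Multiplier formulas and the frequency/coupling tables follow the NIOSH
Applications Manual, in metric units (cm, kg).  The load constant departs
from the manual's single 23 kg value and is sex- and age-banded instead:
25/20 kg for males under/over 45 years and 20/15 kg for females.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import ParameterError
from .simulate import NO_RISK, RISK

NOT_PERMISSIBLE = "NOT-PERMISSIBLE"

DURATION_CLASSES = ("<=1h", "<=2h", "<=8h")
_DURATION_ALIASES = {
    "<=1h": "<=1h", "1h": "<=1h", "≤1h": "<=1h",
    "<=2h": "<=2h", "2h": "<=2h", "≤2h": "<=2h",
    "<=8h": "<=8h", "8h": "<=8h", "≤8h": "<=8h",
}

#: Frequency-multiplier table (NIOSH Applications Manual).  Per lifting
#: frequency (lifts/min): {duration class: (FM for V < 75 cm, FM for V >= 75 cm)}.
_FM_TABLE: dict[float, dict[str, tuple[float, float]]] = {
    0.2: {"<=1h": (1.00, 1.00), "<=2h": (0.95, 0.95), "<=8h": (0.85, 0.85)},
    0.5: {"<=1h": (0.97, 0.97), "<=2h": (0.92, 0.92), "<=8h": (0.81, 0.81)},
    1:   {"<=1h": (0.94, 0.94), "<=2h": (0.88, 0.88), "<=8h": (0.75, 0.75)},
    2:   {"<=1h": (0.91, 0.91), "<=2h": (0.84, 0.84), "<=8h": (0.65, 0.65)},
    3:   {"<=1h": (0.88, 0.88), "<=2h": (0.79, 0.79), "<=8h": (0.55, 0.55)},
    4:   {"<=1h": (0.84, 0.84), "<=2h": (0.72, 0.72), "<=8h": (0.45, 0.45)},
    5:   {"<=1h": (0.80, 0.80), "<=2h": (0.60, 0.60), "<=8h": (0.35, 0.35)},
    6:   {"<=1h": (0.75, 0.75), "<=2h": (0.50, 0.50), "<=8h": (0.27, 0.27)},
    7:   {"<=1h": (0.70, 0.70), "<=2h": (0.42, 0.42), "<=8h": (0.22, 0.22)},
    8:   {"<=1h": (0.60, 0.60), "<=2h": (0.35, 0.35), "<=8h": (0.18, 0.18)},
    9:   {"<=1h": (0.52, 0.52), "<=2h": (0.30, 0.30), "<=8h": (0.00, 0.15)},
    10:  {"<=1h": (0.45, 0.45), "<=2h": (0.26, 0.26), "<=8h": (0.00, 0.13)},
    11:  {"<=1h": (0.41, 0.41), "<=2h": (0.00, 0.23), "<=8h": (0.00, 0.00)},
    12:  {"<=1h": (0.37, 0.37), "<=2h": (0.00, 0.21), "<=8h": (0.00, 0.00)},
    13:  {"<=1h": (0.00, 0.34), "<=2h": (0.00, 0.00), "<=8h": (0.00, 0.00)},
    14:  {"<=1h": (0.00, 0.31), "<=2h": (0.00, 0.00), "<=8h": (0.00, 0.00)},
    15:  {"<=1h": (0.00, 0.28), "<=2h": (0.00, 0.00), "<=8h": (0.00, 0.00)},
}

#: Coupling (grab) multiplier: {quality: (GM for V < 75 cm, GM for V >= 75 cm)}.
_GM_TABLE = {
    "good": (1.00, 1.00),
    "fair": (0.95, 1.00),
    "poor": (0.90, 0.90),
}


@dataclass(frozen=True)
class LiftingTaskParams:
    """Geometry, cadence and load of a single-task lift (metric units)."""

    sex: str  # 'M' or 'F'
    age_years: float
    load_kg: float
    H: float  # horizontal hand location, cm
    V: float  # vertical origin height, cm
    D: float  # vertical travel distance, cm
    A: float  # asymmetry angle, degrees
    F: float  # lifting frequency, lifts/min
    duration_class: str = "<=1h"
    coupling: str = "good"

    def validate(self) -> None:
        if self.sex not in ("M", "F"):
            raise ParameterError(f"sex must be 'M' or 'F', got {self.sex!r}")
        if self.load_kg <= 0:
            raise ParameterError("load_kg must be positive")
        if min(self.H, self.V, self.D) < 0:
            raise ParameterError("H, V, D must be nonnegative")
        if not 0 <= self.A <= 135:
            raise ParameterError("asymmetry angle must lie in [0, 135]")
        if self.F <= 0:
            raise ParameterError("lifting frequency must be positive")
        if self.duration_class not in _DURATION_ALIASES:
            raise ParameterError(
                f"unknown duration_class {self.duration_class!r}")
        if self.coupling not in _GM_TABLE:
            raise ParameterError(f"unknown coupling {self.coupling!r}")


@dataclass(frozen=True)
class RnleResult:
    """Multipliers, recommended weight limit and lifting index."""

    lc: float
    hm: float
    vm: float
    dm: float
    am: float
    fm: float
    gm: float
    rwl: float  # kg
    li: float  # load / rwl; inf when the task is not permissible
    risk_class: str  # NO-RISK, RISK, or NOT-PERMISSIBLE

    @property
    def task_permissible(self) -> bool:
        return self.rwl > 0


def load_constant(sex: str, age_years: float) -> float:
    """Sex- and age-banded load constant in kg.

    Males: 25 kg under 45 years, 20 kg from 45 up; females: 20 / 15 kg.
    Age exactly 45 falls in the older (lower-constant) band.
    """
    if age_years <= 0:
        raise ParameterError("age_years must be positive")
    if sex == "M":
        return 25.0 if age_years < 45 else 20.0
    if sex == "F":
        return 20.0 if age_years < 45 else 15.0
    raise ParameterError(f"sex must be 'M' or 'F', got {sex!r}")


def geometric_multipliers(params: LiftingTaskParams
                          ) -> tuple[float, float, float, float]:
    """(HM, VM, DM, AM) from the task geometry.

    HM = 25/H with H clamped to [25, 63] cm (beyond reach -> 0);
    VM = 1 - 0.003|V - 75| (V > 175 cm -> 0);
    DM = 0.82 + 4.5/D with D clamped to >= 25 cm (D > 175 -> 0);
    AM = 1 - 0.0032 A (A > 135 deg -> 0).
    """
    params.validate()
    hm = 0.0 if params.H > 63 else 25.0 / max(params.H, 25.0)
    vm = 0.0 if params.V > 175 else max(1.0 - 0.003 * abs(params.V - 75.0), 0.0)
    dm = 0.0 if params.D > 175 else 0.82 + 4.5 / max(params.D, 25.0)
    am = 0.0 if params.A > 135 else 1.0 - 0.0032 * params.A
    return hm, vm, dm, am


def frequency_multiplier(F: float, duration_class: str, V: float) -> float:
    """Frequency multiplier by table lookup with linear interpolation.

    Frequencies below the first tabulated row (0.2/min) use that row;
    frequencies above 15/min give 0.
    """
    if F <= 0:
        raise ParameterError("lifting frequency must be positive")
    try:
        duration = _DURATION_ALIASES[duration_class]
    except KeyError:
        raise ParameterError(f"unknown duration_class {duration_class!r}")
    col = 0 if V < 75.0 else 1
    freqs = sorted(_FM_TABLE)
    if F > freqs[-1]:
        return 0.0
    if F <= freqs[0]:
        return _FM_TABLE[freqs[0]][duration][col]
    for f_lo, f_hi in zip(freqs, freqs[1:]):
        if f_lo <= F <= f_hi:
            y_lo = _FM_TABLE[f_lo][duration][col]
            y_hi = _FM_TABLE[f_hi][duration][col]
            if f_hi == f_lo:
                return y_lo
            w = (F - f_lo) / (f_hi - f_lo)
            return y_lo + w * (y_hi - y_lo)
    raise AssertionError("unreachable")


def coupling_multiplier(coupling: str, V: float) -> float:
    """Grab (coupling) multiplier from the coupling quality and height."""
    try:
        lo, hi = _GM_TABLE[coupling]
    except KeyError:
        raise ParameterError(f"unknown coupling {coupling!r}")
    return lo if V < 75.0 else hi


def compute_rwl_li(params: LiftingTaskParams) -> RnleResult:
    """Full RNLE evaluation: multipliers, RWL, LI and risk class.

    Any zero multiplier makes RWL 0; the LI is then undefined (reported
    as infinity) and the task is flagged NOT-PERMISSIBLE.  Otherwise the
    class is RISK iff LI > 1; LI == 1 is treated as boundary-safe.
    """
    params.validate()
    lc = load_constant(params.sex, params.age_years)
    hm, vm, dm, am = geometric_multipliers(params)
    fm = frequency_multiplier(params.F, params.duration_class, params.V)
    gm = coupling_multiplier(params.coupling, params.V)
    rwl = lc * hm * vm * dm * am * fm * gm
    if rwl <= 0:
        return RnleResult(lc, hm, vm, dm, am, fm, gm, rwl=0.0, li=math.inf,
                          risk_class=NOT_PERMISSIBLE)
    li = params.load_kg / rwl
    risk = RISK if li > 1.0 else NO_RISK
    return RnleResult(lc, hm, vm, dm, am, fm, gm, rwl=rwl, li=li,
                      risk_class=risk)
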