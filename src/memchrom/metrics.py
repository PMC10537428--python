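"""Performance-indicator panel computed from a breakthrough curve.

The panel covers the breakthrough/exhaustion times, loaded volume and bed
volumes at breakthrough, dynamic and equilibrium binding capacities,
adsorbent exhaustion rate, mass-transfer-zone length, bed utilization,
productivity, hydraulic residence time and permeation flux.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import curve_fit

from .curve_io import BedSpec, BreakthroughCurve
from .errors import CurveValidationError, NotReachedError

#: default breakthrough / exhaustion fractions
BREAKTHROUGH_FRACTION = 0.1
EXHAUSTION_FRACTION = 0.9

#: a curve is considered exhausted once c_ratio reaches this level
EXHAUSTION_C_RATIO = 0.99

#: mL/(cm^2 min) -> L/(m^2 h)
_FLUX_TO_LMH = 600.0


@dataclass
class PerformanceIndicators:
    """Per-experiment indicator panel.

    Capacities are mg protein per g adsorptive membrane; HMTZ is in the
    same length unit as the bed height (micrometres). Fields depending on
    bed exhaustion (EBC, MBU) are NaN when the curve never reaches it.
    """

    t_b: float  # time at 10% breakthrough, min
    t_e: float  # time at 90% breakthrough, min
    V_b: float  # volume loaded at breakthrough, mL
    BV: float  # bed volumes at breakthrough
    DBC: float  # dynamic binding capacity, mg/g
    EBC: float  # equilibrium binding capacity, mg/g
    MAER: float  # adsorbent exhaustion rate, g/mL
    HMTZ: float  # mass-transfer-zone length, um
    MBU: float  # bed utilization, %
    P: float  # productivity, mg/(min g)
    tau_res: float  # hydraulic residence time, min
    J: float  # permeation flux, L/(m^2 h)
    # operating metadata carried for table output
    Z: float = float("nan")
    C0: float = float("nan")
    F: float = float("nan")
    W: float = float("nan")
    label: str = ""


def _logistic(t, k, t05):
    return 1.0 / (1.0 + np.exp(np.clip(k * (t05 - t), -700, 700)))


def fit_front_logistic(curve: BreakthroughCurve) -> tuple[float, float]:
    """Least-squares fit of the two-parameter logistic front.

    Returns (k, t05) of c(t) = 1 / (1 + exp(k (t05 - t))).
    """
    t, c = curve.t, np.clip(curve.c_ratio, 0.0, 1.0)
    # crude initial guess from the 25/50/75% crossings
    t05_0 = _interp_crossing(curve, 0.5, strict=False)
    lo = _interp_crossing(curve, 0.25, strict=False)
    hi = _interp_crossing(curve, 0.75, strict=False)
    width = hi - lo if hi > lo else max(t[-1] - t[0], 1.0) / 4
    k0 = 2.0 * math.log(3.0) / width
    popt, _ = curve_fit(
        _logistic, t, c, p0=[k0, t05_0], maxfev=10000, method="lm"
    )
    k, t05 = float(popt[0]), float(popt[1])
    if k <= 0:
        raise NotReachedError(0.5, float(c.max()))
    return k, t05


def _interp_crossing(
    curve: BreakthroughCurve, fraction: float, strict: bool = True
) -> float:
    """First upward crossing of `fraction` by linear interpolation."""
    t, c = curve.t, curve.c_ratio
    above = np.nonzero(c >= fraction)[0]
    if above.size == 0:
        if strict:
            raise NotReachedError(fraction, float(c.max()))
        return float(t[-1])
    i = int(above[0])
    if i == 0:
        return float(t[0])
    t0, t1 = t[i - 1], t[i]
    c0, c1 = c[i - 1], c[i]
    if c1 == c0:
        return float(t1)
    return float(t0 + (fraction - c0) * (t1 - t0) / (c1 - c0))


def breakthrough_time(
    curve: BreakthroughCurve, fraction: float, method: str = "logistic"
) -> float:
    """Time at which the front crosses `fraction` of the inlet concentration.

    The default fits the two-parameter logistic front by non-linear least
    squares and inverts it; method="interp" linearly interpolates between
    the bracketing samples instead (also the fallback if the fit fails).
    """
    if not (0 < fraction < 1):
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    if float(curve.c_ratio.max()) < fraction:
        raise NotReachedError(fraction, float(curve.c_ratio.max()))
    if method == "interp":
        return _interp_crossing(curve, fraction)
    if method != "logistic":
        raise ValueError(f"unknown method {method!r}")
    try:
        k, t05 = fit_front_logistic(curve)
    except (RuntimeError, NotReachedError):
        return _interp_crossing(curve, fraction)
    t = t05 + math.log(fraction / (1.0 - fraction)) / k
    if not math.isfinite(t):
        return _interp_crossing(curve, fraction)
    return t


def uptake_at(curve: BreakthroughCurve, t_end: Optional[float] = None) -> float:
    """Bound mass per adsorbent mass (mg/g) accumulated up to `t_end`.

    Trapezoidal integral of F (C0 - C) / W over the sample grid; defaults
    to the full record.
    """
    t, c = curve.t, curve.c_ratio
    if t_end is not None:
        mask = t <= t_end + 1e-12
        t, c = t[mask], c[mask]
        if t.size < 2:
            return 0.0
    integrand = curve.C0 * (1.0 - c)
    return float(curve.F * np.trapezoid(integrand, t) / curve.bed.W)


def equilibrium_binding_capacity(curve: BreakthroughCurve) -> float:
    """EBC (mg/g): uptake integral to the last sample at >= 99% breakthrough.

    NaN if the curve never reaches 90% breakthrough (not exhausted enough
    for a meaningful estimate); if it reaches 90% but not 99%, the integral
    runs to the final sample.
    """
    c = curve.c_ratio
    if float(c.max()) < EXHAUSTION_FRACTION:
        return float("nan")
    at_eq = np.nonzero(c >= EXHAUSTION_C_RATIO)[0]
    t_end = curve.t[int(at_eq[-1])] if at_eq.size else curve.t[-1]
    return uptake_at(curve, t_end)


def performance_indicators(
    curve: BreakthroughCurve,
    fractions: tuple[float, float] = (BREAKTHROUGH_FRACTION, EXHAUSTION_FRACTION),
    method: str = "logistic",
    dbc_route: str = "direct",
) -> PerformanceIndicators:
    """Compute the full indicator panel for one experiment.

    dbc_route="direct" uses DBC = C0 V_b / W (assumes negligible
    breakthrough before t_b, the convention of sharp-front practice);
    dbc_route="integral" evaluates the uptake integral at t_b instead.
    """
    f_low, f_high = fractions
    if not (0 < f_low < f_high < 1):
        raise ValueError(f"fractions must satisfy 0 < low < high < 1, got {fractions}")
    t_b = breakthrough_time(curve, f_low, method=method)
    try:
        t_e = breakthrough_time(curve, f_high, method=method)
    except NotReachedError:
        t_e = float("nan")
    ebc = equilibrium_binding_capacity(curve)
    return _assemble(
        t_b=t_b,
        t_e=t_e,
        ebc=ebc,
        curve_for_dbc=curve if dbc_route == "integral" else None,
        bed=curve.bed,
        C0=curve.C0,
        F=curve.F,
        label=curve.label,
        t_total=float(curve.t[-1]),
    )


def indicators_from_times(
    t_b: float,
    t_e: float,
    C0: float,
    F: float,
    bed: BedSpec,
    ebc: float = float("nan"),
    label: str = "",
) -> PerformanceIndicators:
    """Indicator panel from already-known breakthrough/exhaustion times.

    Used when only the 10%/90% times are available (no raw trace), e.g. to
    reproduce a published indicator table. EBC cannot be derived from the
    times alone, so it is taken as given (or NaN).
    """
    return _assemble(
        t_b=t_b, t_e=t_e, ebc=ebc, curve_for_dbc=None,
        bed=bed, C0=C0, F=F, label=label, t_total=float("nan"),
    )


def _assemble(
    t_b: float,
    t_e: float,
    ebc: float,
    curve_for_dbc,
    bed: BedSpec,
    C0: float,
    F: float,
    label: str,
    t_total: float,
) -> PerformanceIndicators:
    if math.isfinite(t_e) and t_b > t_e:
        raise CurveValidationError(f"t_b={t_b:g} exceeds t_e={t_e:g}")
    V_b = F * t_b
    if V_b <= 0:
        raise CurveValidationError(f"non-positive breakthrough volume V_b={V_b:g}")
    BV = V_b / bed.V_M
    if curve_for_dbc is not None:
        dbc = uptake_at(curve_for_dbc, t_b)
    else:
        dbc = C0 * V_b / bed.W
    maer = bed.W / V_b
    hmtz = bed.Z * (t_e - t_b) / t_e if math.isfinite(t_e) and t_e > 0 else float("nan")
    mbu = 100.0 * dbc / ebc if math.isfinite(ebc) and ebc > 0 else float("nan")
    productivity = dbc / t_b
    tau_res = bed.epsilon * bed.V_M / F
    flux = (F / bed.A) * _FLUX_TO_LMH  # loaded volume per area per time
    return PerformanceIndicators(
        t_b=t_b, t_e=t_e, V_b=V_b, BV=BV, DBC=dbc, EBC=ebc, MAER=maer,
        HMTZ=hmtz, MBU=mbu, P=productivity, tau_res=tau_res, J=flux,
        Z=bed.Z, C0=C0, F=F, W=bed.W, label=label,
    )


def total_bound_mass(ind: PerformanceIndicators, W: Optional[float] = None) -> float:
    """Total bound protein mass (mg) at breakthrough: DBC x adsorptive mass."""
    if not math.isfinite(ind.DBC):
        raise CurveValidationError("DBC unavailable for this experiment")
    mass = W if W is not None else ind.W
    return ind.DBC * mass


def percent_increase(m_ref: float, m_new: float) -> float:
    """100 (m_new / m_ref - 1): percent change of m_new relative to m_ref."""
    if m_ref == 0:
        raise ZeroDivisionError("reference mass is zero")
    return 100.0 * (m_new / m_ref - 1.0)
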