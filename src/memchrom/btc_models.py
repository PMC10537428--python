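"""Linearized breakthrough-curve models, error statistics and ranking.

Four models are fitted by ordinary least squares on their linearized
forms: Bohart-Adams (early-front exponential), Thomas and Yoon-Nelson
(two parameterizations of the same logistic front) and the single-depth
BDST rearrangement. Capacity-type parameters are compared with their
experimental counterparts via the percent-error statistic, and models
are ranked by that error.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
from scipy.stats import linregress

from .curve_io import BreakthroughCurve
from .errors import FitDegenerateError, InsufficientDataError
from .metrics import breakthrough_time, equilibrium_binding_capacity

#: default c_ratio windows for point selection
BA_WINDOW = (0.001, 0.999)
LOGISTIC_WINDOW = (0.01, 0.99)
#: optional early-front window for Bohart-Adams
BA_EARLY_WINDOW = (0.001, 0.15)

_MIN_POINTS = 3


@dataclass
class BTCModelFit:
    """One fitted breakthrough model.

    params by model:
      bohart_adams -> {"k_BA": mL/(mg min), "N_o": mg/mL}
      thomas       -> {"k_T": mL/(mg min), "q_e": mg/g}
      yoon_nelson  -> {"k_YN": 1/min, "t05": min}
      bdst         -> {"k_BDST": mL/(mg min), "Q_o": mg/mL}

    E_pct is the percent error of the model's capacity-type parameter
    against its experimental counterpart; None until attached.
    """

    model: str
    params: dict
    r2: float
    n_used: int
    n_dropped: int = 0
    E_pct: Optional[float] = None
    x_exp: Optional[float] = None  # experimental comparator value
    # operating snapshot for unit-dependent back-solves downstream
    C0: float = float("nan")
    F: float = float("nan")
    W: float = float("nan")
    Z_um: float = float("nan")
    A: float = float("nan")
    V_M: float = float("nan")
    label: str = ""

    def with_snapshot(self, curve: BreakthroughCurve) -> "BTCModelFit":
        self.C0, self.F, self.W = curve.C0, curve.F, curve.bed.W
        self.Z_um, self.A, self.V_M = curve.bed.Z, curve.bed.A, curve.bed.V_M
        self.label = curve.label
        return self


def _window_mask(c: np.ndarray, window: tuple[float, float]) -> np.ndarray:
    lo, hi = window
    return (c > lo) & (c < hi)


def _select(curve: BreakthroughCurve, window, name: str):
    mask = _window_mask(curve.c_ratio, window)
    n = int(mask.sum())
    if n < _MIN_POINTS:
        raise InsufficientDataError(
            f"{name} fit needs >= {_MIN_POINTS} points with c_ratio in "
            f"{window}, got {n}"
        )
    return curve.t[mask], curve.c_ratio[mask], int(curve.t.size - n)


def _ols(x, y):
    res = linregress(x, y)
    return res.slope, res.intercept, res.rvalue**2


def fit_bohart_adams(
    curve: BreakthroughCurve, window: tuple[float, float] = BA_WINDOW
) -> BTCModelFit:
    """OLS of ln(c_ratio) on t.

    Slope -> k_BA C0; intercept -> -k_BA N_o Z / v with v = F/A (cm/min)
    and Z in cm. The default window spans the whole front (the model is
    derived for the early front only, so expect a poor fit there);
    BA_EARLY_WINDOW restricts to c_ratio < 0.15.
    """
    t, c, n_dropped = _select(curve, window, "Bohart-Adams")
    slope, intercept, r2 = _ols(t, np.log(c))
    if slope <= 0:
        raise FitDegenerateError("Bohart-Adams slope is non-positive")
    k_ba = slope / curve.C0
    n_o = -intercept * curve.v / (k_ba * curve.bed.Z_cm)
    if n_o <= 0:
        raise FitDegenerateError("Bohart-Adams capacity is non-positive")
    fit = BTCModelFit(
        model="bohart_adams",
        params={"k_BA": k_ba, "N_o": n_o},
        r2=r2,
        n_used=t.size,
        n_dropped=n_dropped,
    )
    return fit.with_snapshot(curve)


def fit_thomas(
    curve: BreakthroughCurve, window: tuple[float, float] = LOGISTIC_WINDOW
) -> BTCModelFit:
    """OLS of ln(C0/C_t - 1) on t.

    Slope -> -k_T C0; intercept -> k_T q_e W / F.
    """
    t, c, n_dropped = _select(curve, window, "Thomas")
    slope, intercept, r2 = _ols(t, np.log(1.0 / c - 1.0))
    if slope >= 0:
        raise FitDegenerateError("Thomas slope is non-negative")
    k_t = -slope / curve.C0
    q_e = intercept * curve.F / (k_t * curve.bed.W)
    if q_e <= 0:
        raise FitDegenerateError("Thomas capacity is non-positive")
    fit = BTCModelFit(
        model="thomas",
        params={"k_T": k_t, "q_e": q_e},
        r2=r2,
        n_used=t.size,
        n_dropped=n_dropped,
    )
    return fit.with_snapshot(curve)


def fit_yoon_nelson(
    curve: BreakthroughCurve, window: tuple[float, float] = LOGISTIC_WINDOW
) -> BTCModelFit:
    """OLS of ln(C_t/(C0 - C_t)) on t.

    Slope -> k_YN; intercept -> -k_YN t05.
    """
    t, c, n_dropped = _select(curve, window, "Yoon-Nelson")
    slope, intercept, r2 = _ols(t, np.log(c / (1.0 - c)))
    if slope <= 0:
        raise FitDegenerateError("Yoon-Nelson slope is non-positive")
    fit = BTCModelFit(
        model="yoon_nelson",
        params={"k_YN": slope, "t05": -intercept / slope},
        r2=r2,
        n_used=t.size,
        n_dropped=n_dropped,
    )
    return fit.with_snapshot(curve)


def fit_bdst(
    curve: BreakthroughCurve, window: tuple[float, float] = LOGISTIC_WINDOW
) -> BTCModelFit:
    """Single-depth BDST: OLS of t on ln(C0/C_t - 1).

    Slope -> -1/(k_BDST C0); intercept -> Q_o Z/(C0 v). This is the
    inverse regression of the Thomas line, so r2 is identical by
    symmetry of the Pearson correlation.
    """
    t, c, n_dropped = _select(curve, window, "BDST")
    slope, intercept, r2 = _ols(np.log(1.0 / c - 1.0), t)
    if slope >= 0:
        raise FitDegenerateError("BDST slope is non-negative")
    k_bdst = -1.0 / (slope * curve.C0)
    q_o = intercept * curve.C0 * curve.v / curve.bed.Z_cm
    if q_o <= 0:
        raise FitDegenerateError("BDST capacity is non-positive")
    fit = BTCModelFit(
        model="bdst",
        params={"k_BDST": k_bdst, "Q_o": q_o},
        r2=r2,
        n_used=t.size,
        n_dropped=n_dropped,
    )
    return fit.with_snapshot(curve)


def error_percent(x_exp: float, x_cal: float) -> float:
    """Percent error 100 |x_exp - x_cal| / x_cal (calculated in denominator)."""
    if x_cal == 0:
        raise ZeroDivisionError("calculated value is zero")
    return 100.0 * abs(x_exp - x_cal) / abs(x_cal)


#: cross-model capacity identities ------------------------------------------


def capacity_from_midpoint_time(C0: float, F: float, t05: float, W: float) -> float:
    """Per-mass capacity q (mg/g) implied by a logistic midpoint time."""
    return C0 * F * t05 / W


def saturation_concentration(ebc: float, W: float, V_M: float) -> float:
    """Per-bed-volume capacity N_o (mg/mL) from a per-mass capacity (mg/g)."""
    return ebc * W / V_M


_CAPACITY_KEY = {
    "bohart_adams": "N_o",
    "thomas": "q_e",
    "yoon_nelson": "t05",
    "bdst": "Q_o",
}


def experimental_comparator(curve: BreakthroughCurve, model: str) -> float:
    """Experimental counterpart of a model's capacity-type parameter.

    Thomas -> EBC (mg/g); Yoon-Nelson -> measured half-breakthrough time;
    Bohart-Adams / BDST -> EBC converted to a per-bed-volume capacity.
    """
    if model == "thomas":
        return equilibrium_binding_capacity(curve)
    if model == "yoon_nelson":
        return breakthrough_time(curve, 0.5)
    if model in ("bohart_adams", "bdst"):
        ebc = equilibrium_binding_capacity(curve)
        return saturation_concentration(ebc, curve.bed.W, curve.bed.V_M)
    raise ValueError(f"unknown model {model!r}")


def attach_error(fit: BTCModelFit, curve: BreakthroughCurve) -> BTCModelFit:
    """Fill E_pct by comparing the fitted capacity with the experimental one."""
    x_exp = experimental_comparator(curve, fit.model)
    x_cal = fit.params[_CAPACITY_KEY[fit.model]]
    fit.x_exp = x_exp
    fit.E_pct = error_percent(x_exp, x_cal)
    return fit


def fit_all(
    curve: BreakthroughCurve,
    ba_window: tuple[float, float] = BA_WINDOW,
    logistic_window: tuple[float, float] = LOGISTIC_WINDOW,
) -> list[BTCModelFit]:
    """Fit all four models and attach percent errors."""
    fits = [
        fit_bohart_adams(curve, ba_window),
        fit_thomas(curve, logistic_window),
        fit_yoon_nelson(curve, logistic_window),
        fit_bdst(curve, logistic_window),
    ]
    return [attach_error(f, curve) for f in fits]


def rank_models(fits: Sequence[BTCModelFit]) -> list[BTCModelFit]:
    """Best model first: ascending E_pct, ties broken by descending r2."""
    if len(fits) < 2:
        raise ValueError("ranking needs at least two fits")
    if any(f.E_pct is None for f in fits):
        raise ValueError("all fits must have E_pct attached before ranking")
    return sorted(fits, key=lambda f: (f.E_pct, -f.r2))


def predict_curve(fit: BTCModelFit, times) -> np.ndarray:
    """Evaluate the fitted model's closed form; output clipped to [0, 1]."""
    t = np.asarray(times, dtype=float)
    if fit.model == "bohart_adams":
        k_ba, n_o = fit.params["k_BA"], fit.params["N_o"]
        v = fit.F / fit.A
        z_cm = fit.Z_um / 1.0e4
        log_c = k_ba * fit.C0 * t - k_ba * n_o * z_cm / v
        c = np.exp(np.clip(log_c, -700.0, 0.0))
    elif fit.model == "thomas":
        k = fit.params["k_T"] * fit.C0
        t05 = fit.params["q_e"] * fit.W / (fit.C0 * fit.F)
        c = 1.0 / (1.0 + np.exp(np.clip(k * (t05 - t), -700.0, 700.0)))
    elif fit.model == "yoon_nelson":
        k, t05 = fit.params["k_YN"], fit.params["t05"]
        c = 1.0 / (1.0 + np.exp(np.clip(k * (t05 - t), -700.0, 700.0)))
    elif fit.model == "bdst":
        v = fit.F / fit.A
        z_cm = fit.Z_um / 1.0e4
        k, q_o = fit.params["k_BDST"], fit.params["Q_o"]
        t_mid = q_o * z_cm / (fit.C0 * v)
        c = 1.0 / (1.0 + np.exp(np.clip(k * fit.C0 * (t_mid - t), -700.0, 700.0)))
    else:
        raise ValueError(f"unknown model {fit.model!r}")
    return np.clip(c, 0.0, 1.0)


def bdst_scaleup(
    fits: Sequence[BTCModelFit], target_fraction: float = 0.1
) -> tuple[Callable[[float], float], dict]:
    """Service-time-versus-depth line from single-depth BDST fits.

    Each fit contributes its predicted service time at `target_fraction`
    and its bed height; OLS of time on depth gives slope a (min/um, the
    capacity term per unit height) and intercept b (min). Returns a
    predictor t(Z_um) and {"a", "b", "k_BDST"}.
    """
    if len(fits) < 2:
        raise InsufficientDataError("scale-up needs fits at >= 2 bed depths")
    z = np.array([f.Z_um for f in fits], dtype=float)
    if np.unique(z).size < 2:
        raise FitDegenerateError("bed depths are not distinct")
    log_term = math.log(1.0 / target_fraction - 1.0)
    times = []
    for f in fits:
        if f.model != "bdst":
            raise ValueError("scale-up expects single-depth BDST fits")
        v = f.F / f.A
        a_i = f.params["Q_o"] * (f.Z_um / 1.0e4) / (f.C0 * v)
        times.append(a_i - log_term / (f.params["k_BDST"] * f.C0))
    res = linregress(z, np.array(times))
    a, b = float(res.slope), float(res.intercept)
    # recover the rate constant from the intercept where possible
    C0 = fits[0].C0
    k_bdst = log_term / (-b * C0) if b != 0 and log_term != 0 else float("nan")
    if k_bdst < 0:
        k_bdst = float("nan")

    def predictor(Z_um: float) -> float:
        return a * Z_um + b

    return predictor, {"a": a, "b": b, "k_BDST": k_bdst, "r2": res.rvalue**2}
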