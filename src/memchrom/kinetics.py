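"""Uptake-curve conversion and linearized kinetic fits.

A breakthrough curve is converted to a dynamic uptake curve q_t(t) by
trapezoidal integration of the unbound fraction; the uptake curve is then
fitted by four linearized kinetic laws: pseudo-first-order, pseudo-second-
order, Elovich and (piecewise) intraparticle diffusion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.stats import linregress

from .curve_io import BreakthroughCurve
from .errors import FitDegenerateError, InsufficientDataError

#: default headroom multiplier for the PFO equilibrium capacity
PFO_QE_FACTOR = 1.02

#: a decrease of q_t larger than this fraction of max(q_t) is flagged
_MONOTONE_TOL = 0.02

_MIN_POINTS = 3


@dataclass
class KineticCurve:
    """Uptake series q_t (mg/g) versus time (min)."""

    t: np.ndarray
    q_t: np.ndarray
    source: Optional[BreakthroughCurve] = None
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.q_t = np.asarray(self.q_t, dtype=float)
        if self.t.shape != self.q_t.shape:
            raise ValueError("t and q_t must have identical shape")
        qmax = float(self.q_t.max(initial=0.0))
        if qmax > 0:
            drops = -np.diff(self.q_t)
            worst = float(drops.max(initial=0.0))
            if worst > _MONOTONE_TOL * qmax:
                self.warnings.append(
                    f"q_t decreases by {worst:g} mg/g "
                    f"(> {_MONOTONE_TOL:.0%} of max {qmax:g}); check noise level"
                )


@dataclass
class StageFit:
    """One linear stage of an intraparticle-diffusion plot."""

    start: int  # index range [start, stop) into the kinetic curve
    stop: int
    k: float  # slope, mg/(g min^0.5)
    intercept: float  # mg/g
    r2: float


@dataclass
class KineticFit:
    """Result of one linearized kinetic regression.

    params by model:
      pfo     -> {"k1": 1/min, "q1": mg/g}
      pso     -> {"k2": g/(mg min), "q2": mg/g}
      elovich -> {"alpha": mg/(g min), "beta": g/mg}
      ipd     -> per-stage (see `stages`)
    """

    model: str
    params: dict
    r2: float
    n_used: int
    n_dropped: int = 0
    stages: list = field(default_factory=list)


def to_kinetic_curve(curve: BreakthroughCurve) -> KineticCurve:
    """Uptake q_t = (F/W) * integral_0^t (C0 - C) ds on the sample grid.

    q_t[0] = 0 (the integral over the leading sample interval is zero);
    when t[0] > 0 the unrecorded initial interval is not extrapolated.
    """
    unbound = curve.C0 * (1.0 - curve.c_ratio)
    q = curve.F * cumulative_trapezoid(unbound, curve.t, initial=0.0) / curve.bed.W
    return KineticCurve(t=curve.t.copy(), q_t=q, source=curve)


def _regress(x: np.ndarray, y: np.ndarray):
    res = linregress(x, y)
    return res.slope, res.intercept, res.rvalue**2


def fit_pfo(kin: KineticCurve, q_e: Optional[float] = None) -> KineticFit:
    """Pseudo-first-order: OLS of ln(q_e - q_t) on t.

    Slope -> -k1, intercept -> ln q1. The linearization needs the
    equilibrium capacity inside the log; if not supplied it defaults to
    1.02 x max(q_t). Points with q_t >= q_e are dropped (count reported).
    """
    qmax = float(kin.q_t.max(initial=0.0))
    if q_e is None:
        q_e = PFO_QE_FACTOR * qmax
    elif q_e < qmax:
        raise ValueError(f"q_e={q_e:g} below max(q_t)={qmax:g}")
    mask = (kin.q_t < q_e) & (kin.q_t > 0)
    n_dropped = int(kin.q_t.size - mask.sum())
    if int(mask.sum()) < _MIN_POINTS:
        raise InsufficientDataError(
            f"pseudo-first-order fit needs >= {_MIN_POINTS} usable points, "
            f"got {int(mask.sum())}"
        )
    slope, intercept, r2 = _regress(kin.t[mask], np.log(q_e - kin.q_t[mask]))
    if slope >= 0:
        raise FitDegenerateError("pseudo-first-order slope is non-negative")
    return KineticFit(
        model="pfo",
        params={"k1": -slope, "q1": math.exp(intercept)},
        r2=r2,
        n_used=int(mask.sum()),
        n_dropped=n_dropped,
    )


def fit_pso(kin: KineticCurve) -> KineticFit:
    """Pseudo-second-order: OLS of t/q_t on t.

    Slope -> 1/q2, intercept -> 1/(k2 q2^2).
    """
    mask = kin.q_t > 0
    n = int(mask.sum())
    if n < _MIN_POINTS:
        raise InsufficientDataError(
            f"pseudo-second-order fit needs >= {_MIN_POINTS} positive points, got {n}"
        )
    t, q = kin.t[mask], kin.q_t[mask]
    slope, intercept, r2 = _regress(t, t / q)
    if slope <= 0:
        raise FitDegenerateError("pseudo-second-order slope is non-positive")
    q2 = 1.0 / slope
    if intercept <= 0:
        raise FitDegenerateError("pseudo-second-order intercept is non-positive")
    k2 = 1.0 / (intercept * q2**2)
    return KineticFit(
        model="pso",
        params={"k2": k2, "q2": q2},
        r2=r2,
        n_used=n,
        n_dropped=int(kin.q_t.size - n),
    )


def fit_elovich(kin: KineticCurve) -> KineticFit:
    """Elovich: OLS of q_t on ln t (t = 0 samples excluded).

    Slope -> 1/beta, intercept -> (1/beta) ln(alpha beta).
    """
    mask = kin.t > 0
    n = int(mask.sum())
    if n < _MIN_POINTS:
        raise InsufficientDataError(
            f"Elovich fit needs >= {_MIN_POINTS} points with t > 0, got {n}"
        )
    slope, intercept, r2 = _regress(np.log(kin.t[mask]), kin.q_t[mask])
    if slope <= 0:
        raise FitDegenerateError("Elovich slope is non-positive")
    beta = 1.0 / slope
    alpha = math.exp(intercept * beta) / beta
    return KineticFit(
        model="elovich",
        params={"alpha": alpha, "beta": beta},
        r2=r2,
        n_used=n,
        n_dropped=int(kin.t.size - n),
    )


# -- intraparticle diffusion (piecewise sqrt-time) --------------------------


class _SegmentOLS:
    """O(1) per-segment least squares of y on x via prefix sums."""

    def __init__(self, x: np.ndarray, y: np.ndarray):
        z = np.zeros(1)
        self.sx = np.concatenate([z, np.cumsum(x)])
        self.sy = np.concatenate([z, np.cumsum(y)])
        self.sxx = np.concatenate([z, np.cumsum(x * x)])
        self.sxy = np.concatenate([z, np.cumsum(x * y)])
        self.syy = np.concatenate([z, np.cumsum(y * y)])

    def fit(self, i: int, j: int) -> tuple[float, float, float, float]:
        """(slope, intercept, r2, sse) on index range [i, j)."""
        n = j - i
        sx = self.sx[j] - self.sx[i]
        sy = self.sy[j] - self.sy[i]
        sxx = self.sxx[j] - self.sxx[i]
        sxy = self.sxy[j] - self.sxy[i]
        syy = self.syy[j] - self.syy[i]
        vxx = sxx - sx * sx / n
        vyy = syy - sy * sy / n
        vxy = sxy - sx * sy / n
        if vxx <= 0:
            return math.nan, math.nan, 0.0, math.inf
        slope = vxy / vxx
        intercept = (sy - slope * sx) / n
        sse = max(vyy - slope * vxy, 0.0)
        r2 = 1.0 if vyy <= 0 else max(vxy * vxy / (vxx * vyy), 0.0)
        return slope, intercept, r2, sse


def fit_ipd(
    kin: KineticCurve,
    n_stages: int = 3,
    breakpoints: Optional[Sequence[int]] = None,
) -> KineticFit:
    """Piecewise intraparticle-diffusion fit: q_t on sqrt(t), 1-3 stages.

    Each stage is an OLS line q = k_i sqrt(t) + I on a contiguous index
    range with at least 3 points. If `breakpoints` (stage start indices,
    excluding 0) is omitted, they are chosen by exhaustive search
    minimizing the total residual sum of squares.
    """
    if not 1 <= n_stages <= 3:
        raise ValueError(f"n_stages must be 1..3, got {n_stages}")
    n = kin.t.size
    if n < _MIN_POINTS * n_stages:
        raise InsufficientDataError(
            f"{n_stages}-stage fit needs >= {_MIN_POINTS * n_stages} points, got {n}"
        )
    x = np.sqrt(kin.t)
    ols = _SegmentOLS(x, kin.q_t)

    if breakpoints is not None:
        cuts = [0, *sorted(int(b) for b in breakpoints), n]
        if len(cuts) - 1 != n_stages:
            raise ValueError(
                f"{len(cuts) - 2} breakpoints given for {n_stages} stages"
            )
        if any(cuts[i + 1] - cuts[i] < _MIN_POINTS for i in range(n_stages)):
            raise InsufficientDataError("a stage has fewer than 3 points")
    else:
        cuts = _search_breakpoints(ols, n, n_stages)

    stages = []
    total_sse = 0.0
    for i in range(n_stages):
        lo, hi = cuts[i], cuts[i + 1]
        slope, intercept, r2, sse = ols.fit(lo, hi)
        stages.append(StageFit(start=lo, stop=hi, k=slope, intercept=intercept, r2=r2))
        total_sse += sse
    # overall r2 across the piecewise fit
    sy = ols.sy[n]
    syy = ols.syy[n]
    tss = syy - sy * sy / n
    r2_total = 1.0 if tss <= 0 else max(1.0 - total_sse / tss, 0.0)
    params = {f"k{i + 1}": s.k for i, s in enumerate(stages)}
    params.update({f"I{i + 1}": s.intercept for i, s in enumerate(stages)})
    return KineticFit(
        model="ipd", params=params, r2=r2_total, n_used=n, stages=stages
    )


def _search_breakpoints(ols: _SegmentOLS, n: int, n_stages: int) -> list[int]:
    """Exhaustive minimum-SSE segmentation with >= 3 points per stage."""
    if n_stages == 1:
        return [0, n]
    best_sse = math.inf
    best = None
    if n_stages == 2:
        for i in range(_MIN_POINTS, n - _MIN_POINTS + 1):
            sse = ols.fit(0, i)[3] + ols.fit(i, n)[3]
            if sse < best_sse:
                best_sse, best = sse, [0, i, n]
    else:
        # precompute tail costs for the third segment
        tail = {j: ols.fit(j, n)[3] for j in range(2 * _MIN_POINTS, n - _MIN_POINTS + 1)}
        for i in range(_MIN_POINTS, n - 2 * _MIN_POINTS + 1):
            head = ols.fit(0, i)[3]
            for j in range(i + _MIN_POINTS, n - _MIN_POINTS + 1):
                sse = head + ols.fit(i, j)[3] + tail[j]
                if sse < best_sse:
                    best_sse, best = sse, [0, i, j, n]
    assert best is not None
    return best
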