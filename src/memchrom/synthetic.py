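"""Synthetic breakthrough-curve generator with known ground truth.

Curves are produced from the closed forms of the logistic-front family
(Yoon-Nelson / Thomas parameterizations) or the early-front exponential
(Bohart-Adams), plus seeded additive Gaussian noise, so every downstream
fitting stage can be tested by construct-and-recover.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np

from .curve_io import BedSpec, BreakthroughCurve, C_RATIO_HARD_LIMIT
from .errors import ConfigError

MODELS = ("yoon_nelson", "thomas", "bohart_adams")

#: default bed matching the single-layer experimental stack
DEFAULT_BED = BedSpec(Z=115.0, A=3.7, epsilon=0.8367, W=0.015, layers=1)

#: minimum number of samples across the 5-95% front with auto sampling
_FRONT_POINTS = 40


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic curve.

    params by model:
      yoon_nelson  -> {"k_YN": 1/min, "t05": min}
      thomas       -> {"k_T": mL/(mg min), "q_e": mg/g}
      bohart_adams -> {"k_BA": mL/(mg min), "N_o": mg/mL}
    """

    model: str
    params: Mapping[str, float]
    C0: float
    F: float
    bed: BedSpec = DEFAULT_BED
    t_start: float = 0.0
    t_stop: Optional[float] = None  # None -> auto window past exhaustion
    t_step: Optional[float] = None  # None -> auto (dense front coverage)
    noise_sd: float = 0.0
    seed: int = 0
    label: str = ""

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ConfigError(f"unknown model {self.model!r}; expected one of {MODELS}")
        for name, value in self.params.items():
            if value <= 0:
                raise ConfigError(f"parameter {name} must be > 0, got {value}")
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.C0 <= 0 or self.F <= 0:
            raise ConfigError("C0 and F must be > 0")
        if self.t_stop is not None and self.t_stop <= self.t_start:
            raise ConfigError("t_stop must exceed t_start")

    # -- model algebra -------------------------------------------------

    def logistic_params(self) -> tuple[float, float]:
        """(k, t05) of the equivalent logistic front.

        Thomas and Yoon-Nelson describe the same logistic with
        k = k_T C0 and t05 = q_e W / (C0 F).
        """
        if self.model == "yoon_nelson":
            return self.params["k_YN"], self.params["t05"]
        if self.model == "thomas":
            k = self.params["k_T"] * self.C0
            t05 = self.params["q_e"] * self.bed.W / (self.C0 * self.F)
            return k, t05
        raise ConfigError(f"{self.model} has no logistic equivalent")

    def capacity(self) -> float:
        """Ground-truth equilibrium capacity q_e in mg/g."""
        if self.model == "thomas":
            return self.params["q_e"]
        if self.model == "yoon_nelson":
            return self.C0 * self.F * self.params["t05"] / self.bed.W
        return self.params["N_o"] * self.bed.V_M / self.bed.W

    def _front(self) -> tuple[float, float]:
        """(characteristic rate 1/min, midpoint time min) for windowing."""
        if self.model in ("yoon_nelson", "thomas"):
            return self.logistic_params()
        k_eff = self.params["k_BA"] * self.C0
        v = self.F / self.bed.A
        t_sat = self.params["N_o"] * self.bed.Z_cm / (v * self.C0)
        return k_eff, t_sat

    def time_grid(self) -> np.ndarray:
        k, t_mid = self._front()
        stop = self.t_stop
        if stop is None:
            stop = t_mid + 8.0 / k  # logistic reaches ~0.9997 by t05 + 8/k
        step = self.t_step
        if step is None:
            front_width = 2.0 * math.log(19.0) / k  # 5% to 95% span
            step = min(front_width / _FRONT_POINTS, (stop - self.t_start) / 60.0)
        n = int(math.floor((stop - self.t_start) / step + 1e-9)) + 1
        return self.t_start + step * np.arange(n)


def model_curve(spec: SyntheticSpec, t: np.ndarray) -> np.ndarray:
    """Noiseless c_ratio(t) of the spec's closed-form model."""
    t = np.asarray(t, dtype=float)
    if spec.model in ("yoon_nelson", "thomas"):
        k, t05 = spec.logistic_params()
        return 1.0 / (1.0 + np.exp(np.clip(k * (t05 - t), -700.0, 700.0)))
    k_ba, n_o = spec.params["k_BA"], spec.params["N_o"]
    v = spec.F / spec.bed.A
    log_c = k_ba * spec.C0 * t - k_ba * n_o * spec.bed.Z_cm / v
    # the early-front exponential is only physical below saturation
    return np.minimum(np.exp(np.clip(log_c, -700.0, 0.0)), 1.0)


def generate_breakthrough(spec: SyntheticSpec) -> BreakthroughCurve:
    """Generate one curve: closed-form model plus seeded truncated noise."""
    t = spec.time_grid()
    c = model_curve(spec, t)
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        c = c + rng.normal(0.0, spec.noise_sd, size=c.shape)
        c = np.clip(c, 0.0, C_RATIO_HARD_LIMIT)
    return BreakthroughCurve(
        t=t, c_ratio=c, C0=spec.C0, F=spec.F, bed=spec.bed, label=spec.label
    )


_GRID_KEYS = ("C0", "F", "layers", "capacity")


def _respecify(base: SyntheticSpec, updates: Mapping[str, float]) -> SyntheticSpec:
    """Apply operating-factor updates, holding the bed capacity fixed.

    Capacity (mg/g at the base bed) is the conserved ground truth: changing
    C0 or F moves the front accordingly; changing layers scales Z and W
    together; "capacity" overrides the per-mass capacity itself.
    """
    cap = updates.get("capacity", base.capacity())
    C0 = float(updates.get("C0", base.C0))
    F = float(updates.get("F", base.F))
    bed = base.bed
    if "layers" in updates:
        bed = bed.with_layers(int(updates["layers"]))
    params = dict(base.params)
    if base.model == "thomas":
        params["q_e"] = cap
    elif base.model == "yoon_nelson":
        params["t05"] = cap * bed.W / (C0 * F)
    else:
        params["N_o"] = cap * bed.W / bed.V_M
    parts = [f"{k}={updates[k]:g}" for k in _GRID_KEYS if k in updates]
    label = ",".join(parts) if parts else base.label
    return replace(base, params=params, C0=C0, F=F, bed=bed, label=label)


def generate_condition_grid(
    base: SyntheticSpec, grid: Mapping[str, Sequence[float]]
) -> list[BreakthroughCurve]:
    """One curve per grid combination, varying operating factors.

    Grid keys: C0 (mg/mL), F (mL/min), layers, capacity (mg/g). An empty
    grid returns just the base curve. Seeds advance by combination index so
    noise differs between curves but the whole set is reproducible.
    """
    unknown = set(grid) - set(_GRID_KEYS)
    if unknown:
        raise ConfigError(f"unknown grid keys {sorted(unknown)}; allowed {_GRID_KEYS}")
    keys = [k for k in _GRID_KEYS if k in grid]
    combos = list(itertools.product(*(grid[k] for k in keys))) or [()]
    curves = []
    for i, combo in enumerate(combos):
        spec = _respecify(base, dict(zip(keys, combo)))
        spec = replace(spec, seed=base.seed + i)
        curves.append(generate_breakthrough(spec))
    return curves


# ---------------------------------------------------------------------------
# standard 12-condition fixture set
# ---------------------------------------------------------------------------

#: (label, C0 mg/mL, F mL/min, layers, capacity mg/g) for the standard set:
#: a pH sweep, a feed-concentration sweep, a flow-rate sweep and a layer
#: sweep around the common reference condition (pH 9, 2 mg/mL, 1 mL/min, 1
#: layer), with capacities spanning the 200-1000 mg/g operating range.
STANDARD_CONDITIONS: tuple[tuple[str, float, float, int, float], ...] = (
    ("pH=5", 2.0, 1.0, 1, 460.0),
    ("pH=7", 2.0, 1.0, 1, 735.0),
    ("pH=9", 2.0, 1.0, 1, 770.0),
    ("C0=0.5", 0.5, 1.0, 1, 260.0),
    ("C0=1.0", 1.0, 1.0, 1, 475.0),
    ("C0=2.0", 2.0, 1.0, 1, 770.0),
    ("F=0.1", 2.0, 0.1, 1, 960.0),
    ("F=0.5", 2.0, 0.5, 1, 875.0),
    ("F=1.0", 2.0, 1.0, 1, 770.0),
    ("layers=1", 2.0, 1.0, 1, 770.0),
    ("layers=3", 2.0, 1.0, 3, 470.0),
    ("layers=5", 2.0, 1.0, 5, 435.0),
)

_STANDARD_K_YN = 2.0  # 1/min; keeps every front sharp and fully after t = 0


def standard_specs(seed: int = 0, noise_sd: float = 0.01) -> list[SyntheticSpec]:
    """Specs for the 12-condition standard test set (Thomas ground truth).

    k_T is scaled as 1/C0 so the logistic sharpness k_YN = k_T C0 is the
    same for every condition; otherwise low-C0 fronts would start before
    the injection time.
    """
    specs = []
    for i, (label, C0, F, layers, cap) in enumerate(STANDARD_CONDITIONS):
        bed = DEFAULT_BED.with_layers(layers)
        specs.append(
            SyntheticSpec(
                model="thomas",
                params={"k_T": _STANDARD_K_YN / C0, "q_e": cap},
                C0=C0,
                F=F,
                bed=bed,
                noise_sd=noise_sd,
                seed=seed + i,
                label=label,
            )
        )
    return specs


def standard_curves(seed: int = 0, noise_sd: float = 0.01) -> list[BreakthroughCurve]:
    return [generate_breakthrough(s) for s in standard_specs(seed, noise_sd)]
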