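"""Breakthrough-curve and bed-descriptor I/O.

Internal unit canon: minutes, mL, mg, g and cm. Bed height is accepted in
micrometres at the boundary and converted; all derived volumes are in mL.
Curves travel as two-column delimited text (time [min], C/C0), the operating
metadata as a flat ``key = value`` descriptor file.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigError, CurveValidationError, FormatError

UM_PER_CM = 1.0e4

#: c_ratio above 1 is tolerated up to this value (detector overshoot);
#: anything larger is treated as a unit/parsing mistake.
C_RATIO_HARD_LIMIT = 1.05

MIN_SAMPLES = 4


@dataclass(frozen=True)
class BedSpec:
    """Geometry and loading of a stacked membrane bed.

    Parameters
    ----------
    Z : float
        Bed height in micrometres (total stack height).
    A : float
        Frontal (effective) area in cm^2.
    epsilon : float
        Bed porosity, fraction in (0, 1].
    W : float
        Mass of the adsorptive nanofiber layers in grams. Excludes any
        inert support fabric.
    layers : int
        Number of stacked membrane layers.
    """

    Z: float
    A: float
    epsilon: float
    W: float
    layers: int = 1

    def __post_init__(self) -> None:
        if self.Z <= 0:
            raise CurveValidationError(f"bed height Z must be > 0, got {self.Z}")
        if self.A <= 0:
            raise CurveValidationError(f"frontal area A must be > 0, got {self.A}")
        if not (0 < self.epsilon <= 1):
            raise CurveValidationError(
                f"porosity must lie in (0, 1], got {self.epsilon}"
            )
        if self.W <= 0:
            raise CurveValidationError(f"adsorptive mass W must be > 0, got {self.W}")
        if self.layers < 1 or int(self.layers) != self.layers:
            raise CurveValidationError(
                f"layers must be a positive integer, got {self.layers}"
            )

    @property
    def Z_cm(self) -> float:
        """Bed height in cm."""
        return self.Z / UM_PER_CM

    @property
    def V_M(self) -> float:
        """Geometric bed volume in mL (= A [cm^2] x Z [cm])."""
        return self.A * self.Z_cm

    def with_layers(self, layers: int) -> "BedSpec":
        """Return a bed rescaled to `layers`, scaling Z and W proportionally."""
        if layers < 1:
            raise CurveValidationError(f"layers must be >= 1, got {layers}")
        factor = layers / self.layers
        return BedSpec(
            Z=self.Z * factor,
            A=self.A,
            epsilon=self.epsilon,
            W=self.W * factor,
            layers=layers,
        )


@dataclass
class BreakthroughCurve:
    """Time series of normalized outlet concentration with operating metadata.

    Attributes
    ----------
    t : ndarray
        Sample times in minutes, strictly increasing, t[0] >= 0.
    c_ratio : ndarray
        Outlet/inlet concentration ratio C_t/C0, each >= 0.
    C0 : float
        Inlet concentration, mg/mL.
    F : float
        Volumetric flow rate, mL/min.
    bed : BedSpec
    label : str
        Free-text condition tag (e.g. a pH).
    warnings : list of str
        Non-fatal validation notes (e.g. c_ratio slightly above 1).
    """

    t: np.ndarray
    c_ratio: np.ndarray
    C0: float
    F: float
    bed: BedSpec
    label: str = ""
    warnings: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.c_ratio = np.asarray(self.c_ratio, dtype=float)
        if self.t.ndim != 1 or self.c_ratio.ndim != 1:
            raise CurveValidationError("t and c_ratio must be 1-D")
        if self.t.size != self.c_ratio.size:
            raise CurveValidationError(
                f"t and c_ratio length mismatch ({self.t.size} vs {self.c_ratio.size})"
            )
        if self.t.size < MIN_SAMPLES:
            raise CurveValidationError(
                f"need at least {MIN_SAMPLES} samples, got {self.t.size}"
            )
        if self.t[0] < 0:
            raise CurveValidationError(f"t[0] must be >= 0, got {self.t[0]}")
        dt = np.diff(self.t)
        if np.any(dt <= 0):
            raise CurveValidationError("sample times must be strictly increasing")
        if np.any(self.c_ratio < 0):
            raise CurveValidationError("c_ratio values must be >= 0")
        cmax = float(self.c_ratio.max())
        if cmax > C_RATIO_HARD_LIMIT:
            raise CurveValidationError(
                f"c_ratio {cmax:g} exceeds hard limit {C_RATIO_HARD_LIMIT}"
            )
        if cmax > 1.0:
            self.warnings.append(
                f"c_ratio exceeds 1 (max {cmax:g} <= tolerance "
                f"{C_RATIO_HARD_LIMIT}); values retained"
            )
        if self.C0 <= 0:
            raise CurveValidationError(f"C0 must be > 0, got {self.C0}")
        if self.F <= 0:
            raise CurveValidationError(f"F must be > 0, got {self.F}")

    @property
    def v(self) -> float:
        """Superficial linear velocity F/A in cm/min."""
        return self.F / self.bed.A

    @property
    def n_samples(self) -> int:
        return self.t.size


# descriptor keys accepted for each BedSpec / curve field
_DESCRIPTOR_ALIASES = {
    "C0": ("C0", "c0", "Co", "co"),
    "F": ("F", "f", "flow_rate"),
    "Z": ("Z", "z", "bed_height_um"),
    "A": ("A", "a", "area_cm2"),
    "epsilon": ("epsilon", "eps", "porosity", "ε"),
    "W": ("W", "w", "mass_g"),
    "layers": ("layers", "n_layers"),
    "label": ("label", "condition", "tag"),
}


def _lookup(descriptor: Mapping, canonical: str):
    for alias in _DESCRIPTOR_ALIASES[canonical]:
        if alias in descriptor:
            return descriptor[alias]
    return None


def bed_from_descriptor(descriptor: Mapping) -> BedSpec:
    """Build a BedSpec from a flat descriptor mapping."""
    values = {}
    for key in ("Z", "A", "epsilon", "W"):
        raw = _lookup(descriptor, key)
        if raw is None:
            raise ConfigError(f"descriptor is missing required field '{key}'")
        values[key] = float(raw)
    layers = _lookup(descriptor, "layers")
    values["layers"] = int(layers) if layers is not None else 1
    return BedSpec(**values)


def curve_from_arrays(
    t: Sequence[float],
    c_ratio: Sequence[float],
    descriptor: Mapping,
) -> BreakthroughCurve:
    """Assemble a validated curve from raw arrays plus a descriptor mapping."""
    for key in ("C0", "F"):
        if _lookup(descriptor, key) is None:
            raise ConfigError(f"descriptor is missing required field '{key}'")
    return BreakthroughCurve(
        t=np.asarray(t, dtype=float),
        c_ratio=np.asarray(c_ratio, dtype=float),
        C0=float(_lookup(descriptor, "C0")),
        F=float(_lookup(descriptor, "F")),
        bed=bed_from_descriptor(descriptor),
        label=str(_lookup(descriptor, "label") or ""),
    )


def read_curve(path, descriptor: Mapping) -> BreakthroughCurve:
    """Read a two-column delimited curve file and attach its descriptor.

    The file must contain two numeric columns (time in minutes, C/C0);
    a header row is optional and the delimiter (comma/tab/whitespace) is
    sniffed. Rows are sorted by time; duplicate times are rejected.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#", header=None)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise FormatError(
            f"{path}: expected two columns (time, c_ratio), found {df.shape[1]}"
        )
    df = df.iloc[:, :2]
    # a non-numeric first row is an optional header
    try:
        [float(v) for v in df.iloc[0]]
    except (TypeError, ValueError):
        df = df.iloc[1:]
    try:
        data = df.to_numpy().astype(float)
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric values in curve columns") from exc
    if not np.all(np.isfinite(data)):
        raise FormatError(f"{path}: missing or non-numeric values in curve columns")
    order = np.argsort(data[:, 0], kind="stable")
    data = data[order]
    if np.any(np.diff(data[:, 0]) == 0):
        raise CurveValidationError(f"{path}: duplicate time values")
    return curve_from_arrays(data[:, 0], data[:, 1], descriptor)


def write_curve(curve: BreakthroughCurve, path, delimiter: str = "\t") -> None:
    """Write a curve as two-column delimited text with a header row."""
    df = pd.DataFrame({"time_min": curve.t, "c_ratio": curve.c_ratio})
    df.to_csv(path, sep=delimiter, index=False, float_format="%.12g")


def read_descriptor(path) -> dict:
    """Read a flat ``key = value`` (or ``key: value``) descriptor file."""
    out: dict = {}
    text = Path(path).read_text(encoding="utf-8")
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        for sep in ("=", ":"):
            if sep in line:
                key, _, value = line.partition(sep)
                break
        else:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        out[key.strip()] = value.strip()
    return out


def write_descriptor(mapping: Mapping, path) -> None:
    lines = [f"{k} = {v}" for k, v in mapping.items()]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def descriptor_from_curve(curve: BreakthroughCurve) -> dict:
    """Flat descriptor round-trippable through read_descriptor/curve_from_arrays."""
    return {
        "C0": repr(curve.C0),
        "F": repr(curve.F),
        "Z": repr(curve.bed.Z),
        "A": repr(curve.bed.A),
        "epsilon": repr(curve.bed.epsilon),
        "W": repr(curve.bed.W),
        "layers": str(curve.bed.layers),
        "label": curve.label,
    }


#: column order of the indicator table (one row per experiment)
INDICATOR_COLUMNS = (
    "Z_um",
    "label",
    "C0_mg_mL",
    "F_mL_min",
    "t_b_min",
    "t_e_min",
    "HMTZ_um",
    "V_b_mL",
    "BV",
    "MAER_g_mL",
    "DBC_mg_g",
    "EBC_mg_g",
    "MBU_pct",
    "P_mg_min_g",
)


def write_indicator_table(indicators: Iterable, path, delimiter: str = "\t") -> None:
    """Write one delimited row per experiment in the standard column order.

    `indicators` is a non-empty iterable of PerformanceIndicators
    (see memchrom.metrics).
    """
    rows = list(indicators)
    if not rows:
        raise CurveValidationError("indicator list is empty")
    records = []
    for ind in rows:
        records.append(
            {
                "Z_um": ind.Z,
                "label": ind.label,
                "C0_mg_mL": ind.C0,
                "F_mL_min": ind.F,
                "t_b_min": ind.t_b,
                "t_e_min": ind.t_e,
                "HMTZ_um": ind.HMTZ,
                "V_b_mL": ind.V_b,
                "BV": ind.BV,
                "MAER_g_mL": ind.MAER,
                "DBC_mg_g": ind.DBC,
                "EBC_mg_g": ind.EBC,
                "MBU_pct": ind.MBU,
                "P_mg_min_g": ind.P,
            }
        )
    df = pd.DataFrame.from_records(records, columns=list(INDICATOR_COLUMNS))
    df.to_csv(path, sep=delimiter, index=False, float_format="%.12g")


def read_indicator_table(path, delimiter: str = "\t") -> pd.DataFrame:
    df = pd.read_csv(path, sep=delimiter)
    missing = set(INDICATOR_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing indicator columns {sorted(missing)}")
    return df


def relative_close(a: float, b: float, rtol: float = 1e-9) -> bool:
    return math.isclose(a, b, rel_tol=rtol, abs_tol=0.0)
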