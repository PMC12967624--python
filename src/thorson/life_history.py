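"""Per-species life-history quantities from metabolic theory.

Volumes are assigned from shell geometry (spheres for the initial embryo
and juvenile stages; cylinder / cone / parallelepiped / semi-spheroid for
adults, by shell shape).  Growth ratios are Gr1 = JS/IS, Gr2 = AS/JS,
Gr3 = AS/IS, so Gr1 * Gr2 = Gr3 identically.

Developmental time follows the temperature-size scaling of the metabolic
theory of ecology,

    DT = (4/a0) * exp(E / (k T)) * dS**alpha

with activation energy E = 0.65 eV, Boltzmann constant k (eV/K), allometric
exponent alpha = 0.25, T in kelvin and dS = JS - IS in mm^3.  The constant
4/a0 is calibrated by a through-origin least-squares fit of observed
developmental times against the metabolic term x = exp(E/(kT)) * dS^alpha.

Fecundity per gram of female per day, temperature-corrected, is

    ln Cx = -0.99 ln m0 + 19.15

with m0 the initial-embryo mass in grams (volume at a nominal density of
1 g/L, i.e. 1e-6 g/mm^3); whole-female daily fecundity at ambient
temperature is C = Cx * M^0.75 * exp(-E/(k T)).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

BOLTZMANN_EV = 8.617333e-5  # eV / K
DENSITY_G_PER_MM3 = 1e-6  # nominal tissue density of 1 g/L

#: Fecundity-allometry coefficients: ln Cx = FECUNDITY_SLOPE*ln m0 + FECUNDITY_INTERCEPT
FECUNDITY_SLOPE = -0.99
FECUNDITY_INTERCEPT = 19.15


@dataclass(frozen=True)
class MetabolicParams:
    """Constants of the temperature-size developmental-time model."""

    E: float = 0.65  # activation energy, eV
    k: float = BOLTZMANN_EV
    alpha: float = 0.25
    a0const: float | None = None  # calibrated 4/a0, days / mm^0.75

    def __post_init__(self) -> None:
        if self.E <= 0 or not (0 < self.alpha < 1):
            raise ValueError("require E > 0 and 0 < alpha < 1")
        if self.a0const is not None and self.a0const <= 0:
            raise ValueError("a0const must be positive")

    def with_a0const(self, a0const: float) -> "MetabolicParams":
        return replace(self, a0const=a0const)


@dataclass(frozen=True)
class CalibrationRecord:
    """An observed developmental time at a known rearing temperature."""

    species: str
    DT_obs: float  # days
    T: float  # kelvin
    deltaS: float  # JS - IS, mm^3

    def __post_init__(self) -> None:
        if self.DT_obs <= 0 or self.T <= 0 or self.deltaS <= 0:
            raise ValueError(f"invalid calibration record for {self.species!r}")


_SHAPE_DIMS = {
    "sphere": ("length",),  # length doubles as the diameter
    "cylinder": ("length", "width"),
    "cone": ("length", "width"),
    "parallelepiped": ("length", "width", "height"),
    "semi_spheroid": ("width", "height"),
}


def shell_volume(shape: str, length: float | None = None,
                 width: float | None = None,
                 height: float | None = None) -> float:
    """Volume (mm^3) of a shell idealised as a geometric solid.

    sphere(d=length): (pi/6) d^3; cylinder: pi (w/2)^2 L;
    cone: (pi/3) (w/2)^2 L; parallelepiped: L w h;
    semi-spheroid (two equal equatorial semi-axes w/2, polar semi-axis h):
    (2/3) pi (w/2)^2 h.
    """
    if shape not in _SHAPE_DIMS:
        raise ValueError(f"unknown shape {shape!r}; one of {sorted(_SHAPE_DIMS)}")
    dims = {"length": length, "width": width, "height": height}
    for name in _SHAPE_DIMS[shape]:
        val = dims[name]
        if val is None or val <= 0:
            raise ValueError(f"shape {shape!r} needs positive {name}")
    if shape == "sphere":
        return np.pi / 6.0 * length**3
    if shape == "cylinder":
        return np.pi * (width / 2.0) ** 2 * length
    if shape == "cone":
        return np.pi / 3.0 * (width / 2.0) ** 2 * length
    if shape == "parallelepiped":
        return length * width * height
    return 2.0 / 3.0 * np.pi * (width / 2.0) ** 2 * height


def growth_ratios(IS: float, JS: float, AS: float) -> tuple[float, float, float]:
    """(Gr1, Gr2, Gr3) = (JS/IS, AS/JS, AS/IS)."""
    if min(IS, JS, AS) <= 0:
        raise ValueError("sizes must be positive")
    return JS / IS, AS / JS, AS / IS


def metabolic_term(T, deltaS, params: MetabolicParams = MetabolicParams()):
    """x = exp(E/(kT)) * deltaS^alpha, the temperature-size regressor."""
    T = np.asarray(T, dtype=float)
    deltaS = np.asarray(deltaS, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive kelvin")
    if np.any(deltaS < 0):
        raise ValueError("deltaS must be non-negative")
    x = np.exp(params.E / (params.k * T)) * deltaS**params.alpha
    return float(x) if x.ndim == 0 else x


def calibrate_dt(records, params: MetabolicParams = MetabolicParams(),
                 intercept: str = "zero") -> tuple[float, float]:
    """Least-squares calibration of the constant 4/a0.

    Regresses observed DT on the metabolic term x, through the origin by
    default (``intercept="zero"``; the slope is the constant).  Returns
    ``(a0const, r_squared)``; with the through-origin fit r_squared is
    computed against the uncentred total sum of squares, consistent with
    the zero-intercept model.  ``intercept="free"`` fits an ordinary line
    and returns its slope with the conventional centred r^2.
    """
    records = list(records)
    if len(records) < 3:
        raise ValueError("need at least 3 calibration records")
    x = np.array([metabolic_term(r.T, r.deltaS, params) for r in records])
    y = np.array([r.DT_obs for r in records])
    if np.allclose(x, x[0]):
        raise ValueError("degenerate metabolic terms (all equal): cannot calibrate")
    if intercept == "zero":
        slope = float(x @ y / (x @ x))
        resid = y - slope * x
        ss_tot = float(y @ y)  # uncentred, matching the through-origin model
    elif intercept == "free":
        (slope, b0), *_ = np.linalg.lstsq(np.column_stack([x, np.ones_like(x)]), y,
                                          rcond=None)
        slope = float(slope)
        resid = y - slope * x - b0
        ss_tot = float(np.sum((y - y.mean()) ** 2))
    else:
        raise ValueError(f"intercept must be 'zero' or 'free', got {intercept!r}")
    if slope <= 0:
        raise ValueError("calibration produced a non-positive constant")
    r_squared = 1.0 - float(resid @ resid) / ss_tot
    return slope, r_squared


def developmental_time(T, deltaS, params: MetabolicParams):
    """DT (days) = a0const * exp(E/(kT)) * deltaS^alpha; needs calibration."""
    if params.a0const is None:
        raise ValueError("uncalibrated params: a0const is missing; run calibrate_dt")
    x = metabolic_term(T, deltaS, params)
    return params.a0const * x


def embryo_mass(volume, density: float = DENSITY_G_PER_MM3):
    """Mass (g) of a body of given volume (mm^3) at the nominal 1 g/L density."""
    volume = np.asarray(volume, dtype=float)
    if np.any(volume <= 0):
        raise ValueError("volume must be positive")
    m = volume * density
    return float(m) if m.ndim == 0 else m


def fecundity(m0, M, T, params: MetabolicParams = MetabolicParams()):
    """Offspring per female per day: C = Cx * M^0.75 * exp(-E/(kT)).

    ``Cx = exp(-0.99 ln m0 + 19.15)`` is the temperature-corrected
    fecundity per gram of female; m0 and M in grams, T in kelvin.
    """
    m0 = np.asarray(m0, dtype=float)
    M = np.asarray(M, dtype=float)
    T = np.asarray(T, dtype=float)
    if np.any(m0 <= 0) or np.any(M <= 0) or np.any(T <= 0):
        raise ValueError("m0, M and T must be positive")
    cx = np.exp(FECUNDITY_SLOPE * np.log(m0) + FECUNDITY_INTERCEPT)
    c = cx * M**0.75 * np.exp(-params.E / (params.k * T))
    return float(c) if c.ndim == 0 else c
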