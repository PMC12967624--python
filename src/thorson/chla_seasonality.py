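"""Chlorophyll-a summaries and Colwell's predictability components.

Colwell's indices decompose a periodic series (here, monthly chlorophyll-a
over several years) into predictability ``P``, constancy ``C`` and
contingency ``M`` via a month-by-magnitude-class contingency table:

    C = 1 - H(Y) / ln s
    M = (H(X) + H(Y) - H(XY)) / ln s
    P = C + M

where ``H(X)`` is the entropy of the month totals, ``H(Y)`` of the state
(magnitude-class) totals, ``H(XY)`` of the full table, and ``s`` the number
of state classes (configured a priori, default 11, not the number occupied).
Natural logarithms throughout; all indices lie in [0, 1] and P = C + M holds
identically.  ``C`` is maximal when all observations share one class (a
constant series); ``M`` is maximal when each month maps to its own class
(a strictly seasonal series).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class ChlaSeries:
    """Monthly chlorophyll-a values (mg/m^3) indexed by (year, month).

    ``values`` has shape (n_years, 12); NaN marks missing months.
    """

    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != 12:
            raise ValueError(
                f"expected 12 monthly columns, got {self.values.shape[1]}"
            )
        with np.errstate(invalid="ignore"):
            if np.any(self.values < 0):
                raise ValueError("negative chlorophyll-a concentration")

    @property
    def n_years(self) -> int:
        return self.values.shape[0]


@dataclass
class ColwellResult:
    """Colwell's P, C, M with the underlying month-by-state count table."""

    P: float
    C: float
    M: float
    s: int
    table: np.ndarray


def classify_states(series: ChlaSeries, n_classes: int = 11,
                    binning: str = "equal_width") -> np.ndarray:
    """Month-by-state count table from equal-width magnitude classes.

    ``n_classes`` equal-width bins span [min, max] of the non-missing
    values (log-spaced bins with ``binning="log_width"``); the maximum is
    assigned to the top class; a constant series puts everything in class 1.
    Returns an integer array of shape (12, n_classes).
    """
    if n_classes < 2:
        raise ValueError("need at least 2 magnitude classes")
    vals = series.values
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("all-missing chlorophyll series")
    obs = vals[finite]
    lo, hi = float(obs.min()), float(obs.max())
    if binning == "log_width":
        if lo <= 0:
            raise ValueError("log_width binning requires strictly positive values")
        edges = np.exp(np.linspace(np.log(lo), np.log(hi), n_classes + 1))
    elif binning == "equal_width":
        edges = np.linspace(lo, hi, n_classes + 1)
    else:
        raise ValueError(f"unknown binning {binning!r}")

    table = np.zeros((12, n_classes), dtype=int)
    if hi == lo:  # constant series: everything in class 1
        for month in range(12):
            table[month, 0] = int(finite[:, month].sum())
        return table
    # np.digitize with right-open bins; clip the max into the top class
    states = np.clip(np.digitize(vals, edges) - 1, 0, n_classes - 1)
    for month in range(12):
        col = states[finite[:, month], month]
        np.add.at(table[month], col, 1)
    return table


def _entropy(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-np.sum(p * np.log(p)))


def colwell_from_table(table: np.ndarray, s: int | None = None) -> ColwellResult:
    """Colwell indices from a month-by-state count table."""
    table = np.asarray(table, dtype=float)
    if s is None:
        s = table.shape[1]
    n = table.sum()
    if n <= 0:
        raise ValueError("empty contingency table")
    x = table.sum(axis=1)  # month totals
    y = table.sum(axis=0)  # state totals
    hx = _entropy(x / n)
    hy = _entropy(y / n)
    hxy = _entropy(table.ravel() / n)
    log_s = np.log(s)
    c = 1.0 - hy / log_s
    m = (hx + hy - hxy) / log_s
    return ColwellResult(P=c + m, C=c, M=m, s=int(s), table=table)


def colwell(series: ChlaSeries, n_classes: int = 11,
            binning: str = "equal_width") -> ColwellResult:
    """Predictability, constancy and contingency of a monthly series."""
    table = classify_states(series, n_classes=n_classes, binning=binning)
    return colwell_from_table(table, s=n_classes)


def chla_stats(series: ChlaSeries) -> tuple[float, float]:
    """(CHLA_mean, CHLA_max) over the non-missing values of the series."""
    vals = series.values
    if not np.isfinite(vals).any():
        raise ValueError("all-missing chlorophyll series")
    return float(np.nanmean(vals)), float(np.nanmax(vals))
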