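"""Spectrophotometric pigment quantification and group comparison.

Chlorophyll a and total carotenoids are quantified from methanol-extract
absorbances at 470, 665 and 720 nm:

    Chl a (ug/mL)             = 12.9447 * (A665 - A720)
    total carotenoids (ug/mL) = [1000 * (A470 - A720) - 2.86 * Chl a] / 221

A720 serves as the turbidity reference.  Physically impossible inputs can
yield negative concentrations; these are returned as-is with a warning rather
than clamped, so bad readings surface instead of hiding.

Group comparisons (Fv/Fm, pigment levels, cell density across culture
conditions) use a two-sided Welch t-test with the conventional significance
stars: ns p>0.05, * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "AbsorbanceReading",
    "PigmentResult",
    "GrowthRecord",
    "chl_a",
    "total_carotenoids",
    "pigment_concentrations",
    "welch_compare",
    "significance_stars",
]

CHL_A_COEFF = 12.9447
CAROTENOID_CHL_COEFF = 2.86
CAROTENOID_DENOM = 221.0


@dataclass(frozen=True)
class AbsorbanceReading:
    """Absorbances of one methanol extract at 470, 665 and 720 nm."""

    a470: float
    a665: float
    a720: float

    def __post_init__(self) -> None:
        for name in ("a470", "a665", "a720"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v}")


@dataclass(frozen=True)
class PigmentResult:
    chl_a_ug_ml: float
    carotenoids_ug_ml: float


@dataclass(frozen=True)
class GrowthRecord:
    """One experimental group's replicate measurements (unit tag in meta)."""

    group: str
    values: tuple
    meta: dict = field(default_factory=dict)

    def __init__(self, group: str, values, meta: dict | None = None) -> None:
        values = tuple(float(v) for v in values)
        if len(values) < 2:
            raise ValueError("need >= 2 values per group")
        object.__setattr__(self, "group", group)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "meta", dict(meta or {}))


def chl_a(reading: AbsorbanceReading) -> float:
    """Chlorophyll a concentration in ug/mL."""
    value = CHL_A_COEFF * (reading.a665 - reading.a720)
    if value < 0:
        warnings.warn(
            f"negative chlorophyll a ({value:.4g} ug/mL): check the reading",
            stacklevel=2,
        )
    return value


def total_carotenoids(reading: AbsorbanceReading, chl_a_ug_ml: float) -> float:
    """Total carotenoid concentration in ug/mL (requires Chl a from the same reading)."""
    value = (
        1000.0 * (reading.a470 - reading.a720)
        - CAROTENOID_CHL_COEFF * chl_a_ug_ml
    ) / CAROTENOID_DENOM
    if value < 0:
        warnings.warn(
            f"negative carotenoids ({value:.4g} ug/mL): check the reading",
            stacklevel=2,
        )
    return value


def pigment_concentrations(reading: AbsorbanceReading) -> PigmentResult:
    """Both pigment concentrations from one reading."""
    c = chl_a(reading)
    k = total_carotenoids(reading, c)
    return PigmentResult(chl_a_ug_ml=c, carotenoids_ug_ml=k)


def significance_stars(p: float) -> str:
    """Map a p-value to its significance stars (most extreme applicable)."""
    if p < 0.0001:
        return "****"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def welch_compare(g1: GrowthRecord, g2: GrowthRecord) -> dict:
    """Two-sided Welch (unequal-variance) t-test between two groups.

    Returns ``{"p_value": p, "stars": str}``.  Two zero-variance groups with
    equal means are reported as ns with p = 1.
    """
    a = np.asarray(g1.values)
    b = np.asarray(g2.values)
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        p = 1.0 if a[0] == b[0] else 0.0
    else:
        p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
        if np.isnan(p):
            p = 1.0
    return {"p_value": p, "stars": significance_stars(p)}
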