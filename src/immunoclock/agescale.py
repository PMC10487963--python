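"""Reference curves, equivalent years of life (EYOL), and the immunological age gap.

A reference curve maps age to a reference IMMAX value — usually the fitted P50
of a centile model, or the hypothetical HYP composite whose percentile profile
rises linearly from the 0.5th percentile at age 19 to the 99.5th at age 99
(1.2375 % per year), with IMMAX 0 pinned to age 18 and 1 to age 100.  EYOL is
the chronological age at which the reference curve attains a given IMMAX value
(curve inversion, with linear extrapolation beyond the adult range for P50
references), and the age gap is EYOL minus chronological age: positive values
mean fast/accelerated immunological aging.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .centiles import LMSCentileModel, SplineQuantileRegressor, UnsupportedOperationError

__all__ = [
    "ReferenceCurve",
    "hyp_percentile_profile",
    "build_reference",
    "eyol",
    "age_gap",
]

AGE_MIN, AGE_MAX = 18.0, 100.0
HYP_AGE_LO, HYP_P_LO = 19.0, 0.005
HYP_AGE_HI, HYP_P_HI = 99.0, 0.995
#: slope of the HYP percentile profile, in probability per year
HYP_SLOPE = (HYP_P_HI - HYP_P_LO) / (HYP_AGE_HI - HYP_AGE_LO)


def hyp_percentile_profile(age):
    """Percentile level of the HYP reference at a given age.

    Linear between (19 y, 0.5 %) and (99 y, 99.5 %); ages in [18, 19) and
    (99, 100] use the boundary percentiles.  Outside [18, 100] the profile is
    undefined (the HYP reference is never extrapolated).
    """
    a = np.asarray(age, dtype=float)
    if np.any((a < AGE_MIN) | (a > AGE_MAX)):
        raise ValueError("HYP profile is defined on ages [18, 100] only")
    p = np.clip(HYP_P_LO + HYP_SLOPE * (a - HYP_AGE_LO), HYP_P_LO, HYP_P_HI)
    return float(p) if np.isscalar(age) else p


@dataclass
class ReferenceCurve:
    """Monotone age -> IMMAX map with linear extrapolation slopes per year."""

    kind: str  # LMS_P50 | LQR_P50 | HYP
    age_grid: np.ndarray
    values: np.ndarray
    left_slope: float
    right_slope: float
    provenance: str = ""

    def __post_init__(self):
        self.age_grid = np.asarray(self.age_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.values) < 0):
            raise ValueError("reference values must be non-decreasing along the grid")
        if self.left_slope < 0 or self.right_slope < 0:
            raise ValueError("extrapolation slopes must be non-negative")

    def __call__(self, age):
        return np.interp(np.asarray(age, dtype=float), self.age_grid, self.values)

    def to_dict(self) -> dict:
        return {
            "kind": "reference_curve", "reference": self.kind,
            "age_grid": self.age_grid.tolist(), "values": self.values.tolist(),
            "left_slope": self.left_slope, "right_slope": self.right_slope,
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ReferenceCurve":
        return cls(kind=d["reference"], age_grid=np.asarray(d["age_grid"]),
                   values=np.asarray(d["values"]), left_slope=d["left_slope"],
                   right_slope=d["right_slope"], provenance=d.get("provenance", ""))


def _default_grid(step: float = 0.1) -> np.ndarray:
    n = int(round((AGE_MAX - AGE_MIN) / step))
    return np.round(AGE_MIN + step * np.arange(n + 1), 10)


def build_reference(source, kind: str | None = None, *, grid_step: float = 0.1,
                    boundary_years: float = 5.0) -> ReferenceCurve:
    """Build a monotone reference curve from a fitted centile model.

    ``source`` is a fitted LMS or LQR model (P50 reference) or a fitted LMS
    model with ``kind='HYP'`` for the hypothetical composite.  Values are
    isotonized (pool-adjacent-violators) on a dense age grid; extrapolation
    slopes are the mean slopes over the outer ``boundary_years`` of the grid.
    Spline quantile models cannot serve as references: their basis does not
    extrapolate beyond the data range.
    """
    if isinstance(source, SplineQuantileRegressor):
        raise UnsupportedOperationError(
            "spline quantile (NQR) models cannot define a reference curve: "
            "extrapolation beyond the fitted age range is not feasible"
        )
    grid = _default_grid(grid_step)
    if kind == "HYP" or (isinstance(source, str) and source.upper() == "HYP"):
        if not isinstance(source, LMSCentileModel):
            raise UnsupportedOperationError(
                "the HYP reference is built from a fitted LMS model's centiles"
            )
        profile = hyp_percentile_profile(grid)
        vals = np.array([
            source.predict_quantiles(np.array([a]), (p,))[0, 0]
            for a, p in zip(grid, profile)
        ])
        vals[0], vals[-1] = 0.0, 1.0  # hard endpoint assignments: 0 at 18, 1 at 100
        vals = IsotonicRegression(increasing=True).fit_transform(grid, vals)
        return ReferenceCurve(kind="HYP", age_grid=grid, values=np.clip(vals, 0, 1),
                              left_slope=0.0, right_slope=0.0,
                              provenance="HYP composite of LMS centiles")

    vals = source.predict_quantiles(grid, (0.5,))[:, 0]
    vals = IsotonicRegression(increasing=True).fit_transform(grid, vals)
    vals = np.clip(vals, 0.0, 1.0)
    k = max(int(round(boundary_years / grid_step)), 1)
    left = max((vals[k] - vals[0]) / (grid[k] - grid[0]), 0.0)
    right = max((vals[-1] - vals[-1 - k]) / (grid[-1] - grid[-1 - k]), 0.0)
    name = kind or f"{source.algorithm}_P50"
    return ReferenceCurve(kind=name, age_grid=grid, values=vals,
                          left_slope=left, right_slope=right,
                          provenance=f"P50 of fitted {source.algorithm} model")


def eyol(ref: ReferenceCurve, immax) -> np.ndarray | float:
    """Equivalent years of life: the age where the reference attains ``immax``.

    Linear interpolation on the grid; on a flat segment the midpoint of the
    matching age interval; beyond the curve's range, linear extrapolation with
    the boundary slopes (EYOL may then exceed 100 or fall below 18, including
    negative ages).  A zero extrapolation slope makes out-of-range values
    unresolvable.
    """
    x = np.atleast_1d(np.asarray(immax, dtype=float))
    v, a = ref.values, ref.age_grid
    out = np.empty_like(x)
    for i, xi in enumerate(x):
        if xi < v[0]:
            if ref.left_slope <= 0:
                raise ValueError(
                    f"IMMAX {xi:.4g} below the curve range and left slope is zero: "
                    "EYOL unresolvable")
            out[i] = a[0] - (v[0] - xi) / ref.left_slope
        elif xi > v[-1]:
            if ref.right_slope <= 0:
                raise ValueError(
                    f"IMMAX {xi:.4g} above the curve range and right slope is zero: "
                    "EYOL unresolvable")
            out[i] = a[-1] + (xi - v[-1]) / ref.right_slope
        else:
            lo = int(np.searchsorted(v, xi, side="left"))
            hi = int(np.searchsorted(v, xi, side="right"))
            if hi > lo:  # exact grid hits, possibly a flat run: take the midpoint
                out[i] = 0.5 * (a[lo] + a[hi - 1])
            else:
                out[i] = a[lo - 1] + (xi - v[lo - 1]) / (v[lo] - v[lo - 1]) * (
                    a[lo] - a[lo - 1])
    return float(out[0]) if np.isscalar(immax) else out


def age_gap(ref: ReferenceCurve, immax, age) -> np.ndarray | float:
    """EYOL minus chronological age; positive = fast/accelerated immune aging."""
    e = eyol(ref, immax)
    return e - (float(age) if np.isscalar(age) else np.asarray(age, dtype=float))
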