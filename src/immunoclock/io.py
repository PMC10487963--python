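"""Cohort CSV reading/validation and JSON model serialization."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .agescale import ReferenceCurve
from .centiles import LMSCentileModel, LinearQuantileRegressor, SplineQuantileRegressor
from .cohort import COHORT_COLUMNS, validate_cohort
from .immax import ImmaxPCR

__all__ = ["read_cohort", "write_cohort", "save_model", "load_model", "percentile_chart"]

SCHEMA_VERSION = 1

_KINDS = {
    "immax_pcr": ImmaxPCR,
    "reference_curve": ReferenceCurve,
}
_ALGORITHMS = {
    "LMS": LMSCentileModel,
    "LQR": LinearQuantileRegressor,
    "NQR": SplineQuantileRegressor,
}


class CohortValidationError(ValueError):
    def __init__(self, problems: list[str]):
        super().__init__("cohort validation failed:\n" + "\n".join(problems))
        self.problems = problems


def read_cohort(path, *, require_biomarkers: bool = False) -> pd.DataFrame:
    """Read and validate a cohort CSV; raises with row/column details on violations."""
    table = pd.read_csv(path)
    unknown = [c for c in table.columns if c not in COHORT_COLUMNS]
    if unknown:
        import warnings
        warnings.warn(f"unknown columns preserved: {unknown}", stacklevel=2)
    problems = validate_cohort(table, require_biomarkers=require_biomarkers)
    if problems:
        raise CohortValidationError(problems)
    return table


def write_cohort(table: pd.DataFrame, path) -> None:
    cols = [c for c in COHORT_COLUMNS if c in table.columns] + [
        c for c in table.columns if c not in COHORT_COLUMNS]
    table[cols].to_csv(path, index=False, float_format="%.12g")


def save_model(obj, path) -> None:
    """Serialize a fitted model or reference curve to versioned JSON."""
    payload = obj.to_dict()
    payload["schema_version"] = SCHEMA_VERSION
    Path(path).write_text(json.dumps(payload))


def load_model(path):
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"not a valid model file: {exc}") from exc
    version = payload.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(
            f"model schema version {version!r} not supported by this reader "
            f"(expected {SCHEMA_VERSION})")
    kind = payload.get("kind")
    if kind == "centile_model":
        cls = _ALGORITHMS.get(payload.get("algorithm"))
        if cls is None:
            raise ValueError(f"unknown centile algorithm {payload.get('algorithm')!r}")
        return cls.from_dict(payload)
    cls = _KINDS.get(kind)
    if cls is None:
        raise ValueError(f"unknown model kind {kind!r}")
    return cls.from_dict(payload)


def percentile_chart(model, taus=None, age_min: float = 18.0, age_max: float = 100.0,
                     step: float = 0.5) -> pd.DataFrame:
    """Long-format percentile chart (age, tau, quantile) on a regular age grid."""
    lo, hi = age_min, age_max
    if model.algorithm == "NQR":  # spline models never extrapolate
        lo = max(lo, model.age_range_[0])
        hi = min(hi, model.age_range_[1])
    n = int(np.floor((hi - lo) / step + 1e-9))
    ages = np.round(lo + step * np.arange(n + 1), 10)
    taus = tuple(model.taus) if taus is None else tuple(taus)
    Q = model.predict_quantiles(ages, taus)
    rows = [(a, t, Q[i, j]) for i, a in enumerate(ages) for j, t in enumerate(taus)]
    return pd.DataFrame(rows, columns=["age", "tau", "quantile"])
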