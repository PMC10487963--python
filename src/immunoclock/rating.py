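"""Six-category immunological aging types and inter-rater agreement.

The five percentile curves (P03, P15, P50, P85, P97) partition the biomarker
axis at every age into six ordered categories: 1 = slowest aging (below P03)
up to 6 = fastest (at or above P97); values lying exactly on a curve fall in
the upper (faster) category so the partition is exhaustive and deterministic.

Agreement between rating algorithms is quantified by Krippendorff's alpha,
alpha = 1 - D_o / D_e, with D_o the observed disagreement between pairable
ratings within units and D_e the disagreement expected if ratings were
assigned by chance from the pooled marginals.  The ordinal difference
function (cumulative-marginal weights) is the default; nominal 0/1 is
available.  Confidence intervals come from a percentile bootstrap over units.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "AgreementResult",
    "rate_aging_type",
    "confusion_matrix",
    "krippendorff_alpha",
    "alpha_bootstrap_ci",
]

N_CATEGORIES = 6


class DegenerateAgreementError(ValueError):
    """All codes identical: expected disagreement is zero, alpha is undefined."""


@dataclass
class AgreementResult:
    alpha: float
    d_observed: float
    d_expected: float
    metric: str
    ci_low: float | None = None
    ci_high: float | None = None

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha, "D_o": self.d_observed, "D_e": self.d_expected,
            "metric": self.metric, "ci_low": self.ci_low, "ci_high": self.ci_high,
        }


def rate_aging_type(model, age, y) -> np.ndarray:
    """Aging-type category 1..6 from a fitted centile model's five curves.

    Boundary convention: a value equal to a percentile curve belongs to the
    category above it, so y == P50 rates as 4 (mildly fast).
    """
    age = np.atleast_1d(np.asarray(age, dtype=float))
    y_arr = np.atleast_1d(np.asarray(y, dtype=float))
    if age.shape != y_arr.shape:
        raise ValueError("age and y must have equal length")
    curves = model.predict_quantiles(age)  # n x 5, non-crossing
    if curves.shape[1] != 5:
        raise ValueError("aging-type rating requires exactly five percentile curves")
    codes = 1 + (y_arr[:, None] >= curves).sum(axis=1)
    return codes.astype(int) if codes.size > 1 or not np.isscalar(y) else int(codes[0])


def confusion_matrix(a, b) -> tuple[np.ndarray, float]:
    """Joint 6x6 proportion matrix of two rating vectors plus Spearman's rho."""
    a = np.asarray(a, dtype=int)
    b = np.asarray(b, dtype=int)
    if a.shape != b.shape:
        raise ValueError("rating vectors must have equal length")
    M = np.zeros((N_CATEGORIES, N_CATEGORIES))
    for i, j in zip(a, b):
        M[i - 1, j - 1] += 1
    M /= M.sum()
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        rho = 1.0 if np.array_equal(a, b) else float("nan")
    else:
        rho = float(spearmanr(a, b).statistic)
    return M, rho


def _coincidence(codes: np.ndarray):
    """Coincidence matrix over pairable values; codes is units x raters, NaN = missing."""
    values = np.unique(codes[~np.isnan(codes)])
    index = {v: i for i, v in enumerate(values)}
    k = len(values)
    O = np.zeros((k, k))
    for row in codes:
        present = row[~np.isnan(row)]
        m = len(present)
        if m < 2:
            continue
        idx = np.array([index[v] for v in present])
        counts = np.bincount(idx, minlength=k).astype(float)
        pair = np.outer(counts, counts) - np.diag(counts)
        O += pair / (m - 1)
    return O, values


def _difference_matrix(marginals: np.ndarray, metric: str) -> np.ndarray:
    k = len(marginals)
    if metric == "nominal":
        return 1.0 - np.eye(k)
    if metric == "ordinal":
        # delta_ck = (sum of marginals from c to k minus half the endpoints)^2
        csum = np.concatenate([[0.0], np.cumsum(marginals)])
        D = np.zeros((k, k))
        for c in range(k):
            for g in range(c + 1, k):
                span = csum[g + 1] - csum[c]
                D[c, g] = D[g, c] = (span - (marginals[c] + marginals[g]) / 2.0) ** 2
        return D
    raise ValueError(f"unknown metric {metric!r}; use 'ordinal' or 'nominal'")


def _codes_array(ratings) -> np.ndarray:
    if isinstance(ratings, pd.DataFrame):
        codes = ratings.to_numpy(dtype=float)
    else:
        codes = np.asarray(ratings, dtype=float)
    if codes.ndim != 2 or codes.shape[0] < 2 or codes.shape[1] < 2:
        raise ValueError("ratings must be a units x raters matrix with >= 2 of each")
    finite = codes[~np.isnan(codes)]
    if len(finite) and not np.all(np.isin(finite, np.arange(1, N_CATEGORIES + 1))):
        raise ValueError("codes must be integers in 1..6 (or missing)")
    return codes


def krippendorff_alpha(ratings, metric: str = "ordinal") -> AgreementResult:
    """Krippendorff's alpha = 1 - D_o/D_e for a units x raters code matrix."""
    codes = _codes_array(ratings)
    O, values = _coincidence(codes)
    n_c = O.sum(axis=1)
    n = n_c.sum()
    if n < 2:
        raise ValueError("need at least one unit with two or more pairable codes")
    if len(values) < 2:
        raise DegenerateAgreementError(
            "all pairable codes are identical: expected disagreement D_e = 0, "
            "agreement is undefined (not 1.0)"
        )
    D = _difference_matrix(n_c, metric)
    d_o = float((O * D).sum() / n)
    E = np.outer(n_c, n_c) - np.diag(n_c)
    d_e = float((E * D).sum() / (n * (n - 1.0)))
    if d_e == 0.0:
        raise DegenerateAgreementError("expected disagreement D_e = 0; alpha undefined")
    return AgreementResult(alpha=1.0 - d_o / d_e, d_observed=d_o, d_expected=d_e,
                           metric=metric)


def alpha_bootstrap_ci(ratings, metric: str = "ordinal", B: int = 1000,
                       seed: int = 0, level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap CI over units; deterministic given seed."""
    if B < 100:
        raise ValueError("B must be at least 100")
    codes = _codes_array(ratings)
    rng = np.random.default_rng(seed)
    n_units = codes.shape[0]
    alphas, degenerate = [], 0
    for _ in range(B):
        idx = rng.integers(0, n_units, size=n_units)
        try:
            alphas.append(krippendorff_alpha(codes[idx], metric).alpha)
        except (DegenerateAgreementError, ValueError):
            degenerate += 1
    if degenerate > B / 2:
        raise DegenerateAgreementError(
            f"{degenerate}/{B} bootstrap resamples had zero expected disagreement"
        )
    lo, hi = np.quantile(alphas, [(1 - level) / 2, 1 - (1 - level) / 2])
    return float(lo), float(hi)
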