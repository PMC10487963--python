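"""Synthetic cohorts with the statistical structure of pooled adult immune-aging studies.

The generator emulates a cross-sectional adult cohort (ages 18-100) carrying the
IMMAX immune-age index on the (0, 1) scale together with the five flow-cytometry
biomarkers it is built from.  IMMAX follows a logit-scale location-scale-shape
model: the logit-scale median rises linearly with age, the spread widens with
age, and the noise is (optionally) skewed.  Each record stores its true latent
centile so that downstream centile models can be checked against a known oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit, logit, ndtr, ndtri

__all__ = [
    "GeneratorParams",
    "COHORT_COLUMNS",
    "BIOMARKER_COLUMNS",
    "validate_cohort",
    "true_quantile",
    "generate_cohort",
    "generate_followup",
    "stratified_subsample",
]

#: canonical column order of a cohort table
COHORT_COLUMNS = [
    "subject_id",
    "study",
    "sex",
    "age_years",
    "nk_t_ratio",
    "cd4_cd8_ratio",
    "cd4_mem_naive_ratio",
    "cd8_mem_naive_ratio",
    "cd28neg_cd8_freq",
    "immax",
    "visit",
    "true_centile",
]

BIOMARKER_COLUMNS = [
    "nk_t_ratio",
    "cd4_cd8_ratio",
    "cd4_mem_naive_ratio",
    "cd8_mem_naive_ratio",
    "cd28neg_cd8_freq",
]

AGE_MIN, AGE_MAX = 18.0, 100.0

# fixed location offsets putting the synthetic biomarkers on realistic scales
# (NK:T around 0.3, CD4:CD8 around 1.8, memory:naive ratios around 1,
#  CD28neg fraction of CD8 around 0.25 at mid latent immune age)
_BIOMARKER_OFFSETS = np.array([-1.2, 0.6, 0.2, 0.0, -1.0])


class ValidationError(ValueError):
    """Input failed a domain-validity check; the message names the field."""


@dataclass
class GeneratorParams:
    """Parameters of the synthetic-cohort generator.

    The IMMAX quantile function at age ``a`` is
    ``invlogit(mu(a) + sigma(a) * z_skew(u))`` with ``mu(a) = mu0 + mu1*a``,
    ``sigma(a) = sigma0 + sigma1*a`` and ``z_skew`` the median-centred
    skew-normal standard quantile with shape ``skew`` (``skew=0`` is Gaussian).
    Biomarkers load on the latent immune age ``logit(immax)`` with independent
    marker-specific noise of comparable magnitude.
    """

    age_components: tuple = ((18.0, 40.0, 0.45), (40.0, 65.0, 0.35), (65.0, 97.0, 0.20))
    mu0: float = -0.62
    mu1: float = 0.013
    sigma0: float = 0.065
    sigma1: float = 0.0005
    skew: float = 0.8
    biomarker_loadings: tuple = (0.9, 0.6, 0.8, 1.0, 0.7)
    biomarker_noise_sd: tuple = (0.24, 0.16, 0.21, 0.27, 0.19)
    centile_drift_sd: float = 0.05
    seed: int = 2025

    def validate(self) -> None:
        comps = list(self.age_components)
        if not comps:
            raise ValidationError("age_components: at least one component required")
        total = 0.0
        for lo, hi, w in comps:
            if not (AGE_MIN <= lo < hi <= AGE_MAX):
                raise ValidationError(
                    f"age_components: bounds ({lo}, {hi}) must satisfy 18 <= lo < hi <= 100"
                )
            if w <= 0:
                raise ValidationError("age_components: weights must be positive")
            total += w
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"age_components: weights sum to {total}, expected 1")
        if len(self.biomarker_loadings) != 5:
            raise ValidationError("biomarker_loadings: exactly 5 loadings required")
        if len(self.biomarker_noise_sd) != 5:
            raise ValidationError("biomarker_noise_sd: exactly 5 noise scales required")
        if any(a <= 0 for a in self.biomarker_loadings):
            raise ValidationError("biomarker_loadings: loadings must be positive")
        if any(s <= 0 for s in self.biomarker_noise_sd):
            raise ValidationError("biomarker_noise_sd: noise scales must be positive")
        if self.sigma0 <= 0 or self.sigma0 + self.sigma1 * AGE_MAX <= 0:
            raise ValidationError("sigma0/sigma1: spread must stay positive over [18, 100]")
        if self.centile_drift_sd < 0:
            raise ValidationError("centile_drift_sd: must be non-negative")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_components"] = [list(c) for c in self.age_components]
        d["biomarker_loadings"] = list(self.biomarker_loadings)
        d["biomarker_noise_sd"] = list(self.biomarker_noise_sd)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorParams":
        d = dict(d)
        if "age_components" in d:
            d["age_components"] = tuple(tuple(c) for c in d["age_components"])
        for key in ("biomarker_loadings", "biomarker_noise_sd"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _z_skew(u: np.ndarray, skew: float) -> np.ndarray:
    """Median-centred standard skew-normal quantile (Gaussian when skew == 0)."""
    u = np.asarray(u, dtype=float)
    if skew == 0.0:
        return ndtri(u)
    return stats.skewnorm.ppf(u, skew) - stats.skewnorm.ppf(0.5, skew)


def true_quantile(u, age, params: GeneratorParams):
    """Oracle quantile of IMMAX at latent centile ``u`` and age ``age``.

    Strictly increasing in ``u`` at fixed age; the median (u = 0.5) is
    ``invlogit(mu0 + mu1 * age)`` regardless of the skew because the skewed
    standard quantile is centred at its own median.
    """
    u_arr = np.asarray(u, dtype=float)
    age_arr = np.asarray(age, dtype=float)
    if np.any((u_arr <= 0.0) | (u_arr >= 1.0)):
        raise ValidationError("u: latent centile must lie strictly inside (0, 1)")
    if np.any((age_arr < AGE_MIN) | (age_arr > AGE_MAX)):
        raise ValidationError("age: must lie within [18, 100]")
    mu = params.mu0 + params.mu1 * age_arr
    sigma = params.sigma0 + params.sigma1 * age_arr
    out = expit(mu + sigma * _z_skew(u_arr, params.skew))
    if np.isscalar(u) and np.isscalar(age):
        return float(out)
    return out


def _draw_ages(n: int, params: GeneratorParams, rng: np.random.Generator) -> np.ndarray:
    comps = list(params.age_components)
    weights = np.array([c[2] for c in comps], dtype=float)
    weights = weights / weights.sum()
    idx = rng.choice(len(comps), size=n, p=weights)
    lo = np.array([c[0] for c in comps])[idx]
    hi = np.array([c[1] for c in comps])[idx]
    return lo + (hi - lo) * rng.random(n)


def _biomarkers_from_latent(
    latent: np.ndarray, params: GeneratorParams, rng: np.random.Generator
) -> dict:
    """Monotone transforms of loading*latent + noise: exp for the four ratios,
    inverse-logit for the CD28neg fraction of CD8 T cells."""
    cols = {}
    for j, name in enumerate(BIOMARKER_COLUMNS):
        lin = (
            _BIOMARKER_OFFSETS[j]
            + params.biomarker_loadings[j] * latent
            + rng.normal(0.0, params.biomarker_noise_sd[j], size=latent.shape)
        )
        cols[name] = expit(lin) if name == "cd28neg_cd8_freq" else np.exp(lin)
    return cols


def generate_cohort(
    n: int,
    params: GeneratorParams | None = None,
    *,
    study: str = "SYN",
    seed: int | None = None,
) -> pd.DataFrame:
    """Generate ``n`` cross-sectional baseline records; deterministic given seed.

    ``seed`` overrides ``params.seed`` when given.
    """
    params = params or GeneratorParams()
    params.validate()
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValidationError("n: number of records must be a positive integer")
    rng = np.random.default_rng(params.seed if seed is None else seed)

    ages = _draw_ages(int(n), params, rng)
    u = rng.random(int(n))
    u = np.clip(u, 1e-12, 1 - 1e-12)
    immax = true_quantile(u, ages, params)
    latent = logit(immax)

    table = {
        "subject_id": [f"{study}-{i:05d}" for i in range(int(n))],
        "study": study,
        "sex": rng.choice(["F", "M"], size=int(n)),
        "age_years": ages,
    }
    table.update(_biomarkers_from_latent(latent, params, rng))
    table["immax"] = immax
    table["visit"] = "baseline"
    table["true_centile"] = u
    return pd.DataFrame(table, columns=COHORT_COLUMNS)


def generate_followup(
    baseline: pd.DataFrame,
    fpl: float = 5.0,
    params: GeneratorParams | None = None,
    *,
    seed: int | None = None,
) -> pd.DataFrame:
    """Advance each baseline record by ``fpl`` years.

    The latent centile is perturbed on the probit scale with SD
    ``params.centile_drift_sd`` (clamped to (0.001, 0.999)) and IMMAX is
    recomputed from the oracle quantile function, so with zero drift every
    subject keeps its exact centile while IMMAX moves along its own centile
    curve.  Follow-up ages saturate at 100 years, the oldest age the cohort
    schema represents.
    """
    params = params or GeneratorParams()
    params.validate()
    if fpl <= 0:
        raise ValidationError("fpl: follow-up period length must be positive")
    if "true_centile" not in baseline.columns or baseline["true_centile"].isna().any():
        raise ValidationError(
            "true_centile: missing — only synthetic baselines carrying their "
            "latent centile can be advanced to follow-up"
        )
    rng = np.random.default_rng((params.seed if seed is None else seed) + 1)

    u0 = baseline["true_centile"].to_numpy(dtype=float)
    if params.centile_drift_sd > 0:
        z = ndtri(u0) + rng.normal(0.0, params.centile_drift_sd, size=u0.shape)
        u1 = np.clip(ndtr(z), 0.001, 0.999)
    else:
        u1 = u0.copy()
    ages = np.minimum(baseline["age_years"].to_numpy(dtype=float) + float(fpl), AGE_MAX)
    immax = true_quantile(np.clip(u1, 1e-12, 1 - 1e-12), ages, params)
    latent = logit(immax)

    out = baseline.copy()
    out["age_years"] = ages
    out["true_centile"] = u1
    out["immax"] = immax
    for name, values in _biomarkers_from_latent(latent, params, rng).items():
        out[name] = values
    out["visit"] = "followup"
    return out.reset_index(drop=True)


def stratified_subsample(
    cohort: pd.DataFrame,
    n_out: int,
    stratum_width: float = 10.0,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a cohort into an age-stratified subsample and its remainder.

    Strata are half-open age bins ``[18, 18+w), [18+w, 18+2w), ...``;
    allocation is proportional to stratum size with largest-remainder
    rounding, so subsample and remainder always partition the cohort.
    """
    if stratum_width <= 0:
        raise ValidationError("stratum_width: must be positive")
    n = len(cohort)
    if not (0 < n_out < n):
        raise ValidationError(f"n_out: must satisfy 0 < n_out < cohort size ({n})")

    ages = cohort["age_years"].to_numpy(dtype=float)
    bins = np.floor((ages - AGE_MIN) / stratum_width).astype(int)
    rng = np.random.default_rng(seed)

    labels = np.unique(bins)
    sizes = np.array([(bins == b).sum() for b in labels], dtype=float)
    exact = n_out * sizes / sizes.sum()
    alloc = np.floor(exact).astype(int)
    # largest-remainder rounding, stratum order breaks exact ties deterministically
    short = n_out - alloc.sum()
    order = np.argsort(-(exact - alloc), kind="stable")
    alloc[order[:short]] += 1
    alloc = np.minimum(alloc, sizes.astype(int))
    # if capping at stratum size left a shortfall, refill from strata with room
    while alloc.sum() < n_out:
        room = sizes.astype(int) - alloc
        alloc[np.argmax(room)] += 1

    take = np.zeros(n, dtype=bool)
    for b, k in zip(labels, alloc):
        idx = np.flatnonzero(bins == b)
        take[rng.choice(idx, size=int(k), replace=False)] = True
    sub = cohort.loc[take].reset_index(drop=True)
    rem = cohort.loc[~take].reset_index(drop=True)
    return sub, rem


def validate_cohort(table: pd.DataFrame, *, require_biomarkers: bool = False) -> list[str]:
    """Return a list of human-readable violations (empty when valid)."""
    problems: list[str] = []
    if "subject_id" not in table.columns:
        return ["column subject_id: missing"]
    if "age_years" not in table.columns:
        return ["column age_years: missing"]
    age = pd.to_numeric(table["age_years"], errors="coerce")
    bad = table.index[(age < AGE_MIN) | (age > AGE_MAX) | age.isna()]
    problems += [f"row {i}, column age_years: value outside [18, 100]" for i in bad]
    if "immax" in table.columns:
        ix = pd.to_numeric(table["immax"], errors="coerce")
        bad = table.index[((ix < 0) | (ix > 1)) & table["immax"].notna()]
        problems += [f"row {i}, column immax: value outside [0, 1]" for i in bad]
    for col in BIOMARKER_COLUMNS:
        if col not in table.columns:
            if require_biomarkers:
                problems.append(f"column {col}: missing")
            continue
        v = pd.to_numeric(table[col], errors="coerce")
        if col == "cd28neg_cd8_freq":
            bad = table.index[((v < 0) | (v > 1)) & table[col].notna()]
            problems += [f"row {i}, column {col}: fraction outside [0, 1]" for i in bad]
        else:
            bad = table.index[(v <= 0) & table[col].notna()]
            problems += [f"row {i}, column {col}: ratio must be strictly positive" for i in bad]
    if "visit" in table.columns:
        ok = table["visit"].isin(["baseline", "followup"]) | table["visit"].isna()
        problems += [f"row {i}, column visit: unknown label" for i in table.index[~ok]]
        fu = table[table["visit"] == "followup"]
        base_ids = set(table.loc[table["visit"] == "baseline", "subject_id"])
        for i, sid in zip(fu.index, fu["subject_id"]):
            if sid not in base_ids:
                problems.append(f"row {i}, column subject_id: followup without matching baseline")
    return problems
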