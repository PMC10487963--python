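"""Change from baseline in IMMAX, centiles, EYOL and age gap, with tests.

For each subject observed at baseline and follow-up, the module computes the
deltas of IMMAX, the individual LMS centile, and EYOL / age gap under each
requested reference curve.  For a follow-up period length FPL the changes are
algebraically linked by  dEYOL = dAgeGap + FPL,  which holds exactly on every
record by construction.

The statistical report mirrors the standard longitudinal analysis: paired
Wilcoxon signed-rank tests of each delta against zero, pairwise paired
Wilcoxon comparisons of dEYOL across references with Holm adjustment,
Spearman correlations among the deltas, and independent-sample Wilcoxon
(Mann-Whitney) comparisons between the sexes where both are present.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .agescale import ReferenceCurve, eyol
from .centiles import LMSCentileModel

__all__ = ["StatsReport", "change_from_baseline", "longitudinal_report"]


@dataclass
class StatsReport:
    entries: list  # (comparison, test, statistic, p_raw, p_adjusted)
    adjustment: str
    correlations: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "adjustment": self.adjustment,
            "tests": [
                {"comparison": c, "test": t, "statistic": s, "p_raw": p, "p_adjusted": q}
                for c, t, s, p, q in self.entries
            ],
            "spearman_correlations": self.correlations.to_dict(),
        }


def _pair_visits(paired: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    base = paired[paired["visit"] == "baseline"].set_index("subject_id")
    fup = paired[paired["visit"] == "followup"].set_index("subject_id")
    dup = base.index[base.index.duplicated()].tolist() + fup.index[
        fup.index.duplicated()].tolist()
    if dup:
        raise ValueError(f"subjects with duplicated visits: {sorted(set(dup))}")
    unpaired = sorted(set(base.index) ^ set(fup.index))
    if unpaired:
        raise ValueError(f"subjects without a baseline/followup pair: {unpaired}")
    fup = fup.loc[base.index]
    return base, fup


def change_from_baseline(
    paired: pd.DataFrame,
    lms_model: LMSCentileModel | None = None,
    references: dict[str, ReferenceCurve] | None = None,
) -> pd.DataFrame:
    """Per-subject delta table from a cohort with baseline and followup visits.

    ``lms_model`` (when given) supplies individual centiles at each visit's own
    age; ``references`` maps a label (e.g. ``"LQR_P50"``) to a reference curve
    used for EYOL and age gap.  ``delta_age_gap`` is derived as
    ``delta_eyol - fpl`` so the FPL identity is exact on every record.
    """
    if "immax" not in paired.columns or paired["immax"].isna().any():
        raise ValueError("every record needs an IMMAX value (column 'immax')")
    base, fup = _pair_visits(paired)
    fpl = fup["age_years"].to_numpy(float) - base["age_years"].to_numpy(float)
    if np.any(fpl <= 0):
        raise ValueError("followup age must exceed baseline age")

    out = pd.DataFrame({
        "subject_id": base.index,
        "sex": base["sex"].to_numpy() if "sex" in base.columns else "unknown",
        "fpl": fpl,
        "delta_immax": fup["immax"].to_numpy(float) - base["immax"].to_numpy(float),
    })
    if lms_model is not None:
        c0 = lms_model.centile(base["age_years"].to_numpy(float),
                               np.clip(base["immax"].to_numpy(float), 1e-6, 1 - 1e-6))
        c1 = lms_model.centile(fup["age_years"].to_numpy(float),
                               np.clip(fup["immax"].to_numpy(float), 1e-6, 1 - 1e-6))
        out["delta_centile"] = c1 - c0
    for name, ref in (references or {}).items():
        e0 = eyol(ref, base["immax"].to_numpy(float))
        e1 = eyol(ref, fup["immax"].to_numpy(float))
        out[f"delta_eyol_{name}"] = e1 - e0
        out[f"delta_age_gap_{name}"] = (e1 - e0) - fpl
    return out.reset_index(drop=True)


def _paired_wilcoxon(x: np.ndarray) -> tuple[float, float]:
    """Signed-rank test of median zero; exact for n <= 25 without ties/zeros."""
    x = np.asarray(x, dtype=float)
    nz = x[x != 0]
    if len(nz) == 0:
        return float("nan"), float("nan")  # degenerate: all differences zero
    method = "exact" if (len(nz) <= 25 and len(np.unique(np.abs(nz))) == len(nz)) \
        else "approx"
    res = stats.wilcoxon(nz, zero_method="wilcox", correction=(method == "approx"),
                         method=method)
    return float(res.statistic), float(res.pvalue)


def longitudinal_report(deltas: pd.DataFrame, adjustment: str = "holm") -> StatsReport:
    """Paired tests against zero, cross-reference comparisons, correlations, sex."""
    delta_cols = [c for c in deltas.columns if c.startswith("delta_")]
    if len(deltas) < 6:
        raise ValueError("at least 6 paired subjects required")

    entries = []
    for col in delta_cols:
        s, p = _paired_wilcoxon(deltas[col].to_numpy(float))
        test = "wilcoxon-signed-rank" if np.isfinite(p) else "degenerate (all zero)"
        entries.append([f"{col} vs 0", test, s, p])

    eyol_cols = [c for c in delta_cols if c.startswith("delta_eyol_")]
    pair_entries = []
    for i in range(len(eyol_cols)):
        for j in range(i + 1, len(eyol_cols)):
            d = deltas[eyol_cols[i]].to_numpy(float) - deltas[eyol_cols[j]].to_numpy(float)
            s, p = _paired_wilcoxon(d)
            pair_entries.append([f"{eyol_cols[i]} vs {eyol_cols[j]}",
                                 "wilcoxon-signed-rank (paired)", s, p])

    sexes = deltas["sex"].dropna().unique() if "sex" in deltas.columns else []
    if {"F", "M"}.issubset(set(sexes)):
        f = deltas[deltas["sex"] == "F"]
        m = deltas[deltas["sex"] == "M"]
        if len(f) >= 6 and len(m) >= 6:
            for col in delta_cols:
                res = stats.mannwhitneyu(f[col].to_numpy(float), m[col].to_numpy(float),
                                         alternative="two-sided")
                entries.append([f"{col} by sex (F vs M)", "wilcoxon-rank-sum",
                                float(res.statistic), float(res.pvalue)])

    # Holm adjustment over the cross-reference dEYOL family (the multiplicity
    # family is configurable in scope: here the reference comparisons)
    if pair_entries:
        raw = [e[3] for e in pair_entries]
        adj = multipletests(raw, method=adjustment)[1]
        for e, q in zip(pair_entries, adj):
            e.append(float(q))
    for e in entries:
        e.append(e[3])  # single tests: adjusted = raw
    all_entries = [tuple(e) for e in entries + pair_entries]

    corr = deltas[delta_cols].corr(method="spearman")
    return StatsReport(entries=all_entries, adjustment=adjustment, correlations=corr)
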