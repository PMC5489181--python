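"""Derived demography from an abundance series.

Given per-sex annual abundance estimates N_t and apparent survival phi_t, this
module computes the finite annual rate of change lambda_t = N_{t+1} / N_t, its
geometric mean, annual recruitment B_t = N_{t+1} - N_t phi_t (floored at zero),
minimum ages from first/last detection years, and first-detection cohort
decompositions.

Conventions mirror the source study's presentation:

* lambda and B are defined only across one-calendar-year intervals; a survey
  gap (e.g. 2008 -> 2011) yields no entries.
* A year in which a sex was detected but its abundance is not estimable
  contributes 0 to the total-abundance lambda (flagged ``partial``) and a
  recruitment of 0.0 for that sex.
* Totals are male + female sums (recruits floored per sex before summing).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

GROUPS = ("male", "female", "total")


def _pivot(abundance: pd.DataFrame) -> pd.DataFrame:
    """abundance (sex, year, N_hat[, estimable]) -> years x {male, female,
    total} with NaN for not-estimable; total treats NE as 0 when the other sex
    is estimable."""
    ab = abundance.copy()
    if "estimable" in ab.columns:
        ab.loc[~ab["estimable"].astype(bool), "N_hat"] = np.nan
    wide = ab.pivot_table(index="year", columns="sex", values="N_hat", dropna=False)
    wide = wide.reindex(columns=["male", "female"])
    any_est = wide.notna().any(axis=1)
    wide["total"] = wide.fillna(0.0).sum(axis=1).where(any_est)
    wide["partial"] = wide[["male", "female"]].isna().any(axis=1) & any_est
    return wide.sort_index()


def lambda_series(abundance: pd.DataFrame) -> pd.DataFrame:
    """Finite annual rate of change lambda_t = N_{t+1} / N_t per group.

    Defined only where both years are estimable and exactly one calendar year
    apart; otherwise the entry is NaN (never a division error — N_t = 0 also
    yields NaN).  Total-abundance entries computed with one sex not estimable
    are flagged in ``partial``.
    """
    wide = _pivot(abundance)
    years = wide.index.to_numpy()
    rows = []
    for i, y in enumerate(years[:-1]):
        if years[i + 1] != y + 1:
            continue
        rec = {"year": y}
        for g in GROUPS:
            a, b = wide[g].iloc[i], wide[g].iloc[i + 1]
            rec[g] = b / a if np.isfinite(a) and np.isfinite(b) and a > 0 else np.nan
        rec["partial"] = bool(wide["partial"].iloc[i] or wide["partial"].iloc[i + 1])
        rows.append(rec)
    return pd.DataFrame(rows, columns=["year", *GROUPS, "partial"])


@dataclass(frozen=True)
class GeometricMeanResult:
    gmean: float
    variance: float        # sample variance, n-1 denominator (default report)
    variance_n: float      # population form, n denominator
    n: int


def geometric_mean_lambda(lambdas) -> GeometricMeanResult:
    """Geometric mean annual rate of change with the sample variance of the
    lambda values (both n-1 and n denominators reported)."""
    lam = np.asarray(pd.Series(lambdas).dropna(), dtype=float)
    if (lam <= 0).any():
        bad = np.flatnonzero(lam <= 0)
        raise ValueError(f"non-positive lambda at positions {bad.tolist()}")
    n = len(lam)
    gm = float(np.exp(np.mean(np.log(lam))))
    var1 = float(np.var(lam, ddof=1)) if n > 1 else 0.0
    var0 = float(np.var(lam, ddof=0))
    return GeometricMeanResult(gm, var1, var0, n)


def recruits(
    abundance: pd.DataFrame,
    survival: pd.DataFrame,
    floor: bool = True,
) -> pd.DataFrame:
    """Annual recruitment B_t = N_{t+1} - N_t phi_t per sex, plus totals.

    Negative values are truncated to 0 when ``floor`` (the unfloored value is
    kept in ``<sex>_raw`` columns for diagnostics).  A sex whose N_t is not
    estimable gets B_t = 0.0 for that year.  Totals sum the per-sex (floored)
    values.  Entries exist only for one-calendar-year intervals with N_{t+1}
    estimable and phi_t available.
    """
    wide = _pivot(abundance)
    phi = survival.pivot_table(index="year", columns="sex", values="phi", dropna=False)
    years = wide.index.to_numpy()
    rows = []
    for i, y in enumerate(years[:-1]):
        if years[i + 1] != y + 1:
            continue
        rec = {"year": y}
        for g in ("male", "female"):
            n0, n1 = wide[g].iloc[i], wide[g].iloc[i + 1]
            ph = phi.at[y, g] if (y in phi.index and g in phi.columns) else np.nan
            if not np.isfinite(n1) or not np.isfinite(ph):
                rec[g] = rec[f"{g}_raw"] = np.nan
                continue
            if not np.isfinite(n0):
                # sex undetected / not estimable in year t: reported as 0.0
                rec[g], rec[f"{g}_raw"] = 0.0, np.nan
                continue
            raw = n1 - n0 * ph
            rec[f"{g}_raw"] = raw
            rec[g] = max(0.0, raw) if floor else raw
        rows.append(rec)
    df = pd.DataFrame(
        rows,
        columns=["year", "male", "female", "total", "male_raw", "female_raw"],
    )
    df["total"] = df["male"] + df["female"]
    return df


@dataclass(frozen=True)
class RecruitSummary:
    mean: float
    variance: float  # sample variance (n-1)
    minimum: float
    maximum: float
    n: int


def recruit_summary(values) -> RecruitSummary:
    """Arithmetic mean, sample variance, range and n of annual recruit counts."""
    v = np.asarray(pd.Series(values).dropna(), dtype=float)
    if len(v) < 2:
        raise ValueError("need at least two defined years")
    return RecruitSummary(
        float(v.mean()), float(np.var(v, ddof=1)), float(v.min()), float(v.max()), len(v)
    )


def minimum_age(first_year: int, last_year: int) -> int:
    """Minimum age at last detection, assuming adults are at least 2 years old
    at first solo detection."""
    if last_year < first_year:
        raise ValueError("last_year must be >= first_year")
    return (last_year - first_year) + 2


def cohort_table(yearly_matrix: pd.DataFrame, merge_after_gap: bool = True) -> pd.DataFrame:
    """Decompose per-year detection counts into first-detection cohorts.

    ``yearly_matrix`` is a binary individual x survey-year table.  Each
    individual belongs to the cohort of its first detected year.  When
    ``merge_after_gap``, a cohort first detected in the first survey year
    after a multi-year gap is labelled ``"<gap start>/<year>"`` (such animals
    may have entered unobserved during the gap).

    Returns a tidy table (year, cohort, count) whose per-year counts sum to
    the individuals detected that year.
    """
    years = list(yearly_matrix.columns)
    mat = yearly_matrix.to_numpy() > 0
    first_idx = np.argmax(mat, axis=1)

    labels = {}
    for j, y in enumerate(years):
        if merge_after_gap and j > 0 and y - years[j - 1] > 1:
            labels[j] = f"{years[j - 1] + 1}/{y}"
        else:
            labels[j] = str(y)

    rows = []
    for j, y in enumerate(years):
        present = mat[:, j]
        if not present.any():
            continue
        cohorts = pd.Series([labels[i] for i in first_idx[present]])
        for cohort, count in cohorts.value_counts().items():
            rows.append((y, cohort, int(count)))
    return (
        pd.DataFrame(rows, columns=["year", "cohort", "count"])
        .sort_values(["year", "cohort"])
        .reset_index(drop=True)
    )


def demography_table(
    abundance: pd.DataFrame, survival: pd.DataFrame, floor: bool = True
) -> dict:
    """Full annual-change-and-recruitment report.

    Returns ``{"table": wide per-year lambda & recruits, "lambda_summary":
    {group: GeometricMeanResult}, "recruit_summary": {group: RecruitSummary}}``.
    """
    lam = lambda_series(abundance)
    rec = recruits(abundance, survival, floor=floor)
    table = lam[["year", *GROUPS]].merge(
        rec[["year", *GROUPS]], on="year", suffixes=("_lambda", "_recruits")
    )
    lam_summary = {g: geometric_mean_lambda(lam[g]) for g in GROUPS}
    rec_summary = {g: recruit_summary(rec[g]) for g in GROUPS}
    return {"table": table, "lambda_summary": lam_summary, "recruit_summary": rec_summary}
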