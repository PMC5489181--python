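"""Population-structure analyses: residency classification, tenure tests,
detection-span regression, and seasonal subsampling.

A *local resident* is an individual detected within the survey grid for at
least three consecutive survey years; all others are *transients* with respect
to the grid.  Unsurveyed calendar years are skipped, not counted as absences:
a run spanning the last survey year before a gap and the first after it counts
as consecutive (absence of data is not absence of the animal).
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, datetime, timedelta
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .survey import DetectionEvent


# ---------------------------------------------------------------------------
# residency
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResidencyRecord:
    individual_id: str
    sex: str
    years_detected: tuple[int, ...]
    span: int                 # last - first detection year, over all data
    longest_run: int          # consecutive surveyed years, within window+buffer
    status: str               # "resident" | "transient"
    detections_per_location_per_year: float


def longest_consecutive_run(detected_years, surveyed_years) -> int:
    """Length of the longest run of detections over *consecutive surveyed*
    years (adjacent entries of ``surveyed_years``; survey gaps are bridged)."""
    det = set(detected_years)
    best = cur = 0
    for y in surveyed_years:
        cur = cur + 1 if y in det else 0
        best = max(best, cur)
    return best


def classify_residency(
    yearly_matrix: pd.DataFrame,
    window: tuple[int, int] = (2003, 2007),
    min_run: int = 3,
    sexes: dict[str, str] | pd.Series | None = None,
    rates: dict[str, float] | pd.Series | None = None,
) -> list[ResidencyRecord]:
    """Classify individuals as residents or transients.

    ``yearly_matrix`` is a binary individual x survey-year table covering the
    evaluation ``window``; one buffer survey year on either side of the window
    is used when available, so that residency at the window edges can be
    judged.  Only individuals detected within the window are classified.
    """
    years = list(yearly_matrix.columns)
    lo, hi = window
    if lo not in years or hi not in years:
        raise ValueError(f"window {window} not covered by data years {years}")
    i_lo, i_hi = years.index(lo), years.index(hi)
    eval_years = years[max(i_lo - 1, 0) : min(i_hi + 1, len(years) - 1) + 1]

    records = []
    mat = yearly_matrix.to_numpy() > 0
    for i, ind in enumerate(yearly_matrix.index):
        det_all = [y for j, y in enumerate(years) if mat[i, j]]
        det_win = [y for y in det_all if lo <= y <= hi]
        if not det_win:
            continue
        run = longest_consecutive_run(det_all, eval_years)
        records.append(
            ResidencyRecord(
                individual_id=str(ind),
                sex=(sexes.get(ind, "unknown") if sexes is not None else "unknown"),
                years_detected=tuple(det_all),
                span=det_all[-1] - det_all[0],
                longest_run=run,
                status="resident" if run >= min_run else "transient",
                detections_per_location_per_year=(
                    float(rates.get(ind, np.nan)) if rates is not None else np.nan
                ),
            )
        )
    return records


def residency_table(records: Sequence[ResidencyRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "individual_id": [r.individual_id for r in records],
            "sex": [r.sex for r in records],
            "n_years_detected": [len(r.years_detected) for r in records],
            "span": [r.span for r in records],
            "longest_run": [r.longest_run for r in records],
            "status": [r.status for r in records],
            "detections_per_location_per_year": [
                r.detections_per_location_per_year for r in records
            ],
        }
    )


# ---------------------------------------------------------------------------
# tests
# ---------------------------------------------------------------------------

def permutation_test(
    group_a,
    group_b,
    statistic: Callable[[np.ndarray, np.ndarray], float] | None = None,
    n_perm: int = 9999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-sided Monte-Carlo permutation test; returns (observed stat, p).

    ``statistic`` defaults to the difference of means.  The p-value uses the
    add-one convention p = (1 + #{|stat*| >= |stat|}) / (n_perm + 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both groups must be non-empty")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if statistic is None:
        statistic = lambda x, y: float(np.mean(x) - np.mean(y))
    obs = statistic(a, b)
    pooled = np.concatenate([a, b])
    na = len(a)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(pooled)
        if abs(statistic(perm[:na], perm[na:])) >= abs(obs) - 1e-12:
            count += 1
    return obs, (1 + count) / (n_perm + 1)


def paired_wilcoxon(x, y) -> tuple[float, float]:
    """Wilcoxon signed-rank test (V = sum of positive signed ranks), with the
    standard zero-drop convention; exact null for n <= 25 without ties.

    All-zero differences return (V = 0, p = 1).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("paired samples must have equal length")
    d = x - y
    if np.all(d == 0):
        return 0.0, 1.0
    nz = d != 0
    ranks = stats.rankdata(np.abs(d[nz]))
    v_plus = float(ranks[d[nz] > 0].sum())
    res = stats.wilcoxon(x, y, zero_method="wilcox", alternative="two-sided")
    return v_plus, float(res.pvalue)


def mann_whitney(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney test; returns (W, p) where W is the rank-based
    statistic for ``x`` (R's ``wilcox.test`` convention), with midranks for
    ties; exact null for small samples without ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# detection-span regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2_adj: float
    f_stat: float
    df: int            # residual degrees of freedom, n - 2
    p_value: float
    n: int


def _ols(y: np.ndarray, x: np.ndarray) -> RegressionResult:
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    return RegressionResult(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r2_adj=float(res.rsquared_adj),
        f_stat=float(res.fvalue),
        df=int(res.df_resid),
        p_value=float(res.f_pvalue),
        n=len(y),
    )


def detection_span_regression(
    spans, years_detected, sexes
) -> dict:
    """Per-sex OLS of detection span (last - first year, y) on the number of
    years actually detected (x).  A slope near 1 means individuals were
    detected in consecutive years; near 2, every other year.

    Returns ``{"male": RegressionResult, "female": RegressionResult,
    "slope_difference_p": p}`` where the slope comparison is the interaction
    term of a pooled model.
    """
    y = np.asarray(spans, dtype=float)
    x = np.asarray(years_detected, dtype=float)
    sex = np.asarray(sexes)
    out = {}
    for s in ("male", "female"):
        m = sex == s
        if m.sum() < 3:
            raise ValueError(f"need at least 3 individuals of sex {s!r}")
        out[s] = _ols(y[m], x[m])
    is_male = (sex == "male").astype(float)
    X = np.column_stack([np.ones_like(x), x, is_male, x * is_male])
    pooled = sm.OLS(y, X).fit()
    out["slope_difference_p"] = float(pooled.pvalues[3])
    return out


# ---------------------------------------------------------------------------
# seasonal subsampling of a year-long survey
# ---------------------------------------------------------------------------

def quarterly_subsample(
    events: Sequence[DetectionEvent],
    start: date | datetime,
    n_quarters: int = 4,
) -> pd.DataFrame:
    """Split a year-long event record into contiguous 3-month quarters and
    report, per quarter and sex, how many of the year's detected individuals
    were seen (denominator = individuals detected at any point in the year).

    Returns a tidy table (quarter, sex, n_detected, n_total, proportion,
    percent) with percent rounded to the nearest whole number.
    """
    if isinstance(start, date) and not isinstance(start, datetime):
        start = datetime.combine(start, datetime.min.time())
    edges = [start + timedelta(days=round(365 * k / n_quarters)) for k in range(n_quarters + 1)]

    sex_of: dict[str, str] = {}
    seen_in: list[dict[str, set]] = [dict() for _ in range(n_quarters)]
    for ev in events:
        sex_of[ev.individual_id] = ev.sex
        for q in range(n_quarters):
            if edges[q] <= ev.timestamp < edges[q + 1]:
                seen_in[q].setdefault(ev.sex, set()).add(ev.individual_id)
                break

    totals: dict[str, set] = {}
    for ind, s in sex_of.items():
        totals.setdefault(s, set()).add(ind)

    rows = []
    for q in range(n_quarters):
        for s, all_inds in sorted(totals.items()):
            n_det = len(seen_in[q].get(s, set()))
            prop = n_det / len(all_inds)
            rows.append((q + 1, s, n_det, len(all_inds), prop, round(100 * prop)))
    return pd.DataFrame(
        rows,
        columns=["quarter", "sex", "n_detected", "n_total", "proportion", "percent"],
    )
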