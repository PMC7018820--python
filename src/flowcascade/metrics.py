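"""Flow-regime metrics: the dh4 statistic and IHA-vector distances.

dh4 is the maximum 30-day moving-average flow (m3 s-1) over a 12-month
window.  The moving-average convention is trailing 30-day windows fully
contained in the window (a 365-day window has 365 - 30 + 1 = 336 candidate
windows); no partial windows are used.  A "12-month" window is always 365
days long, regardless of leap years, so the statistic stays comparable
across years.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hydro import DischargeSeries, Period, STUDY_PERIODS

logger = logging.getLogger(__name__)

WINDOW_DAYS = 30
YEAR_DAYS = 365
DEFAULT_ANCHOR = (12, 31)

METRIC_COLUMNS = ["site_id", "model_id", "period", "year", "metric", "value"]


def _rolling_window_means(flow: np.ndarray, width: int = WINDOW_DAYS) -> np.ndarray:
    """Means of every fully contained ``width``-day window; entry j covers days j..j+width-1."""
    csum = np.concatenate(([0.0], np.cumsum(flow, dtype=float)))
    return (csum[width:] - csum[:-width]) / width


def dh4(flows) -> float:
    """Maximum 30-day moving-average flow of a daily window of >= 30 days."""
    arr = np.asarray(flows, dtype=float)
    if arr.ndim != 1:
        raise ValueError("flows must be 1-d")
    if arr.size < WINDOW_DAYS:
        raise ValueError(f"dh4 needs at least {WINDOW_DAYS} days, got {arr.size}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("dh4: non-finite flow values")
    return float(_rolling_window_means(arr).max())


def _dh4_between(rolled: np.ndarray, start_idx: int, end_idx: int) -> float:
    """dh4 over series days [start_idx, end_idx] from precomputed rolling means."""
    # contained 30-day windows start at j in [start_idx, end_idx - 29]
    return float(rolled[start_idx : end_idx - WINDOW_DAYS + 2].max())


def dh4_annual(
    series: DischargeSeries,
    period: Period | None = None,
    anchor: tuple[int, int] = DEFAULT_ANCHOR,
) -> pd.DataFrame:
    """One dh4 per period year, on the 365 days ending on (year, anchor).

    Parameters
    ----------
    series
        Daily discharge covering the period.
    period
        The period definition; defaults to the study period matching
        ``series.period_label``.
    anchor
        (month, day) end of each 12-month window; default December 31, i.e.
        calendar-year-ending windows.

    Returns
    -------
    DataFrame with columns site_id, model_id, period, year, metric, value;
    exactly one row per year whose window lies inside the series (a year whose
    window would extend before the series start is omitted with a warning).
    """
    if period is None:
        try:
            period = STUDY_PERIODS[series.period_label]
        except KeyError:
            raise ValueError(
                f"unknown period label {series.period_label!r}; pass a Period explicitly"
            ) from None
    rolled = _rolling_window_means(series.flow)
    rows = []
    for year in period.years:
        end = dt.date(year, *anchor)
        try:
            end_idx = series.day_index(end)
        except ValueError:
            logger.warning(
                "dh4_annual: %s/%s year %d anchor outside series; year omitted",
                series.site_id, series.model_id, year,
            )
            continue
        start_idx = end_idx - (YEAR_DAYS - 1)
        if start_idx < 0:
            logger.warning(
                "dh4_annual: %s/%s year %d window starts before series; year omitted",
                series.site_id, series.model_id, year,
            )
            continue
        rows.append(
            (series.site_id, series.model_id, period.label, year, "dh4",
             _dh4_between(rolled, start_idx, end_idx))
        )
    return pd.DataFrame(rows, columns=METRIC_COLUMNS)


def dh4_observed(series: DischargeSeries, sampling_date: dt.date) -> float:
    """dh4 of the 365 days ending on the biological sampling date."""
    end_idx = series.day_index(sampling_date)
    start_idx = end_idx - (YEAR_DAYS - 1)
    if start_idx < 0:
        raise ValueError(
            f"insufficient history: need {YEAR_DAYS} days ending {sampling_date}, "
            f"series starts {series.start}"
        )
    rolled = _rolling_window_means(series.flow)
    return _dh4_between(rolled, start_idx, end_idx)


@dataclass(frozen=True)
class IHAVector:
    """Per-model vector of flow-regime metric values, optionally standardized."""

    model_id: str
    values: dict[str, float] = field(repr=False)
    standardized: bool = False

    @property
    def metrics(self) -> frozenset:
        return frozenset(self.values)


#: metric names of the default weighting vector: dh4 plus simple magnitude stats
DEFAULT_IHA_METRICS = (
    ["dh4", "annual_mean", "annual_max", "annual_min"]
    + [f"monthly_mean_{m:02d}" for m in range(1, 13)]
)


def iha_vector(
    model_id: str,
    series_list: list[DischargeSeries],
    period: Period | None = None,
    anchor: tuple[int, int] = DEFAULT_ANCHOR,
) -> IHAVector:
    """Default IHA summary vector for one climate model over a set of sites.

    Metrics (each averaged over years, then over sites): mean annual dh4,
    annual mean/max/min flow, and the 12 monthly mean flows.  This is the
    configurable magnitude-statistics vector used for ensemble weighting; the
    weighting procedure, not a specific metric list, is the reproducible
    content.
    """
    if not series_list:
        raise ValueError("iha_vector: empty series list")
    per_site = []
    for series in series_list:
        vals = {"dh4": dh4_annual(series, period=period, anchor=anchor)["value"].mean()}
        s = pd.Series(series.flow, index=series.dates)
        by_year = s.groupby(s.index.year)
        vals["annual_mean"] = float(by_year.mean().mean())
        vals["annual_max"] = float(by_year.max().mean())
        vals["annual_min"] = float(by_year.min().mean())
        monthly = s.groupby(s.index.month).mean()
        for m in range(1, 13):
            vals[f"monthly_mean_{m:02d}"] = float(monthly.get(m, np.nan))
        per_site.append(vals)
    averaged = pd.DataFrame(per_site).mean()
    return IHAVector(model_id=model_id, values={k: float(v) for k, v in averaged.items()})


def standardize_iha(vectors: list[IHAVector]) -> list[IHAVector]:
    """Z-score each metric across the collection (sd with n-1 denominator).

    Metrics with zero spread across the collection are dropped with a warning;
    at least two vectors are required and all must share the same metric keys.
    """
    if len(vectors) < 2:
        raise ValueError("standardize_iha needs >= 2 vectors")
    keys = vectors[0].metrics
    if any(v.metrics != keys for v in vectors[1:]):
        raise ValueError("standardize_iha: vectors have mismatched metric keys")
    table = pd.DataFrame([v.values for v in vectors])
    mean, sd = table.mean(), table.std(ddof=1)
    dropped = sd.index[sd == 0].tolist()
    if dropped:
        logger.warning("standardize_iha: dropping zero-spread metrics %s", dropped)
    kept = [k for k in table.columns if k not in dropped]
    if not kept:
        raise ValueError("standardize_iha: all metrics have zero spread")
    z = (table[kept] - mean[kept]) / sd[kept]
    return [
        IHAVector(model_id=v.model_id, values=dict(z.iloc[i]), standardized=True)
        for i, v in enumerate(vectors)
    ]


def euclidean_distance(a: IHAVector, b: IHAVector) -> float:
    """Euclidean distance between two IHA vectors over their shared metric keys."""
    if a.metrics != b.metrics:
        raise ValueError("euclidean_distance: metric keys differ")
    if a.standardized != b.standardized:
        raise ValueError("euclidean_distance: one vector is standardized, the other is not")
    diffs = np.array([a.values[k] - b.values[k] for k in sorted(a.values)])
    return float(np.sqrt(np.sum(diffs**2)))
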