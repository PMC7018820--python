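"""Discharge data model, study periods, site handling and hydrological skill scores.

Daily discharge series are stored on real calendar dates (leap days kept) as a
plain numpy array plus a start date; consecutive-day coverage is enforced at
construction.  Skill scores follow the standard hydrological definitions:
Kling-Gupta efficiency (KGE) and Nash-Sutcliffe efficiency (NSE), both equal
to 1 at perfect agreement and unbounded below.
"""

from __future__ import annotations

import datetime as dt
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_STATUS = ("high", "good", "moderate", "poor", "bad")
#: ecological-status classes retained for the analysis (Water Framework Directive)
KEPT_STATUS = frozenset({"high", "good", "moderate"})


class UndefinedStatisticError(ValueError):
    """A statistic is mathematically undefined on this input (e.g. zero variance)."""


@dataclass(frozen=True)
class Period:
    """A labelled study period spanning whole calendar years."""

    label: str
    start_year: int
    end_year: int

    def __post_init__(self) -> None:
        if self.end_year < self.start_year:
            raise ValueError(f"period {self.label}: end_year < start_year")

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def start_date(self) -> dt.date:
        return dt.date(self.start_year, 1, 1)

    @property
    def end_date(self) -> dt.date:
        return dt.date(self.end_year, 12, 31)

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)


#: The three 20-year study periods: baseline, horizon 2050 and horizon 2090.
STUDY_PERIODS: dict[str, Period] = {
    "baseline": Period("baseline", 1998, 2017),
    "h2050": Period("h2050", 2046, 2065),
    "h2090": Period("h2090", 2080, 2099),
}

OBSERVED_MODEL_ID = "observed"


@dataclass(frozen=True)
class Site:
    """A biological sampling site within a catchment.

    ``flow_accumulation`` is the contributing drainage area proxy used to scale
    discharge from the subbasin outlet (``outlet_id``) down to the site.
    """

    site_id: str
    catchment_id: str
    outlet_id: str
    flow_accumulation: float
    ecological_status: str

    def __post_init__(self) -> None:
        if not self.flow_accumulation > 0:
            raise ValueError(f"site {self.site_id}: flow_accumulation must be > 0")
        if self.ecological_status not in VALID_STATUS:
            raise ValueError(
                f"site {self.site_id}: unknown ecological status "
                f"{self.ecological_status!r} (expected one of {VALID_STATUS})"
            )


@dataclass(frozen=True)
class DischargeSeries:
    """Daily flow (m3 s-1) for one site x climate model x period.

    Invariants: dates are consecutive calendar days starting at ``start``;
    all flows are finite and non-negative.
    """

    site_id: str
    model_id: str
    period_label: str
    start: dt.date
    flow: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.flow, dtype=float)
        object.__setattr__(self, "flow", arr)
        if arr.ndim != 1 or arr.size == 0:
            raise ValueError("flow must be a non-empty 1-d array")
        if not np.all(np.isfinite(arr)):
            raise ValueError(f"{self.site_id}/{self.model_id}: non-finite flow values")
        if np.any(arr < 0):
            raise ValueError(f"{self.site_id}/{self.model_id}: negative flow values")

    def __len__(self) -> int:
        return self.flow.size

    @property
    def end(self) -> dt.date:
        return self.start + dt.timedelta(days=self.flow.size - 1)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=self.flow.size, freq="D")

    def day_index(self, date: dt.date) -> int:
        """Position of ``date`` within the series; raises if outside coverage."""
        idx = (date - self.start).days
        if not 0 <= idx < self.flow.size:
            raise ValueError(
                f"{self.site_id}/{self.model_id}: {date} outside series "
                f"[{self.start}, {self.end}]"
            )
        return idx

    def with_flow(self, flow: np.ndarray, **changes) -> "DischargeSeries":
        return replace(self, flow=np.asarray(flow, dtype=float), **changes)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "site_id": self.site_id,
                "model_id": self.model_id,
                "period": self.period_label,
                "date": self.dates,
                "flow_m3s": self.flow,
            }
        )


def filter_sites_by_status(sites: list[Site]) -> list[Site]:
    """Drop sites of "poor" or "bad" ecological status, preserving order.

    Status validity is enforced by the :class:`Site` constructor; this filter
    keeps exactly the {high, good, moderate} classes.
    """
    kept = [s for s in sites if s.ecological_status in KEPT_STATUS]
    n_dropped = len(sites) - len(kept)
    if n_dropped:
        logger.info("filter_sites_by_status: dropped %d of %d sites", n_dropped, len(sites))
    return kept


def extrapolate_discharge(
    outlet_series: DischargeSeries, site: Site, outlet_fa: float
) -> DischargeSeries:
    """Scale outlet discharge to a site by the ratio of flow accumulations.

    Strictly proportional: each day's flow is multiplied by
    ``site.flow_accumulation / outlet_fa``.  Dates are unchanged and
    non-negativity is preserved.
    """
    if not outlet_fa > 0:
        raise ValueError("outlet flow accumulation must be > 0")
    ratio = site.flow_accumulation / outlet_fa
    return outlet_series.with_flow(outlet_series.flow * ratio, site_id=site.site_id)


def _as_flows(x) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError("flow series must be 1-d")
    return arr


def kge(observed, simulated) -> float:
    """Kling-Gupta efficiency: 1 - sqrt((r-1)^2 + (alpha-1)^2 + (beta-1)^2).

    r is the Pearson correlation, alpha the ratio of standard deviations
    (simulated/observed) and beta the ratio of means.  The score is at most 1
    (perfect agreement) and unbounded below.

    Raises
    ------
    UndefinedStatisticError
        If either series has zero variance (correlation undefined) or the
        observed mean is zero (beta undefined).
    """
    obs, sim = _as_flows(observed), _as_flows(simulated)
    if obs.size != sim.size or obs.size < 2:
        raise ValueError("observed and simulated must have equal length >= 2")
    obs_sd = obs.std(ddof=1)
    sim_sd = sim.std(ddof=1)
    if obs_sd == 0:
        raise UndefinedStatisticError("observed series has zero variance")
    if sim_sd == 0:
        raise UndefinedStatisticError("simulated series has zero variance")
    obs_mean = obs.mean()
    if obs_mean == 0:
        raise UndefinedStatisticError("observed series has zero mean")
    r = float(np.corrcoef(obs, sim)[0, 1])
    alpha = float(sim_sd / obs_sd)
    beta = float(sim.mean() / obs_mean)
    return 1.0 - float(np.sqrt((r - 1) ** 2 + (alpha - 1) ** 2 + (beta - 1) ** 2))


def nse(observed, simulated) -> float:
    """Nash-Sutcliffe efficiency: 1 - sum((sim-obs)^2) / sum((obs-mean(obs))^2).

    Equals 1 iff the series are identical; 0 for the mean-of-observations
    predictor.  Raises :class:`UndefinedStatisticError` on a constant observed
    series.
    """
    obs, sim = _as_flows(observed), _as_flows(simulated)
    if obs.size != sim.size or obs.size < 2:
        raise ValueError("observed and simulated must have equal length >= 2")
    denom = float(np.sum((obs - obs.mean()) ** 2))
    if denom == 0:
        raise UndefinedStatisticError("observed series is constant")
    return 1.0 - float(np.sum((sim - obs) ** 2)) / denom
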