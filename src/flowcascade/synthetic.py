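"""Synthetic study generator: discharge ensembles, species and trait tables.

The generator emulates the statistical structure the cascade assumes, so
every stage is testable without external hydrological or climate data:

* daily flows are lognormal with a sinusoidal seasonal cycle and an AR(1)
  anomaly, ``Q(t) = exp(mu_site + A sin(2 pi doy/365 + phi) + eps(t))``;
* an ensemble of climate models diverges through one multiplicative trend
  draw per model and horizon, ``delta ~ Normal(Delta_h, sigma_spread)``,
  applied to the horizon flows;
* two catchment archetypes: "mountainous" (model trends divergent around
  zero, large spread) and "lowland" (trends shifted positive, small spread);
* species are unimodal responders to dh4 with narrow (specialist) or wide
  (generalist) niche breadth, occupying the sites whose observed dh4 falls
  inside their niche; trait affinities are assigned consistently with the
  niche (e.g. an optimum above the median site dh4 gives a strong rheophil
  affinity).

All randomness flows from a single seed through named substreams (sites,
discharge, trends, species) so stages can be regenerated independently.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .abundance import PreferenceCurve
from .hydro import (
    DischargeSeries,
    OBSERVED_MODEL_ID,
    Period,
    STUDY_PERIODS,
    Site,
    extrapolate_discharge,
)
from .metrics import dh4_observed
from .traits import (
    CURRENT_PREFERENCE,
    FEEDING_TYPE,
    STREAM_ZONATION,
    TRAIT_TABLE_COLUMNS,
)

SUBSTREAMS = ("sites", "discharge", "trends", "species")


def _default_periods() -> dict[str, Period]:
    return dict(STUDY_PERIODS)


@dataclass(frozen=True)
class ScenarioConfig:
    """Parameters of one synthetic catchment study.

    Trend parameters are per-horizon multiplicative flow shifts:
    ``delta_mean[h]`` is the ensemble-mean shift and ``sigma_spread`` the
    across-model spread of the one draw each model makes per horizon.
    """

    archetype: str = "mountainous"
    n_sites: int = 10
    n_models: int = 16
    n_species: int = 12
    periods: dict[str, Period] = field(default_factory=_default_periods)
    baseline_label: str = "baseline"
    # site geometry
    outlet_fa_range: tuple[float, float] = (40.0, 200.0)  # km2
    site_fa_fraction: tuple[float, float] = (0.5, 1.0)
    frac_poor_bad: float = 0.2
    # daily flow process (log scale)
    specific_discharge: float = 0.012  # m3 s-1 per km2, sets the log-mean
    seasonal_amplitude: float = 0.6
    seasonal_phase: float = math.pi / 2 - 2 * math.pi * 15 / 365  # winter flow peak
    ar1_rho: float = 0.85
    noise_sd: float = 0.35  # marginal sd of the AR(1) log-flow anomaly
    # climate-model trends
    delta_mean: dict[str, float] = field(default_factory=lambda: {"h2050": 0.0, "h2090": 0.0})
    sigma_spread: float = 0.15
    # species niches
    fraction_specialists: float = 0.5
    specialist_breadth_rel: tuple[float, float] = (0.08, 0.15)  # x optimum
    generalist_breadth_rel: tuple[float, float] = (0.5, 1.0)
    optimum_jitter_breadths: float = 0.5
    occupancy_radius_breadths: float = 2.0
    specialist_max_sites: int = 3
    peak_abundance_range: tuple[float, float] = (20.0, 200.0)
    count_noise: bool = False
    sampling_date: dt.date = dt.date(2017, 6, 15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("n_models must be >= 2")
        if self.n_sites < 1 or self.n_species < 1:
            raise ValueError("n_sites and n_species must be >= 1")
        if self.sigma_spread < 0:
            raise ValueError("sigma_spread must be >= 0")
        if not 0 <= self.fraction_specialists <= 1:
            raise ValueError("fraction_specialists must be in [0, 1]")
        for name in ("specialist_breadth_rel", "generalist_breadth_rel"):
            lo, hi = getattr(self, name)
            if not 0 < lo <= hi:
                raise ValueError(f"{name} must satisfy 0 < low <= high")
        if not 0 < self.ar1_rho < 1:
            raise ValueError("ar1_rho must be in (0, 1)")
        missing = {p for p in self.periods if p != self.baseline_label} - set(self.delta_mean)
        if missing:
            raise ValueError(f"delta_mean missing horizons: {sorted(missing)}")

    @classmethod
    def mountainous(cls, **overrides) -> "ScenarioConfig":
        """Divergent model trends around zero (large across-model spread)."""
        defaults = dict(
            archetype="mountainous",
            delta_mean={"h2050": 0.0, "h2090": 0.0},
            sigma_spread=0.15,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @classmethod
    def lowland(cls, **overrides) -> "ScenarioConfig":
        """Consistently positive model trends (small across-model spread)."""
        defaults = dict(
            archetype="lowland",
            delta_mean={"h2050": 0.08, "h2090": 0.13},
            sigma_spread=0.03,
        )
        defaults.update(overrides)
        return cls(**defaults)

    @property
    def model_ids(self) -> list[str]:
        return [f"gcm_rcm_{i + 1:02d}" for i in range(self.n_models)]

    @property
    def horizon_labels(self) -> list[str]:
        return [p for p in self.periods if p != self.baseline_label]


@dataclass
class ScenarioData:
    """One generated miniature study, in the shapes the pipeline consumes."""

    config: ScenarioConfig
    sites: list[Site]
    outlet_fa: dict[str, float]
    discharge: dict[tuple[str, str, str], DischargeSeries]  # (site, model, period)
    trends: pd.DataFrame  # model_id, horizon, delta
    site_dh4: dict[str, float]  # observed dh4 at the sampling date, per site
    curves: dict[str, PreferenceCurve]
    occurrences: pd.DataFrame
    trait_table: pd.DataFrame
    specialist_flags: dict[str, bool]


def substreams(seed: int) -> dict[str, np.random.Generator]:
    """Named, independent random substreams derived from one seed."""
    children = np.random.SeedSequence(seed).spawn(len(SUBSTREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(SUBSTREAMS, children)}


def generate_sites(config: ScenarioConfig, rng: np.random.Generator) -> tuple[list[Site], dict[str, float]]:
    """Sites attached pairwise to subbasin outlets, with ecological status labels.

    A fixed fraction of sites (``frac_poor_bad``) gets a "poor" or "bad"
    status so the downstream filter is exercised.
    """
    n_outlets = max(1, math.ceil(config.n_sites / 2))
    outlet_ids = [f"out_{i + 1:02d}" for i in range(n_outlets)]
    outlet_fa = {
        oid: float(rng.uniform(*config.outlet_fa_range)) for oid in outlet_ids
    }
    n_bad = int(round(config.frac_poor_bad * config.n_sites))
    statuses = ["poor" if i % 2 else "bad" for i in range(n_bad)]
    statuses += list(rng.choice(["high", "good", "moderate"], size=config.n_sites - n_bad))
    rng.shuffle(statuses)
    sites = []
    for i in range(config.n_sites):
        oid = outlet_ids[i % n_outlets]
        frac = float(rng.uniform(*config.site_fa_fraction))
        sites.append(
            Site(
                site_id=f"site_{i + 1:02d}",
                catchment_id=config.archetype,
                outlet_id=oid,
                flow_accumulation=frac * outlet_fa[oid],
                ecological_status=str(statuses[i]),
            )
        )
    return sites, outlet_fa


def draw_trends(config: ScenarioConfig, rng: np.random.Generator) -> pd.DataFrame:
    """One multiplicative flow-trend draw per model and horizon.

    ``delta ~ Normal(Delta_h, sigma_spread)``, truncated below at -0.9 so the
    multiplied flows stay positive.
    """
    rows = []
    for model_id in config.model_ids:
        for horizon in config.horizon_labels:
            delta = rng.normal(config.delta_mean[horizon], config.sigma_spread)
            rows.append((model_id, horizon, float(max(delta, -0.9))))
    return pd.DataFrame(rows, columns=["model_id", "horizon", "delta"])


def _ar1(rng: np.random.Generator, n_series: int, n_days: int, rho: float, sd: float) -> np.ndarray:
    """Stationary AR(1) anomalies with marginal sd ``sd``, shape (n_series, n_days)."""
    innov = rng.normal(0.0, sd * math.sqrt(1 - rho**2), size=(n_series, n_days))
    innov[:, 0] = rng.normal(0.0, sd, size=n_series)  # stationary start
    return lfilter([1.0], [1.0, -rho], innov, axis=1)


def generate_discharge(
    config: ScenarioConfig,
    outlet_fa: dict[str, float],
    rng_discharge: np.random.Generator,
    trends: pd.DataFrame,
) -> dict[tuple[str, str, str], DischargeSeries]:
    """Daily discharge at every outlet for every model and period.

    Includes the observation-forced series (model id "observed") for the
    baseline period only; horizon flows carry the model's trend factor
    ``(1 + delta)``.
    """
    trend_map = {(r.model_id, r.horizon): r.delta for r in trends.itertuples()}
    jobs = []  # (outlet, model, period) in a fixed, reproducible order
    for oid in outlet_fa:
        for model_id in [OBSERVED_MODEL_ID] + config.model_ids:
            for label, period in config.periods.items():
                if model_id == OBSERVED_MODEL_ID and label != config.baseline_label:
                    continue
                jobs.append((oid, model_id, label, period))
    out: dict[tuple[str, str, str], DischargeSeries] = {}
    # group jobs by period length so the AR(1) filter runs vectorized
    by_len: dict[int, list] = {}
    for job in jobs:
        by_len.setdefault(job[3].n_days, []).append(job)
    for n_days, batch in by_len.items():
        anomalies = _ar1(rng_discharge, len(batch), n_days, config.ar1_rho, config.noise_sd)
        for (oid, model_id, label, period), eps in zip(batch, anomalies):
            dates = pd.date_range(period.start_date, period.end_date, freq="D")
            doy = dates.dayofyear.to_numpy()
            season = config.seasonal_amplitude * np.sin(
                2 * math.pi * doy / 365 + config.seasonal_phase
            )
            mu = math.log(config.specific_discharge * outlet_fa[oid])
            flow = np.exp(mu + season + eps)
            if label != config.baseline_label and model_id != OBSERVED_MODEL_ID:
                flow = flow * (1.0 + trend_map[(model_id, label)])
            out[(oid, model_id, label)] = DischargeSeries(
                site_id=oid, model_id=model_id, period_label=label,
                start=period.start_date, flow=flow,
            )
    return out


def extrapolate_to_sites(
    outlet_discharge: dict[tuple[str, str, str], DischargeSeries],
    sites: list[Site],
    outlet_fa: dict[str, float],
) -> dict[tuple[str, str, str], DischargeSeries]:
    """Site-level discharge via proportional flow-accumulation scaling."""
    out = {}
    for site in sites:
        for (oid, model_id, label), series in outlet_discharge.items():
            if oid != site.outlet_id:
                continue
            scaled = extrapolate_discharge(series, site, outlet_fa[oid])
            out[(site.site_id, model_id, label)] = scaled
    return out


def _trait_rows(
    species_id: str,
    specialist: bool,
    optimum: float,
    dh4_median: float,
    rng: np.random.Generator,
) -> list[tuple]:
    """Trait affinities consistent with the species' niche.

    Specialists carry one strong (>=7) category per trait, chosen from the
    niche position (optimum above the median site dh4 -> rheophil /
    downstream); generalists get low, spread affinities (<= 4) so the
    assignment rules classify them as generalists.  A share of generalists
    gets a dual feeding signature (two categories at 5-6).
    """
    rows = []

    def spread(trait, categories):
        for cat in categories:
            rows.append((species_id, trait, cat, int(rng.integers(2, 5))))

    if specialist:
        current = "rheophil" if optimum > dh4_median else "limnophil"
        zonation = "mid_to_downstream" if optimum > dh4_median else "upstream"
        feeding = str(rng.choice(["grazer", "shredder", "predator", "gatherer"]))
        for trait, strong_cat, categories in (
            (CURRENT_PREFERENCE, current, ["limnophil", "rheophil", "indifferent"]),
            (STREAM_ZONATION, zonation, ["upstream", "mid_to_upstream", "mid_to_downstream"]),
            (FEEDING_TYPE, feeding, ["grazer", "shredder", "predator", "gatherer"]),
        ):
            for cat in categories:
                aff = int(rng.integers(7, 11)) if cat == strong_cat else int(rng.integers(0, 4))
                rows.append((species_id, trait, cat, aff))
    else:
        spread(CURRENT_PREFERENCE, ["limnophil", "rheophil", "indifferent"])
        spread(STREAM_ZONATION, ["upstream", "mid_to_upstream", "mid_to_downstream"])
        if rng.random() < 0.5:  # dual feeders among the generalists
            pair = ["grazer", "shredder"] if rng.random() < 0.5 else ["gatherer", "shredder"]
            for cat in ["grazer", "shredder", "predator", "gatherer"]:
                aff = int(rng.integers(5, 7)) if cat in pair else int(rng.integers(0, 4))
                rows.append((species_id, FEEDING_TYPE, cat, aff))
        else:
            spread(FEEDING_TYPE, ["grazer", "shredder", "predator", "gatherer"])
    return rows


ORDERS = ("Ephemeroptera", "Plecoptera", "Trichoptera", "Diptera", "Coleoptera")


def generate_species(
    config: ScenarioConfig,
    site_dh4: dict[str, float],
    rng: np.random.Generator,
) -> tuple[dict[str, PreferenceCurve], pd.DataFrame, pd.DataFrame, dict[str, bool]]:
    """Preference curves, occurrence table and trait table for one scenario.

    Each species anchors its optimum at one site's observed dh4 (jittered by
    up to ``optimum_jitter_breadths`` niche widths) and occupies the sites
    within ``occupancy_radius_breadths`` widths of the optimum — specialists
    capped at ``specialist_max_sites`` nearest sites.  Observed abundance at
    an occupied site is the curve evaluated at the site's observed dh4
    (optional Poisson count noise, off by default).
    """
    if not site_dh4:
        raise ValueError("generate_species: empty site set")
    site_ids = list(site_dh4)
    dh4_vals = np.array([site_dh4[s] for s in site_ids])
    dh4_median = float(np.median(dh4_vals))
    valid_lo, valid_hi = 0.5 * float(dh4_vals.min()), 1.5 * float(dh4_vals.max())
    n_specialists = int(round(config.fraction_specialists * config.n_species))

    curves: dict[str, PreferenceCurve] = {}
    occ_rows, trait_rows = [], []
    flags: dict[str, bool] = {}
    for i in range(config.n_species):
        species_id = f"sp_{i + 1:02d}"
        specialist = i < n_specialists
        flags[species_id] = specialist
        anchor = float(rng.choice(dh4_vals))
        rel_lo, rel_hi = (
            config.specialist_breadth_rel if specialist else config.generalist_breadth_rel
        )
        breadth = float(rng.uniform(rel_lo, rel_hi)) * anchor
        optimum = anchor + float(
            rng.uniform(-config.optimum_jitter_breadths, config.optimum_jitter_breadths)
        ) * breadth
        curve = PreferenceCurve(
            species_id=species_id,
            optimum=optimum,
            breadth=breadth,
            peak_abundance=float(rng.uniform(*config.peak_abundance_range)),
            dh4_min=valid_lo,
            dh4_max=valid_hi,
        )
        curves[species_id] = curve

        dist = np.abs(dh4_vals - optimum)
        inside = dist <= config.occupancy_radius_breadths * breadth
        idx = np.flatnonzero(inside)
        if idx.size == 0:  # jitter can push every site outside; keep the nearest
            idx = np.array([int(np.argmin(dist))])
        if specialist and idx.size > config.specialist_max_sites:
            idx = idx[np.argsort(dist[idx])][: config.specialist_max_sites]
        order = ORDERS[i % len(ORDERS)]
        for j in idx:
            abundance = curve.peak_abundance * math.exp(
                -((dh4_vals[j] - optimum) ** 2) / (2 * breadth**2)
            )
            if config.count_noise:
                abundance = float(rng.poisson(abundance))
            occ_rows.append(
                (species_id, site_ids[j], abundance, config.sampling_date.isoformat(), order)
            )
        trait_rows.extend(_trait_rows(species_id, specialist, optimum, dh4_median, rng))

    occurrences = pd.DataFrame(
        occ_rows,
        columns=["species_id", "site_id", "abundance", "sampling_date", "taxonomic_order"],
    )
    trait_table = pd.DataFrame(trait_rows, columns=TRAIT_TABLE_COLUMNS)
    return curves, occurrences, trait_table, flags


def generate_scenario(config: ScenarioConfig) -> ScenarioData:
    """Full miniature study from one seed: sites, discharge, species, traits."""
    rngs = substreams(config.seed)
    sites, outlet_fa = generate_sites(config, rngs["sites"])
    trends = draw_trends(config, rngs["trends"])
    outlet_discharge = generate_discharge(config, outlet_fa, rngs["discharge"], trends)
    discharge = extrapolate_to_sites(outlet_discharge, sites, outlet_fa)
    site_dh4 = {
        site.site_id: dh4_observed(
            discharge[(site.site_id, OBSERVED_MODEL_ID, config.baseline_label)],
            config.sampling_date,
        )
        for site in sites
    }
    curves, occurrences, trait_table, flags = generate_species(
        config, site_dh4, rngs["species"]
    )
    return ScenarioData(
        config=config,
        sites=sites,
        outlet_fa=outlet_fa,
        discharge=discharge,
        trends=trends,
        site_dh4=site_dh4,
        curves=curves,
        occurrences=occurrences,
        trait_table=trait_table,
        specialist_flags=flags,
    )


def null_scenario(config: ScenarioConfig) -> ScenarioData:
    """A scenario whose horizon discharge is literally the baseline discharge.

    Horizon period definitions are pinned to the baseline years (each still a
    full 20-year span) and the baseline series are reused under the horizon
    labels, so every downstream change statistic must be exactly zero.
    """
    base = config.periods[config.baseline_label]
    pinned = {label: replace(base, label=label) for label in config.periods}
    cfg = replace(config, periods=pinned, sigma_spread=0.0,
                  delta_mean={h: 0.0 for h in config.horizon_labels})
    data = generate_scenario(cfg)
    for (site_id, model_id, label) in list(data.discharge):
        if label == cfg.baseline_label or model_id == OBSERVED_MODEL_ID:
            continue
        baseline_series = data.discharge[(site_id, model_id, cfg.baseline_label)]
        data.discharge[(site_id, model_id, label)] = replace(
            baseline_series, period_label=label
        )
    return data
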