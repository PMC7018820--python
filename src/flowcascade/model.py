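"""The model/results interface over the full uncertainty cascade.

:class:`FlowAbundanceCascade` is built from data — discharge series per site
x climate model x period, sites, species preference curves, occurrences and
(optionally) trait affinities — and its :meth:`~FlowAbundanceCascade.fit`
runs the whole cascade: site filtering, annual dh4, abundance predictions,
MAV / delta / SR, skill-based model weights, ensemble summaries, trait-group
responses and significance flags.  The returned :class:`CascadeResults`
carries every table plus a ``summary()`` in the style of statistical
modelling packages.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .abundance import PreferenceCurve, occupancy_mask
from .cascade import CascadeTables, run_cascade
from .ensemble import EnsembleSummary, assign_weights, summarize_ensemble, weighted_mean
from .hydro import (
    DischargeSeries,
    OBSERVED_MODEL_ID,
    Period,
    STUDY_PERIODS,
    Site,
    filter_sites_by_status,
)
from .metrics import DEFAULT_ANCHOR, dh4_annual, euclidean_distance, iha_vector, standardize_iha
from .stats import ALPHA_VS_GRAND_MEAN, ALPHA_VS_ZERO, flag_species_responses
from .traits import aggregate_group_sr, assign_all, coverage_check

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CascadeConfig:
    """Analysis decisions surfaced as configuration.

    * ``anchor``: (month, day) ending each annual 12-month dh4 window.
    * ``sr_mode``: "mean_pct" (percent change per site, then averaged) or
      "pooled_pct" (deltas averaged first, then expressed as a percent).
    * ``ladder_mode``: ensemble weight ladder spacing, "endpoint" (1/(N-1),
      weights span [1, 2] inclusive) or "step" (1/N).
    * ``alpha_zero`` / ``alpha_grand``: significance levels of the vs-zero
      and vs-grand-mean species flags.
    * ``arcsine_before_tests``: transform percent data before all tests.
    """

    anchor: tuple[int, int] = DEFAULT_ANCHOR
    sr_mode: str = "mean_pct"
    ladder_mode: str = "endpoint"
    alpha_zero: float = ALPHA_VS_ZERO
    alpha_grand: float = ALPHA_VS_GRAND_MEAN
    arcsine_before_tests: bool = True
    baseline_label: str = "baseline"


def skill_weights(
    discharge: dict[tuple[str, str, str], DischargeSeries],
    kept_sites: list[Site],
    periods: dict[str, Period],
    baseline_label: str = "baseline",
    anchor: tuple[int, int] = DEFAULT_ANCHOR,
    ladder_mode: str = "endpoint",
) -> tuple[pd.DataFrame, bool]:
    """Ladder weights from hindcast-vs-observed IHA distances.

    IHA vectors for the climate-model baseline series and the
    observation-forced baseline series are built from the same
    discharge-to-metric path (so hydrological model error does not enter the
    skill assessment), standardized jointly, and each model is ranked by the
    Euclidean distance of its vector to the observed one.  Falls back to
    uniform weights (flagged by the second return value) when no observed
    series are present.
    """
    kept_ids = [s.site_id for s in kept_sites]
    model_ids = sorted(
        {m for (_, m, _) in discharge if m != OBSERVED_MODEL_ID}
    )
    observed_series = [
        discharge[(sid, OBSERVED_MODEL_ID, baseline_label)]
        for sid in kept_ids
        if (sid, OBSERVED_MODEL_ID, baseline_label) in discharge
    ]
    if not observed_series:
        logger.warning("no observed baseline series; using uniform ensemble weights")
        return (
            pd.DataFrame(
                {"model_id": model_ids, "distance": np.nan, "rank": 1, "weight": 1.0}
            ),
            True,
        )
    period = periods[baseline_label]
    vectors = [
        iha_vector(
            mid,
            [discharge[(sid, mid, baseline_label)] for sid in kept_ids],
            period=period,
            anchor=anchor,
        )
        for mid in model_ids
    ]
    vectors.append(
        iha_vector(OBSERVED_MODEL_ID, observed_series, period=period, anchor=anchor)
    )
    standardized = {v.model_id: v for v in standardize_iha(vectors)}
    obs_vec = standardized[OBSERVED_MODEL_ID]
    distances = {mid: euclidean_distance(standardized[mid], obs_vec) for mid in model_ids}
    return assign_weights(distances, mode=ladder_mode), False


def flow_change_summary(
    metric_values: pd.DataFrame, weights, baseline_label: str = "baseline"
) -> tuple[pd.DataFrame, list[EnsembleSummary]]:
    """Relative dh4 change per model (mean over sites), summarized per horizon."""
    per = metric_values.groupby(["site_id", "model_id", "period"], as_index=False)[
        "value"
    ].mean()
    baseline = per[per["period"] == baseline_label].rename(columns={"value": "base"})
    horizons = per[per["period"] != baseline_label].rename(
        columns={"value": "hor", "period": "horizon"}
    )
    merged = horizons.merge(baseline.drop(columns="period"), on=["site_id", "model_id"])
    merged["pct_change"] = 100.0 * (merged["hor"] - merged["base"]) / merged["base"]
    per_model = merged.groupby(["model_id", "horizon"], as_index=False)["pct_change"].mean()
    summaries = []
    for horizon, grp in per_model.groupby("horizon", sort=False):
        values = dict(zip(grp["model_id"], grp["pct_change"]))
        summaries.append(summarize_ensemble(values, weights, target="flow_dh4", horizon=horizon))
    return per_model, summaries


class FlowAbundanceCascade:
    """Climate-to-abundance uncertainty cascade for one catchment.

    Parameters
    ----------
    discharge
        Mapping ``(site_id, model_id, period_label) -> DischargeSeries``.
        Series under model id "observed" (baseline period) drive the
        skill-based ensemble weights; without them weights are uniform.
    sites, curves, occurrences, traits
        Study tables; ``traits`` (long-form affinities) is optional.
    periods
        Period definitions by label; defaults to the three study periods.
    config
        A :class:`CascadeConfig`; defaults throughout.
    """

    def __init__(
        self,
        discharge: dict[tuple[str, str, str], DischargeSeries],
        sites: list[Site],
        curves: dict[str, PreferenceCurve],
        occurrences: pd.DataFrame,
        traits: pd.DataFrame | None = None,
        periods: dict[str, Period] | None = None,
        config: CascadeConfig | None = None,
    ) -> None:
        self.discharge = discharge
        self.sites = sites
        self.curves = curves
        self.occurrences = occurrences
        self.traits = traits
        self.periods = dict(periods) if periods is not None else dict(STUDY_PERIODS)
        self.config = config or CascadeConfig()
        if self.config.baseline_label not in self.periods:
            raise ValueError(f"no {self.config.baseline_label!r} period defined")
        self._scenario_meta: dict = {}

    @classmethod
    def from_scenario(cls, data, config: CascadeConfig | None = None) -> "FlowAbundanceCascade":
        """Build from a generated :class:`~flowcascade.synthetic.ScenarioData`."""
        model = cls(
            discharge=data.discharge,
            sites=data.sites,
            curves=data.curves,
            occurrences=data.occurrences,
            traits=data.trait_table,
            periods=data.config.periods,
            config=config,
        )
        model._scenario_meta = {
            "archetype": data.config.archetype,
            "seed": data.config.seed,
            "n_models": data.config.n_models,
        }
        return model

    @classmethod
    def from_csv(
        cls,
        discharge_csv,
        sites_csv,
        curves_csv,
        occurrences_csv,
        traits_csv=None,
        periods: dict[str, Period] | None = None,
        config: CascadeConfig | None = None,
    ) -> "FlowAbundanceCascade":
        from . import io

        return cls(
            discharge=io.read_discharge_csv(discharge_csv),
            sites=io.read_sites_csv(sites_csv),
            curves=io.read_curves_csv(curves_csv),
            occurrences=io.read_occurrences_csv(occurrences_csv),
            traits=io.read_traits_csv(traits_csv) if traits_csv else None,
            periods=periods,
            config=config,
        )

    # -- fitting ---------------------------------------------------------

    @property
    def model_ids(self) -> list[str]:
        return sorted({m for (_, m, _) in self.discharge if m != OBSERVED_MODEL_ID})

    def _metric_table(self, kept_sites: list[Site]) -> pd.DataFrame:
        kept_ids = {s.site_id for s in kept_sites}
        frames = []
        for (site_id, model_id, label), series in sorted(self.discharge.items()):
            if site_id not in kept_ids or model_id == OBSERVED_MODEL_ID:
                continue
            frames.append(
                dh4_annual(series, period=self.periods[label], anchor=self.config.anchor)
            )
        if not frames:
            raise ValueError("no discharge series at the retained sites")
        return pd.concat(frames, ignore_index=True)

    def fit(self) -> "CascadeResults":
        kept_sites = filter_sites_by_status(self.sites)
        if not kept_sites:
            raise ValueError("all sites excluded by ecological status")
        n_dropped_sites = len(self.sites) - len(kept_sites)
        kept_ids = {s.site_id for s in kept_sites}

        metric_values = self._metric_table(kept_sites)
        mask = {
            (sp, sid) for sp, sid in occupancy_mask(self.occurrences) if sid in kept_ids
        }
        if not mask:
            raise ValueError("no occupied species-site pairs at the retained sites")

        n_years = {p.n_years for p in self.periods.values()}
        expected_years = n_years.pop() if len(n_years) == 1 else None
        tables = run_cascade(
            self.curves,
            metric_values,
            mask,
            expected_years=expected_years,
            baseline_label=self.config.baseline_label,
            sr_mode=self.config.sr_mode,
        )

        weights, uniform = skill_weights(
            self.discharge,
            kept_sites,
            self.periods,
            baseline_label=self.config.baseline_label,
            anchor=self.config.anchor,
            ladder_mode=self.config.ladder_mode,
        )
        weight_map = dict(zip(weights["model_id"], weights["weight"]))

        flow_per_model, flow_summaries = flow_change_summary(
            metric_values, weight_map, self.config.baseline_label
        )

        species_summaries: list[EnsembleSummary] = []
        for (species, horizon), grp in tables.sr.groupby(["species_id", "horizon"], sort=False):
            values = dict(zip(grp["model_id"], grp["sr_pct"]))
            sub_weights = {m: weight_map[m] for m in values}
            species_summaries.append(
                summarize_ensemble(values, sub_weights, target=species, horizon=horizon)
            )
        species_summary = pd.DataFrame([s.to_row() for s in species_summaries]).rename(
            columns={"target_id": "species_id"}
        )

        clip_counter: dict = {}
        flags = flag_species_responses(
            tables.sr,
            alpha_zero=self.config.alpha_zero,
            alpha_grand=self.config.alpha_grand,
            arcsine=self.config.arcsine_before_tests,
            clip_counter=clip_counter,
        )

        assignments = coverage = group_per_model = group_summary = None
        if self.traits is not None and not self.traits.empty:
            species_ids = sorted({sp for sp, _ in mask})
            assignments = assign_all(self.traits, species_ids)
            coverage = coverage_check(self.traits, species_ids)
            memberships = assignments.rename(
                columns={"trait": "group_type", "category": "group"}
            )[["group_type", "group", "species_id"]]
            if "taxonomic_order" in self.occurrences.columns:
                orders = (
                    self.occurrences[["species_id", "taxonomic_order"]]
                    .drop_duplicates()
                    .rename(columns={"taxonomic_order": "group"})
                )
                orders["group_type"] = "taxonomic_order"
                memberships = pd.concat(
                    [memberships, orders[["group_type", "group", "species_id"]]],
                    ignore_index=True,
                )
            group_per_model, group_summary = aggregate_group_sr(
                memberships, tables.sr, weight_map
            )

        dropped = dict(tables.dropped)
        dropped["sites_poor_bad"] = n_dropped_sites
        dropped["clipped_percent"] = clip_counter.get("clipped", 0)

        return CascadeResults(
            model=self,
            config=self.config,
            periods=self.periods,
            sites_kept=kept_sites,
            metric_values=metric_values,
            tables=tables,
            weights=weights,
            uniform_weights=uniform,
            flow_per_model=flow_per_model,
            flow_summary=pd.DataFrame([s.to_row() for s in flow_summaries]),
            species_summary=species_summary,
            flags=flags,
            assignments=assignments,
            coverage=coverage,
            group_per_model=group_per_model,
            group_summary=group_summary,
            dropped=dropped,
        )


@dataclass
class CascadeResults:
    """Fitted cascade: every intermediate and final table, plus diagnostics."""

    model: FlowAbundanceCascade
    config: CascadeConfig
    periods: dict[str, Period]
    sites_kept: list[Site]
    metric_values: pd.DataFrame
    tables: CascadeTables
    weights: pd.DataFrame
    uniform_weights: bool
    flow_per_model: pd.DataFrame
    flow_summary: pd.DataFrame
    species_summary: pd.DataFrame
    flags: pd.DataFrame
    assignments: pd.DataFrame | None
    coverage: pd.DataFrame | None
    group_per_model: pd.DataFrame | None
    group_summary: pd.DataFrame | None
    dropped: dict = field(default_factory=dict)

    @property
    def sr(self) -> pd.DataFrame:
        return self.tables.sr

    @property
    def mav(self) -> pd.DataFrame:
        return self.tables.mav

    @property
    def deltas(self) -> pd.DataFrame:
        return self.tables.deltas

    def weighted_sr(self, species_id: str, horizon: str) -> float:
        """Skill-weighted ensemble mean SR for one species and horizon."""
        grp = self.sr[(self.sr["species_id"] == species_id) & (self.sr["horizon"] == horizon)]
        if grp.empty:
            raise KeyError(f"no SRs for {species_id} at {horizon}")
        values = dict(zip(grp["model_id"], grp["sr_pct"]))
        wmap = dict(zip(self.weights["model_id"], self.weights["weight"]))
        return weighted_mean(values, {m: wmap[m] for m in values})

    def summary(self) -> str:
        """Human-readable account of the fitted cascade."""
        n_models = len(self.weights)
        n_species = self.sr["species_id"].nunique()
        lines = [
            "Flow-abundance uncertainty cascade",
            "=" * 50,
            f"climate models:       {n_models}"
            + (" (uniform weights)" if self.uniform_weights else " (skill-weighted)"),
            f"sites retained:       {len(self.sites_kept)}"
            f" (excluded poor/bad: {self.dropped.get('sites_poor_bad', 0)})",
            f"species with SRs:     {n_species}",
            f"periods:              "
            + ", ".join(f"{p.label} {p.start_year}-{p.end_year}" for p in self.periods.values()),
            "",
            "Relative dh4 change across sites (% vs baseline):",
        ]
        for row in self.flow_summary.itertuples():
            lines.append(
                f"  {row.horizon}: mean {row.mean:+.1f}%  weighted {row.weighted_mean:+.1f}%"
                f"  sd {row.sd:.1f}"
            )
        lines.append("")
        lines.append("Species responses (SR, % change in abundance):")
        for horizon, grp in self.species_summary.groupby("horizon", sort=False):
            flags_h = self.flags[self.flags["horizon"] == horizon]
            n_zero = int(flags_h[flags_h["test"] == "vs_zero"]["flagged"].sum())
            n_grand = int(flags_h[flags_h["test"] == "vs_grand_mean"]["flagged"].sum())
            lines.append(
                f"  {horizon}: mean of species means {grp['mean'].mean():+.1f}%, "
                f"across-model sd (median species) {grp['sd'].median():.1f}; "
                f"{n_zero}/{len(grp)} species differ from zero (p<{self.config.alpha_zero}), "
                f"{n_grand}/{len(grp)} exceed the grand |SR| mean (p<{self.config.alpha_grand})"
            )
        if self.dropped:
            lines.append("")
            lines.append(
                "dropped/clamped: "
                + ", ".join(f"{k}={v}" for k, v in sorted(self.dropped.items()))
            )
        return "\n".join(lines)

    def manifest(self) -> dict:
        counts = {
            "metric_values": len(self.metric_values),
            "predictions": len(self.tables.predictions),
            "mav": len(self.mav),
            "deltas": len(self.deltas),
            "sr": len(self.sr),
            "weights": len(self.weights),
            "species_summary": len(self.species_summary),
            "flags": len(self.flags),
        }
        if self.group_summary is not None:
            counts["group_summary"] = len(self.group_summary)
        from . import __version__

        return {
            "package_version": __version__,
            "config": dataclasses.asdict(self.config),
            "periods": {
                label: [p.start_year, p.end_year] for label, p in self.periods.items()
            },
            "scenario": self.model._scenario_meta or None,
            "row_counts": counts,
            "dropped": self.dropped,
        }

    def to_csv(self, out_dir) -> dict[str, Path]:
        """Write every result table (and a YAML manifest) under ``out_dir``."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        tables = {
            "metrics": self.metric_values,
            "mav": self.mav,
            "deltas": self.deltas,
            "sr": self.sr,
            "weights": self.weights,
            "flow_per_model": self.flow_per_model,
            "flow_summary": self.flow_summary,
            "species_summary": self.species_summary,
            "flags": self.flags,
        }
        for name, tab in (
            ("assignments", self.assignments),
            ("coverage", self.coverage),
            ("group_per_model", self.group_per_model),
            ("group_summary", self.group_summary),
        ):
            if tab is not None:
                tables[name] = tab
        paths = {}
        for name, tab in tables.items():
            paths[name] = out_dir / f"{name}.csv"
            tab.to_csv(paths[name], index=False)
        paths["manifest"] = out_dir / "manifest.yaml"
        with open(paths["manifest"], "w") as fh:
            yaml.safe_dump(self.manifest(), fh, sort_keys=False)
        return paths
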