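"""CSV readers and writers for the pipeline's external interfaces.

Dialects:

* discharge: ``site_id, model_id, period, date, flow_m3s`` — one row per day
* sites: ``site_id, catchment_id, outlet_id, flow_accumulation, ecological_status``
* curves: ``species_id, form, optimum, breadth, peak_abundance, dh4_min, dh4_max``
* occurrences: ``species_id, site_id, abundance, sampling_date, taxonomic_order``
* traits (long form): ``species_id, trait, category, affinity``
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

from .abundance import PreferenceCurve
from .hydro import DischargeSeries, Site


def write_discharge_csv(discharge: dict[tuple, DischargeSeries], path) -> None:
    frames = [discharge[key].to_frame() for key in sorted(discharge)]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_discharge_csv(path) -> dict[tuple[str, str, str], DischargeSeries]:
    table = pd.read_csv(path, parse_dates=["date"])
    out = {}
    for (site_id, model_id, period), grp in table.groupby(
        ["site_id", "model_id", "period"], sort=False
    ):
        grp = grp.sort_values("date")
        dates = grp["date"].dt.normalize()
        if not (dates.diff().dropna() == pd.Timedelta(days=1)).all():
            raise ValueError(f"discharge {site_id}/{model_id}/{period}: missing or duplicate days")
        out[(site_id, model_id, period)] = DischargeSeries(
            site_id=site_id, model_id=model_id, period_label=period,
            start=dates.iloc[0].date(), flow=grp["flow_m3s"].to_numpy(),
        )
    return out


def write_sites_csv(sites: list[Site], path) -> None:
    pd.DataFrame(
        [
            (s.site_id, s.catchment_id, s.outlet_id, s.flow_accumulation, s.ecological_status)
            for s in sites
        ],
        columns=["site_id", "catchment_id", "outlet_id", "flow_accumulation", "ecological_status"],
    ).to_csv(path, index=False)


def read_sites_csv(path) -> list[Site]:
    table = pd.read_csv(path)
    return [
        Site(
            site_id=str(r.site_id), catchment_id=str(r.catchment_id),
            outlet_id=str(r.outlet_id), flow_accumulation=float(r.flow_accumulation),
            ecological_status=str(r.ecological_status),
        )
        for r in table.itertuples()
    ]


def write_curves_csv(curves: dict[str, PreferenceCurve], path) -> None:
    pd.DataFrame(
        [
            (c.species_id, c.form, c.optimum, c.breadth, c.peak_abundance, c.dh4_min, c.dh4_max)
            for c in curves.values()
        ],
        columns=["species_id", "form", "optimum", "breadth", "peak_abundance", "dh4_min", "dh4_max"],
    ).to_csv(path, index=False)


def read_curves_csv(path) -> dict[str, PreferenceCurve]:
    table = pd.read_csv(path)
    return {
        str(r.species_id): PreferenceCurve(
            species_id=str(r.species_id), form=str(r.form), optimum=float(r.optimum),
            breadth=float(r.breadth), peak_abundance=float(r.peak_abundance),
            dh4_min=float(r.dh4_min), dh4_max=float(r.dh4_max),
        )
        for r in table.itertuples()
    }


def read_occurrences_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def read_traits_csv(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_scenario_csvs(data, out_dir) -> dict[str, Path]:
    """Write one generated scenario as the full set of input CSVs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "discharge": out_dir / "discharge.csv",
        "sites": out_dir / "sites.csv",
        "curves": out_dir / "curves.csv",
        "occurrences": out_dir / "occurrences.csv",
        "traits": out_dir / "traits.csv",
    }
    write_discharge_csv(data.discharge, paths["discharge"])
    write_sites_csv(data.sites, paths["sites"])
    write_curves_csv(data.curves, paths["curves"])
    data.occurrences.to_csv(paths["occurrences"], index=False)
    data.trait_table.to_csv(paths["traits"], index=False)
    return paths
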