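"""The abundance-change cascade: MAV, delta-MAV, percent change, and species responses.

For each species x site x climate model, the 20 annual abundance predictions
of a period are averaged into the mean abundance value (MAV).  The change
from the baseline to a horizon is expressed per site as a percent change of
the baseline MAV, and the species response (SR) for one climate model and
horizon is the unweighted mean percent change across the species' occupied
sites.  Repeating this for all N climate models yields N SR values per
species and horizon — the raw material of the ensemble summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .abundance import PreferenceCurve, predict_all

logger = logging.getLogger(__name__)

BASELINE = "baseline"
HORIZONS = ("h2050", "h2090")

SR_MODES = ("mean_pct", "pooled_pct")


def compute_mav(predictions: pd.DataFrame, expected_years: int | None = 20) -> pd.DataFrame:
    """Mean abundance value per species x site x model x period.

    Each group must contribute exactly ``expected_years`` annual values (the
    20 years of a study period); pass ``None`` to skip the check for ad-hoc
    periods.
    """
    grouped = predictions.groupby(
        ["species_id", "site_id", "model_id", "period"], sort=False, as_index=False
    ).agg(mav=("av", "mean"), n_years=("av", "size"))
    if expected_years is not None:
        bad = grouped[grouped["n_years"] != expected_years]
        if not bad.empty:
            detail = bad[["species_id", "site_id", "model_id", "period", "n_years"]].head(5)
            raise ValueError(
                f"compute_mav: expected {expected_years} annual values per group; "
                f"offending groups (first 5):\n{detail.to_string(index=False)}"
            )
    return grouped.drop(columns="n_years")


def compute_delta(mav: pd.DataFrame, baseline_label: str = BASELINE) -> pd.DataFrame:
    """Per-site change in MAV between each horizon and the baseline.

    Returns columns species_id, site_id, model_id, horizon, mav_baseline,
    mav_horizon, delta, pct_change, undefined_pct.  Sites whose baseline MAV
    is exactly 0 get ``undefined_pct=True`` (pct_change is NaN); they are
    counted and excluded when averaging into species responses.
    """
    base = mav[mav["period"] == baseline_label].rename(columns={"mav": "mav_baseline"})
    hor = mav[mav["period"] != baseline_label].rename(
        columns={"mav": "mav_horizon", "period": "horizon"}
    )
    merged = hor.merge(
        base.drop(columns="period"), on=["species_id", "site_id", "model_id"], how="left"
    )
    if merged["mav_baseline"].isna().any():
        missing = merged[merged["mav_baseline"].isna()].head(5)
        raise ValueError(
            f"compute_delta: horizon groups without baseline MAV (first 5):\n"
            f"{missing[['species_id', 'site_id', 'model_id', 'horizon']].to_string(index=False)}"
        )
    merged["delta"] = merged["mav_horizon"] - merged["mav_baseline"]
    merged["undefined_pct"] = merged["mav_baseline"] == 0
    merged["pct_change"] = 100.0 * merged["delta"] / merged["mav_baseline"].where(
        ~merged["undefined_pct"]
    )
    n_undef = int(merged["undefined_pct"].sum())
    if n_undef:
        logger.warning("compute_delta: %d zero-baseline records flagged undefined-percent", n_undef)
    return merged[
        ["species_id", "site_id", "model_id", "horizon",
         "mav_baseline", "mav_horizon", "delta", "pct_change", "undefined_pct"]
    ]


def compute_sr(deltas: pd.DataFrame, mode: str = "mean_pct") -> pd.DataFrame:
    """Species response per species x model x horizon.

    ``mode="mean_pct"`` (default): percent change is computed per site and
    then averaged across the species' occupied sites.  ``mode="pooled_pct"``:
    the site deltas are averaged first and expressed relative to the averaged
    baseline MAV (the alternative reading of the averaging order).
    Zero-baseline sites are excluded; species-model-horizon groups with no
    usable site are dropped with a warning.
    """
    if mode not in SR_MODES:
        raise ValueError(f"unknown SR mode {mode!r}; expected one of {SR_MODES}")
    usable = deltas[~deltas["undefined_pct"]]
    n_dropped_groups = (
        deltas.groupby(["species_id", "model_id", "horizon"], sort=False)["undefined_pct"]
        .all()
        .sum()
    )
    if n_dropped_groups:
        logger.warning(
            "compute_sr: %d species-model-horizon groups had no usable site and were dropped",
            int(n_dropped_groups),
        )
    keys = ["species_id", "model_id", "horizon"]
    if mode == "mean_pct":
        sr = usable.groupby(keys, sort=False, as_index=False).agg(
            sr_pct=("pct_change", "mean"), n_sites=("pct_change", "size")
        )
    else:
        agg = usable.groupby(keys, sort=False, as_index=False).agg(
            delta=("delta", "mean"), mav_baseline=("mav_baseline", "mean"),
            n_sites=("delta", "size"),
        )
        agg["sr_pct"] = 100.0 * agg["delta"] / agg["mav_baseline"]
        sr = agg[keys + ["sr_pct", "n_sites"]]
    return sr.reset_index(drop=True)


@dataclass
class CascadeTables:
    """Intermediate and final tables of one cascade run, plus drop tallies."""

    predictions: pd.DataFrame
    mav: pd.DataFrame
    deltas: pd.DataFrame
    sr: pd.DataFrame
    dropped: dict = field(default_factory=dict)


def run_cascade(
    curves: dict[str, PreferenceCurve],
    metric_values: pd.DataFrame,
    mask: set[tuple[str, str]],
    expected_years: int | None = 20,
    baseline_label: str = BASELINE,
    sr_mode: str = "mean_pct",
) -> CascadeTables:
    """Full cascade from annual dh4 values to the SR table.

    With N climate models and both horizons present, the SR table holds
    exactly N rows per species per horizon (minus logged zero-baseline drops).
    """
    clamp_counter: dict = {}
    predictions = predict_all(curves, metric_values, mask, clamp_counter)
    mav = compute_mav(predictions, expected_years)
    deltas = compute_delta(mav, baseline_label)
    sr = compute_sr(deltas, sr_mode)
    dropped = {
        "clamped_dh4": clamp_counter.get("clamped", 0),
        "zero_baseline_records": int(deltas["undefined_pct"].sum()),
    }
    return CascadeTables(predictions=predictions, mav=mav, deltas=deltas, sr=sr, dropped=dropped)
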