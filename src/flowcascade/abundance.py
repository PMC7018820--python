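"""Species flow-preference curves and annual abundance prediction.

Each species carries a unimodal response curve mapping dh4 to expected
abundance.  The curves stand in for externally fitted predictive
relationships and are consumed as parameters; a registry keyed by ``form``
allows other unimodal shapes to be added.  dh4 values outside the fitted
range of a curve are clamped to the nearest range edge before evaluation
(out-of-range extrapolation is deliberately avoided), and clamp events are
counted.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

PREDICTION_COLUMNS = ["species_id", "site_id", "model_id", "period", "year", "av"]


def _gaussian(curve: "PreferenceCurve", x: np.ndarray) -> np.ndarray:
    return curve.peak_abundance * np.exp(-((x - curve.optimum) ** 2) / (2 * curve.breadth**2))


#: registry of curve forms: name -> f(curve, clamped dh4 array) -> abundance array
CURVE_FORMS = {"gaussian": _gaussian}


@dataclass(frozen=True)
class PreferenceCurve:
    """Parametric abundance response of one species to dh4.

    ``optimum`` is the dh4 at peak abundance, ``breadth`` the niche width
    (standard-deviation-like; small = specialist, large = generalist), both in
    m3 s-1.  ``valid_range = (dh4_min, dh4_max)`` is the dh4 interval over
    which the curve was fitted.
    """

    species_id: str
    optimum: float
    breadth: float
    peak_abundance: float
    dh4_min: float
    dh4_max: float
    form: str = "gaussian"

    def __post_init__(self) -> None:
        if self.form not in CURVE_FORMS:
            raise ValueError(f"unknown curve form {self.form!r}")
        if not self.breadth > 0:
            raise ValueError(f"{self.species_id}: breadth must be > 0")
        if not self.peak_abundance > 0:
            raise ValueError(f"{self.species_id}: peak_abundance must be > 0")
        if not self.dh4_min < self.dh4_max:
            raise ValueError(f"{self.species_id}: dh4_min must be < dh4_max")


def predict_abundance(curve: PreferenceCurve, dh4_value, clamp_counter: dict | None = None):
    """Predicted abundance at one or more dh4 values (scalar in, scalar out).

    Values outside ``[dh4_min, dh4_max]`` are clamped to the nearest edge
    before evaluating the curve; if ``clamp_counter`` is given, its
    ``"clamped"`` entry is incremented by the number of clamp events.
    """
    x = np.asarray(dh4_value, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError(f"{curve.species_id}: non-finite dh4 input")
    clamped = np.clip(x, curve.dh4_min, curve.dh4_max)
    n_clamped = int(np.sum(clamped != x))
    if clamp_counter is not None and n_clamped:
        clamp_counter["clamped"] = clamp_counter.get("clamped", 0) + n_clamped
    out = CURVE_FORMS[curve.form](curve, clamped)
    return float(out) if np.isscalar(dh4_value) or np.ndim(dh4_value) == 0 else out


def occupancy_mask(occurrences: pd.DataFrame) -> set[tuple[str, str]]:
    """The (species_id, site_id) pairs with observed abundance > 0.

    Predictions are restricted to these within-range pairs: a species is only
    projected at the sampling sites where it was actually recorded.
    """
    required = {"species_id", "site_id", "abundance"}
    if not required.issubset(occurrences.columns):
        raise ValueError(f"occurrence table needs columns {sorted(required)}")
    occ = occurrences[occurrences["abundance"] > 0]
    return set(zip(occ["species_id"], occ["site_id"]))


def predict_all(
    curves: dict[str, PreferenceCurve],
    metric_values: pd.DataFrame,
    mask: set[tuple[str, str]],
    clamp_counter: dict | None = None,
) -> pd.DataFrame:
    """One predicted abundance (AV) per masked species-site per model-period-year.

    ``metric_values`` is the annual dh4 table (columns site_id, model_id,
    period, year, metric, value).  Output cardinality is
    ``|mask| x models x periods x years-per-period``.
    """
    missing = sorted({sp for sp, _ in mask} - set(curves))
    if missing:
        raise ValueError(f"no preference curve for species: {missing}")
    dh4_tab = metric_values[metric_values["metric"] == "dh4"]
    frames = []
    by_site = dict(tuple(dh4_tab.groupby("site_id", sort=False)))
    for species_id, site_id in sorted(mask):
        site_vals = by_site.get(site_id)
        if site_vals is None or site_vals.empty:
            raise ValueError(f"no dh4 values for occupied site {site_id}")
        curve = curves[species_id]
        av = predict_abundance(curve, site_vals["value"].to_numpy(), clamp_counter)
        frames.append(
            pd.DataFrame(
                {
                    "species_id": species_id,
                    "site_id": site_id,
                    "model_id": site_vals["model_id"].to_numpy(),
                    "period": site_vals["period"].to_numpy(),
                    "year": site_vals["year"].to_numpy(),
                    "av": av,
                }
            )
        )
    if not frames:
        return pd.DataFrame(columns=PREDICTION_COLUMNS)
    return pd.concat(frames, ignore_index=True)[PREDICTION_COLUMNS]
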