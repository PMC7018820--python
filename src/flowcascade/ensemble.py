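"""Skill-based weighting of climate models and weighted ensemble summaries.

Models are ranked by the Euclidean distance between their hindcast IHA
vector and the observation-forced baseline IHA vector; the N models then
receive the N equally spaced weights spanning [1, 2] (spacing 1/(N-1)), the
best-fitting model getting weight 2 and the worst weight 1.  For N = 16 the
spacing is 1/15 ~ 0.0667.  Ties receive the mean of the ladder weights their
ranks would span.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

#: ladder spacing modes: "endpoint" = 1/(N-1) spanning [1,2] inclusive;
#: "step" = 1/N starting at 1 (maximum weight 2 - 1/N).
LADDER_MODES = ("endpoint", "step")

WEIGHT_COLUMNS = ["model_id", "distance", "rank", "weight"]


def assign_weights(distances: dict[str, float], mode: str = "endpoint") -> pd.DataFrame:
    """Ladder weights in [1, 2] from per-model distances (smaller = better).

    Returns a DataFrame with columns model_id, distance, rank (1 = smallest
    distance) and weight; tied distances share the mean of the weights their
    ranks would span.
    """
    if mode not in LADDER_MODES:
        raise ValueError(f"unknown ladder mode {mode!r}; expected one of {LADDER_MODES}")
    if len(distances) < 2:
        raise ValueError("assign_weights needs >= 2 models")
    model_ids = list(distances)
    d = np.array([distances[m] for m in model_ids], dtype=float)
    if not np.all(np.isfinite(d)) or np.any(d < 0):
        bad = [m for m, v in zip(model_ids, d) if not np.isfinite(v) or v < 0]
        raise ValueError(f"assign_weights: negative or non-finite distance for {bad}")
    n = len(model_ids)
    avg_rank = rankdata(d, method="average")  # 1 = smallest distance
    spacing = 1.0 / (n - 1) if mode == "endpoint" else 1.0 / n
    weight = 1.0 + (n - avg_rank) * spacing
    out = pd.DataFrame(
        {
            "model_id": model_ids,
            "distance": d,
            "rank": rankdata(d, method="min").astype(int),
            "weight": weight,
        }
    )
    return out.sort_values("rank", kind="stable").reset_index(drop=True)


def _weight_map(weights) -> dict[str, float]:
    if isinstance(weights, pd.DataFrame):
        return dict(zip(weights["model_id"], weights["weight"]))
    return dict(weights)


def weighted_mean(values: dict[str, float], weights) -> float:
    """Weighted average sum(w_i x_i) / sum(w_i) over a shared model set."""
    wmap = _weight_map(weights)
    if set(values) != set(wmap):
        raise ValueError(
            f"weighted_mean: model sets differ "
            f"(values-only: {sorted(set(values) - set(wmap))}, "
            f"weights-only: {sorted(set(wmap) - set(values))})"
        )
    x = np.array([values[m] for m in values], dtype=float)
    w = np.array([wmap[m] for m in values], dtype=float)
    return float(np.sum(w * x) / np.sum(w))


@dataclass(frozen=True)
class EnsembleSummary:
    """Across-model summary of one target quantity at one horizon.

    ``cv`` (coefficient of variation, sd/|mean|) is None when the simple mean
    is zero.
    """

    target: str
    horizon: str
    n_models: int
    mean: float
    weighted_mean: float
    sd: float
    cv: float | None
    minimum: float
    q1: float
    median: float
    q3: float
    maximum: float
    values: dict[str, float] = field(repr=False, default_factory=dict)

    def to_row(self) -> dict:
        return {
            "target_id": self.target,
            "horizon": self.horizon,
            "n_models": self.n_models,
            "mean": self.mean,
            "weighted_mean": self.weighted_mean,
            "sd": self.sd,
            "cv": np.nan if self.cv is None else self.cv,
            "min": self.minimum,
            "q1": self.q1,
            "median": self.median,
            "q3": self.q3,
            "max": self.maximum,
        }


def summarize_ensemble(
    values: dict[str, float], weights, target: str = "", horizon: str = ""
) -> EnsembleSummary:
    """Simple and weighted means, spread and quartiles of per-model values."""
    x = np.array([values[m] for m in values], dtype=float)
    if x.size == 0:
        raise ValueError("summarize_ensemble: no values")
    mean = float(x.mean())
    sd = float(x.std(ddof=1)) if x.size > 1 else 0.0
    q1, med, q3 = (float(q) for q in np.percentile(x, [25, 50, 75]))
    return EnsembleSummary(
        target=target,
        horizon=horizon,
        n_models=x.size,
        mean=mean,
        weighted_mean=weighted_mean(values, weights),
        sd=sd,
        cv=None if mean == 0 else sd / abs(mean),
        minimum=float(x.min()),
        q1=q1,
        median=med,
        q3=q3,
        maximum=float(x.max()),
        values=dict(values),
    )
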