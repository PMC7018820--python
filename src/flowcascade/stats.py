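"""Significance machinery: arcsine transform, t-tests, one-way ANOVA, response flags.

Percent data are normalized with an arcsine(square-root) transformation
before testing.  The classic transform is defined on proportions in [0, 1];
percent changes here are signed, so the transform is extended as an odd
function, sign(p) * arcsin(sqrt(|p|/100)), with inputs clipped to
[-100, 100] (clip events counted).  Test statistics come from scipy;
degenerate inputs (zero spread) raise an explicit undefined-result signal
instead of propagating NaNs.

Flagging conventions for species responses: a two-sided one-sample t-test of
a species' across-model SRs against zero at alpha 0.01 ("vs zero"), and a
one-sided test of the species' |SR| sample against the grand absolute mean
over all species and models at alpha 0.05 ("vs grand mean").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .hydro import UndefinedStatisticError

logger = logging.getLogger(__name__)

ALPHA_VS_ZERO = 0.01
ALPHA_VS_GRAND_MEAN = 0.05


def arcsine_transform(pct, clip_counter: dict | None = None):
    """Signed arcsine-square-root transform of percent data, in radians.

    ``sign(p) * arcsin(sqrt(|p|/100))`` after clipping to [-100, 100]; with a
    ``clip_counter`` dict the number of clipped values is accumulated under
    the ``"clipped"`` key.  Scalar in, scalar out.
    """
    x = np.asarray(pct, dtype=float)
    if not np.all(np.isfinite(x)):
        raise ValueError("arcsine_transform: non-finite input")
    clipped = np.clip(x, -100.0, 100.0)
    n_clip = int(np.sum(clipped != x))
    if clip_counter is not None and n_clip:
        clip_counter["clipped"] = clip_counter.get("clipped", 0) + n_clip
    out = np.sign(clipped) * np.arcsin(np.sqrt(np.abs(clipped) / 100.0))
    return float(out) if np.ndim(pct) == 0 else out


def _check_sample(values, name: str = "values") -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError(f"{name}: need a 1-d sample of size >= 2")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name}: non-finite entries")
    return arr


def t_test_one_sample(values, mu0: float = 0.0, alternative: str = "two-sided") -> tuple[float, float]:
    """One-sample t-test of the sample mean against ``mu0``; returns (t, p).

    A zero-spread sample centred exactly on ``mu0`` gives (0, 1); a
    zero-spread sample off ``mu0`` raises :class:`UndefinedStatisticError`.
    """
    arr = _check_sample(values)
    if arr.std(ddof=1) == 0:
        if arr[0] == mu0:
            return 0.0, 1.0
        raise UndefinedStatisticError("one-sample t-test: zero sample variance off mu0")
    res = sps.ttest_1samp(arr, mu0, alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def t_test_paired(values_a, values_b) -> tuple[float, float]:
    """Paired t-test (one-sample test on the pairwise differences)."""
    a, b = _check_sample(values_a, "values_a"), _check_sample(values_b, "values_b")
    if a.size != b.size:
        raise ValueError("paired t-test: unequal lengths")
    return t_test_one_sample(a - b, 0.0)


def anova_one_way(groups: list) -> tuple[float, float]:
    """One-way ANOVA across >= 2 groups of size >= 2; returns (F, p)."""
    if len(groups) < 2:
        raise ValueError("one-way ANOVA needs >= 2 groups")
    arrays = [_check_sample(g, f"group {i}") for i, g in enumerate(groups)]
    if all(a.std(ddof=1) == 0 for a in arrays):
        raise UndefinedStatisticError("one-way ANOVA: zero within-group variance everywhere")
    res = sps.f_oneway(*arrays)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class SignificanceFlag:
    """Outcome of one significance test on one target."""

    target_id: str
    test: str
    statistic: float
    p_value: float
    alpha: float
    flagged: bool

    def to_row(self) -> dict:
        return {
            "target_id": self.target_id,
            "test": self.test,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "alpha": self.alpha,
            "flagged": self.flagged,
        }


def t_test_vs_grand_mean(
    sr_values, grand_abs_mean: float, alpha: float = ALPHA_VS_GRAND_MEAN, target_id: str = ""
) -> SignificanceFlag:
    """One-sided test: is the species' mean |SR| larger than the grand absolute mean?

    ``grand_abs_mean`` is the mean of |SR| over all species and climate models
    of the catchment-horizon; the species is flagged when its own |SR| sample
    exceeds it significantly (one-sided one-sample t-test).
    """
    abs_vals = np.abs(_check_sample(sr_values, "sr_values"))
    t, p = t_test_one_sample(abs_vals, grand_abs_mean, alternative="greater")
    return SignificanceFlag(
        target_id=target_id, test="vs_grand_mean", statistic=t, p_value=p,
        alpha=alpha, flagged=p < alpha,
    )


def flag_species_responses(
    sr: pd.DataFrame,
    alpha_zero: float = ALPHA_VS_ZERO,
    alpha_grand: float = ALPHA_VS_GRAND_MEAN,
    arcsine: bool = True,
    clip_counter: dict | None = None,
) -> pd.DataFrame:
    """Fig.-style significance flags for every species x horizon in an SR table.

    Two flags per species and horizon: "vs_zero" (two-sided, default alpha
    0.01) and "vs_grand_mean" (one-sided against the grand absolute mean over
    all species and models of the horizon, default alpha 0.05).  With
    ``arcsine=True`` (default) the percent SRs are arcsine-transformed before
    testing.  Degenerate samples are reported with NaN statistics and
    ``flagged=False``.
    """
    work = sr.copy()
    work["x"] = (
        arcsine_transform(work["sr_pct"].to_numpy(), clip_counter)
        if arcsine
        else work["sr_pct"].to_numpy()
    )
    rows = []
    for horizon, hgrp in work.groupby("horizon", sort=False):
        grand_abs_mean = float(np.abs(hgrp["x"]).mean())
        for species, sgrp in hgrp.groupby("species_id", sort=False):
            x = sgrp["x"].to_numpy()
            target = f"{species}:{horizon}"
            for test, runner, alpha in (
                ("vs_zero", lambda v: t_test_one_sample(v, 0.0), alpha_zero),
                (
                    "vs_grand_mean",
                    lambda v: t_test_one_sample(np.abs(v), grand_abs_mean, "greater"),
                    alpha_grand,
                ),
            ):
                try:
                    t, p = runner(x)
                    flagged = p < alpha
                except UndefinedStatisticError:
                    logger.warning("flags: %s %s degenerate sample; not flagged", target, test)
                    t, p, flagged = np.nan, np.nan, False
                rows.append(
                    SignificanceFlag(target, test, t, p, alpha, flagged).to_row()
                    | {"species_id": species, "horizon": horizon}
                )
    cols = ["species_id", "horizon", "test", "statistic", "p_value", "alpha", "flagged", "target_id"]
    return pd.DataFrame(rows)[cols]
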