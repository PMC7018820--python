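"""Functional-trait and taxonomic grouping of species, and group-level responses.

Trait affinities follow the 0-10 scale of the freshwaterecology.info
database: 10 is a very strong affinity of a species for a trait category, 0
none.  A species is assigned to a single category when exactly one category
reaches affinity >= 7; for feeding type, two categories with >= 5 points
each yield a dual category (e.g. grazer-shredder) when no single category
reaches 7; otherwise the species is treated as a generalist.  "Indifferent"
is a genuine database category (current preference / stream zonation) and is
kept distinct from the inferred "generalist".
"""

from __future__ import annotations

import logging
from itertools import combinations

import pandas as pd

from .ensemble import summarize_ensemble

logger = logging.getLogger(__name__)

CURRENT_PREFERENCE = "current_preference"
STREAM_ZONATION = "stream_zonation"
FEEDING_TYPE = "feeding_type"
TRAITS = (CURRENT_PREFERENCE, STREAM_ZONATION, FEEDING_TYPE)

TRAIT_CATEGORIES: dict[str, tuple[str, ...]] = {
    CURRENT_PREFERENCE: (
        "limnobiont", "limnophil", "limno_to_rheophil", "rheo_to_limnophil",
        "rheophil", "rheobiont", "indifferent",
    ),
    STREAM_ZONATION: ("upstream", "mid_to_upstream", "mid_to_downstream", "indifferent"),
    FEEDING_TYPE: (
        "predator", "grazer", "shredder", "gatherer",
        "active_filter_feeder", "passive_filter_feeder",
    ),
}

#: canonical labels of the database's dual feeding categories
DUAL_FEEDING_LABELS = {
    frozenset({"grazer", "shredder"}): "grazer-shredder",
    frozenset({"grazer", "gatherer"}): "grazer-gatherer",
    frozenset({"gatherer", "shredder"}): "gatherer-shredder",
}

STRONG_AFFINITY = 7
DUAL_AFFINITY = 5

TRAIT_TABLE_COLUMNS = ["species_id", "trait", "category", "affinity"]


def _validate_affinities(affinities: dict[str, float], trait: str) -> None:
    for cat, aff in affinities.items():
        if cat not in TRAIT_CATEGORIES[trait]:
            raise ValueError(f"unknown {trait} category {cat!r}")
        if not 0 <= aff <= 10:
            raise ValueError(f"affinity for {cat} out of [0, 10]: {aff}")


def assign_trait_group(affinities: dict[str, float], trait: str) -> str:
    """Category assignment for one species and one trait.

    Rules, in order of precedence: exactly one category with affinity >= 7
    wins; several categories >= 7 means the affinities are spread, hence
    "generalist"; for feeding type, exactly one pair of categories with >= 5
    each yields the dual category; everything else is "generalist".  Missing
    data yields "unknown".
    """
    if trait not in TRAITS:
        raise ValueError(f"unknown trait {trait!r}; expected one of {TRAITS}")
    if not affinities:
        return "unknown"
    _validate_affinities(affinities, trait)
    strong = [c for c, a in affinities.items() if a >= STRONG_AFFINITY]
    if len(strong) == 1:
        return strong[0]
    if len(strong) > 1:
        logger.info("trait %s: multiple categories >= %d -> generalist", trait, STRONG_AFFINITY)
        return "generalist"
    if trait == FEEDING_TYPE:
        dual = [
            frozenset(pair)
            for pair in combinations(affinities, 2)
            if affinities[pair[0]] >= DUAL_AFFINITY and affinities[pair[1]] >= DUAL_AFFINITY
        ]
        if len(dual) == 1:
            pair = dual[0]
            return DUAL_FEEDING_LABELS.get(pair, "-".join(sorted(pair)))
    return "generalist"


def assign_all(trait_table: pd.DataFrame, species_ids: list[str]) -> pd.DataFrame:
    """One assignment per species per trait (long form: species_id, trait, category)."""
    by_species = {
        key: grp for key, grp in trait_table.groupby(["species_id", "trait"], sort=False)
    }
    rows = []
    for sp in species_ids:
        for trait in TRAITS:
            grp = by_species.get((sp, trait))
            affinities = {} if grp is None else dict(zip(grp["category"], grp["affinity"]))
            rows.append((sp, trait, assign_trait_group(affinities, trait)))
    return pd.DataFrame(rows, columns=["species_id", "trait", "category"])


def coverage_check(trait_table: pd.DataFrame, species_ids: list[str]) -> pd.DataFrame:
    """Per-trait fraction of species with known affinities; warns below 0.8."""
    if not species_ids:
        raise ValueError("coverage_check: empty species set")
    known = trait_table.groupby("trait")["species_id"].apply(set)
    rows = []
    for trait in TRAITS:
        frac = len(known.get(trait, set()) & set(species_ids)) / len(species_ids)
        if frac < 0.8:
            logger.warning("trait %s: coverage %.0f%% below the 80%% threshold", trait, 100 * frac)
        rows.append((trait, frac, frac < 0.8))
    return pd.DataFrame(rows, columns=["trait", "coverage", "below_threshold"])


def aggregate_group_sr(
    memberships: pd.DataFrame, sr: pd.DataFrame, weights
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group-level responses: per-model mean SR over member species, then ensemble summary.

    ``memberships`` has columns group_type (a trait name or "taxonomic_order"),
    group (the category / order label) and species_id.  Returns the per-model
    group means (group_type, group, horizon, model_id, sr_pct, n_species) and
    the across-model summaries (mean, weighted mean, sd, cv, quartiles per
    group x horizon).  Groups with no member species holding SRs are omitted
    with a log entry.
    """
    merged = memberships.merge(sr, on="species_id", how="left")
    missing = merged["sr_pct"].isna()
    if missing.any():
        merged = merged[~missing]
    per_model = merged.groupby(
        ["group_type", "group", "horizon", "model_id"], sort=False, as_index=False
    ).agg(sr_pct=("sr_pct", "mean"), n_species=("species_id", "nunique"))
    empty = set(zip(memberships["group_type"], memberships["group"])) - set(
        zip(per_model["group_type"], per_model["group"])
    )
    for gt, g in sorted(empty):
        logger.info("group %s/%s has no species with SRs; omitted", gt, g)
    rows = []
    for (gt, g, h), grp in per_model.groupby(["group_type", "group", "horizon"], sort=False):
        values = dict(zip(grp["model_id"], grp["sr_pct"]))
        summ = summarize_ensemble(values, weights, target=f"{gt}:{g}", horizon=h)
        row = summ.to_row()
        row.update(group_type=gt, group=g, n_species=int(grp["n_species"].iloc[0]))
        rows.append(row)
    summary = pd.DataFrame(rows)
    if not summary.empty:
        lead = ["group_type", "group", "horizon", "n_species"]
        summary = summary[lead + [c for c in summary.columns if c not in lead + ["target_id"]]]
    return per_model, summary
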