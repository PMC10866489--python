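"""Loading, vetting and partitioning fossil occurrence tables.

Occurrence rows follow the Paleobiology-Database style: one row per species
occurrence with taxonomic rank, extant/extinct status, landmass, geologic
unit (formation), depositional environment, lagerstätte class, age interval
and specimen/locality counts.  Vetting retains species-level, extinct
records only and collapses duplicate species rows; every drop or merge is
written to a vetting log so the cleaning is auditable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

REQUIRED_COLUMNS = (
    "accepted_name",
    "accepted_rank",
    "is_extant",
    "taxon_group",
    "landmass",
    "formation",
    "environment",
    "lagerstatte_class",
    "max_ma",
    "min_ma",
    "n_specimens",
    "n_localities",
    "limbless",
)

TAXON_GROUPS = ("non_avian_theropod", "mesozoic_bird", "squamate")

#: Depositional-environment vocabulary (superset; user-editable).
ENVIRONMENTS = (
    "aeolian",
    "lacustrine",
    "fluvial",
    "marine",
    "lagoonal",
    "cave_karst",
    "coastal",
    "floodplain",
    "other",
)

LANDMASSES = (
    "Asia",
    "North America",
    "Europe",
    "Africa",
    "South America",
    "Australasia",
    "India",
    "Madagascar",
    "Antarctica",
    "Caribbean",
)

LAGERSTATTE_CLASSES = ("konservat", "konzentrat", "none")

#: Formation pairs the analyses treat as single units.
UNIT_ALIASES: dict[str, frozenset[str]] = {
    "jehol": frozenset({"Yixian", "Jiufotang"}),
    "gobi": frozenset({"Djadokhta", "Baruungoyot"}),
}

GROUPING_KEYS = {
    "landmass": "landmass",
    "environment": "environment",
    "unit": "formation",
    "lagerstatte_class": "lagerstatte_class",
    "taxon_group": "taxon_group",
}


class OccurrenceError(ValueError):
    pass


def _as_bool(value) -> bool:
    return str(value).strip().lower() in {"1", "true", "yes", "t"}


@dataclass
class OccurrenceDataset:
    """Vetted species table plus the log of vetting decisions."""

    table: pd.DataFrame
    vetting_log: list[dict] = field(default_factory=list)

    @property
    def n_species(self) -> int:
        return len(self.table)

    @property
    def species(self) -> list[str]:
        return list(self.table["accepted_name"])

    def to_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)

    def log_to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            self.vetting_log, columns=["rule", "accepted_name", "detail"]
        ).to_csv(path, index=False)


def load_and_vet(source: str | Path | pd.DataFrame) -> OccurrenceDataset:
    """Load an occurrence table and apply the vetting rules.

    Rules, in order: keep rank == "species"; keep extinct (is_extant false);
    collapse duplicate species rows, summing specimen and locality counts.
    Duplicates whose categorical labels disagree keep the first-seen label
    and the disagreement is flagged in the log.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    missing = set(REQUIRED_COLUMNS) - set(df.columns)
    if missing:
        raise OccurrenceError(f"missing required columns: {sorted(missing)}")

    log: list[dict] = []
    df["is_extant"] = df["is_extant"].map(_as_bool).astype(bool)
    df["limbless"] = df["limbless"].map(_as_bool).astype(bool)

    not_species = df["accepted_rank"].astype(str).str.lower() != "species"
    for name in df.loc[not_species, "accepted_name"]:
        log.append(
            {"rule": "drop_non_species", "accepted_name": name, "detail": ""}
        )
    df = df[~not_species]

    extant = df["is_extant"]
    for name in df.loc[extant, "accepted_name"]:
        log.append(
            {"rule": "drop_extant", "accepted_name": name, "detail": ""}
        )
    df = df[~extant]

    label_cols = [
        "taxon_group",
        "landmass",
        "formation",
        "environment",
        "lagerstatte_class",
        "limbless",
    ]
    rows = []
    for name, grp in df.groupby("accepted_name", sort=False):
        first = grp.iloc[0].copy()
        if len(grp) > 1:
            conflicts = [
                c for c in label_cols if grp[c].nunique(dropna=False) > 1
            ]
            log.append(
                {
                    "rule": "merge_duplicates",
                    "accepted_name": name,
                    "detail": (
                        f"{len(grp)} rows"
                        + (f"; label conflicts kept first-seen: {conflicts}"
                           if conflicts else "")
                    ),
                }
            )
            first["n_specimens"] = grp["n_specimens"].sum()
            first["n_localities"] = grp["n_localities"].sum()
            first["max_ma"] = grp["max_ma"].max()
            first["min_ma"] = grp["min_ma"].min()
        rows.append(first)

    vetted = (
        pd.DataFrame(rows, columns=df.columns).reset_index(drop=True)
        if rows
        else df.iloc[0:0].reset_index(drop=True)
    )
    if len(vetted) and (vetted["max_ma"] < vetted["min_ma"]).any():
        bad = vetted.loc[vetted["max_ma"] < vetted["min_ma"], "accepted_name"]
        raise OccurrenceError(f"max_ma < min_ma for: {list(bad)}")
    return OccurrenceDataset(table=vetted, vetting_log=log)


@dataclass
class GroupPartition:
    """Species ids grouped under one key (landmass, environment, ...)."""

    key: str
    groups: dict[str, list[str]]
    exclusion_log: list[dict] = field(default_factory=list)

    def sizes(self) -> dict[str, int]:
        return {label: len(members) for label, members in self.groups.items()}


def partition_by(dataset: OccurrenceDataset, key: str) -> GroupPartition:
    """Partition species by one of: landmass, environment, unit,
    lagerstatte_class, taxon_group."""
    if key not in GROUPING_KEYS:
        raise OccurrenceError(
            f"unknown grouping key {key!r}; expected one of {sorted(GROUPING_KEYS)}"
        )
    column = GROUPING_KEYS[key]
    groups: dict[str, list[str]] = {}
    for name, label in zip(
        dataset.table["accepted_name"], dataset.table[column]
    ):
        groups.setdefault(str(label), []).append(name)
    return GroupPartition(key=key, groups=groups)


def apply_min_sample(
    partition: GroupPartition, threshold: int
) -> GroupPartition:
    """Drop groups below a minimum sample size, logging each exclusion.

    The published analyses use ≥ 6 species per landmass and ≥ 17 species
    per depositional environment.
    """
    if threshold < 1:
        raise OccurrenceError("threshold must be ≥ 1")
    kept = {}
    log = list(partition.exclusion_log)
    for label, members in partition.groups.items():
        if len(members) >= threshold:
            kept[label] = members
        else:
            log.append(
                {
                    "rule": "min_sample",
                    "group": label,
                    "detail": f"n={len(members)} < {threshold}",
                }
            )
    return GroupPartition(key=partition.key, groups=kept, exclusion_log=log)


def subset_without_units(
    dataset: OccurrenceDataset, units: Iterable[str]
) -> OccurrenceDataset:
    """Dataset minus all species from the given geologic units.

    Unit names absent from the dataset are logged as warnings, not errors,
    so alias sets spanning several taxon groups can be applied uniformly.
    """
    units = set(units)
    if not units:
        raise OccurrenceError("units must be nonempty")
    log = list(dataset.vetting_log)
    present = set(dataset.table["formation"])
    for u in sorted(units - present):
        log.append(
            {
                "rule": "remove_unit_warning",
                "accepted_name": "",
                "detail": f"unit {u!r} not present in dataset",
            }
        )
    keep = ~dataset.table["formation"].isin(units)
    removed = dataset.table.loc[~keep, "accepted_name"]
    for name in removed:
        log.append(
            {"rule": "remove_unit", "accepted_name": name, "detail": ""}
        )
    return OccurrenceDataset(
        table=dataset.table[keep].reset_index(drop=True), vetting_log=log
    )


def resolve_units(alias_or_units: str | Sequence[str]) -> frozenset[str]:
    """Resolve a named alias ("jehol", "gobi") or explicit unit list."""
    if isinstance(alias_or_units, str):
        if alias_or_units.lower() in UNIT_ALIASES:
            return UNIT_ALIASES[alias_or_units.lower()]
        return frozenset({alias_or_units})
    return frozenset(alias_or_units)
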