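"""CCM2 scoring of fossil species from preserved skeletal elements.

CCM2 asks: of the characters in a reference morphological matrix, what
percentage could be scored for a species given every skeletal element
preserved across *all* specimens referred to it?  The denominator is the
full character count for limbed taxa, and a reduced "True Completeness"
denominator for limbless lineages (snakes, amphisbaenians, dibamids), which
can never exhibit limb or girdle characters no matter how complete the
skeleton.

Region-level skeletal completeness (SCM2: fraction of the physical skeleton
preserved, per body partition) converts to CCM2 by weighting each
partition's preserved proportion by its character density.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from ccmkit.charmap import (
    LIMB_PARTITIONS,
    CharacterRegionMap,
    characters_for_elements,
)


class ScoringError(ValueError):
    pass


@dataclass(frozen=True)
class PreservationRecord:
    """Per-species preservation: union of elements over referred specimens."""

    species_id: str
    elements: frozenset[str]
    limbless: bool = False
    n_specimens: int = 1

    def __post_init__(self) -> None:
        if self.n_specimens < 1:
            raise ScoringError("a described species has at least one specimen")


@dataclass(frozen=True)
class CCM2Score:
    species_id: str
    scorable: int
    applicable: int

    def __post_init__(self) -> None:
        if not 0 <= self.scorable <= self.applicable:
            raise ScoringError(
                f"{self.species_id}: scorable {self.scorable} outside "
                f"[0, {self.applicable}]"
            )

    @property
    def ccm2(self) -> float:
        """Completeness percentage, full precision (format to 2 dp on output)."""
        return 100.0 * self.scorable / self.applicable


def applicable_characters(
    cmap: CharacterRegionMap, limbless: bool
) -> frozenset[int]:
    """Character ids in the denominator for a limbed or limbless taxon.

    Limbless taxa exclude every character any of whose required elements
    lies in a limb/girdle partition — a character spanning a limb and a
    non-limb element can never be fully scored for such a taxon.
    """
    if not limbless:
        return frozenset(cmap.characters)
    return frozenset(
        cid
        for cid in cmap.characters
        if not (cmap.partitions_of(cid) & LIMB_PARTITIONS)
    )


def applicable_count(cmap: CharacterRegionMap, limbless: bool) -> int:
    """Denominator size: C for limbed taxa, C minus limb/girdle characters
    for limbless taxa (860 → 710 under the squamate reference map)."""
    return len(applicable_characters(cmap, limbless))


def score_species_ccm2(
    cmap: CharacterRegionMap, record: PreservationRecord
) -> CCM2Score:
    """Score one species: scorable characters over applicable characters."""
    if not cmap.elements:
        raise ScoringError("character map has an empty element vocabulary")
    scorable_all = characters_for_elements(cmap, record.elements)
    applicable = applicable_characters(cmap, record.limbless)
    return CCM2Score(
        species_id=record.species_id,
        scorable=len(scorable_all & applicable),
        applicable=len(applicable),
    )


def union_preservation(
    specimen_elements: Sequence[Iterable[str]],
    species_id: str,
    limbless: bool = False,
) -> PreservationRecord:
    """Collapse per-specimen element sets to the species-wide union."""
    if not specimen_elements:
        raise ScoringError(f"{species_id}: no specimens supplied")
    union: set[str] = set()
    for elems in specimen_elements:
        union |= set(elems)
    return PreservationRecord(
        species_id=species_id,
        elements=frozenset(union),
        limbless=limbless,
        n_specimens=len(specimen_elements),
    )


@dataclass(frozen=True)
class RegionDensity:
    """Per-partition character counts and preserved proportions."""

    char_counts: Mapping[str, int]
    preserved: Mapping[str, float]

    def __post_init__(self) -> None:
        for part, p in self.preserved.items():
            if not 0.0 <= p <= 1.0:
                raise ScoringError(f"proportion for {part} outside [0, 1]: {p}")
        if set(self.preserved) - set(self.char_counts):
            raise ScoringError("preserved proportions for unknown partitions")


def convert_scm2_to_ccm2(density: RegionDensity) -> float:
    """Convert skeletal completeness to character completeness.

    Each partition contributes its preserved proportion weighted by its
    character density:  100 · Σ_r p_r·c_r / Σ_r c_r.  When only a scalar
    SCM2 is known, broadcast it to all partitions before calling (the result
    then equals the scalar itself).
    """
    total = sum(density.char_counts.values())
    if total == 0:
        raise ScoringError("character map has zero characters")
    weighted = sum(
        density.preserved.get(part, 0.0) * c
        for part, c in density.char_counts.items()
    )
    return 100.0 * weighted / total


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

def read_specimen_csv(path: str | Path) -> list[PreservationRecord]:
    """Read per-specimen rows and collapse to species-level records.

    Expected columns: species_id, specimen_id, elements (semicolon-
    separated), limbless (true/false).  A species' limbless flag must be
    consistent across its specimens.
    """
    by_species: dict[str, list[frozenset[str]]] = {}
    limbless_flags: dict[str, set[bool]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            sid = row["species_id"]
            elems = frozenset(
                e.strip() for e in row["elements"].split(";") if e.strip()
            )
            by_species.setdefault(sid, []).append(elems)
            limbless_flags.setdefault(sid, set()).add(
                str(row.get("limbless", "false")).strip().lower()
                in {"1", "true", "yes"}
            )
    records = []
    for sid, specimens in by_species.items():
        flags = limbless_flags[sid]
        if len(flags) > 1:
            raise ScoringError(f"{sid}: inconsistent limbless flags")
        records.append(union_preservation(specimens, sid, limbless=flags.pop()))
    return records


def write_scores_csv(scores: Iterable[CCM2Score], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["species_id", "scorable", "applicable", "ccm2"])
        for s in scores:
            writer.writerow(
                [s.species_id, s.scorable, s.applicable, f"{s.ccm2:.2f}"]
            )
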