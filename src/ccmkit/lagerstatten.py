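"""Quantifying the lagerstätten effect.

Two complementary measurements:

* **Leave-unit-out**: compare a scope's full CCM2 distribution (e.g., all
  squamates from Asia) against the same scope with one exceptionally
  preserving unit (or unit pair, e.g. Yixian+Jiufotang) removed.  A
  significant drop in median/shape quantifies how much that unit props up
  the region's apparent phylogenetic completeness.
* **Matrix representation**: what fraction of the fossil terminals of a
  published phylogenetic matrix derive from the unit, and how many distinct
  families those terminals span — the unit's grip on taxon selection.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from ccmkit.comparisons import ComparisonResult, compare_pair
from ccmkit.occurrences import OccurrenceDataset, subset_without_units


class LagerstattenError(ValueError):
    pass


@dataclass(frozen=True)
class LeaveOutResult:
    """Full-vs-reduced comparison after removing one unit set from a scope."""

    unit_label: str
    taxon_group: str
    scope: str
    n_full: int
    n_reduced: int
    median_full: float
    median_reduced: float
    comparison: ComparisonResult
    removed_species: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_reduced != self.n_full - len(self.removed_species):
            raise LagerstattenError("removed count inconsistent with sizes")


def leave_unit_out(
    scores: Mapping[str, float],
    dataset: OccurrenceDataset,
    units: Iterable[str],
    scope: str | None = None,
    group: str | None = None,
    unit_label: str = "",
    mode: str = "full_vs_reduced",
) -> LeaveOutResult:
    """Remove a unit set from a scope and compare the distributions.

    ``scope`` filters by landmass (None = global); ``group`` filters by
    taxon group.  The default comparison is the full scope sample against
    the scope-minus-unit sample (overlapping samples); ``mode="unit_vs_rest"``
    instead compares the unit's members against the remainder.
    """
    units = frozenset(units)
    table = dataset.table
    mask = table["accepted_name"].notna()
    if scope is not None:
        mask &= table["landmass"] == scope
    if group is not None:
        mask &= table["taxon_group"] == group
    scoped = table[mask]
    if len(scoped) == 0:
        raise LagerstattenError(
            f"scope {scope!r} × group {group!r} selects no species"
        )
    full_names = [n for n in scoped["accepted_name"] if n in scores]
    in_unit = set(
        scoped.loc[scoped["formation"].isin(units), "accepted_name"]
    ) & set(full_names)
    reduced_names = [n for n in full_names if n not in in_unit]
    if not reduced_names:
        raise LagerstattenError("removing the unit leaves an empty sample")
    full = [scores[n] for n in full_names]
    reduced = [scores[n] for n in reduced_names]
    scope_str = scope if scope is not None else "global"
    label = unit_label or "+".join(sorted(units))
    if mode == "full_vs_reduced":
        comparison = compare_pair(
            full, reduced, f"{scope_str} full", f"{scope_str} without {label}"
        )
    elif mode == "unit_vs_rest":
        unit_scores = [scores[n] for n in sorted(in_unit)]
        if not unit_scores:
            unit_scores = reduced  # degenerate: no unit members in scope
        comparison = compare_pair(
            unit_scores, reduced, label, f"{scope_str} without {label}"
        )
    else:
        raise LagerstattenError(f"unknown mode {mode!r}")
    return LeaveOutResult(
        unit_label=label,
        taxon_group=group or "all",
        scope=scope_str,
        n_full=len(full),
        n_reduced=len(reduced),
        median_full=statistics.median(full),
        median_reduced=statistics.median(reduced),
        comparison=comparison,
        removed_species=tuple(sorted(in_unit)),
    )


@dataclass(frozen=True)
class MatrixRepresentation:
    """A unit set's footprint in one phylogenetic matrix's taxon sample."""

    matrix_name: str
    unit_label: str
    n_fossil: int
    n_terminals: int
    n_from_unit: int
    percent_of_fossil: float
    percent_of_terminals: float
    families: tuple[str, ...]
    unmatched_unit_members: tuple[str, ...] = ()

    @property
    def n_families(self) -> int:
        return len(self.families)


def matrix_representation(
    matrix_taxa: Sequence[tuple[str, bool, str]],
    unit_members: Iterable[str],
    matrix_name: str,
    unit_label: str = "",
) -> MatrixRepresentation:
    """Representation of a unit's taxa among a matrix's terminals.

    ``matrix_taxa`` rows are (taxon, is_fossil, family).  The headline
    percentage is over fossil terminals (extant terminals excluded from the
    denominator); the all-terminals percentage is carried alongside.  Unit
    members absent from the matrix contribute nothing and are logged in
    ``unmatched_unit_members``.
    """
    taxa = [t for t, _, _ in matrix_taxa]
    if len(set(taxa)) != len(taxa):
        raise LagerstattenError("matrix taxa must be unique")
    members = set(unit_members)
    fossil = [(t, fam) for t, is_fossil, fam in matrix_taxa if is_fossil]
    from_unit = [(t, fam) for t, fam in fossil if t in members]
    families = tuple(sorted({fam for _, fam in from_unit if fam}))
    n_fossil = len(fossil)
    n_terminals = len(matrix_taxa)
    n_from_unit = len(from_unit)
    return MatrixRepresentation(
        matrix_name=matrix_name,
        unit_label=unit_label or "unit",
        n_fossil=n_fossil,
        n_terminals=n_terminals,
        n_from_unit=n_from_unit,
        percent_of_fossil=(
            100.0 * n_from_unit / n_fossil if n_fossil else 0.0
        ),
        percent_of_terminals=(
            100.0 * n_from_unit / n_terminals if n_terminals else 0.0
        ),
        families=families,
        unmatched_unit_members=tuple(sorted(members - set(taxa))),
    )
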