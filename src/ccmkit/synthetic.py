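"""Synthetic fossil-record generator with closed-form expected completeness.

The generator emulates the statistical structure the downstream analyses
assume: species grouped into geologic units whose preservation quality
differs (a lagerstätte is a high-``q`` unit), anatomical regions that differ
in how readily they fossilize (fragility weights ``w_r``), several specimens
per described species (element union across specimens raises completeness),
and limbless lineages whose limb elements are structurally absent.

Model, per species in unit *u*: specimen count ``s = 1 + Poisson(λ_u)``;
each specimen independently preserves each element of partition *r* with
probability ``q_u · w_r``; the species record is the element union across
its specimens.  Expected CCM2 then has the closed form

    100 · Σ_c  E_s[ Π_{e∈req(c)} (1 − (1 − q_u·w_{r(e)})^s) ]  /  C_applicable

which the generator exposes for law-of-large-numbers validation.

Element preservation is i.i.d. given (q_u, w_r); no articulation
correlation is modeled — the simplest structure that exercises every
downstream stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from ccmkit.charmap import LIMB_PARTITIONS, CharacterRegionMap, synthetic_squamate_map
from ccmkit.occurrences import OccurrenceDataset, load_and_vet
from ccmkit.scoring import PreservationRecord


class SyntheticError(ValueError):
    pass


@dataclass(frozen=True)
class UnitSpec:
    """One geologic unit: labels plus preservation parameters.

    ``q``: per-element, per-specimen preservation probability scale in
    (0, 1]; ``lam``: expected extra specimens per species (specimen count is
    1 + Poisson(lam)); ``species`` maps taxon group -> species count.
    """

    name: str
    landmass: str
    environment: str
    lagerstatte_class: str = "none"
    q: float = 0.5
    lam: float = 1.0
    species: Mapping[str, int] = field(
        default_factory=lambda: {"squamate": 10}
    )
    max_ma: float = 100.0
    min_ma: float = 90.0

    def __post_init__(self) -> None:
        if not 0.0 < self.q <= 1.0:
            raise SyntheticError(f"unit {self.name}: q must be in (0, 1]")
        if self.lam < 0:
            raise SyntheticError(f"unit {self.name}: lam must be ≥ 0")
        if any(n < 0 for n in self.species.values()):
            raise SyntheticError(f"unit {self.name}: species counts must be ≥ 0")


@dataclass
class SimulationConfig:
    """Full generator configuration; reproducible from ``seed`` alone."""

    seed: int
    units: Sequence[UnitSpec]
    fragility: Mapping[str, float] = field(default_factory=dict)
    limbless_fraction: Mapping[str, float] = field(default_factory=dict)
    cmap: CharacterRegionMap | None = None

    def __post_init__(self) -> None:
        if self.cmap is None:
            self.cmap = synthetic_squamate_map()
        for part, w in self.fragility.items():
            if not 0.0 < w <= 1.0:
                raise SyntheticError(
                    f"fragility weight for {part!r} must be in (0, 1]"
                )
        for grp, f in self.limbless_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise SyntheticError(
                    f"limbless fraction for {grp!r} must be in [0, 1]"
                )
        names = [u.name for u in self.units]
        if len(set(names)) != len(names):
            raise SyntheticError("unit names must be unique")

    def weight(self, partition: str) -> float:
        return float(self.fragility.get(partition, 1.0))

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text())
        units = [UnitSpec(**u) for u in raw["units"]]
        return cls(
            seed=seed if seed is not None else int(raw.get("seed", 0)),
            units=units,
            fragility=raw.get("fragility", {}),
            limbless_fraction=raw.get("limbless_fraction", {}),
        )


@dataclass
class GroundTruth:
    """Per-species generation record plus per-unit expected completeness."""

    species_unit: dict[str, str]
    species_specimens: dict[str, int]
    unit_expected_ccm2: dict[str, float]


def _species_rng(seed: int, unit_index: int, species_index: int) -> np.random.Generator:
    # per-species substream: adding species or units never perturbs
    # earlier species' draws
    ss = np.random.SeedSequence(
        entropy=seed, spawn_key=(unit_index, species_index)
    )
    return np.random.default_rng(ss)


def generate(
    config: SimulationConfig,
) -> tuple[OccurrenceDataset, list[PreservationRecord], GroundTruth]:
    """Generate an occurrence table + preservation records + ground truth.

    Within each unit and taxon group the first ``round(fraction · n)``
    species are limbless (deterministic count, so the limbless share is
    exact rather than binomial).
    """
    cmap = config.cmap
    assert cmap is not None
    elements = sorted(cmap.elements)
    limb_elements = {
        e for e in elements if cmap.element_partition[e] in LIMB_PARTITIONS
    }
    probs = np.array(
        [config.weight(cmap.element_partition[e]) for e in elements]
    )
    rows = []
    records: list[PreservationRecord] = []
    truth = GroundTruth(
        species_unit={}, species_specimens={}, unit_expected_ccm2={}
    )
    for u_idx, unit in enumerate(config.units):
        truth.unit_expected_ccm2[unit.name] = expected_ccm2(config, unit.name)
        s_idx = 0
        for group in sorted(unit.species):
            n = unit.species[group]
            n_limbless = round(config.limbless_fraction.get(group, 0.0) * n)
            for i in range(n):
                limbless = i < n_limbless
                rng = _species_rng(config.seed, u_idx, s_idx)
                s_idx += 1
                sid = f"{unit.name}_{group}_{i:03d}"
                n_spec = 1 + int(rng.poisson(unit.lam))
                union = np.zeros(len(elements), dtype=bool)
                for _ in range(n_spec):
                    union |= rng.random(len(elements)) < unit.q * probs
                preserved = {
                    e for e, kept in zip(elements, union) if kept
                }
                if limbless:
                    preserved -= limb_elements
                records.append(
                    PreservationRecord(
                        species_id=sid,
                        elements=frozenset(preserved),
                        limbless=limbless,
                        n_specimens=n_spec,
                    )
                )
                truth.species_unit[sid] = unit.name
                truth.species_specimens[sid] = n_spec
                rows.append(
                    {
                        "accepted_name": sid,
                        "accepted_rank": "species",
                        "is_extant": False,
                        "taxon_group": group,
                        "landmass": unit.landmass,
                        "formation": unit.name,
                        "environment": unit.environment,
                        "lagerstatte_class": unit.lagerstatte_class,
                        "max_ma": unit.max_ma,
                        "min_ma": unit.min_ma,
                        "n_specimens": n_spec,
                        "n_localities": 1,
                        "limbless": limbless,
                    }
                )
    table = pd.DataFrame(
        rows,
        columns=[
            "accepted_name", "accepted_rank", "is_extant", "taxon_group",
            "landmass", "formation", "environment", "lagerstatte_class",
            "max_ma", "min_ma", "n_specimens", "n_localities", "limbless",
        ],
    )
    dataset = load_and_vet(table)
    return dataset, records, truth


def _specimen_count_pmf(lam: float, tol: float = 1e-12) -> tuple[np.ndarray, np.ndarray]:
    """Support and pmf of s = 1 + Poisson(lam), truncated at mass 1 − tol."""
    if lam == 0:
        return np.array([1]), np.array([1.0])
    kmax = int(stats.poisson.ppf(1 - tol, lam)) + 1
    k = np.arange(kmax + 1)
    pmf = stats.poisson.pmf(k, lam)
    pmf = pmf / pmf.sum()
    return k + 1, pmf


def expected_ccm2(
    config: SimulationConfig, unit_name: str, limbless: bool = False
) -> float:
    """Closed-form expected CCM2 for species generated in one unit.

    For each applicable character the probability that all its required
    elements appear in the specimen union is averaged over the
    shifted-Poisson specimen count; characters sharing a required-element
    multiset share the computation.
    """
    cmap = config.cmap
    assert cmap is not None
    unit = next((u for u in config.units if u.name == unit_name), None)
    if unit is None:
        raise SyntheticError(f"unknown unit {unit_name!r}")
    support, pmf = _specimen_count_pmf(unit.lam)
    from ccmkit.scoring import applicable_characters

    applicable = applicable_characters(cmap, limbless)
    total_prob = 0.0
    cache: dict[frozenset[str], float] = {}
    for cid in applicable:
        req = cmap.characters[cid]
        if req not in cache:
            # P(char scorable) = E_s[ prod_e (1 - (1 - q w_r(e))^s) ]
            per_s = np.ones_like(pmf)
            for e in req:
                w = config.weight(cmap.element_partition[e])
                per_s = per_s * (1.0 - (1.0 - unit.q * w) ** support)
            cache[req] = float(np.dot(pmf, per_s))
        total_prob += cache[req]
    return 100.0 * total_prob / len(applicable)


def write_synthetic_inputs(
    config: SimulationConfig, out_dir: str | Path
) -> dict[str, Path]:
    """Write generator outputs in the CSV schemas the pipeline consumes."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    dataset, records, truth = generate(config)
    occ_path = out / "occurrences.csv"
    dataset.to_csv(occ_path)
    spec_path = out / "specimens.csv"
    with open(spec_path, "w", newline="") as fh:
        fh.write("species_id,specimen_id,elements,limbless\n")
        for rec in records:
            elems = ";".join(sorted(rec.elements))
            fh.write(f"{rec.species_id},1,{elems},{rec.limbless}\n")
    truth_path = out / "ground_truth.csv"
    with open(truth_path, "w", newline="") as fh:
        fh.write("unit,expected_ccm2\n")
        for unit, e in truth.unit_expected_ccm2.items():
            fh.write(f"{unit},{e:.6f}\n")
    return {
        "occurrences": occ_path,
        "specimens": spec_path,
        "ground_truth": truth_path,
    }
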