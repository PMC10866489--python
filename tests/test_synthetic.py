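"""Synthetic generator: reproducibility, limits, closed-form agreement."""

import numpy as np
import pytest

from ccmkit.charmap import LIMB_PARTITIONS
from ccmkit.occurrences import load_and_vet
from ccmkit.scoring import score_species_ccm2
from ccmkit.synthetic import (
    SimulationConfig,
    SyntheticError,
    UnitSpec,
    expected_ccm2,
    generate,
    write_synthetic_inputs,
)


def _config(seed=0, **unit_kwargs):
    defaults = dict(
        name="U", landmass="Asia", environment="aeolian",
        q=0.5, lam=1.0, species={"squamate": 20},
    )
    defaults.update(unit_kwargs)
    return SimulationConfig(seed=seed, units=[UnitSpec(**defaults)])


class TestGenerate:
    def test_perfect_preservation_scores_100(self):
        cfg = _config(q=1.0, lam=0.0)
        _, records, _ = generate(cfg)
        for rec in records:
            assert score_species_ccm2(cfg.cmap, rec).ccm2 == 100.0

    def test_vanishing_quality_scores_near_zero(self):
        cfg = _config(q=1e-9)
        _, records, _ = generate(cfg)
        for rec in records:
            assert score_species_ccm2(cfg.cmap, rec).ccm2 == 0.0

    def test_reproducible_from_seed(self):
        a = generate(_config(seed=5))
        b = generate(_config(seed=5))
        assert [r.elements for r in a[1]] == [r.elements for r in b[1]]
        assert a[0].table.equals(b[0].table)

    def test_adding_a_unit_preserves_earlier_draws(self):
        cfg1 = _config(seed=5)
        cfg2 = SimulationConfig(
            seed=5,
            units=list(cfg1.units)
            + [UnitSpec(name="V", landmass="Europe", environment="marine",
                        species={"squamate": 5})],
        )
        recs1 = generate(cfg1)[1]
        recs2 = generate(cfg2)[1]
        assert [r.elements for r in recs1] == [
            r.elements for r in recs2[: len(recs1)]
        ]

    def test_limbless_species_lack_limb_elements(self):
        cfg = SimulationConfig(
            seed=2,
            units=[UnitSpec(name="U", landmass="Asia", environment="aeolian",
                            q=0.9, species={"squamate": 20})],
            limbless_fraction={"squamate": 0.5},
        )
        _, records, _ = generate(cfg)
        limbless = [r for r in records if r.limbless]
        assert len(limbless) == 10
        for rec in limbless:
            parts = {cfg.cmap.element_partition[e] for e in rec.elements}
            assert not parts & LIMB_PARTITIONS

    def test_unit_quality_separates_distributions(self):
        """q = 0.9 vs 0.3 units (n=50 each): the completeness gap is
        detected by Mann-Whitney at α = 0.05 in ≥ 95% of seeds."""
        from ccmkit.comparisons import mann_whitney

        hits = 0
        n_seeds = 40
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                seed=seed,
                units=[
                    UnitSpec(name="Hi", landmass="Asia", environment="aeolian",
                             q=0.9, lam=1.0, species={"squamate": 50}),
                    UnitSpec(name="Lo", landmass="Asia", environment="fluvial",
                             q=0.3, lam=1.0, species={"squamate": 50}),
                ],
            )
            _, records, _ = generate(cfg)
            hi = [score_species_ccm2(cfg.cmap, r).ccm2
                  for r in records if r.species_id.startswith("Hi")]
            lo = [score_species_ccm2(cfg.cmap, r).ccm2
                  for r in records if r.species_id.startswith("Lo")]
            if mann_whitney(hi, lo).p_mw < 0.05:
                hits += 1
        assert hits / n_seeds >= 0.95

    def test_invalid_q_named_in_error(self):
        with pytest.raises(SyntheticError, match="q must be"):
            UnitSpec(name="U", landmass="Asia", environment="aeolian", q=1.5)

    def test_invalid_fragility_rejected(self):
        with pytest.raises(SyntheticError, match="fragility"):
            SimulationConfig(
                seed=0,
                units=[UnitSpec(name="U", landmass="Asia", environment="aeolian")],
                fragility={"skull": 0.0},
            )


class TestExpectedCcm2:
    def test_perfect_quality_is_100(self):
        for lam in (0.0, 1.0, 5.0):
            cfg = _config(q=1.0, lam=lam)
            assert expected_ccm2(cfg, "U") == pytest.approx(100.0)

    def test_single_specimen_half_quality(self):
        """With one specimen, one effective partition weight and q = 0.5,
        every character is scorable with probability 0.5."""
        cfg = _config(q=0.5, lam=0.0)
        assert expected_ccm2(cfg, "U") == pytest.approx(50.0)

    def test_unknown_unit_rejected(self):
        with pytest.raises(SyntheticError):
            expected_ccm2(_config(), "Atlantis")

    def test_monotone_in_quality_and_multiplicity(self):
        base = expected_ccm2(_config(q=0.4, lam=1.0), "U")
        assert expected_ccm2(_config(q=0.6, lam=1.0), "U") > base
        assert expected_ccm2(_config(q=0.4, lam=3.0), "U") > base
        cfg_frag = SimulationConfig(
            seed=0,
            units=[UnitSpec(name="U", landmass="Asia", environment="aeolian",
                            q=0.4, lam=1.0, species={"squamate": 1})],
            fragility={"skull": 0.5},
        )
        assert expected_ccm2(cfg_frag, "U") < base

    def test_monte_carlo_mean_within_3_se(self):
        """Law of large numbers: the mean CCM2 of generated species matches
        the closed form within 3 standard errors (3-partition map)."""
        from ccmkit.charmap import CharacterRegionMap

        cmap = CharacterRegionMap(
            characters={
                **{i: frozenset({"skull_el"}) for i in range(1, 6)},
                **{i: frozenset({"vert_el"}) for i in range(6, 9)},
                **{i: frozenset({"femur_el"}) for i in range(9, 11)},
            },
            element_partition={
                "skull_el": "skull", "vert_el": "axial", "femur_el": "hindlimb",
            },
        )
        cfg = SimulationConfig(
            seed=123,
            units=[UnitSpec(name="U", landmass="Asia", environment="aeolian",
                            q=0.6, lam=1.5, species={"squamate": 4000})],
            fragility={"skull": 0.9, "axial": 0.6, "hindlimb": 0.3},
            cmap=cmap,
        )
        _, records, _ = generate(cfg)
        scores = np.array(
            [score_species_ccm2(cmap, r).ccm2 for r in records]
        )
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean() - expected_ccm2(cfg, "U")) <= 3 * se

    def test_rankings_recover_true_quality_order(self):
        """Sorting units by sample median CCM2 recovers the q ordering when
        gaps are ≥ 0.2 and n ≥ 50 per unit."""
        import statistics

        correct = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                seed=seed,
                units=[
                    UnitSpec(name="A", landmass="Asia", environment="aeolian",
                             q=0.9, species={"squamate": 50}),
                    UnitSpec(name="B", landmass="Asia", environment="fluvial",
                             q=0.6, species={"squamate": 50}),
                    UnitSpec(name="C", landmass="Asia", environment="marine",
                             q=0.3, species={"squamate": 50}),
                ],
            )
            _, records, _ = generate(cfg)
            medians = {}
            for unit in "ABC":
                medians[unit] = statistics.median(
                    score_species_ccm2(cfg.cmap, r).ccm2
                    for r in records if r.species_id.startswith(unit)
                )
            if medians["A"] > medians["B"] > medians["C"]:
                correct += 1
        assert correct / n_seeds >= 0.95


class TestWriteSyntheticInputs:
    def test_outputs_pass_vetting_with_zero_drops(self, tmp_path):
        cfg = _config(seed=9)
        paths = write_synthetic_inputs(cfg, tmp_path)
        ds = load_and_vet(paths["occurrences"])
        assert ds.n_species == 20
        assert ds.vetting_log == []

    def test_same_seed_gives_identical_files(self, tmp_path):
        p1 = write_synthetic_inputs(_config(seed=4), tmp_path / "a")
        p2 = write_synthetic_inputs(_config(seed=4), tmp_path / "b")
        for key in p1:
            assert p1[key].read_text() == p2[key].read_text()
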