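"""CCM2 scoring: denominators, species scores, SCM2 conversion."""

import numpy as np
import pytest

from ccmkit.scoring import (
    PreservationRecord,
    RegionDensity,
    ScoringError,
    applicable_count,
    convert_scm2_to_ccm2,
    read_specimen_csv,
    score_species_ccm2,
    union_preservation,
    write_scores_csv,
)

from _oracles import brute_ccm2, random_record, random_region_map


class TestApplicableCount:
    def test_squamate_denominators(self, squamate_map):
        """Limbed taxa score out of 860 characters, limbless out of 710."""
        assert applicable_count(squamate_map, limbless=False) == 860
        assert applicable_count(squamate_map, limbless=True) == 710

    def test_no_limb_characters_means_equal_denominators(self):
        from ccmkit.charmap import CharacterRegionMap

        cmap = CharacterRegionMap(
            characters={1: frozenset({"skull"}), 2: frozenset({"dentary"})},
            element_partition={"skull": "skull", "dentary": "mandible"},
        )
        assert applicable_count(cmap, True) == applicable_count(cmap, False)

    def test_fixture_limbless_excludes_limb_spanning(self, fixture_map):
        # 3 femur-only + 1 skull+femur characters leave 6 of 10
        assert applicable_count(fixture_map, limbless=True) == 6


class TestScoreSpecies:
    def test_fully_preserved_limbed_scores_100(self, fixture_map):
        rec = PreservationRecord("sp", frozenset({"skull", "femur"}))
        assert score_species_ccm2(fixture_map, rec).ccm2 == 100.0

    def test_nothing_preserved_scores_0(self, fixture_map):
        rec = PreservationRecord("sp", frozenset())
        assert score_species_ccm2(fixture_map, rec).ccm2 == 0.0

    def test_limbless_full_preservation_is_true_completeness(self, squamate_map):
        """A limbless species with every non-limb element preserved scores
        710/710 = 100%."""
        limb = {"pectoral_girdle", "forelimb", "pelvic_girdle", "hindlimb"}
        non_limb = frozenset(
            e for e in squamate_map.elements
            if squamate_map.element_partition[e] not in limb
        )
        rec = PreservationRecord("snake", non_limb, limbless=True)
        score = score_species_ccm2(squamate_map, rec)
        assert (score.scorable, score.applicable) == (710, 710)
        assert score.ccm2 == 100.0

    def test_skull_only_fixture_scores_60(self, fixture_map):
        rec = PreservationRecord("sp", frozenset({"skull"}))
        assert score_species_ccm2(fixture_map, rec).ccm2 == 60.0

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            cmap = random_region_map(rng, max_chars=50)
            rec = random_record(rng, cmap)
            score = score_species_ccm2(cmap, rec)
            scorable, applicable = brute_ccm2(cmap, rec.elements, rec.limbless)
            assert (score.scorable, score.applicable) == (scorable, applicable)

    def test_monotone_in_preserved_elements(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            cmap = random_region_map(rng, max_chars=30)
            elements = sorted(cmap.elements)
            k = int(rng.integers(0, len(elements)))
            base = set(rng.choice(elements, size=k, replace=False).tolist()) if k else set()
            extra = [e for e in elements if e not in base]
            bigger = base | set(extra[: max(1, len(extra) // 2)])
            s1 = score_species_ccm2(cmap, PreservationRecord("a", frozenset(base)))
            s2 = score_species_ccm2(cmap, PreservationRecord("a", frozenset(bigger)))
            assert s2.ccm2 >= s1.ccm2


class TestUnionPreservation:
    def test_single_specimen_identity(self):
        rec = union_preservation([{"skull"}], "sp")
        assert rec.elements == frozenset({"skull"})
        assert rec.n_specimens == 1

    def test_union_of_two_specimens(self):
        rec = union_preservation([{"skull"}, {"femur"}], "sp")
        assert rec.elements == frozenset({"skull", "femur"})

    def test_empty_specimen_list_rejected(self):
        with pytest.raises(ScoringError):
            union_preservation([], "sp")

    def test_union_score_dominates_per_specimen_scores(self):
        rng = np.random.default_rng(23)
        for _ in range(50):
            cmap = random_region_map(rng, max_chars=30)
            elements = sorted(cmap.elements)
            specimens = []
            for _ in range(int(rng.integers(1, 5))):
                k = int(rng.integers(0, len(elements) + 1))
                specimens.append(
                    set(rng.choice(elements, size=k, replace=False).tolist())
                )
            union_rec = union_preservation(specimens, "sp")
            union_score = score_species_ccm2(cmap, union_rec).ccm2
            per_specimen = [
                score_species_ccm2(
                    cmap, PreservationRecord("sp", frozenset(s))
                ).ccm2
                for s in specimens
            ]
            assert union_score >= max(per_specimen)


class TestScm2Conversion:
    def test_full_preservation_everywhere(self):
        d = RegionDensity({"skull": 10, "axial": 5}, {"skull": 1.0, "axial": 1.0})
        assert convert_scm2_to_ccm2(d) == 100.0

    def test_uniform_densities_reduce_to_mean(self):
        d = RegionDensity(
            {"skull": 10, "axial": 10, "hindlimb": 10},
            {"skull": 0.9, "axial": 0.6, "hindlimb": 0.3},
        )
        assert convert_scm2_to_ccm2(d) == pytest.approx(60.0)

    def test_density_weighting(self):
        d = RegionDensity(
            {"skull": 10, "axial": 20, "hindlimb": 70},
            {"skull": 1.0, "axial": 0.5, "hindlimb": 0.0},
        )
        assert convert_scm2_to_ccm2(d) == pytest.approx(20.0)

    def test_zero_characters_rejected(self):
        with pytest.raises(ScoringError):
            convert_scm2_to_ccm2(RegionDensity({}, {}))

    def test_binary_densities_agree_with_element_scoring(self):
        """With p_r ∈ {0,1} the conversion equals scoring the record that
        preserves exactly the p_r = 1 partitions (single-partition chars)."""
        rng = np.random.default_rng(31)
        for _ in range(25):
            cmap = random_region_map(rng, max_chars=40)
            single = all(
                len({cmap.element_partition[e] for e in req}) == 1
                for req in cmap.characters.values()
            )
            if not single:
                continue
            parts = sorted({p for p in cmap.element_partition.values()})
            chosen = {p for p in parts if rng.random() < 0.5}
            counts = {p: 0 for p in parts}
            for cid in cmap.characters:
                counts[next(iter(cmap.partitions_of(cid)))] += 1
            density = RegionDensity(
                counts, {p: 1.0 if p in chosen else 0.0 for p in parts}
            )
            elements = frozenset(
                e for e, p in cmap.element_partition.items() if p in chosen
            )
            score = score_species_ccm2(
                cmap, PreservationRecord("sp", elements)
            )
            assert convert_scm2_to_ccm2(density) == pytest.approx(score.ccm2)


class TestCsvIO:
    def test_specimen_csv_round_trip(self, tmp_path, fixture_map):
        path = tmp_path / "specimens.csv"
        path.write_text(
            "species_id,specimen_id,elements,limbless\n"
            "spA,1,skull,false\n"
            "spA,2,femur,false\n"
            "spB,1,skull,true\n"
        )
        records = {r.species_id: r for r in read_specimen_csv(path)}
        assert records["spA"].elements == frozenset({"skull", "femur"})
        assert records["spA"].n_specimens == 2
        assert records["spB"].limbless is True
        out = tmp_path / "scores.csv"
        write_scores_csv(
            [score_species_ccm2(fixture_map, r) for r in records.values()],
            out,
        )
        lines = out.read_text().strip().splitlines()
        assert lines[0] == "species_id,scorable,applicable,ccm2"
        assert len(lines) == 3
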