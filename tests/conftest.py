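import pytest

from ccmkit.charmap import CharacterRegionMap, synthetic_squamate_map


@pytest.fixture(scope="session")
def squamate_map() -> CharacterRegionMap:
    return synthetic_squamate_map()


@pytest.fixture()
def fixture_map() -> CharacterRegionMap:
    """10 characters: 6 require {skull}, 3 require {femur}, 1 requires both.

    femur sits in a limb partition, so 4 characters are excluded from the
    limbless denominator.
    """
    characters = {}
    for cid in range(1, 7):
        characters[cid] = frozenset({"skull"})
    for cid in range(7, 10):
        characters[cid] = frozenset({"femur"})
    characters[10] = frozenset({"skull", "femur"})
    return CharacterRegionMap(
        characters=characters,
        element_partition={"skull": "skull", "femur": "hindlimb"},
    )


@pytest.fixture()
def occurrence_rows():
    """Toy occurrence table builder."""
    def make(rows):
        import pandas as pd

        defaults = {
            "accepted_rank": "species",
            "is_extant": False,
            "taxon_group": "squamate",
            "landmass": "Asia",
            "formation": "FmA",
            "environment": "fluvial",
            "lagerstatte_class": "none",
            "max_ma": 100.0,
            "min_ma": 90.0,
            "n_specimens": 1,
            "n_localities": 1,
            "limbless": False,
        }
        columns = ["accepted_name", *defaults.keys()]
        full = [{**defaults, **row} for row in rows]
        return pd.DataFrame(full, columns=columns)

    return make
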