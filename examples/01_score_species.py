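"""Score per-species character completeness (CCM2) by hand-built records.

Builds preservation records for three imaginary fossil squamates — a
near-complete lizard, a skull-only fragment, and a fully preserved snake —
and scores them against the 860-character squamate reference map.  The
snake illustrates "True Completeness": limbless taxa are scored out of the
710 characters they could ever exhibit.
"""

from ccmkit import (
    score_species_ccm2,
    synthetic_squamate_map,
    union_preservation,
)

cmap = synthetic_squamate_map()
limb_parts = {"pectoral_girdle", "forelimb", "pelvic_girdle", "hindlimb"}
all_elements = sorted(cmap.elements)
non_limb = [e for e in all_elements if cmap.element_partition[e] not in limb_parts]

species = [
    # (name, per-specimen element sets, limbless)
    ("Lacerta exemplaris", [all_elements[:20], all_elements[15:]], False),
    ("Fragmentosaurus cranialis",
     [["premaxilla", "maxilla", "frontal", "dentary"]], False),
    ("Serpens integra", [non_limb], True),
]

print(f"reference map: {cmap.n_characters} characters")
for name, specimens, limbless in species:
    record = union_preservation(specimens, name, limbless=limbless)
    score = score_species_ccm2(cmap, record)
    print(
        f"{name:28s} specimens={record.n_specimens} "
        f"scorable={score.scorable:4d}/{score.applicable} "
        f"CCM2={score.ccm2:6.2f}%"
    )

print(
    "\nCCM2 is the percentage of reference characters scorable from the\n"
    "union of elements across a species' specimens; the snake's denominator\n"
    "is 710 (limb and girdle characters excluded), so full preservation of\n"
    "everything it can preserve reads 100%."
)
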