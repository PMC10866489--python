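# Synthetic fossil-record configuration for `ccmkit simulate`.
# Each unit is one geologic formation: q scales per-element preservation
# probability, lam is the expected number of extra specimens per species
# (specimen count = 1 + Poisson(lam)).
seed: 11
units:
  - name: DuneField
    landmass: Asia
    environment: aeolian
    lagerstatte_class: none
    q: 0.9
    lam: 1.5
    species: {squamate: 40}
  - name: LakeBeds
    landmass: Asia
    environment: lacustrine
    lagerstatte_class: konservat
    q: 0.8
    lam: 2.0
    species: {squamate: 10, mesozoic_bird: 25, non_avian_theropod: 20}
  - name: RiverPlain
    landmass: Europe
    environment: fluvial
    q: 0.35
    lam: 1.0
    species: {squamate: 30, non_avian_theropod: 15}
# anatomical fragility: skulls survive transport better than girdles here
fragility: {skull: 0.9, mandible: 0.9, axial: 0.7, pectoral_girdle: 0.5,
            forelimb: 0.5, pelvic_girdle: 0.5, hindlimb: 0.5, integument: 0.2}
limbless_fraction: {squamate: 0.25}
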