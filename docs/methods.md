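# Methods

## The completeness model

The package treats "phylogenetic information content" of a fossil species
as the fraction of a reference morphological matrix that could in principle
be scored from its preserved anatomy. The unit of observation is the
species, not the specimen: a species' preserved-element set is the union
over all specimens referred to it, so adding a specimen can only raise the
score (CCM2, as opposed to best-single-specimen variants). Per-specimen
scores are retained for diagnostics but never enter the analyses.

A character is **scorable** iff *all* of its required elements are
preserved. Most characters reference a single element, where the two
possible readings (any vs. all) coincide; for ratio and articulation
characters that reference several bones, the all-elements rule is the
conservative one — a ratio cannot be measured from half its bones. This is
a deliberate design choice where the underlying convention is ambiguous.

**Denominators.** Limbed taxa are scored against the full character count
(860 under the squamate reference map). Limbless lineages are scored
against a reduced "True Completeness" denominator that drops every
character touching a limb or girdle partition (pectoral girdle, forelimb,
pelvic girdle, hindlimb) — 710 under the squamate map. A character spanning
a limb and a non-limb element is excluded from the limbless denominator
because it can never be fully scored for such a taxon.

**The squamate reference map is synthetic.** The real combined squamate
character set's per-character element assignments live in a study's
supplementary workbook; `synthetic_squamate_map()` is a synthetic stand-in
that reproduces the structural facts every computation depends on: 860
characters total, exactly 150 in the four limb/girdle partitions (hence the
710 limbless denominator), and over two-thirds concentrated in skull +
mandible, as is characteristic of squamate matrices. Characters are
assigned cyclically to each partition's element vocabulary, single-element
throughout, deterministically. Analyses that depend only on these counts
(denominator logic, conversion weights) are exact; per-element detail is
illustrative.

**SCM2 → CCM2 conversion.** When only region-level skeletal completeness
is available, CCM2 is estimated as `100 · Σ_r p_r c_r / Σ_r c_r`, with
`p_r` the preserved proportion of partition *r* and `c_r` its character
count. This density-weighted form is the package's explicit choice; the
conversion procedure is not standardized in the literature, and the
weighted form is the only one consistent with using a character matrix to
perform the conversion. When a scalar SCM2 is broadcast to all partitions
the conversion returns the scalar itself, which is the intended degenerate
behaviour. With binary `p_r` and single-partition characters, the
conversion agrees exactly with element-level scoring (tested).

## Occurrence vetting and partitioning

Vetting applies three rules in order: keep species-rank rows only; keep
extinct species only (fossil material assigned to extant species would
score 100% trivially, since the living skeleton is available); collapse
duplicate species rows, summing specimen and locality counts and widening
the age interval. Label conflicts among duplicates keep the first-seen
label and are flagged in the vetting log rather than silently resolved.
Vetting is idempotent at the dataset level.

Grouping keys are landmass, depositional environment, geologic unit
(formation), lagerstätte class and taxon group. The environment and
landmass vocabularies are supersets and editable; unknown map *elements*
are hard errors (silent vocabulary drift corrupts denominators), unknown
*unit names* in a removal request are warnings (alias sets legitimately
span taxon groups). Minimum-sample defaults follow the published analyses:
≥ 6 species per landmass, ≥ 17 per depositional environment. The formation
pairs Yixian+Jiufotang ("jehol") and Djadokhta+Baruungoyot ("gobi") ship as
named unit-set aliases because the analyses treat each pair as a single
depositional system.

## Statistical comparisons

Each results panel (e.g. all pairwise landmass comparisons for one taxon
group) is one comparison family: all C(k, 2) pairs, each tested two-sided
with Mann-Whitney U and two-sample Kolmogorov-Smirnov, flagged at the
Bonferroni-adjusted α = 0.05/m. Families are never pooled across panels.

The Mann-Whitney p-value is exact (full enumeration of the permutation
null of U) when n_x·n_y ≤ 400 and the pooled sample is tie-free, otherwise
a tie-corrected normal approximation with continuity correction; the
threshold is an implementation choice balancing exactness against cost,
and results carry a method tag (plus both p-values when both are
computable) so discrepancies against other software's tie policies are
auditable. CCM2 data contain many ties (identical element sets), so the
approximate path is the common one on real-shaped data. The KS p-value is
asymptotic throughout. Computations are delegated to scipy.stats; the test
suite checks them against independent oracles (rank-assignment enumeration;
direct ECDF supremum).

The violin "95% interval" reported with each summary is the central 95%
data interval (2.5th–97.5th percentiles). Plotting conventions for this
whisker vary across implementations; the choice is recorded in output
metadata. Quartiles use linear interpolation between order statistics.

## Lagerstätten-effect measurements

**Leave-unit-out** compares the complete scope sample (a landmass ×
taxon-group slice, or global) against the same sample minus the unit set's
members — overlapping samples, mirroring the full-vs-reduced design of
published figure panels, rather than unit-vs-rest (available behind
`mode="unit_vs_rest"`). The result carries both medians, both sample
sizes, the removed-species list and the two-sample tests.

**Matrix representation** reports what share of a phylogenetic matrix's
fossil terminals derive from a unit set, and how many distinct families
those terminals span. The headline denominator is fossil (extinct)
terminals; the all-terminals percentage is emitted alongside because
published panels are not always explicit about which denominator they use.
Family assignments come from an input table, never inferred from names.

## The synthetic generator

The generator emulates the statistical structure the analyses assume, not
any particular fauna. Per species in unit *u*: specimen count
`s = 1 + Poisson(λ_u)` (a described species has at least one specimen);
each specimen preserves each element of partition *r* independently with
probability `q_u · w_r`; the species record is the union. Limbless species
(a configurable fraction per taxon group, deterministic count) have limb
elements forced absent and the flag set. Seeding uses one `SeedSequence`
per species keyed by (unit index, species index), so adding units or
species never perturbs earlier draws.

Expected CCM2 has the closed form
`100 · Σ_c E_s[Π_{e∈req(c)} (1 − (1 − q_u·w_r(e))^s)] / C_applicable`,
with the expectation over the shifted-Poisson specimen count evaluated by
truncating the Poisson at mass 1 − 1e-12. It is monotone in `q_u`, every
`w_r` and `λ_u`, and the Monte-Carlo mean at n = 10,000 sits within 3
standard errors (tested and recomputed by the acceptance script).

What the generator does **not** model: anatomical articulation correlation
(elements preserve i.i.d. given quality and fragility — real specimens
preserve correlated blocks), collection and publication bias, time- or
facies-dependent sampling, character-state evolution. Passing tests on
synthetic data therefore demonstrate the pipeline's internal correctness
and statistical calibration, not that any particular empirical record is
unbiased.

## Problem sizes and numerical choices

The validation battery uses 1,000 random map/record pairs for oracle
equivalence, every tie-free Mann-Whitney configuration with n_x, n_y ≤ 6
(3,418 configurations) for exactness, 2,000 null families of three
20-observation groups for type-I control, 200 seeds of the two-unit
(q = 0.9 vs 0.3, n = 50 each) design for parameter recovery, and 10,000
species for the law-of-large-numbers check — sizes chosen so each claim's
binomial/Monte-Carlo error is small relative to its margin while the whole
battery runs in well under a minute of compute. Percentages are computed at
full precision and formatted to two decimals on output. Degenerate inputs
(empty samples, empty element vocabularies, zero-character maps, empty
reduced samples) raise typed errors rather than returning NaN.

## Known limitations

* The synthetic squamate map is structurally faithful but not
  character-for-character real; see above.
* Exact Mann-Whitney is unavailable under ties; the tie-corrected
  approximation is standard but can differ from other packages' exact-test
  conventions in small tied samples.
* Landmass assignment is single-valued per species; species spanning
  landmasses are carried under their first-seen label (logged).
* Age intervals are carried but unused; no time-series analyses are
  implemented.
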