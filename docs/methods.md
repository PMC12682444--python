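# Methods

## The model

`ethnosurvey` analyzes informant use-report surveys, the standard data
structure of quantitative ethnobotany and ethnoveterinary medicine. The
atomic observation is a *use report*: one informant citing one plant
species for one ailment category. A survey is the deduplicated set of
(informant, species, category) triples plus the total number of informants
interviewed, `N`. An informant describing several preparations of the same
species for the same ailment contributes a single report. This convention
is not arbitrary: it is the only counting rule under which the cultural
importance index `CI = Σ_c Np_sc / N` collapses to `UR/N` and therefore
equals the use value, as it does for every species row of the packaged
reference survey.

All indices derive from three tallies:

| symbol | meaning |
|---|---|
| `UR_s` | use reports for species *s* (triples) |
| `FC_s` | distinct informants citing *s* |
| `NU_s` | distinct ailment categories of *s* |
| `Nur_c` | use reports within category *c* |
| `Ntaxa_c` | distinct species cited for *c* |
| `Np_sc` | distinct informants citing *s* for *c* |

and the derived indices are

- use value `UV = UR/N` and cultural importance `CI = UR/N` (equal under
  the dedup convention),
- relative frequency of citation `RFC = FC/N`,
- relative importance `RI = (RFC/max RFC + NU/max NU)/2` — 1 exactly for a
  species that is maximal in both salience and versatility,
- informant consensus factor `ICF = (Nur − Ntaxa)/(Nur − 1)`, defined as 0
  when `Nur ≤ 1` (the formula is 0/0 there; the convention matches the
  printed zeros of single-report categories in the reference survey),
- fidelity level `FL = 100·Np/FC` (percent),
- choice value `CV = Np/Ntaxa_c`.

The reference survey prints these indices by name but not by formula; the
formulas above were fixed by numerically inverting the printed tables
themselves and are pinned by tests: every species-index value (UV, RFC,
CI, RI for 31 species) and every category consensus value reproduce
exactly, and 18 of the 19 printed choice values reproduce (see
"Known inconsistencies").

## Rounding

Printed tables round half-up: UV/RFC/CI/RI to 3 decimals, ICF/FL/CV to 2.
`round_half_up` quantizes the shortest decimal representation of the float
(`Decimal(repr(x))`), so 0.855 rounds to 0.86 rather than falling on the
binary representation 0.85499…. Internal computation is always unrounded;
rounding happens only at table emission (`summarize(rounded=True)`).
Because `N = 200`, every UV/RFC value is an exact multiple of 0.005 and
3-decimal rounding is exact.

## Margin reconstruction

Printed fidelity levels are rounded from integer ratios, so half-up
inversion `Np = round(FL·FC/100)` recovers the integer cell counts:
81.03 % of 58 informants gives 46.997 → 47, 92.86 % of 14 gives 13.0004
→ 13, 33.33 % of 3 gives 0.9999 → 1. The reconstruction is validated by
conservation: the per-category counts of every species sum exactly to its
printed use-report total (e.g. 47+1+2+2+1+3+29+2+1 = 88 for the
top-cited species).

`realize_dataset` is the constructive inverse of the tally: for a species
with citation frequency `FC` it creates `FC` informant slots and deals
each category's `Np` citations onto consecutive slots modulo `FC`,
continuing the pointer across categories. With `max_c Np ≤ FC ≤ Σ_c Np`
each category lands on distinct slots and every slot receives at least one
citation, so the realized dataset tallies back to exactly the input
margins (property-tested on random feasible margins). Margins violating
either inequality are rejected as infeasible. Informant identities are
namespaced per species: printed tables carry no information about which
informants co-cite several species, so cross-species informant overlap is
deliberately not modeled. This is a documented limitation — any
informant-level statistic *across* species (e.g. distinct informants in
the whole survey) is not meaningful on a realized dataset, while all
per-species and per-category indices are exact. A seed only permutes the
synthetic informant labels.

## Known inconsistencies of the reference tables

The validator cross-checks every table against every other and reports,
never repairs. On the packaged tables it finds, reproducibly:

- **urinary retention**: the category table prints 1 use report, but the
  fidelity table implies 2 (a species with FC = 2 and FL = 100 %). This is
  also why the species table's grand total is 191 reports while the
  category table's is 190.
- **animal bite**: the category table prints 5 taxa, but only 3 species
  have a fidelity entry for it — and the printed choice value 1.67 = 5/3
  is consistent only with the data-derived 3, so the validator computes
  `CV` from data-derived `Ntaxa`.
- one choice value, 0.66 for the milk-production category, recomputes to
  2/3 → 0.67 (a rounding slip in the printed table).

The first two are *warnings* (margin disagreements among the printed
tables); their arithmetic consequences (the grand total, the two
recomputed consensus factors for the flagged categories, the choice-value
slip) are *informational*. Internal inconsistencies — a reconstruction
that fails its own margins — would be *failures* and make the
`validate-reference` command exit nonzero; the packaged tables produce
none.

## Species and category vocabulary

Species are keyed by the species-index table's names. The registry records
synonyms ("Amygdalus lycioides Spach" is *Prunus eburnea*; the identity is
arithmetically confirmed because the five fidelity rows printed under the
synonym, 40/20/40/20/80 % of FC = 5, sum exactly to the *P. eburnea* use
total of 10) and resolves genus-initial abbreviations ("A. lycioides
Spach", "T. undulata (Sm.) Seem") by matching the epithet-plus-author tail.
"Ziziphus sp." is registered as ambiguous between the two Ziziphus
species — the validator accepts either candidate when checking its choice
value (both have `Np = 5`, so the printed 0.45 is consistent with both) —
and is never silently assigned. The ailment vocabulary is the 15 category
labels, lowercase, with a free-text alias map (diarrhea → digestive,
muscular pain → muscle and joint pain, …).

The reference survey covers 31 species in 21 families; one species
(*Ephedra pachyclada*, the only gymnosperm, family Ephedraceae) is
documented through a three-ingredient complex remedy and therefore appears
in the index tables but not in the per-species use table.

## Use comparison

Each species' local uses are compared against its literature record:
empty record → **novel**; at least one literature phrase that normalizes
to a locally used category → **corroborated**; otherwise **divergent**.
Phrases are normalized by an ordered keyword lexicon
(`LITERATURE_LEXICON`) folding folk disease terms onto the category
vocabulary: internal-parasite and gastric terms into *digestive*,
bone-setting terms (bruises, dislocations, strains) into *fractures*,
skin-parasite terms into *scabies*, wound-family terms into *infected
wound*, and so on. Phrases matching nothing are carried as unmatched,
never dropped.

Whether two folk labels denote the same use is a judgment call. The
packaged use table carries a per-use label as ground truth — firm for the
13 species with no literature record and for the two explicitly discussed
comparisons (the corroborated asafoetida and the divergent caper), and
*provisional* for the rest. The lexicon was tuned until the automatic
matcher reproduces the packaged labels; `classify_reference_uses` emits
the matcher-vs-reference diff so any future lexicon change surfaces
disagreements instead of hiding them. The resulting breakdown is 13 novel
(42 %), 9 divergent (29 %), 9 corroborated (29 %) of 31 documented uses.

## Synthetic surveys

The generator emulates the statistical shape of the reference survey so
every pipeline stage is testable without field data:

- **popularity**: truncated power law over species ranks, weight ∝
  `rank^−a`. Default `a = 1.6` reproduces the observed dominance (the
  top species holds ≈ 40 % of all citations).
- **citation rate**: each informant cites a Poisson number of distinct
  species, default mean 0.8 — the reference records are a veterinary
  subset of a broader interview, so many informants contribute nothing
  (total per-species citation slots are 141 against N = 200).
- **category profiles**: each species has one dominant ailment holding
  `category_concentration` = 0.75 of its profile mass, with a Poisson
  (mean 0.3) number of extra categories per informant-species pair. This
  mirrors the 30 printed cells where a species' fidelity for a single
  ailment is 100 %.

Identical seeds give identical datasets (numpy `default_rng`). The
generator does **not** model informant covariates, community/tribe
structure, or snowball-sampling correlation; passing tests show the
pipeline's arithmetic is right under the assumed shape, not that real
surveys satisfy the shape.

The rank-recovery experiment checks that observed citation frequencies
estimate the latent popularity ranks: over 50 seeded replicates it reports
the mean Spearman correlation between true weights and per-species FC.
At the survey-emulation citation rate the mean is ≈ 0.77, limited by ties
among never-cited tail species; the calibrated check configuration
(`recovery_config`: same gradient, 1.5 citations per informant) settles
around 0.84 and is the config under which the ≥ 0.8 sanity bound is
asserted. With a flat popularity vector the correlation is
indistinguishable from 0.

## Invariances (and two non-invariances)

Duplicating every informant under fresh identities while doubling `N`
leaves all per-informant ratios unchanged: UV, RFC, CI, RI, FL. It does
**not** leave ICF or CV unchanged — `Nur` and `Np` double while `Ntaxa`
stays fixed, so ICF moves to `(2Nur − Ntaxa)/(2Nur − 1)` and CV doubles.
Both are counts-per-taxon, not per-informant proportions; the tests assert
the exact transformation law rather than a false invariance.

## Problem sizes

All reference computations are desk-scale: 31 species × 15 categories,
59 nonzero cells, 191 reports. Property tests run on surveys of ≤ 20
informants × 8 species (where a naive set-enumeration recount is the
independent oracle) and on random feasible margin sets of ≤ 4 species ×
5 categories; the stochastic rank-recovery check uses 50 replicates of a
200-informant survey. The whole suite runs in well under a minute.
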