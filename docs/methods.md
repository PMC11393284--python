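# Methods

## Model

`deer_cba` values alternative hunting regimes for Danish red deer (*Cervus
elaphus*) by coupling a stationary sex- and age-structured life table to an
annual net-benefit function.

**Life table.** Each sex has 25 September-age classes (0–24). Age-specific
total annual mortality `q_x` gives survivorship
`l_x = Π_{i<x}(1 − q_i)`, populations `n_x = n_0 · l_x` and deaths
`dn_x = n_x · q_x`. The model is stationary: recruitment, mortality and
therefore the whole age structure repeat every year, with no immigration or
emigration and no density dependence.

**Mortality convention.** Management strategies are stated as hunting
mortality rates per sex and age band. The package interprets these as
*total* annual mortality floored at a baseline vehicle-collision rate of
0.02 that applies to every sex and age class:
`q_x = max(hunting_x, 0.02)`. Collision deaths are `n_x · 0.02` and harvest
is the remainder `n_x · (q_x − 0.02)`. This convention — rather than adding
collisions on top of hunting — is what reproduces the documented male
survivorship figures (about 56% of trophy-regime males reach age 8+, via
0.65 × 0.98⁷) and the reference population compositions, and it makes
`harvest + collisions = deaths` exact in every cell. Every schedule cell
carries a provenance tag (`stated`, `derived`, `floor`) so reports can audit
which rates were filled in.

**Recruitment closure.** The stated fecundities (0.57 calves per yearling
hind, 0.82 per adult hind, half of recruits female) and mortality schedules
do not jointly satisfy replacement, so recruitment is *not* taken from the
fecundity equation. Instead the life table is treated as a pure stationary
cohort model: both sexes share one recruit cohort size, chosen so that the
spring census — ages 1–24 over both sexes, i.e. the post-season population
before calving — equals the configured target (1000 by default, which turns
every result into a statement about population *composition*, not size).
The fecundity schedule is used only for the September (pre-season) census,
`N_September = N_Spring + Σ n_{x,f} · m_x`.

**Terminal age.** Survivors of age 24 are counted as deaths that year
(`q_24 := 1` for accounting). Under all built-in strategies the mass
involved is below 10⁻⁴ of recruitment, and the convention makes the per-sex
conservation identity — recruits equal total deaths — hold to machine
precision, which the suite asserts at 1e-9.

**Forward-projection oracle.** `project_forward` iterates cohort aging
under constant recruitment from an arbitrary starting structure. It exists
purely as an independent check: after at most 25 years in exact arithmetic
the projection equals the closed-form stationary table, and the acceptance
suite verifies that equivalence on 1000 random schedules at 1e-6 relative.

## Strategies

Five built-in regimes (free harvest, trophy hunting, maximum harvest, and
two "natural demographic composition" variants) are stored as data — band
rates per sex — and resolved to full 25-age schedules. Two bands the
management descriptions leave unstated are filled with the value that
reproduces the documented male survivorship to age 8+ and the reference
composition, and are tagged `derived`:

- strategy 1 male yearlings: 0.35 (gives ~1% survivorship to 8+);
- strategy 4.B male yearlings: 0.20, matching the 2–7-year band (gives
  10.5%).

For strategy 1 the male bands "0.35 at 2–3, 0.50 at 4+" are applied at
September-ages 1–2 and 3+; only that placement reproduces the reference
young/near-mature/mature stag cells (172 / 25 / 4). The literal placement
remains available through `age_offset=1`.

Strategy 3 is implemented with its stated male 8+ rate of 0.50 even though
the published strategy-3 composition implies a lower internal rate (~0.34):
the package follows the stated rates and treats the affected cells as
unverified. One consequence is that the engine flags strategy 3 (34 mature
stags against a 38-stag requirement) under the one-mature-stag-per-20-hinds
feasibility check; the check is a warning, not an error, for exactly this
kind of boundary case.

## Valuation

The life table collapses to eight classes (female calves/yearlings/adults;
male calves/yearlings; young, near-mature and mature stags). Annual net
benefit in DKK:

    NB = Σ_i m·w_i·h_i + Σ_i r_i·h_i − Σ_i b_i·n_i − α·Σ_i t_i·n_i

Meat (`m` = 20 DKK/kg times carcass weight `w_i`) and recreational values
`r_i` follow the harvest `h_i`; browsing costs `b_i` and traffic costs
`α·t_i` (α = 0.02 collision probability) follow the standing population
`n_i`. The trophy value of old stags is embodied in their large marginal
recreational values (7,272 DKK for mature stags) rather than a separate
term. All benchmark values are producer prices in 2022 DKK; the packaged
table is ingested as final. `normalize_price` (VAT division, default Danish
25%, then net-price-index rescaling) is provided for users bringing raw
consumer prices, and `allocate_by_weight` distributes a per-individual
damage cost across classes linearly in body weight — the published
allocation is weight-proportional only to within ~2%, and the tabulated
values take precedence over re-derivation.

## Decision rules and sensitivity

The strategy with the highest positive NB is recommended. If every NB is
negative, the zero-population alternative (NB = 0) dominates and the
recommendation is extinction; exact ties, including NB = 0 against
extinction, are reported as indifference.

Sensitivity varies one marginal value/cost group at a time — meat `m·w_i`,
recreational `r_i`, browsing `b_i`, traffic `α·t_i`, each scaled
simultaneously across all classes — by ±50% (configurable). NB is linear in
each group, so the bounds satisfy `NB ± factor × group_total` exactly; the
implementation computes them through that identity and a second,
independent path (rescale the parameters, re-evaluate NB) exists as a
cross-check, asserted to 1e-9. Because a grouped variation shifts every
strategy in the same direction, the strategy ranking is invariant under all
eight bounds, which the suite asserts directly.

## Estimators

The cull-based estimator `N = C·L·λ/η` reconstructs a spring population
from bag statistics (C culled, mean harvested age L, annual growth λ, cull
share of deaths η). With the national 2018 inputs (9745, 2.91, 0.971, 0.97)
it gives 28,387 individuals. The collision probability divides the red deer
share of registered deer-vehicle collisions (12,000 × 295/6862 ≈ 515.9,
kept unrounded — truncating to 515 loses the fourth decimal) by that
population: 0.0182. The regional variant of the same chain (C = 3612) gives
10,522 post-season; the reference reports 10,527 pre-/14,144 post-season
from an unstated combination, and the package reports its own formula
values rather than matching those.

## Reference dataset and known inconsistencies

The packaged reference tables (valuation benchmark; population/harvest
composition of the five strategies at a 1000-head spring census; value
components; sensitivity bounds) carry a `verified` flag per cell. Cells the
engine reproduces exactly after integer rounding are verified anchors; the
rest are known only to rounding tolerance. Documented gaps, which the
pipeline flags in its JSON summary instead of absorbing:

- strategy-3 reported NB (296,684) differs from the sum of its own
  components (298,684) by −2,000 DKK; strategy 4.B by 1 DKK of rounding;
- the strategy-2 and strategy-3 sensitivity rows violate the linearity
  identity by ~2,000–9,500 DKK;
- several male harvest cells in the reference composition match total
  deaths `n·q` rather than harvest net of collisions `n·(q − 0.02)`
  (e.g. 44 vs 41 young stags under 4.A), so reference harvest cells are
  treated as ±1–2 tolerance cells, never exact anchors. For the same reason
  the engine's meat/recreational totals sit ~2% below the reference
  component totals while its browsing/traffic totals (population-driven)
  match closely; the decision outcome (implement strategy 3; NB ≈ +297k) is
  unaffected.

## Synthetic scenarios

`ScenarioSpec` draws band-wise hunting rates uniformly within bounds
(default [0, 0.8], keeping schedules clear of the degenerate all-lethal
boundary) and perturbs every benchmark valuation entry by an independent
log-uniform factor in [1/d, d] (default d = 1.5). Generated scenarios
emulate the structure of the real inputs — band-constant rates, calves
unsexed by hunters, positive valuation parameters — but not real hunter
behaviour, bag noise or year-to-year variation; passing property tests
therefore demonstrate internal consistency (conservation, linearity,
pipeline robustness), not empirical calibration. All draws are
deterministic given the seed.

## Numerical choices

- Populations and harvests are computed in floating point and rounded to
  integers only in reports; monetary amounts are rounded to whole DKK with
  Python's banker's rounding.
- The spring-census scaling is a single division, so doubling the target
  exactly doubles every cell.
- Degenerate schedules (no survival past age 0) raise a dedicated error
  rather than producing a zero division.
- Property tests run at problem sizes of 200–1000 random schedules, enough
  to cover the schedule space while keeping the whole suite under a few
  seconds.

## Limitations

No density dependence, carrying capacity, stochastic demography, migration,
discounting or multi-period dynamics; values and costs are constant at the
margin; browsing damage to forestry and non-hunter recreational/existence
values are excluded. The analysis compares population *compositions* at a
fixed census, so absolute NB levels scale linearly with the census target.
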