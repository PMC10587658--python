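# Methods

## Decision problem and structure

The model evaluates point-of-care *CYP2C19* genotyping to guide secondary
stroke prevention in the UK NHS, against universal clopidogrel. A decision
tree resolves, once at model entry, which regimen each patient ends up on;
a five-state Markov cohort model then follows each (genotype, regimen)
sub-cohort in annual cycles from age 67 over a lifetime horizon (to age
100). Costs are £ 2021; outcomes are QALYs; both are discounted at 3.5%
per year; willingness to pay is £20,000/QALY.

The modelled cohort is the estimated 60,424 annual UK first ischaemic
strokes, derived as round(1.07/1000 × 66,436,000) = 71,087 first strokes,
of which 85% (rounded to 60,424) are ischaemic. Rounding is to the nearest
integer at each step.

## Decision tree

Tolerance cascades are resolved at entry: a fraction
`tolerance.clopidogrel` of patients offered clopidogrel stay on it; of the
remainder, `tolerance.mrd_aspirin` settle on modified-release dipyridamole
plus aspirin and the rest on aspirin alone. Carriers in the testing arm
start at the dipyridamole step. The test is assumed perfectly accurate; a
`test_failure_rate` hook (fraction falling back to the untested pathway)
exists but defaults to 0. Switching later in life (time-to-intolerance,
re-testing) is out of scope.

## Markov component

States: no additional stroke, one additional stroke, two or more
additional strokes, vascular death, non-vascular death; everyone enters in
"no additional stroke". With annual recurrence probability *p*,
case-fatality *f* and background mortality *q(age)*:

* vascular death: *p·f*
* next stroke-count state (two-plus recurs into itself): *p·(1 − f)*
* non-vascular death: *(1 − p)·q*
* stay: remainder.

Competing risks are composed in that order — the stroke event is resolved
first and background mortality applies to the stroke-free — as a stated
convention; the source appraisal gives none. *q* is all-cause mortality
used without decrementing the vascular deaths already modelled (a
simplification that slightly double-counts mortality at old ages). The
final cycle, at the horizon age, sets *p* = 0 and *q* = 1 so the cohort is
fully extinct at the horizon; without this closure the event-first
composition would leave a *p·(1 − f)* sliver of stroke survivors alive
past the horizon.

Genotype stratification applies only to clopidogrel: the unstratified
risk `p_stroke_clopidogrel_avg` is split by the mixture identity
(README) using the non-carrier risk ratio 0.702 and prevalence 0.25; at
the defaults this gives 2.79%/yr for non-carriers and 7.53%/yr for
carriers. Recurrence risk from the one-additional and two-plus states is a
single baseline parameter `p_stroke_after_first_recurrence` (on the
unstratified-clopidogrel scale) multiplied by each sub-cohort's relative
first-recurrence risk, so treatment effects persist after a recurrence and
vanish when the risk ratio is 1.

## Costing and QALYs

Start-of-cycle occupancy accrues: the state annual cost (non-disabling for
the no-additional and one-additional states, disabling for two-plus), the
regimen's annual drug cost and adverse-event treatment cost, and the state
utility (0.61 stroke-free; 0.61 − 0.174 = 0.436 for both stroke states —
the decrement is applied once, not cumulatively) minus the expected
adverse-event disutility (probability × disutility for minor bleed, major
bleed and worsening cardiac function; adverse events are per-cycle expected
burdens, not states). Every recurrence event attracts a one-off cost:
non-fatal recurrences are split disabling/non-disabling by
`disabling_fraction`, fatal recurrences and non-stroke deaths have their
own one-off costs. Cycle *t* quantities are discounted by (1 + r)^−t; the
up-front test cost enters undiscounted at cycle 0. No half-cycle
correction by default (a flag enables trapezoidal averaging of the annual
accruals).

## Incremental analysis

Δ = testing − no testing throughout. ICER = ΔC/ΔQ with dominance labels
covering the quadrants where the ratio is meaningless; NHB = ΔQ − ΔC/λ;
NMB = ΔQ·λ − ΔC (so NMB ≡ λ·NHB). Per-patient NHB/NMB are multiplied
unrounded by the cohort size for population totals. Display rounding (£ to
the pound, QALYs to three decimals) never feeds back into arithmetic.
Strokes prevented are undiscounted event-count differences scaled to the
cohort.

## Probabilistic sensitivity analysis

Every registered scalar is redrawn each iteration: beta for probabilities,
proportions and utilities (method-of-moments from mean and SE), gamma for
costs, lognormal for the risk ratio. The appraisal's own distribution
choices are not published, so default dispersions are package assumptions:
SE = 0.10 × mean for beta-like inputs, CV 0.15 for costs, CV 0.10 for the
risk ratio, each overridable per parameter in the YAML `psa.overrides`
block. Parameters at the edge of their support (0 or 1 probability, zero
cost) stay fixed. Transition-matrix rows are never sampled directly — they
are composed from sampled scalars, which induces row uncertainty without a
Dirichlet layer. A master seed spawns independent per-iteration
substreams, so results are reproducible and order-invariant; jointly
infeasible draws (e.g. a carrier risk outside [0, 1]) are resampled within
the iteration's own stream, capped at 100 attempts and counted in the
summary. "Cost-effective" means strictly positive NMB; "cost-saving"
means strictly negative ΔCost.

Because the dispersions are assumptions, the published 77% probability of
cost-effectiveness and 62% of cost-saving are plausibility references, not
reproduction targets; under the defaults here the intervention is
cost-effective in ≈100% of iterations.

## Threshold analysis

One parameter is varied with all else at base case; the boundary of
cost-effectiveness is per-patient NMB = 0 (equivalent to ICER = λ in the
north-east quadrant but defined in all quadrants). Plain bisection stops
when |NMB| ≤ £0.01 (at most 200 steps); if NMB has the same sign at both
bounds the result is "none in range". Any registered scalar is searchable;
the four headline ones are the non-carrier risk ratio, the test cost, and
the two tolerances. The up-front test cost enters the testing arm linearly
and undiscounted, so its threshold has a closed form (base cost plus base
NMB) used as an analytic oracle in the tests.

## Synthetic inputs

No machine-readable inputs accompany the source study, so the fixtures
module generates them. `paper_default` embeds every published point
estimate (unit costs, utilities and disutilities, prevalence 0.25, risk
ratio 0.702, λ, discount rate, start age, cohort size) and fills the
unpublished appraisal inputs with documented assumptions:

| assumption | value | rationale |
| --- | --- | --- |
| stroke risk on dipyridamole + aspirin, aspirin | = unstratified clopidogrel (0.03974/yr) | the comparator drugs are described as similarly effective on average |
| `p_stroke_after_first_recurrence` | 0.06/yr | recurrent-stroke patients carry a higher baseline risk |
| `fatal_stroke_fraction` | 0.20 | plausible case-fatality of recurrent stroke |
| tolerances (clopidogrel, dipyridamole) | 0.95, 0.90 | most patients tolerate; dipyridamole worse (headache) |
| `disabling_fraction` | 0.50 | even split of non-fatal recurrences |
| adverse-event probabilities | 0.8–3.5%/yr per regimen | small, regimen-specific annual rates |

The unstratified clopidogrel risk 0.03974/yr is chosen so the stratified
non-carrier risk is exactly the reported 2.79%/yr (0.702 × 0.03974).

The life table is a synthetic Gompertz fit, hazard a·e^{b·age} with
a = 2×10⁻⁵, b = 0.097, giving annual mortality ≈1.3% at 67 and ≈12% at 90 —
plausible for a UK cohort — closed with q = 1 at age 100. A loader for a
real two-column (age, q) table is provided.

What the synthetic fixtures do **not** emulate: the real appraisal's
transition probabilities and cost mappings, correlated parameter
uncertainty, non-European allele frequencies, TIA index events, and
ticagrelor comparators. Passing tests therefore validate the machinery and
the printed-input arithmetic, not the study's headline increments (£512
saved, 0.107 QALYs), which depend on unpublished inputs; under the default
assumptions here the model lands in the same region (testing dominant,
ΔQ ≈ 0.17, ΔC ≈ −£1,750) and reproduces the qualitative threshold
findings (dipyridamole tolerance never flips the result; clopidogrel
tolerance can fall to a few percent; the risk ratio can approach 1).

## Numerical choices

* Occupancy propagation is exact matrix–vector arithmetic in float64;
  conservation holds to 1e−12 over the 34-cycle horizon.
* Problem sizes in the shipped tests: 1,000 randomized parameter sets for
  the conservation properties; PSA runs of 10–50 iterations in unit tests
  (the engine does ~90 full pipeline runs/second on one core, so the
  published 10,000-iteration design takes about two minutes).
* The null-effect scenario must yield ΔC equal to the up-front test cost
  exactly; the two arms aggregate identical per-regimen outcomes under
  different allocation weights, so equality is asserted to 1e−9 (float
  summation order), which is exact for every displayed digit.
* Ties at ΔCost = 0 count as not cost-saving; NMB = 0 counts as not
  cost-effective (strict inequalities).

## Known limitations

Cohort-level (no microsimulation, no tunnel states); one-time prescribing
decision; all-cause mortality not decremented for modelled vascular
deaths; cardiovascular benefits beyond stroke prevention, TIA populations
and ticagrelor are out of scope; costs fixed at 2021 prices with no
inflation machinery.
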