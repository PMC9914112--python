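# Methods

This note documents the model, the knowledge base, the numerical choices
and the known limitations of `msud-buddy`. It states no number that the
test suite or `scripts/acceptance.py` does not itself compute.

## Clinical setting and scope

Maple syrup urine disease (MSUD) blocks catabolism of the branched-chain
amino acids (BCAAs) leucine, isoleucine and valine. Management in the
first six months of life is entirely dietary: BCAA intake from formula
must stay under age- and weight-dependent caps while protein, energy and
fluid targets are met, and the plan is re-derived every few weeks as the
infant grows. The package covers exactly this window — ages 0–6 months,
weights up to 15 kg, formula feeding only. Solid foods, breast-milk BCAA
content, sick-day protocols and longitudinal record keeping are out of
scope.

## Knowledge base

Two tables ship with the package as CSV, validated on every load:

* **Allowances** (`data/allowances.csv`): per-kg daily values for six
  monthly age bands — isoleucine, leucine, valine (mg/kg), protein (g/kg),
  energy (kcal/kg, 120 in every band) and fluid (mL/kg, 100 in every
  band). Units are per kilogram of body weight per day; absolute
  allowances are these values times the weight. An age in months maps to
  band ⌈age⌉ clamped to [1, 6] (a newborn at age 0 is band 1); fractional
  ages are accepted because reassessment happens at 2–4 week intervals.
* **Formulas** (`data/formulas.csv`): nutrient content per 100 g of powder
  for three commercial formulas (Nan 1, Similac, Aptamil — intact protein,
  hence BCAAs) and three medical formulas (Ketonex-1, Anamix, Comida —
  BCAA-free by definition; the loader rejects a medical row with any
  nonzero BCAA).

Two quirks of the verified tables are shipped **as recorded** rather than
smoothed: Nan 1's BCAA content (106.4/51.6/53.6 mg per 100 g) is an order
of magnitude below Similac's and Aptamil's, and the allowance columns are
not monotone across bands 3→4 (leucine drops 92.5→56 mg/kg). The dosing
arithmetic is agnostic to both; the Nan 1 values do mean its BCAA cap can
exceed 60 scoops at higher weights, in which case the protein-tolerance
flag (below) fires rather than any hard error.

Operational constants live in `data/config.yaml`, all overridable:

| key | default | meaning |
|---|---|---|
| `scoop_grams` | 5 g | the dosing unit (one level scoop of powder) |
| `protein_tolerance` | 0.10 | warning band around the protein target |
| `energy_tolerance` | 0.10 | warning band around the energy target |
| `feeds_per_day_by_band` | 8 (bands 1–3), 6 (bands 4–6) | feeds the daily plan is split over |
| `plasma_bands` | leucine 75–200, isoleucine/valine 200–400 µmol/L | therapeutic windows used by the default rules |

The plasma bands and the feed counts are **configuration, not clinical
authority**: centres must substitute their own targets. The default feed
counts reflect typical newborn (every ~3 h) versus older-infant (every
~4 h) schedules.

## Rule engine

Plasma-driven adjustments run through a single-classification ripple-down
-rules (RDR) tree. Each node holds a conjunction of atomic comparisons
(`==, !=, <, <=, >, >=, present, absent`; a comparison on an absent
attribute is false, so partial cases fall through to defaults), a
conclusion, and the cornerstone case that motivated the rule. Inference
descends to the exception child when the condition holds, to the
alternative child otherwise, and returns the last satisfied node's
conclusion; the always-true root guarantees one. Acquisition attaches a
new rule exactly where inference ended for the misclassified case and is
rejected outright — tree rolled back — if it would change any stored
cornerstone's conclusion, so deployed behaviour never changes silently.
Disjunctions, arithmetic in conditions, and multiple-classification RDR
are deliberately unsupported: the conjunctive language covers every rule
the knowledge base needs and keeps acquisition checkable.

The shipped tree (`data/default_tree.json`) is a conservative placeholder,
not clinical guidance: a plasma BCAA above its configured band halves that
BCAA's allowance (`<bcaa>_factor: 0.5` in the conclusion payload, factors
restricted to (0, 1]) and raises a `consult_dietitian` flag; leucine is
checked first, reflecting its primacy in MSUD management. Whether real
plasma values should modulate allowances multiplicatively, by band
substitution, or only by referral is a genuinely open design point; the
factor mechanism was chosen because it composes with any tree an expert
builds and is trivially auditable in the payload.

## Dosing algorithm

Given the (possibly adjusted) daily allowance, a commercial composition
`c` and a medical composition `m` (per 100 g):

1. **Allocate (continuous).** Commercial grams are the minimum over BCAAs
   with `c_n > 0` of `allowance_n / (c_n / 100)`; the argmin is the
   limiting nutrient (ties break leucine > isoleucine > valine). A
   hypothetical BCAA-free commercial formula is capped by the protein
   target instead. Medical grams fill the remaining protein:
   `max(0, (protein − g_c·c_P/100) / (m_P/100))`. Energy is a checked
   output, not a third allocation variable — two formulas give two degrees
   of freedom, already spent on the BCAA cap and the protein target.
2. **Discretize.** Commercial scoops = ⌊g_c / scoop⌋ — rounding down so
   BCAA delivery cannot exceed the cap — followed by a defensive decrement
   loop in case floating-point rounding of the division chain lands one
   ulp above an allowance. Medical scoops are recomputed from the protein
   left after the *discretized* commercial dose and rounded half-up: the
   medical powder is BCAA-free, so symmetric rounding is safe and protein
   and energy carry the ±10 % tolerance flags. Zero total scoops against a
   positive protein requirement is an infeasibility error advising
   dietitian referral.
3. **Schedule.** Water equals the fluid allowance (interpreted as added
   water; powder displacement volume is ignored) and is split equally over
   the band's feeds; scoops are split as evenly as integers allow, with
   remainders assigned to the earliest feeds.

The scoop policy is equivalent to a lexicographic optimum over whole-scoop
pairs: among BCAA-feasible pairs, take the maximal commercial count, then
the medical count minimizing |delivered protein − target|, with exact
half-scoop ties to the larger count. The test suite checks this
equivalence against an independent exhaustive grid search (the grid
extends past 60 scoops when a low-BCAA formula such as Nan 1 admits more),
alongside the hard safety property (delivered BCAAs ≤ allowance, checked
over 9000 random patient × formula-pair instances), monotonicity of the
continuous commercial dose in weight, scale invariance of the rounding
rule (weight and scoop size doubled together), and zero BCAA delivery for
medical-only plans.

## Synthetic cohort

Property sweeps draw patients uniformly: age 0–6 months, weight 2–10 kg,
plasma values 0–600 µmol/L per BCAA (spanning in-band and out-of-band
levels so both the default and the reduction rules fire). This emulates
the input *space*, not a clinical population: real weights correlate with
age, real plasma values correlate across BCAAs and with intake history,
and real panels arrive with measurement error. Passing sweeps therefore
demonstrate the algebraic safety and optimality of the dosing rules over
the whole input domain, not calibration against patient outcomes.
Cohort sizes (1000 patients × 9 pairs in the sweeps, a few hundred random
trees/cases in the rule-engine checks) were chosen to exercise every
branch combination while keeping the default test run quick.

## Error contract

Validation reports **all** offending fields by name in one error (a panel
missing valine and carrying a negative isoleucine names both); an empty
formula selection raises the literal caregiver-facing message
`Please select formula`; pipeline errors are tagged with the stage that
raised them. The CLI maps any of these to a nonzero exit code, keeps
machine output (JSON) on stdout and diagnostics on stderr, and never
mutates the packaged knowledge base — only user-supplied tree files are
written, and only after a rule is accepted.

## Known limitations

* The shipped adjustment rules and plasma bands are placeholders pending
  centre-specific clinical input; every adjustment carries a
  `consult_dietitian` flag for that reason.
* Energy can drift outside its tolerance for formula pairs whose
  energy-to-protein ratio differs strongly from the allowance's (e.g.
  Comida at 205 kcal/100 g); the plan flags rather than rebalances, since
  no third degree of freedom exists with two powders.
* Height is recorded for completeness but unused by any rule.
* Fluid is treated as water to add; mixed-feed volume is not modelled.
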