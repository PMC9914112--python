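# msud-buddy

Knowledge-based daily formula dosing for infants (0–6 months) with maple
syrup urine disease (MSUD).

MSUD is an inborn error of metabolism in which the three branched-chain
amino acids (BCAAs) — leucine, isoleucine and valine — cannot be
catabolized, so their dietary intake must be strictly capped while protein,
energy and fluid needs are still met. In the first six months of life the
only controllable intake is formula, and caregivers must translate
per-kilogram clinical limits into concrete scoop counts every few weeks as
the infant grows. `msud-buddy` automates that translation: it is a
command-line decision-support tool for caregivers and metabolic dietitians,
built as a ripple-down-rules (RDR) inference engine over a
dietitian-verified nutrition knowledge base.

## The model

For an infant of age *a* months (age band *b* = ⌈*a*⌉ ∈ {1,…,6}) and weight
*w* kg, the daily allowance of each nutrient is the per-kg table value
scaled by weight, e.g. the leucine cap *L* = ℓ_b · *w* (mg/day). A plasma
BCAA panel may tighten the caps via the rule tree (single-classification
RDR: descend to the exception child when a node's condition holds, to the
alternative child otherwise; the last satisfied node's conclusion wins).

The feeding plan uses two powders: a **commercial formula** (the sole BCAA
source, nutrient content *c_n* per 100 g) and a BCAA-free **medical
formula** (protein content *m_P* per 100 g). The continuous allocation is

* commercial grams  g_c = min over BCAAs n with c_n > 0 of  allowance_n / (c_n/100),
* medical grams     g_m = max(0, (protein target − g_c · c_P/100) / (m_P/100)),

and discretization to 5 g scoops rounds the commercial dose **down**
(BCAA delivery must never exceed the cap) and the medical dose to the
nearest scoop (protein and energy carry ±10 % tolerances). Water equals
the daily fluid allowance and the scoops are split across 6–8 feeds per
day. Delivered BCAAs ≤ allowance is a hard invariant, property-tested
against an exhaustive grid-search oracle.

## Worked example

A 3-month-old weighing 5 kg, plasma panel in range (leucine 80,
isoleucine 17, valine 55 µmol/L), fed Similac (commercial) and Ketonex-1
(medical):

```sh
$ msud-buddy recommend --age-months 3 --weight-kg 5 \
    --leucine 80 --isoleucine 17 --valine 55 \
    --commercial Similac --medical Ketonex-1
Recommended daily intake:
  Leucine         462.5 mg
  Isoleucine      280.0 mg
  Valine          322.5 mg
  Protein         15.80 g
  Energy          600.0 kcal
  Fluid           500.0 mL
Daily feeding plan:
  Similac: 8 scoops (40 g)
  Ketonex-1: 15 scoops (75 g)
  Water: 500 mL over 8 feeds
  Delivers: leucine 431.6 mg, isoleucine 229.2 mg, valine 256.4 mg, protein 15.58 g, energy 570.4 kcal
  Limiting nutrient: leucine
```

Reading the numbers: band 3 allows 92.5 mg leucine/kg/day, so this infant
may take 462.5 mg/day; Similac carries 1079 mg leucine per 100 g, capping
it at 42.9 g/day, floored to 8 scoops (40 g, delivering 431.6 ≤ 462.5 mg).
The protein left over (15.8 − 4.33 g) is met with 15 scoops of BCAA-free
Ketonex-1. Delivered energy (570.4 kcal) sits inside the ±10 % band of the
600 kcal target, so no warning flag is raised.

Other surfaces: `msud-buddy limits` shows allowances only (plasma panel
optional), `msud-buddy kb show|validate` inspects the knowledge base,
`msud-buddy rdr trace|add-rule` maintains a rule-tree file with cornerstone
protection, and `msud-buddy tips` prints general caregiver guidance.
Add `--json` for machine-readable output.

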