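"""Dosing core: allowance scaling, plasma-driven adjustment, two-formula
allocation under BCAA constraints, and scoop discretization.

The pipeline turns a validated patient record into a daily feeding plan:

1. ``lookup_allowance`` — per-kg limits for the infant's age band.
2. ``scale_allowance`` — multiply by weight to get absolute daily values.
3. ``apply_plasma_adjustment`` — run the RDR tree on the case; an
   out-of-band plasma BCAA may multiplicatively tighten the corresponding
   allowance and raise a consult-dietitian flag.
4. ``allocate`` — the commercial formula (the only BCAA source) is dosed
   up to the tightest BCAA limit; the BCAA-free medical formula fills the
   remaining protein target.
5. ``discretize`` — convert grams to whole 5 g scoops.  Commercial scoops
   round DOWN (BCAA delivery must never exceed the limit); medical scoops
   round to nearest (protein and energy carry tolerances, so symmetry is
   safe).  Scoops and water are split across the day's feeds.

Safety invariant: delivered leucine, isoleucine and valine never exceed
the (possibly adjusted) daily allowance, by construction and re-checked in
floating point after rounding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Any

from .errors import (
    ConfigurationError,
    InfeasiblePlanError,
    OutOfRangeError,
    StageError,
)
from .intake import FormulaSelection, PatientProfile, PlasmaPanel, to_case
from .kb import BCAAS, FormulaComposition, KBConfig, KnowledgeBase, PerKgAllowance
from .rdr import RDRTree

CONSULT_DIETITIAN = "consult_dietitian"


@dataclass(frozen=True)
class DailyAllowance:
    """Absolute daily limits/targets for one infant (allowance x weight)."""

    isoleucine: float  # mg/day
    leucine: float  # mg/day
    valine: float  # mg/day
    protein: float  # g/day
    energy: float  # kcal/day
    fluid: float  # mL/day
    age_band: int
    adjustment_applied: str | None = None

    def bcaa(self, nutrient: str) -> float:
        return {"leucine": self.leucine, "isoleucine": self.isoleucine, "valine": self.valine}[nutrient]

    def to_dict(self) -> dict[str, Any]:
        return {
            "leucine_mg": self.leucine,
            "isoleucine_mg": self.isoleucine,
            "valine_mg": self.valine,
            "protein_g": self.protein,
            "energy_kcal": self.energy,
            "fluid_ml": self.fluid,
            "age_band": self.age_band,
            "adjustment_applied": self.adjustment_applied,
        }


@dataclass(frozen=True)
class AllocationResult:
    """Continuous (pre-rounding) grams of each powder per day."""

    commercial_grams: float
    medical_grams: float
    limiting_nutrient: str  # "leucine" | "isoleucine" | "valine" | "none"


@dataclass(frozen=True)
class Delivered:
    leucine: float  # mg
    isoleucine: float  # mg
    valine: float  # mg
    protein: float  # g
    energy: float  # kcal

    def to_dict(self) -> dict[str, float]:
        return {
            "leucine_mg": self.leucine,
            "isoleucine_mg": self.isoleucine,
            "valine_mg": self.valine,
            "protein_g": self.protein,
            "energy_kcal": self.energy,
        }


@dataclass(frozen=True)
class Feed:
    commercial_scoops: int
    medical_scoops: int
    water_ml: float


@dataclass(frozen=True)
class FeedingPlan:
    commercial_scoops: int
    medical_scoops: int
    water_ml: float
    feeds_per_day: int
    per_feed: tuple[Feed, ...]
    delivered: Delivered
    flags: tuple[str, ...]
    limiting_nutrient: str
    scoop_grams: float


# ---------------------------------------------------------------------------
# Stage 2: weight scaling
# ---------------------------------------------------------------------------

def scale_allowance(per_kg: PerKgAllowance, weight_kg: float) -> DailyAllowance:
    """Absolute daily allowance: each per-kg field times the weight."""
    if not weight_kg > 0:
        raise OutOfRangeError(f"Weight must be positive, got {weight_kg} kg")
    return DailyAllowance(
        isoleucine=per_kg.isoleucine * weight_kg,
        leucine=per_kg.leucine * weight_kg,
        valine=per_kg.valine * weight_kg,
        protein=per_kg.protein * weight_kg,
        energy=per_kg.energy * weight_kg,
        fluid=per_kg.fluid * weight_kg,
        age_band=per_kg.age_band,
        adjustment_applied=None,
    )


# ---------------------------------------------------------------------------
# Stage 3: plasma-driven adjustment via the RDR tree
# ---------------------------------------------------------------------------

def apply_plasma_adjustment(
    allowance: DailyAllowance,
    profile: PatientProfile,
    panel: PlasmaPanel,
    tree: RDRTree,
) -> tuple[DailyAllowance, list[str], list[str]]:
    """Run the rule tree on the patient case and apply any multiplicative
    BCAA factors its conclusion carries.

    Returns (possibly adjusted allowance, flags, fired rule path).  A
    conclusion with a ``<bcaa>_factor`` payload entry scales that BCAA's
    allowance; any such adjustment also raises the consult-dietitian flag
    because the shipped reduction rules are placeholders, not clinical
    guidance.  The default (root) conclusion leaves the allowance alone.
    """
    case = to_case(profile, panel)
    conclusion, fired_path = tree.infer(case)
    factors: dict[str, float] = {}
    for nutrient in BCAAS:
        key = f"{nutrient}_factor"
        if key in conclusion.payload:
            factor = conclusion.payload[key]
            if not isinstance(factor, (int, float)) or not 0 < factor <= 1:
                raise ConfigurationError(
                    f"Adjustment factor {key} in rule {conclusion.label!r} must lie in (0, 1], got {factor!r}"
                )
            factors[nutrient] = float(factor)
    if not factors:
        return allowance, [], fired_path
    adjusted = replace(
        allowance,
        leucine=allowance.leucine * factors.get("leucine", 1.0),
        isoleucine=allowance.isoleucine * factors.get("isoleucine", 1.0),
        valine=allowance.valine * factors.get("valine", 1.0),
        adjustment_applied=conclusion.label,
    )
    flags = [CONSULT_DIETITIAN, f"adjustment:{conclusion.label}"]
    return adjusted, flags, fired_path


# ---------------------------------------------------------------------------
# Stage 4: continuous allocation
# ---------------------------------------------------------------------------

def allocate(
    allowance: DailyAllowance,
    commercial: FormulaComposition | None,
    medical: FormulaComposition | None,
) -> AllocationResult:
    """Continuous two-formula split.

    Commercial grams are capped by the tightest BCAA limit: the minimum
    over the formula's nonzero BCAA contents of allowance / content-per-
    gram.  A formula with no BCAAs at all is capped by the protein target
    instead (limiting nutrient "none").  The medical formula then fills
    whatever protein remains.  Ties between equally limiting BCAAs break
    leucine > isoleucine > valine, leucine being the amino acid of primary
    concern in MSUD.
    """
    if commercial is not None and commercial.category != "commercial":
        raise ConfigurationError(f"{commercial.name!r} is not a commercial formula")
    if medical is not None and medical.category != "medical":
        raise ConfigurationError(f"{medical.name!r} is not a medical formula")

    if commercial is None:
        commercial_grams, limiting = 0.0, "none"
    else:
        ratios = [
            (allowance.bcaa(b) / (commercial.bcaa(b) / 100.0), b)
            for b in BCAAS
            if commercial.bcaa(b) > 0
        ]
        if ratios:
            best = min(r for r, _ in ratios)
            # tie-break in BCAAS order (leucine first)
            limiting = next(b for r, b in ratios if r == best)
            commercial_grams = best
        else:
            commercial_grams = allowance.protein / (commercial.protein / 100.0)
            limiting = "none"

    remaining_protein = allowance.protein - commercial_grams * (
        (commercial.protein / 100.0) if commercial is not None else 0.0
    )
    if medical is None:
        medical_grams = 0.0
    else:
        if medical.protein <= 0:  # already excluded at KB load; defensive
            raise InfeasiblePlanError(
                f"Medical formula {medical.name!r} has no protein; cannot meet the protein target"
            )
        medical_grams = max(0.0, remaining_protein / (medical.protein / 100.0))
    return AllocationResult(
        commercial_grams=commercial_grams,
        medical_grams=medical_grams,
        limiting_nutrient=limiting,
    )


# ---------------------------------------------------------------------------
# Stage 5: scoop discretization
# ---------------------------------------------------------------------------

def _delivered(
    commercial_scoops: int,
    medical_scoops: int,
    commercial: FormulaComposition | None,
    medical: FormulaComposition | None,
    scoop_grams: float,
) -> Delivered:
    cg = commercial_scoops * scoop_grams
    mg = medical_scoops * scoop_grams
    def tot(attr: str) -> float:
        c = getattr(commercial, attr) if commercial is not None else 0.0
        m = getattr(medical, attr) if medical is not None else 0.0
        return cg * c / 100.0 + mg * m / 100.0
    return Delivered(
        leucine=tot("leucine"),
        isoleucine=tot("isoleucine"),
        valine=tot("valine"),
        protein=tot("protein"),
        energy=tot("energy"),
    )


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def discretize(
    result: AllocationResult,
    allowance: DailyAllowance,
    commercial: FormulaComposition | None,
    medical: FormulaComposition | None,
    config: KBConfig,
    extra_flags: tuple[str, ...] = (),
) -> FeedingPlan:
    """Whole-scoop daily plan from the continuous allocation.

    Commercial scoops floor so BCAA delivery can never exceed the limit
    (and are further decremented if floating-point rounding of the
    continuous cap would let a delivered BCAA exceed its allowance by an
    ulp).  Medical scoops are recomputed from the protein left after the
    *discretized* commercial dose and rounded half-up.  Water equals the
    daily fluid allowance, split evenly over the feeds; scoop remainders go
    to the earliest feeds.
    """
    s = config.scoop_grams
    commercial_scoops = int(math.floor(result.commercial_grams / s)) if commercial is not None else 0
    while commercial_scoops > 0:
        d = _delivered(commercial_scoops, 0, commercial, None, s)
        if all(getattr(d, b) <= allowance.bcaa(b) for b in BCAAS):
            break
        commercial_scoops -= 1

    if medical is not None:
        remaining_protein = allowance.protein - (
            commercial_scoops * s * commercial.protein / 100.0 if commercial is not None else 0.0
        )
        medical_scoops = max(0, _round_half_up(remaining_protein / (medical.protein / 100.0) / s))
    else:
        medical_scoops = 0

    if commercial_scoops + medical_scoops == 0 and allowance.protein > 0:
        raise InfeasiblePlanError(
            "No whole-scoop plan can deliver any nutrition within the BCAA "
            "limits; refer to the metabolic dietitian"
        )

    delivered = _delivered(commercial_scoops, medical_scoops, commercial, medical, s)

    flags = list(extra_flags)
    tol_p = config.protein_tolerance
    tol_e = config.energy_tolerance
    if not (allowance.protein * (1 - tol_p) <= delivered.protein <= allowance.protein * (1 + tol_p)):
        flags.append("protein_outside_tolerance")
    if not (allowance.energy * (1 - tol_e) <= delivered.energy <= allowance.energy * (1 + tol_e)):
        flags.append("energy_outside_tolerance")

    feeds_per_day = config.feeds_per_day_by_band[allowance.age_band]
    water_ml = allowance.fluid
    per_feed = []
    for i in range(feeds_per_day):
        def split(total: int) -> int:
            base, rem = divmod(total, feeds_per_day)
            return base + (1 if i < rem else 0)
        per_feed.append(
            Feed(
                commercial_scoops=split(commercial_scoops),
                medical_scoops=split(medical_scoops),
                water_ml=water_ml / feeds_per_day,
            )
        )

    return FeedingPlan(
        commercial_scoops=commercial_scoops,
        medical_scoops=medical_scoops,
        water_ml=water_ml,
        feeds_per_day=feeds_per_day,
        per_feed=tuple(per_feed),
        delivered=delivered,
        flags=tuple(flags),
        limiting_nutrient=result.limiting_nutrient,
        scoop_grams=s,
    )


# ---------------------------------------------------------------------------
# Composition
# ---------------------------------------------------------------------------

def recommend(
    profile: PatientProfile,
    panel: PlasmaPanel,
    selection: FormulaSelection,
    kb: KnowledgeBase,
    tree: RDRTree,
) -> tuple[FeedingPlan, DailyAllowance, list[str]]:
    """Full pipeline; returns (plan, adjusted daily allowance, RDR path).

    Errors from each stage propagate wrapped in :class:`StageError` so the
    caller can see where the pipeline failed.
    """
    def stage(name: str, fn, *args):
        try:
            return fn(*args)
        except StageError:
            raise
        except Exception as exc:
            raise StageError(name, exc) from exc

    per_kg = stage("lookup_allowance", kb.lookup_allowance, profile.age_months)
    base = stage("scale_allowance", scale_allowance, per_kg, profile.weight_kg)
    allowance, flags, rdr_path = stage(
        "apply_plasma_adjustment", apply_plasma_adjustment, base, profile, panel, tree
    )
    commercial = (
        stage("lookup_formula", kb.lookup_formula, selection.commercial_name)
        if selection.commercial_name is not None
        else None
    )
    medical = (
        stage("lookup_formula", kb.lookup_formula, selection.medical_name)
        if selection.medical_name is not None
        else None
    )
    allocation = stage("allocate", allocate, allowance, commercial, medical)
    plan = stage(
        "discretize", discretize, allocation, allowance, commercial, medical, kb.config, tuple(flags)
    )
    return plan, allowance, rdr_path


def plan_to_document(
    plan: FeedingPlan,
    allowance: DailyAllowance,
    selection: FormulaSelection,
    rdr_path: list[str],
) -> dict[str, Any]:
    """JSON-ready plan document (the machine output of the CLI)."""
    s = plan.scoop_grams
    return {
        "allowance": allowance.to_dict(),
        "plan": {
            "commercial": {
                "name": selection.commercial_name,
                "scoops": plan.commercial_scoops,
                "grams": plan.commercial_scoops * s,
            },
            "medical": {
                "name": selection.medical_name,
                "scoops": plan.medical_scoops,
                "grams": plan.medical_scoops * s,
            },
            "scoop_grams": s,
            "water_ml": plan.water_ml,
            "feeds_per_day": plan.feeds_per_day,
            "limiting_nutrient": plan.limiting_nutrient,
            "feeds": [
                {
                    "commercial_scoops": f.commercial_scoops,
                    "medical_scoops": f.medical_scoops,
                    "water_ml": f.water_ml,
                }
                for f in plan.per_feed
            ],
        },
        "delivered": plan.delivered.to_dict(),
        "flags": list(plan.flags),
        "rdr_path": list(rdr_path),
    }
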