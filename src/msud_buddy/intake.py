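"""Patient-facing inputs: profile, plasma BCAA panel, formula selection.

Validation follows an all-offending-fields contract: every invalid or
missing field is reported by name in a single error, and the empty formula
selection produces the literal caregiver-facing message
``Please select formula``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Any

from .errors import FieldValidationError, OutOfRangeError, SchemaError, SelectionError
from .kb import BCAAS, KnowledgeBase
from .rdr import Case

PLEASE_SELECT_FORMULA = "Please select formula"


@dataclass(frozen=True)
class PatientProfile:
    """Infant biometrics.  Height is recorded but plays no role in dosing."""

    age_months: float
    weight_kg: float
    height_cm: float | None = None

    def __post_init__(self) -> None:
        problems: dict[str, str] = {}
        if not isinstance(self.age_months, (int, float)) or math.isnan(self.age_months):
            problems["age_months"] = f"must be a number, got {self.age_months!r}"
        elif not 0 <= self.age_months <= 6:
            problems["age_months"] = (
                f"{self.age_months} is outside the supported span (0 to 6 months)"
            )
        if not isinstance(self.weight_kg, (int, float)) or math.isnan(self.weight_kg):
            problems["weight_kg"] = f"must be a number, got {self.weight_kg!r}"
        elif not 0 < self.weight_kg <= 15:
            problems["weight_kg"] = f"{self.weight_kg} is outside the supported span (0 to 15 kg)"
        if problems:
            raise OutOfRangeError(
                "Invalid patient profile: "
                + "; ".join(f"{k}: {v}" for k, v in problems.items())
            )


@dataclass(frozen=True)
class PlasmaPanel:
    """Plasma BCAA concentrations in umol/L; fields may be absent (None)."""

    leucine: float | None = None
    isoleucine: float | None = None
    valine: float | None = None

    def values(self) -> dict[str, float | None]:
        return {"leucine": self.leucine, "isoleucine": self.isoleucine, "valine": self.valine}

    def is_empty(self) -> bool:
        return all(v is None for v in self.values().values())


@dataclass(frozen=True)
class FormulaSelection:
    commercial_name: str | None = None
    medical_name: str | None = None


def validate_panel(panel: PlasmaPanel) -> PlasmaPanel:
    """Require a fully present, finite, nonnegative panel.

    All offending fields are listed in one :class:`FieldValidationError`,
    not just the first, so the caregiver can fix the whole form at once.
    """
    problems: dict[str, str] = {}
    for name, value in panel.values().items():
        if value is None:
            problems[name] = "missing value"
        elif not isinstance(value, (int, float)) or not math.isfinite(value):
            problems[name] = f"must be a finite number, got {value!r}"
        elif value < 0:
            problems[name] = f"must be >= 0 umol/L, got {value}"
    if problems:
        raise FieldValidationError(problems, prefix="Invalid plasma panel")
    return panel


def validate_selection(selection: FormulaSelection, kb: KnowledgeBase) -> FormulaSelection:
    """Resolve formula names against the KB and check category slots.

    An empty selection raises with the literal message
    ``Please select formula``; a name in the wrong slot (e.g. a medical
    formula passed as the commercial choice) is a category-mismatch error.
    """
    if selection.commercial_name is None and selection.medical_name is None:
        raise SelectionError(PLEASE_SELECT_FORMULA)
    resolved: dict[str, str | None] = {"commercial": None, "medical": None}
    for slot, name in (
        ("commercial", selection.commercial_name),
        ("medical", selection.medical_name),
    ):
        if name is None:
            continue
        formula = kb.lookup_formula(name)  # raises UnknownFormulaError
        if formula.category != slot:
            raise SelectionError(
                f"Category mismatch: {formula.name!r} is a {formula.category} formula "
                f"but was selected in the {slot} slot"
            )
        resolved[slot] = formula.name
    return FormulaSelection(
        commercial_name=resolved["commercial"], medical_name=resolved["medical"]
    )


def to_case(
    profile: PatientProfile,
    panel: PlasmaPanel,
    selection: FormulaSelection | None = None,
) -> Case:
    """Flatten validated inputs into an RDR :class:`Case`.

    Absent fields are omitted (never encoded as 0); height is recorded on
    the profile but deliberately excluded — no dosing rule uses it.
    """
    attrs: dict[str, Any] = {
        "age_months": profile.age_months,
        "weight_kg": profile.weight_kg,
    }
    for name, value in panel.values().items():
        if value is not None:
            attrs[f"plasma_{name}"] = value
    if selection is not None:
        if selection.commercial_name is not None:
            attrs["commercial_formula"] = selection.commercial_name
        if selection.medical_name is not None:
            attrs["medical_formula"] = selection.medical_name
    return Case(attrs)


# ---------------------------------------------------------------------------
# Patient JSON document
# ---------------------------------------------------------------------------
#
# {"age_months": number, "weight_kg": number, "height_cm": number|null,
#  "plasma": {"leucine": n, "isoleucine": n, "valine": n},
#  "formulas": {"commercial": s|null, "medical": s|null}}

_TOP_KEYS = {"age_months", "weight_kg", "height_cm", "plasma", "formulas"}


def parse_patient_document(
    document: dict[str, Any],
) -> tuple[PatientProfile, PlasmaPanel, FormulaSelection]:
    """Parse (without cross-validating) a stored patient record.

    ``plasma``/``formulas`` sections and ``height_cm`` may be omitted or
    null; panel completeness and formula resolution are checked separately
    so the record can also serve the limits-only display.
    """
    if not isinstance(document, dict):
        raise SchemaError("$", "expected an object")
    unknown = set(document) - _TOP_KEYS
    if unknown:
        raise SchemaError(f"$.{sorted(unknown)[0]}", "unknown key")
    for key in ("age_months", "weight_kg"):
        if key not in document:
            raise SchemaError(f"$.{key}", "missing required key")
        if not isinstance(document[key], (int, float)):
            raise SchemaError(f"$.{key}", f"expected a number, got {document[key]!r}")
    height = document.get("height_cm")
    if height is not None and not isinstance(height, (int, float)):
        raise SchemaError("$.height_cm", f"expected a number or null, got {height!r}")
    profile = PatientProfile(
        age_months=float(document["age_months"]),
        weight_kg=float(document["weight_kg"]),
        height_cm=float(height) if height is not None else None,
    )

    plasma_raw = document.get("plasma") or {}
    if not isinstance(plasma_raw, dict):
        raise SchemaError("$.plasma", "expected an object")
    unknown = set(plasma_raw) - set(BCAAS)
    if unknown:
        raise SchemaError(f"$.plasma.{sorted(unknown)[0]}", "unknown key")
    panel_kwargs = {}
    for name in BCAAS:
        v = plasma_raw.get(name)
        if v is not None and not isinstance(v, (int, float)):
            raise SchemaError(f"$.plasma.{name}", f"expected a number or null, got {v!r}")
        panel_kwargs[name] = float(v) if v is not None else None
    panel = PlasmaPanel(**panel_kwargs)

    formulas_raw = document.get("formulas") or {}
    if not isinstance(formulas_raw, dict):
        raise SchemaError("$.formulas", "expected an object")
    unknown = set(formulas_raw) - {"commercial", "medical"}
    if unknown:
        raise SchemaError(f"$.formulas.{sorted(unknown)[0]}", "unknown key")
    selection = FormulaSelection(
        commercial_name=formulas_raw.get("commercial"),
        medical_name=formulas_raw.get("medical"),
    )
    return profile, panel, selection


def load_patient_file(path: str | Path) -> tuple[PatientProfile, PlasmaPanel, FormulaSelection]:
    try:
        document = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise SchemaError("$", f"not valid JSON: {exc}") from exc
    return parse_patient_document(document)
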