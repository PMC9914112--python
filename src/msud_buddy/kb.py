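"""Nutrition knowledge base: per-age daily allowances and formula
compositions, plus the operational configuration.

The packaged tables hold the dietitian-verified ground truth for infants
0-6 months with MSUD: six monthly age bands of per-kg daily limits for the
three branched-chain amino acids (BCAAs) plus protein/energy/fluid
targets, and the nutrient content per 100 g of powder for three commercial
and three BCAA-free medical formulas.

Two quirks of the verified tables are shipped exactly as the dietitians
recorded them rather than "corrected": Nan 1's BCAA content is an order of
magnitude below the other commercial formulas, and the allowance columns
are not monotone across bands 3 -> 4.  Both are documented in
docs/methods.md.
"""

from __future__ import annotations

import math
import unicodedata
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import IO, Any, Union

import pandas as pd
import yaml

from .errors import ConfigurationError, KBLoadError, OutOfRangeError, UnknownFormulaError

Source = Union[str, Path, IO[str]]

BCAAS = ("leucine", "isoleucine", "valine")

ALLOWANCE_COLUMNS = [
    "age_band",
    "isoleucine_mg_per_kg",
    "leucine_mg_per_kg",
    "valine_mg_per_kg",
    "protein_g_per_kg",
    "energy_kcal_per_kg",
    "fluid_ml_per_kg",
]
FORMULA_COLUMNS = [
    "name",
    "category",
    "leucine_mg_per_100g",
    "isoleucine_mg_per_100g",
    "valine_mg_per_100g",
    "protein_g_per_100g",
    "energy_kcal_per_100g",
]


@dataclass(frozen=True)
class PerKgAllowance:
    """Daily per-kg limits/targets for one monthly age band (1-6)."""

    age_band: int
    isoleucine: float  # mg/kg/day
    leucine: float  # mg/kg/day
    valine: float  # mg/kg/day
    protein: float  # g/kg/day
    energy: float  # kcal/kg/day
    fluid: float  # mL/kg/day


@dataclass(frozen=True)
class FormulaComposition:
    """Nutrient content per 100 g of powder for a named formula."""

    name: str
    category: str  # "commercial" | "medical"
    leucine: float  # mg/100 g
    isoleucine: float  # mg/100 g
    valine: float  # mg/100 g
    protein: float  # g/100 g
    energy: float  # kcal/100 g

    def bcaa(self, nutrient: str) -> float:
        return {"leucine": self.leucine, "isoleucine": self.isoleucine, "valine": self.valine}[nutrient]


@dataclass(frozen=True)
class PlasmaBand:
    """Therapeutic plasma window (umol/L): below low_max is low, above
    high_min is high."""

    low_max: float
    high_min: float


@dataclass(frozen=True)
class KBConfig:
    scoop_grams: float = 5.0
    protein_tolerance: float = 0.10
    energy_tolerance: float = 0.10
    feeds_per_day_by_band: dict[int, int] = field(
        default_factory=lambda: {1: 8, 2: 8, 3: 8, 4: 6, 5: 6, 6: 6}
    )
    plasma_bands: dict[str, PlasmaBand] = field(
        default_factory=lambda: {
            "leucine": PlasmaBand(75, 200),
            "isoleucine": PlasmaBand(200, 400),
            "valine": PlasmaBand(200, 400),
        }
    )

    def __post_init__(self) -> None:
        if not self.scoop_grams > 0:
            raise ConfigurationError(f"scoop_grams must be > 0, got {self.scoop_grams}")
        for name in ("protein_tolerance", "energy_tolerance"):
            tol = getattr(self, name)
            if not 0 < tol < 0.5:
                raise ConfigurationError(f"{name} must lie in (0, 0.5), got {tol}")
        for band, feeds in self.feeds_per_day_by_band.items():
            if feeds < 1:
                raise ConfigurationError(f"feeds_per_day for band {band} must be >= 1, got {feeds}")


def _normalize_name(name: str) -> str:
    """Case-fold and strip trademark glyphs/diacritic junk for matching."""
    cleaned = []
    for ch in unicodedata.normalize("NFKD", name):
        if ch in "®™©^":  # (R), TM, (C), caret markup
            continue
        cleaned.append(ch)
    return "".join(cleaned).strip().casefold()


class KnowledgeBase:
    """Validated allowance table, formula table, and config."""

    def __init__(
        self,
        allowances: dict[int, PerKgAllowance],
        formulas: list[FormulaComposition],
        config: KBConfig,
    ):
        self.allowances = allowances
        self.formulas = formulas
        self.config = config
        self._by_name = {_normalize_name(f.name): f for f in formulas}

    # -- lookups -----------------------------------------------------------

    def lookup_allowance(self, age_months: float) -> PerKgAllowance:
        """Per-kg allowance record for the band containing ``age_months``.

        Bands are monthly: band = ceil(age) clamped to [1, 6]; a newborn
        (age 0) falls in band 1.  Fractional ages are accepted because the
        plan is re-derived every few weeks as the infant grows.
        """
        if not (0 <= age_months <= 6) or math.isnan(age_months):
            raise OutOfRangeError(
                f"Age {age_months} months is outside the supported span (0 to 6 months)"
            )
        band = min(6, max(1, math.ceil(age_months)))
        return self.allowances[band]

    def lookup_formula(self, name: str) -> FormulaComposition:
        key = _normalize_name(name)
        if key not in self._by_name:
            raise UnknownFormulaError(name, [f.name for f in self.formulas])
        return self._by_name[key]

    def formula_names(self, category: str | None = None) -> list[str]:
        return [f.name for f in self.formulas if category is None or f.category == category]

    def feeds_per_day(self, age_months: float) -> int:
        band = self.lookup_allowance(age_months).age_band
        return self.config.feeds_per_day_by_band[band]

    # -- frames for display ------------------------------------------------

    def allowance_frame(self) -> pd.DataFrame:
        rows = [
            {
                "age_band": a.age_band,
                "isoleucine_mg_per_kg": a.isoleucine,
                "leucine_mg_per_kg": a.leucine,
                "valine_mg_per_kg": a.valine,
                "protein_g_per_kg": a.protein,
                "energy_kcal_per_kg": a.energy,
                "fluid_ml_per_kg": a.fluid,
            }
            for a in self.allowances.values()
        ]
        return pd.DataFrame(rows, columns=ALLOWANCE_COLUMNS).sort_values("age_band").reset_index(drop=True)

    def formula_frame(self) -> pd.DataFrame:
        rows = [
            {
                "name": f.name,
                "category": f.category,
                "leucine_mg_per_100g": f.leucine,
                "isoleucine_mg_per_100g": f.isoleucine,
                "valine_mg_per_100g": f.valine,
                "protein_g_per_100g": f.protein,
                "energy_kcal_per_100g": f.energy,
            }
            for f in self.formulas
        ]
        return pd.DataFrame(rows, columns=FORMULA_COLUMNS)


# ---------------------------------------------------------------------------
# Loading & validation
# ---------------------------------------------------------------------------

def _read_csv(source: Source, expected_columns: list[str], what: str) -> pd.DataFrame:
    try:
        df = pd.read_csv(source)
    except Exception as exc:
        raise KBLoadError(f"Could not read {what} table: {exc}") from exc
    if list(df.columns) != expected_columns:
        raise KBLoadError(
            f"{what} table has wrong header: expected {expected_columns}, got {list(df.columns)}"
        )
    return df


def _load_allowances(source: Source) -> dict[int, PerKgAllowance]:
    df = _read_csv(source, ALLOWANCE_COLUMNS, "allowance")
    records: dict[int, PerKgAllowance] = {}
    for i, row in df.iterrows():
        band = row["age_band"]
        if not float(band).is_integer() or not 1 <= int(band) <= 6:
            raise KBLoadError(f"allowance row {i}: age_band must be an integer in 1..6, got {band}")
        band = int(band)
        if band in records:
            raise KBLoadError(f"allowance row {i}: duplicate age_band {band}")
        values = {}
        for col, attr in [
            ("isoleucine_mg_per_kg", "isoleucine"),
            ("leucine_mg_per_kg", "leucine"),
            ("valine_mg_per_kg", "valine"),
            ("protein_g_per_kg", "protein"),
            ("energy_kcal_per_kg", "energy"),
            ("fluid_ml_per_kg", "fluid"),
        ]:
            v = float(row[col])
            if not v > 0 or not math.isfinite(v):
                raise KBLoadError(f"allowance row {i} (band {band}): field {col} must be strictly positive, got {v}")
            values[attr] = v
        records[band] = PerKgAllowance(age_band=band, **values)
    missing = sorted(set(range(1, 7)) - set(records))
    if missing:
        raise KBLoadError(f"allowance table is missing age band(s) {missing}; all of 1..6 are required")
    return records


def _load_formulas(source: Source) -> list[FormulaComposition]:
    df = _read_csv(source, FORMULA_COLUMNS, "formula")
    formulas: list[FormulaComposition] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        name = str(row["name"]).strip()
        if not name:
            raise KBLoadError(f"formula row {i}: field name must be non-empty")
        key = _normalize_name(name)
        if key in seen:
            raise KBLoadError(f"formula row {i}: duplicate formula name {name!r}")
        seen.add(key)
        category = str(row["category"]).strip()
        if category not in ("commercial", "medical"):
            raise KBLoadError(
                f"formula row {i} ({name}): field category must be 'commercial' or 'medical', got {category!r}"
            )
        values = {}
        for col, attr in [
            ("leucine_mg_per_100g", "leucine"),
            ("isoleucine_mg_per_100g", "isoleucine"),
            ("valine_mg_per_100g", "valine"),
            ("protein_g_per_100g", "protein"),
            ("energy_kcal_per_100g", "energy"),
        ]:
            v = float(row[col])
            if not math.isfinite(v) or v < 0:
                raise KBLoadError(f"formula row {i} ({name}): field {col} must be finite and >= 0, got {v}")
            values[attr] = v
        if category == "medical" and any(values[b] != 0 for b in BCAAS):
            raise KBLoadError(
                f"formula row {i} ({name}): medical formulas must be BCAA-free, "
                f"got leucine={values['leucine']}, isoleucine={values['isoleucine']}, valine={values['valine']}"
            )
        for col, attr in (("protein_g_per_100g", "protein"), ("energy_kcal_per_100g", "energy")):
            if not values[attr] > 0:
                raise KBLoadError(f"formula row {i} ({name}): field {col} must be strictly positive")
        formulas.append(FormulaComposition(name=name, category=category, **values))
    return formulas


def _load_config(source: Source | None) -> KBConfig:
    if source is None:
        return KBConfig()
    if hasattr(source, "read"):
        raw = yaml.safe_load(source.read())
    else:
        raw = yaml.safe_load(Path(source).read_text())
    if raw is None:
        return KBConfig()
    if not isinstance(raw, dict):
        raise ConfigurationError("config file must contain a mapping")
    kwargs: dict[str, Any] = {}
    known = {"scoop_grams", "protein_tolerance", "energy_tolerance", "feeds_per_day_by_band", "plasma_bands"}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config key(s): {sorted(unknown)}")
    for key in ("scoop_grams", "protein_tolerance", "energy_tolerance"):
        if key in raw:
            kwargs[key] = float(raw[key])
    if "feeds_per_day_by_band" in raw:
        kwargs["feeds_per_day_by_band"] = {int(k): int(v) for k, v in raw["feeds_per_day_by_band"].items()}
    if "plasma_bands" in raw:
        bands = {}
        for nutrient, spec in raw["plasma_bands"].items():
            if nutrient not in BCAAS:
                raise ConfigurationError(f"plasma_bands: unknown nutrient {nutrient!r}")
            bands[nutrient] = PlasmaBand(float(spec["low_max"]), float(spec["high_min"]))
        kwargs["plasma_bands"] = bands
    return KBConfig(**kwargs)


def load_kb(
    allowance_source: Source | None = None,
    formula_source: Source | None = None,
    config_source: Source | None = None,
) -> KnowledgeBase:
    """Load and validate the knowledge base.

    Any source left as ``None`` falls back to the packaged, dietitian-
    verified default.  Every type invariant is checked at load time; a
    violation raises :class:`KBLoadError` naming the row and field.
    """
    data = resources.files("msud_buddy") / "data"
    if allowance_source is None:
        with resources.as_file(data / "allowances.csv") as p:
            allowances = _load_allowances(p)
    else:
        allowances = _load_allowances(allowance_source)
    if formula_source is None:
        with resources.as_file(data / "formulas.csv") as p:
            formulas = _load_formulas(p)
    else:
        formulas = _load_formulas(formula_source)
    if config_source is None:
        with resources.as_file(data / "config.yaml") as p:
            config = _load_config(p)
    else:
        config = _load_config(config_source)
    return KnowledgeBase(allowances, formulas, config)


def packaged_tips() -> str:
    """The static caregiver health-tips text shipped with the package."""
    return (resources.files("msud_buddy") / "data" / "tips.txt").read_text()
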