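"""Reading, validation and cleaning of packaged-food product records.

Products enter as CSV (RFC 4180, UTF-8, header row) or JSON-lines rows
carrying on-pack information: an ingredient list and a nutrition panel
(energy, total fat, saturated fat, carbohydrate, fiber, total sugars,
protein, sodium), all normalized to a per-100 g basis.  Cleaning keeps
only products whose panel is internally consistent -- the same
"complete information available on-pack" standard a food-supply
surveillance pipeline needs before any modelling.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "NutrientPanel",
    "ProductRecord",
    "CleaningRules",
    "Rejection",
    "NUTRIENT_COLUMNS",
    "read_products",
    "write_products",
    "normalize_to_100g",
    "clean_products",
    "write_rejection_report",
]

#: Canonical panel column names, in feature order.  Sodium stays in mg.
NUTRIENT_COLUMNS = (
    "energy_kcal",
    "total_fat",
    "saturated_fat",
    "carbohydrate",
    "fiber",
    "total_sugars",
    "protein",
    "sodium_mg",
)

_META_COLUMNS = (
    "product_id",
    "market",
    "category",
    "sub_category",
    "launch_year",
    "serving_size_g",
    "ingredient_text",
)

KJ_PER_KCAL = 4.184


@dataclass(frozen=True)
class NutrientPanel:
    """Nutrition-facts panel per 100 g of product.

    Energy in kcal, sodium in mg, every other nutrient in g.
    """

    energy_kcal: float
    total_fat: float
    saturated_fat: float
    carbohydrate: float
    fiber: float
    total_sugars: float
    protein: float
    sodium_mg: float

    def as_tuple(self) -> tuple[float, ...]:
        return tuple(getattr(self, c) for c in NUTRIENT_COLUMNS)

    def as_dict(self) -> dict[str, float]:
        return {c: getattr(self, c) for c in NUTRIENT_COLUMNS}


@dataclass(frozen=True)
class ProductRecord:
    """One packaged food or beverage as captured from its label."""

    product_id: str
    market: str
    category: str
    sub_category: str
    launch_year: int
    serving_size_g: float
    ingredient_text: str
    panel: NutrientPanel
    declared_added_sugars: float | None = None
    claims: frozenset[str] = field(default_factory=frozenset)


@dataclass(frozen=True)
class Rejection:
    product_id: str
    reason: str


@dataclass(frozen=True)
class CleaningRules:
    """Configurable completeness/consistency filter.

    ``tol_g`` absorbs label rounding in the pairwise nutrient checks;
    ``energy_rel_tol`` is the relative tolerance of the Atwater 4/9/4
    energy-consistency check (fiber not counted separately); the macro
    sum cap allows slight double counting on real labels.
    """

    tol_g: float = 0.5
    macro_sum_max_g: float = 105.0
    energy_rel_tol: float = 0.25
    year_min: int = 2014
    year_max: int = 2024
    require_ingredients: bool = True


def atwater_energy(panel: NutrientPanel) -> float:
    """4/9/4 kcal per g of carbohydrate / fat / protein."""
    return 4.0 * panel.carbohydrate + 9.0 * panel.total_fat + 4.0 * panel.protein


def panel_violations(panel: NutrientPanel, rules: CleaningRules | None = None) -> list[str]:
    """Return every panel-invariant violation, in check order."""
    rules = rules or CleaningRules()
    out: list[str] = []
    values = panel.as_tuple()
    if any(v is None or (isinstance(v, float) and math.isnan(v)) for v in values):
        return ["missing nutrient"]
    if not all(math.isfinite(v) for v in values):
        return ["non-finite nutrient"]
    if any(v < 0 for v in values):
        out.append("negative nutrient")
    if panel.saturated_fat > panel.total_fat + rules.tol_g:
        out.append("saturated fat exceeds total fat")
    if panel.total_sugars > panel.carbohydrate + rules.tol_g:
        out.append("sugars exceed carbohydrate")
    if panel.fiber > panel.carbohydrate + rules.tol_g:
        out.append("fiber exceeds carbohydrate")
    if panel.total_fat + panel.carbohydrate + panel.protein > rules.macro_sum_max_g:
        out.append("macronutrient sum exceeds cap")
    expected = atwater_energy(panel)
    if abs(panel.energy_kcal - expected) > rules.energy_rel_tol * max(panel.energy_kcal, 1e-9):
        # zero-energy waters pass: expected is then also ~0
        if not (panel.energy_kcal == 0 and expected <= rules.tol_g):
            out.append("energy inconsistent with macronutrients")
    return out


def normalize_to_100g(values: Mapping[str, float], serving_size_g: float) -> NutrientPanel:
    """Rescale per-serving nutrient amounts to a per-100 g panel.

    Linear in the nutrient vector (degree 1) and inverse in serving
    size; unit conventions are preserved (sodium stays mg).
    """
    if not (serving_size_g > 0) or not math.isfinite(serving_size_g):
        raise ValueError(f"invalid serving size: {serving_size_g!r}")
    scale = 100.0 / serving_size_g
    missing = [c for c in NUTRIENT_COLUMNS if c not in values]
    if missing:
        raise KeyError(f"missing nutrient fields: {missing}")
    return NutrientPanel(**{c: float(values[c]) * scale for c in NUTRIENT_COLUMNS})


def _parse_claims(raw) -> frozenset[str]:
    if raw is None or (isinstance(raw, float) and math.isnan(raw)):
        return frozenset()
    if isinstance(raw, str):
        return frozenset(c.strip() for c in raw.split("|") if c.strip())
    return frozenset(str(c).strip() for c in raw if str(c).strip())


def _record_from_row(row: Mapping[str, object]) -> ProductRecord:
    nutrients = {}
    for col in NUTRIENT_COLUMNS:
        raw = row.get(col)
        if raw is None or raw == "":
            nutrients[col] = float("nan")
        else:
            nutrients[col] = float(raw)  # may raise ValueError -> row rejection
    declared = row.get("declared_added_sugars")
    if declared in (None, ""):
        declared_val = None
    else:
        declared_val = float(declared)
        if isinstance(declared_val, float) and math.isnan(declared_val):
            declared_val = None
    year_raw = row.get("launch_year")
    return ProductRecord(
        product_id=str(row.get("product_id", "")),
        market=str(row.get("market", "")),
        category=str(row.get("category", "")),
        sub_category=str(row.get("sub_category", "")),
        launch_year=int(float(year_raw)) if year_raw not in (None, "") else 0,
        serving_size_g=float(row.get("serving_size_g", 0) or 0),
        ingredient_text=str(row.get("ingredient_text") or ""),
        panel=NutrientPanel(**nutrients),
        declared_added_sugars=declared_val,
        claims=_parse_claims(row.get("claims")),
    )


def read_products(
    path: str | Path,
    dialect: str = "auto",
    column_map: Mapping[str, str] | None = None,
) -> tuple[list[ProductRecord], list[Rejection]]:
    """Read product records from CSV or JSON-lines.

    ``column_map`` maps canonical field names to the file's column
    names.  Rows with unparseable numerics are rejected with a reason,
    never raised; a missing mandatory column is a configuration error.
    Row order is preserved.
    """
    path = Path(path)
    if dialect == "auto":
        dialect = "jsonl" if path.suffix in {".jsonl", ".ndjson", ".json"} else "csv"
    if dialect == "csv":
        frame = pd.read_csv(path, dtype=object, keep_default_na=False)
    elif dialect == "jsonl":
        with open(path, "r", encoding="utf-8") as fh:
            rows = [json.loads(line) for line in fh if line.strip()]
        frame = pd.DataFrame(rows, dtype=object)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")

    if column_map:
        missing_src = [src for src in column_map.values() if src not in frame.columns]
        if missing_src:
            raise KeyError(f"column mapping refers to absent columns: {missing_src}")
        frame = frame.rename(columns={v: k for k, v in column_map.items()})

    mandatory = set(_META_COLUMNS) | set(NUTRIENT_COLUMNS)
    absent = sorted(mandatory - set(frame.columns))
    if absent:
        raise KeyError(f"missing mandatory columns: {absent}")

    records: list[ProductRecord] = []
    rejections: list[Rejection] = []
    for _, row in frame.iterrows():
        row_d = row.to_dict()
        pid = str(row_d.get("product_id", ""))
        try:
            rec = _record_from_row(row_d)
        except (ValueError, TypeError):
            rejections.append(Rejection(pid, "unparseable numeric"))
            continue
        if any(math.isnan(v) for v in rec.panel.as_tuple()):
            rejections.append(Rejection(pid, "missing nutrient"))
            continue
        records.append(rec)
    return records, rejections


def record_to_row(record: ProductRecord) -> dict[str, object]:
    row: dict[str, object] = {
        "product_id": record.product_id,
        "market": record.market,
        "category": record.category,
        "sub_category": record.sub_category,
        "launch_year": record.launch_year,
        "serving_size_g": record.serving_size_g,
        "ingredient_text": record.ingredient_text,
    }
    row.update(record.panel.as_dict())
    row["declared_added_sugars"] = record.declared_added_sugars
    row["claims"] = "|".join(sorted(record.claims))
    return row


def write_products(records: Iterable[ProductRecord], path: str | Path, dialect: str = "auto") -> None:
    """Write records as canonical CSV or JSON-lines (round-trips with read)."""
    path = Path(path)
    if dialect == "auto":
        dialect = "jsonl" if path.suffix in {".jsonl", ".ndjson", ".json"} else "csv"
    rows = [record_to_row(r) for r in records]
    if dialect == "csv":
        pd.DataFrame(rows).to_csv(path, index=False)
    elif dialect == "jsonl":
        with open(path, "w", encoding="utf-8") as fh:
            for row in rows:
                fh.write(json.dumps(row) + "\n")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")


def clean_products(
    records: Sequence[ProductRecord],
    rules: CleaningRules | None = None,
) -> tuple[list[ProductRecord], list[Rejection]]:
    """Partition records into kept and rejected-with-reason.

    Kept records satisfy every panel invariant, carry at least one
    parseable ingredient, fall inside the launch-year window and pass
    the Atwater energy-consistency check.  Filtering never raises; the
    kept/rejected lists partition the input and preserve order.
    Idempotent: cleaning the kept list again keeps everything.
    """
    from .ingredient_tagger import parse_ingredient_list

    rules = rules or CleaningRules()
    kept: list[ProductRecord] = []
    rejected: list[Rejection] = []
    for rec in records:
        violations = panel_violations(rec.panel, rules)
        if not violations:
            if not (rec.serving_size_g > 0):
                violations.append("invalid serving size")
            elif not (rules.year_min <= rec.launch_year <= rules.year_max):
                violations.append("launch year outside window")
            elif rules.require_ingredients and not parse_ingredient_list(rec.ingredient_text):
                violations.append("empty ingredient list")
            elif rec.declared_added_sugars is not None and not (
                -rules.tol_g <= rec.declared_added_sugars <= rec.panel.total_sugars + rules.tol_g
            ):
                violations.append("declared added sugars exceed total sugars")
        if violations:
            rejected.append(Rejection(rec.product_id, violations[0]))
        else:
            kept.append(rec)
    return kept, rejected


def rejection_counts(rejected: Sequence[Rejection]) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in rejected:
        counts[r.reason] = counts.get(r.reason, 0) + 1
    return counts


def write_rejection_report(rejected: Sequence[Rejection], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in rejected], columns=["product_id", "reason"]).to_csv(
        path, index=False
    )
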