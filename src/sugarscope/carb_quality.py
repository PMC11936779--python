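"""Free-sugar assignment and the 10:1|1:2 carbohydrate-quality criterion.

A product meets the carbohydrate-quality ratio when it carries at least
1 g of dietary fiber for every 10 g of total carbohydrate (10:1,
inclusive) and less than 2 g of free sugars for every 1 g of fiber
(1:2, strict).  Free sugars are taken from the declared added-sugar
value when present, otherwise from the model prediction -- except in a
fixed set of beverage/confectionery categories where essentially all
sugars are free and total sugars is used directly.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

from .product_io import ProductRecord
from .sugar_model import PredictionResult

__all__ = [
    "OverrideRules",
    "FreeSugarEstimate",
    "RatioVerdict",
    "assign_free_sugars",
    "meets_carb_ratio",
    "score_dataset",
    "score_products",
]

#: Categories where total sugars approximates free sugars (all sugars free).
DEFAULT_OVERRIDE_CATEGORIES = frozenset(
    {
        "Juice Drinks",
        "Carbonated Soft Drinks",
        "Sweeteners & Sugar",
        "Sugar & Gum Confectionery",
    }
)
DEFAULT_OVERRIDE_SUBCATEGORIES = frozenset(
    {
        "Flavoured Water",
        "Honey",
        "Syrups",
        "Ready To Drink (Iced) Tea",
        "Water Based Ice Lollies, Pops & Sorbets",
    }
)


def _norm(name: str) -> str:
    return re.sub(r"\s+", " ", name).strip().casefold()


@dataclass(frozen=True)
class OverrideRules:
    """Category/sub-category lists where free sugars := total sugars.

    Matching is exact after whitespace normalization, case-insensitive
    (the lists come from a controlled category vocabulary).
    """

    override_categories: frozenset[str] = DEFAULT_OVERRIDE_CATEGORIES
    override_subcategories: frozenset[str] = DEFAULT_OVERRIDE_SUBCATEGORIES

    def applies(self, category: str, sub_category: str) -> bool:
        cats = {_norm(c) for c in self.override_categories}
        subs = {_norm(s) for s in self.override_subcategories}
        return _norm(category) in cats or _norm(sub_category) in subs

    @classmethod
    def from_yaml(cls, path: str | Path) -> "OverrideRules":
        with open(path, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        return cls(
            override_categories=frozenset(data.get("override_categories") or ()),
            override_subcategories=frozenset(data.get("override_subcategories") or ()),
        )


@dataclass(frozen=True)
class FreeSugarEstimate:
    free_sugars: float
    source: str  # declared | predicted | total_sugar_override


@dataclass(frozen=True)
class RatioVerdict:
    meets_10_1: bool
    meets_1_2: bool

    @property
    def meets_combined(self) -> bool:
        return self.meets_10_1 and self.meets_1_2


def assign_free_sugars(
    record: ProductRecord,
    prediction: PredictionResult | None = None,
    rules: OverrideRules | None = None,
    prefer_declared: bool = True,
) -> FreeSugarEstimate | None:
    """Resolve a product's free-sugar value and its provenance.

    Override categories/sub-categories always use total sugars,
    regardless of what else is available.  Otherwise the declared value
    wins when present and ``prefer_declared`` is set, else the model
    prediction.  Returns ``None`` when no source applies (the caller
    excludes and counts such products).
    """
    rules = rules or OverrideRules()
    if rules.applies(record.category, record.sub_category):
        return FreeSugarEstimate(record.panel.total_sugars, "total_sugar_override")
    if prefer_declared and record.declared_added_sugars is not None:
        return FreeSugarEstimate(float(record.declared_added_sugars), "declared")
    if prediction is not None:
        return FreeSugarEstimate(prediction.added_sugars_pred, "predicted")
    if record.declared_added_sugars is not None:
        return FreeSugarEstimate(float(record.declared_added_sugars), "declared")
    return None


def meets_carb_ratio(
    carbohydrate: float,
    fiber: float,
    free_sugars: float,
    zero_free_sugars_meets_1_2: bool = True,
) -> RatioVerdict:
    """Evaluate the 10:1 and 1:2 tests on any common mass basis.

    10:1 is inclusive ("at least 1 g fiber per 10 g carbohydrate"):
    fiber >= carbohydrate/10.  1:2 is strict ("less than 2 g free
    sugars per 1 g fiber"): free_sugars < 2*fiber, with zero free
    sugars meeting the test by default even at zero fiber (a product
    with no free sugars cannot violate a free-sugar limit).  The test
    is scale-invariant, so zero-carbohydrate products score 10:1
    vacuously true.
    """
    if carbohydrate < 0 or fiber < 0 or free_sugars < 0:
        raise ValueError("carbohydrate, fiber and free sugars must be non-negative")
    meets_10_1 = fiber >= carbohydrate / 10.0
    if free_sugars == 0:
        meets_1_2 = zero_free_sugars_meets_1_2 or fiber > 0
    else:
        meets_1_2 = free_sugars < 2.0 * fiber
    return RatioVerdict(meets_10_1=meets_10_1, meets_1_2=meets_1_2)


def score_dataset(
    resolved: Iterable[tuple[ProductRecord, FreeSugarEstimate | None]],
    zero_free_sugars_meets_1_2: bool = True,
) -> tuple[list[tuple[ProductRecord, FreeSugarEstimate, RatioVerdict]], list[str]]:
    """Score every resolved product; collect unresolved product ids.

    Zero-carbohydrate products are scored by the same formula (10:1
    vacuously true; 1:2 true iff free sugars are zero under the default
    limit convention).
    """
    scored: list[tuple[ProductRecord, FreeSugarEstimate, RatioVerdict]] = []
    excluded: list[str] = []
    for record, estimate in resolved:
        if estimate is None:
            excluded.append(record.product_id)
            continue
        verdict = meets_carb_ratio(
            record.panel.carbohydrate,
            record.panel.fiber,
            estimate.free_sugars,
            zero_free_sugars_meets_1_2=zero_free_sugars_meets_1_2,
        )
        scored.append((record, estimate, verdict))
    return scored, excluded


def score_products(
    records: Sequence[ProductRecord],
    predictions: Sequence[PredictionResult | None] | None = None,
    rules: OverrideRules | None = None,
    prefer_declared: bool = True,
) -> pd.DataFrame:
    """End-to-end scoring into a tidy frame (one row per resolved product).

    Columns: product metadata, carbohydrate/fiber/free_sugars, source,
    and the three verdict flags -- the shape the surveillance module
    aggregates.  Unresolved products are dropped (their count is the
    difference in row counts).
    """
    if predictions is None:
        predictions = [None] * len(records)
    resolved = [
        (rec, assign_free_sugars(rec, pred, rules, prefer_declared))
        for rec, pred in zip(records, predictions)
    ]
    scored, _ = score_dataset(resolved)
    rows = []
    for rec, est, verdict in scored:
        rows.append(
            {
                "product_id": rec.product_id,
                "market": rec.market,
                "category": rec.category,
                "sub_category": rec.sub_category,
                "launch_year": rec.launch_year,
                "carbohydrate": rec.panel.carbohydrate,
                "fiber": rec.panel.fiber,
                "free_sugars": est.free_sugars,
                "source": est.source,
                "meets_10_1": verdict.meets_10_1,
                "meets_1_2": verdict.meets_1_2,
                "meets_combined": verdict.meets_combined,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "product_id",
            "market",
            "category",
            "sub_category",
            "launch_year",
            "carbohydrate",
            "fiber",
            "free_sugars",
            "source",
            "meets_10_1",
            "meets_1_2",
            "meets_combined",
        ],
    )
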