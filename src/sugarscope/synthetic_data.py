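"""Label-realistic synthetic packaged-food data with known ground truth.

Real launch databases of packaged products are proprietary, so every
other module is exercised against a generator that emulates their
structure: ingredient lists in descending-quantity order drawn from
sugar/dairy/fruit/filler term pools, nutrition panels that are
internally consistent by construction (sugars + starch + fiber =
carbohydrate, Atwater 4/9/4 energy), category-dependent added-sugar
prevalence, and market/year strata.  The true added- and free-sugar
content of every product is emitted in a sidecar keyed by product id,
never inside the feature-visible record.

The generative rule per product: ingredients are ordered by a noisy
type-dependent priority, the i-th ingredient receives a mass share
proportional to ``position_decay**i`` of the 100 g basis, and every
nutrient is the mass-weighted sum of fixed per-ingredient composition
fractions.  Added sugars are therefore a deterministic function of the
full ingredient list; the declared label adds truncated-normal noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .product_io import NutrientPanel, ProductRecord

__all__ = [
    "IngredientProfile",
    "Recipe",
    "MarketConfig",
    "GenConfig",
    "Benchmark",
    "INGREDIENT_PROFILES",
    "RECIPES",
    "CLAIM_VOCABULARY",
    "generate_products",
    "make_benchmark",
    "write_sidecar",
]

ADDED, DAIRY, FRUIT, FILLER = "added", "dairy", "fruit_veg", "filler"


@dataclass(frozen=True)
class IngredientProfile:
    """Fixed composition of one lexicon term, as fractions per gram.

    ``sugar + starch + fiber`` is the carbohydrate fraction; ``sat_frac``
    is the saturated share of the fat fraction; sodium is mg per gram.
    ``order_weight`` sets the typical list position (heavier earlier).
    """

    kind: str
    sugar: float = 0.0
    starch: float = 0.0
    fiber: float = 0.0
    fat: float = 0.0
    sat_frac: float = 0.0
    protein: float = 0.0
    sodium_mg_per_g: float = 0.0
    order_weight: float = 1.0


# Compositions are rounded literature-style values; every term matches its
# own lexicon category (and only that category) in data/lexicon_en.yaml,
# except "fruit juice concentrate" which is deliberately both an added
# (free) sugar and a fruit term.
INGREDIENT_PROFILES: dict[str, IngredientProfile] = {
    # added sugars
    "sugar": IngredientProfile(ADDED, sugar=1.0, order_weight=3.0),
    "brown sugar": IngredientProfile(ADDED, sugar=0.97, order_weight=3.0),
    "glucose syrup": IngredientProfile(ADDED, sugar=0.80, order_weight=3.0),
    "high fructose corn syrup": IngredientProfile(ADDED, sugar=0.76, order_weight=3.0),
    "honey": IngredientProfile(ADDED, sugar=0.82, order_weight=3.0),
    "dextrose": IngredientProfile(ADDED, sugar=1.0, order_weight=2.0),
    "molasses": IngredientProfile(ADDED, sugar=0.75, order_weight=1.5),
    "maple syrup": IngredientProfile(ADDED, sugar=0.67, order_weight=2.0),
    "invert sugar": IngredientProfile(ADDED, sugar=0.95, order_weight=2.0),
    "date paste": IngredientProfile(ADDED, sugar=0.63, fiber=0.08, order_weight=2.5),
    "fruit juice concentrate": IngredientProfile(ADDED, sugar=0.65, order_weight=2.5),
    # dairy sugar sources
    "milk": IngredientProfile(
        DAIRY, sugar=0.048, fat=0.036, sat_frac=0.63, protein=0.034,
        sodium_mg_per_g=0.4, order_weight=10.0,
    ),
    "skimmed milk powder": IngredientProfile(
        DAIRY, sugar=0.52, fat=0.01, sat_frac=0.6, protein=0.34,
        sodium_mg_per_g=4.0, order_weight=2.0,
    ),
    "whole milk powder": IngredientProfile(
        DAIRY, sugar=0.38, fat=0.27, sat_frac=0.63, protein=0.26,
        sodium_mg_per_g=3.5, order_weight=2.0,
    ),
    "whey powder": IngredientProfile(
        DAIRY, sugar=0.70, fat=0.01, sat_frac=0.6, protein=0.12,
        sodium_mg_per_g=5.0, order_weight=1.5,
    ),
    "cream": IngredientProfile(
        DAIRY, sugar=0.03, fat=0.35, sat_frac=0.66, protein=0.02, order_weight=2.5,
    ),
    "cheese": IngredientProfile(
        DAIRY, sugar=0.015, fat=0.33, sat_frac=0.63, protein=0.25,
        sodium_mg_per_g=6.0, order_weight=3.0,
    ),
    "yogurt": IngredientProfile(
        DAIRY, sugar=0.047, fat=0.033, sat_frac=0.63, protein=0.035, order_weight=4.0,
    ),
    # fruit / vegetable sugar sources
    "apple puree": IngredientProfile(FRUIT, sugar=0.10, fiber=0.015, order_weight=3.0),
    "strawberries": IngredientProfile(FRUIT, sugar=0.049, fiber=0.02, order_weight=2.0),
    "raisins": IngredientProfile(FRUIT, sugar=0.59, starch=0.03, fiber=0.037, order_weight=3.0),
    "banana": IngredientProfile(FRUIT, sugar=0.12, starch=0.05, fiber=0.026, order_weight=3.0),
    "mango puree": IngredientProfile(FRUIT, sugar=0.14, fiber=0.016, order_weight=3.0),
    "orange juice": IngredientProfile(FRUIT, sugar=0.083, fiber=0.002, order_weight=8.0),
    "tomato paste": IngredientProfile(
        FRUIT, sugar=0.12, starch=0.02, fiber=0.04, protein=0.04,
        sodium_mg_per_g=0.6, order_weight=3.0,
    ),
    "carrots": IngredientProfile(FRUIT, sugar=0.047, starch=0.014, fiber=0.028, order_weight=3.0),
    # fillers (never match any lexicon category)
    "water": IngredientProfile(FILLER, order_weight=10.0),
    "carbonated water": IngredientProfile(FILLER, order_weight=10.0),
    "wheat flour": IngredientProfile(
        FILLER, starch=0.70, fiber=0.027, fat=0.01, sat_frac=0.2, protein=0.10,
        order_weight=8.0,
    ),
    "whole wheat flour": IngredientProfile(
        FILLER, starch=0.57, fiber=0.11, fat=0.019, sat_frac=0.2, protein=0.13,
        order_weight=8.0,
    ),
    "oat flakes": IngredientProfile(
        FILLER, starch=0.58, fiber=0.106, fat=0.07, sat_frac=0.18, protein=0.17,
        order_weight=8.0,
    ),
    "oat bran": IngredientProfile(
        FILLER, starch=0.50, fiber=0.155, fat=0.07, sat_frac=0.18, protein=0.17,
        order_weight=4.0,
    ),
    "rice flour": IngredientProfile(FILLER, starch=0.80, protein=0.06, order_weight=6.0),
    "corn flour": IngredientProfile(
        FILLER, starch=0.73, fiber=0.07, fat=0.04, sat_frac=0.15, protein=0.07,
        order_weight=6.0,
    ),
    "wheat starch": IngredientProfile(FILLER, starch=0.85, order_weight=3.0),
    "modified starch": IngredientProfile(FILLER, starch=0.90, order_weight=1.5),
    "inulin": IngredientProfile(FILLER, fiber=0.90, order_weight=1.5),
    "vegetable oil": IngredientProfile(FILLER, fat=1.0, sat_frac=0.15, order_weight=2.5),
    "palm oil": IngredientProfile(FILLER, fat=1.0, sat_frac=0.50, order_weight=2.5),
    "cocoa powder": IngredientProfile(
        FILLER, starch=0.10, fiber=0.33, fat=0.14, sat_frac=0.6, protein=0.20,
        order_weight=2.0,
    ),
    "soy protein isolate": IngredientProfile(FILLER, protein=0.85, order_weight=2.0),
    "salt": IngredientProfile(FILLER, sodium_mg_per_g=390.0, order_weight=0.3),
    "baking soda": IngredientProfile(FILLER, sodium_mg_per_g=274.0, order_weight=0.25),
    "citric acid": IngredientProfile(FILLER, order_weight=0.2),
    "natural flavouring": IngredientProfile(FILLER, order_weight=0.2),
    "green tea extract": IngredientProfile(FILLER, order_weight=0.4),
    "emulsifier": IngredientProfile(FILLER, fat=0.5, sat_frac=0.2, order_weight=0.2),
}


@dataclass(frozen=True)
class Recipe:
    """Template for one product category.

    ``mandatory`` terms always appear; 1–``n_optional[1]`` terms are
    drawn from ``optional`` without replacement; sugar-source terms are
    added per the category probabilities.  ``serving_range`` is grams.
    """

    category: str
    sub_category: str
    mandatory: tuple[str, ...]
    optional: tuple[str, ...]
    n_optional: tuple[int, int]
    added_pool: tuple[str, ...] = ()
    dairy_pool: tuple[str, ...] = ()
    fruit_pool: tuple[str, ...] = ()
    added_prevalence: float = 0.0
    dairy_prob: float = 0.0
    fruit_prob: float = 0.0
    second_added_prob: float = 0.3
    serving_range: tuple[float, float] = (30.0, 60.0)


RECIPES: dict[str, Recipe] = {
    r.category + "/" + r.sub_category: r
    for r in [
        Recipe(
            "Cold Cereals", "Cold Cereals",
            mandatory=("wheat flour",),
            optional=("oat flakes", "corn flour", "rice flour", "whole wheat flour",
                      "salt", "vegetable oil", "inulin"),
            n_optional=(2, 5),
            added_pool=("sugar", "brown sugar", "glucose syrup", "honey", "molasses"),
            fruit_pool=("raisins", "apple puree", "banana"),
            dairy_pool=("skimmed milk powder",),
            added_prevalence=0.80, fruit_prob=0.25, dairy_prob=0.05,
        ),
        Recipe(
            "Hot Cereals", "Hot Cereals",
            mandatory=("oat flakes",),
            optional=("oat bran", "whole wheat flour", "salt", "inulin"),
            n_optional=(1, 3),
            added_pool=("sugar", "brown sugar", "honey", "maple syrup"),
            fruit_pool=("raisins", "apple puree", "banana"),
            dairy_pool=("skimmed milk powder",),
            added_prevalence=0.45, fruit_prob=0.30, dairy_prob=0.05,
        ),
        Recipe(
            "Sweet Biscuits/Cookies", "Cookies",
            mandatory=("wheat flour",),
            optional=("vegetable oil", "palm oil", "cocoa powder", "salt",
                      "baking soda", "emulsifier", "wheat starch"),
            n_optional=(3, 5),
            added_pool=("sugar", "brown sugar", "glucose syrup", "invert sugar",
                        "high fructose corn syrup"),
            dairy_pool=("whole milk powder", "cream", "whey powder"),
            fruit_pool=("raisins", "strawberries"),
            added_prevalence=0.97, dairy_prob=0.15, fruit_prob=0.10,
        ),
        Recipe(
            "Bread & Bread Products", "Bread",
            mandatory=("wheat flour", "water"),
            optional=("whole wheat flour", "salt", "vegetable oil", "oat bran"),
            n_optional=(2, 4),
            added_pool=("sugar", "dextrose", "molasses", "honey"),
            dairy_pool=("skimmed milk powder",),
            fruit_pool=("raisins",),
            added_prevalence=0.50, dairy_prob=0.05, fruit_prob=0.03,
        ),
        Recipe(
            "Snack/Cereal/Energy Bars", "Cereal Bars",
            mandatory=("oat flakes",),
            optional=("rice flour", "inulin", "vegetable oil", "salt",
                      "soy protein isolate", "cocoa powder"),
            n_optional=(2, 4),
            added_pool=("glucose syrup", "honey", "sugar", "date paste",
                        "fruit juice concentrate"),
            fruit_pool=("raisins", "apple puree", "banana", "strawberries"),
            dairy_pool=("whey powder",),
            added_prevalence=0.85, fruit_prob=0.50, dairy_prob=0.10,
            serving_range=(25.0, 45.0),
        ),
        Recipe(
            "Flavoured Milk", "Flavoured Milk",
            mandatory=("milk",),
            optional=("cocoa powder", "modified starch", "salt", "natural flavouring"),
            n_optional=(1, 3),
            added_pool=("sugar", "glucose syrup"),
            dairy_pool=("cream", "skimmed milk powder"),
            added_prevalence=0.90, dairy_prob=0.20,
            serving_range=(200.0, 250.0),
        ),
        Recipe(
            "Juice", "Juice",
            mandatory=("orange juice",),
            optional=("water", "citric acid", "natural flavouring"),
            n_optional=(1, 3),
            added_pool=("sugar", "fruit juice concentrate"),
            fruit_pool=("apple puree", "mango puree"),
            added_prevalence=0.30, fruit_prob=0.30,
            serving_range=(200.0, 250.0),
        ),
        Recipe(
            "Juice Drinks", "Juice Drinks",
            mandatory=("water",),
            optional=("citric acid", "natural flavouring"),
            n_optional=(1, 2),
            added_pool=("sugar", "high fructose corn syrup", "fruit juice concentrate"),
            fruit_pool=("orange juice", "mango puree"),
            added_prevalence=0.85, fruit_prob=0.60,
            serving_range=(200.0, 250.0),
        ),
        Recipe(
            "Carbonated Soft Drinks", "Cola",
            mandatory=("carbonated water",),
            optional=("citric acid", "natural flavouring"),
            n_optional=(1, 2),
            added_pool=("sugar", "high fructose corn syrup", "glucose syrup"),
            added_prevalence=0.85,
            serving_range=(240.0, 330.0),
        ),
        Recipe(
            "Sweeteners & Sugar", "Honey",
            mandatory=("honey",),
            optional=(),
            n_optional=(0, 0),
            added_prevalence=0.0,  # honey itself is the sugar source
            serving_range=(15.0, 25.0),
        ),
        Recipe(
            "Sugar & Gum Confectionery", "Sugar Confectionery",
            mandatory=("sugar",),
            optional=("water", "citric acid", "natural flavouring", "wheat starch"),
            n_optional=(2, 4),
            added_pool=("glucose syrup", "invert sugar", "dextrose"),
            fruit_pool=("apple puree", "strawberries"),
            added_prevalence=0.90, fruit_prob=0.20,
            serving_range=(15.0, 30.0),
        ),
        Recipe(
            "Soup", "Soup",
            mandatory=("water",),
            optional=("modified starch", "salt", "vegetable oil", "wheat flour"),
            n_optional=(2, 4),
            added_pool=("sugar", "dextrose"),
            fruit_pool=("tomato paste", "carrots"),
            dairy_pool=("cream", "milk"),
            added_prevalence=0.25, fruit_prob=0.80, dairy_prob=0.10,
            serving_range=(200.0, 250.0),
        ),
        Recipe(
            "Pizzas", "Pizzas",
            mandatory=("wheat flour", "water"),
            optional=("vegetable oil", "salt", "baking soda"),
            n_optional=(2, 3),
            added_pool=("sugar", "dextrose"),
            dairy_pool=("cheese",),
            fruit_pool=("tomato paste",),
            added_prevalence=0.30, dairy_prob=0.80, fruit_prob=0.70,
            serving_range=(100.0, 150.0),
        ),
        Recipe(
            "Fruit Snacks", "Fruit Snacks",
            mandatory=("raisins",),
            optional=("vegetable oil", "citric acid", "natural flavouring"),
            n_optional=(1, 2),
            added_pool=("sugar", "fruit juice concentrate", "glucose syrup"),
            fruit_pool=("apple puree", "banana", "strawberries", "mango puree"),
            added_prevalence=0.50, fruit_prob=0.60,
            serving_range=(25.0, 40.0),
        ),
        Recipe(
            "Plant Based Drinks", "Plant Based Drinks",
            mandatory=("water",),
            optional=("rice flour", "vegetable oil", "salt", "natural flavouring"),
            n_optional=(2, 3),
            added_pool=("sugar",),
            fruit_pool=(),
            added_prevalence=0.50,
            serving_range=(200.0, 250.0),
        ),
        Recipe(
            "RTDs", "Ready To Drink (Iced) Tea",
            mandatory=("water", "green tea extract"),
            optional=("citric acid", "natural flavouring"),
            n_optional=(0, 2),
            added_pool=("sugar", "honey", "high fructose corn syrup"),
            added_prevalence=0.90,
            serving_range=(240.0, 330.0),
        ),
        Recipe(
            "Water", "Flavoured Water",
            mandatory=("water",),
            optional=("citric acid", "natural flavouring"),
            n_optional=(0, 2),
            added_pool=("sugar",),
            added_prevalence=0.30,
            serving_range=(240.0, 500.0),
        ),
    ]
}

#: Default category mix: solid foods dominate, every override category
#: and override sub-category is represented.
DEFAULT_CATEGORY_MIX: dict[str, float] = {
    "Cold Cereals/Cold Cereals": 0.13,
    "Hot Cereals/Hot Cereals": 0.08,
    "Sweet Biscuits/Cookies/Cookies": 0.14,
    "Bread & Bread Products/Bread": 0.10,
    "Snack/Cereal/Energy Bars/Cereal Bars": 0.12,
    "Flavoured Milk/Flavoured Milk": 0.05,
    "Juice/Juice": 0.05,
    "Juice Drinks/Juice Drinks": 0.05,
    "Carbonated Soft Drinks/Cola": 0.05,
    "Sweeteners & Sugar/Honey": 0.02,
    "Sugar & Gum Confectionery/Sugar Confectionery": 0.05,
    "Soup/Soup": 0.06,
    "Pizzas/Pizzas": 0.04,
    "Fruit Snacks/Fruit Snacks": 0.05,
    "Plant Based Drinks/Plant Based Drinks": 0.03,
    "RTDs/Ready To Drink (Iced) Tea": 0.02,
    "Water/Flavoured Water": 0.01,
}

CLAIM_VOCABULARY = (
    "High/Added Fibre",
    "Wholegrain",
    "Low/No/Reduced Carb",
    "Low/No/Reduced Glycemic",
    "Low/Reduced Sugar",
    "No Added Sugar",
    "Diabetic",
)

_CORRUPTION_KINDS = (
    "sugars exceed carbohydrate",
    "negative nutrient",
    "saturated fat exceeds total fat",
    "energy inconsistent with macronutrients",
    "macronutrient sum exceeds cap",
    "empty ingredient list",
)


@dataclass(frozen=True)
class MarketConfig:
    name: str
    year_range: tuple[int, int] = (2014, 2023)
    claim_prevalence: float = 0.30
    declares_added_sugars: bool = False
    weight: float = 1.0


@dataclass(frozen=True)
class GenConfig:
    """Study conditions for one synthetic dataset draw."""

    n_products: int = 1000
    seed: int = 0
    category_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_MIX)
    )
    added_sugar_prevalence: Mapping[str, float] | None = None
    position_decay: float = 0.55
    noise_sd: float = 0.5
    corruption_rate: float = 0.0
    markets: tuple[MarketConfig, ...] = (
        MarketConfig("United States", declares_added_sugars=True),
    )
    id_prefix: str = "SYN"

    def __post_init__(self):
        if not 0 < self.position_decay < 1:
            raise ValueError("position_decay must lie in (0, 1)")
        if not 0 <= self.corruption_rate <= 1:
            raise ValueError("corruption_rate must lie in [0, 1]")
        unknown = set(self.category_mix) - set(RECIPES)
        if unknown:
            raise ValueError(f"category_mix names unknown recipes: {sorted(unknown)}")


def _assemble_ingredients(recipe: Recipe, prevalence: float, rng: np.random.Generator) -> list[str]:
    terms = list(recipe.mandatory)
    lo, hi = recipe.n_optional
    pool = [t for t in recipe.optional if t not in terms]
    if pool and hi > 0:
        k = int(rng.integers(lo, hi + 1))
        k = min(k, len(pool))
        if k:
            terms += list(rng.choice(pool, size=k, replace=False))
    if recipe.added_pool and rng.random() < prevalence:
        terms.append(str(rng.choice(recipe.added_pool)))
        if len(recipe.added_pool) > 1 and rng.random() < recipe.second_added_prob:
            extra = str(rng.choice(recipe.added_pool))
            if extra not in terms:
                terms.append(extra)
    if recipe.dairy_pool and rng.random() < recipe.dairy_prob:
        terms.append(str(rng.choice(recipe.dairy_pool)))
    if recipe.fruit_pool and rng.random() < recipe.fruit_prob:
        terms.append(str(rng.choice(recipe.fruit_pool)))
    # descending-quantity order: noisy type-dependent priority
    priorities = {
        t: INGREDIENT_PROFILES[t].order_weight * rng.lognormal(0.0, 0.35) for t in terms
    }
    return sorted(dict.fromkeys(terms), key=lambda t: -priorities[t])


def _panel_from_masses(terms: Sequence[str], masses: np.ndarray) -> tuple[NutrientPanel, float]:
    sugar = starch = fiber = fat = sat = protein = sodium = added = 0.0
    for term, m in zip(terms, masses):
        prof = INGREDIENT_PROFILES[term]
        sugar += m * prof.sugar
        starch += m * prof.starch
        fiber += m * prof.fiber
        fat += m * prof.fat
        sat += m * prof.fat * prof.sat_frac
        protein += m * prof.protein
        sodium += m * prof.sodium_mg_per_g
        if prof.kind == ADDED:
            added += m * prof.sugar
    carb = sugar + starch + fiber
    energy = 4.0 * carb + 9.0 * fat + 4.0 * protein
    panel = NutrientPanel(
        energy_kcal=round(float(energy), 4),
        total_fat=round(float(fat), 4),
        saturated_fat=round(float(sat), 4),
        carbohydrate=round(float(carb), 4),
        fiber=round(float(fiber), 4),
        total_sugars=round(float(sugar), 4),
        protein=round(float(protein), 4),
        sodium_mg=round(float(sodium), 2),
    )
    return panel, float(added)


def _corrupt(record: ProductRecord, kind: str) -> ProductRecord:
    p = record.panel
    if kind == "sugars exceed carbohydrate":
        p = replace(p, total_sugars=p.carbohydrate + 5.0)
    elif kind == "negative nutrient":
        p = replace(p, fiber=-2.0)
    elif kind == "saturated fat exceeds total fat":
        p = replace(p, saturated_fat=p.total_fat + 3.0)
    elif kind == "energy inconsistent with macronutrients":
        p = replace(p, energy_kcal=p.energy_kcal * 2.2 if p.energy_kcal > 0 else 100.0)
    elif kind == "macronutrient sum exceeds cap":
        p = replace(p, carbohydrate=90.0, total_fat=30.0)
    elif kind == "empty ingredient list":
        return replace(record, ingredient_text="")
    else:  # pragma: no cover - guarded by _CORRUPTION_KINDS
        raise ValueError(f"unknown corruption kind: {kind}")
    return replace(record, panel=p)


def _ingredient_text(terms: Sequence[str], rng: np.random.Generator) -> str:
    """Render label text with occasional percentage/qualifier dressing."""
    parts = []
    for i, term in enumerate(terms):
        piece = term
        if i == 0 and rng.random() < 0.15:
            piece = "organic " + piece
        if rng.random() < 0.10:
            piece = f"{piece} ({rng.integers(1, 60)}%)"
        parts.append(piece)
    return ", ".join(parts)


def generate_products(
    config: GenConfig,
) -> tuple[list[ProductRecord], dict[str, dict]]:
    """Draw a synthetic product collection plus its ground-truth sidecar.

    The sidecar maps product_id to ``true_added_sugars``,
    ``true_free_sugars`` (total sugars in override categories, added
    sugars elsewhere), ``corrupted`` and ``corruption_reason``.  Output
    is deterministic given the config (including seed).
    """
    from .carb_quality import OverrideRules

    rng = np.random.default_rng(config.seed)
    overrides = OverrideRules()
    keys = sorted(config.category_mix)
    weights = np.array([config.category_mix[k] for k in keys], dtype=float)
    if weights.sum() <= 0:
        raise ValueError("category_mix weights must sum to a positive value")
    weights = weights / weights.sum()
    market_w = np.array([m.weight for m in config.markets], dtype=float)
    market_w = market_w / market_w.sum()

    records: list[ProductRecord] = []
    sidecar: dict[str, dict] = {}
    for i in range(config.n_products):
        key = keys[int(rng.choice(len(keys), p=weights))]
        recipe = RECIPES[key]
        market = config.markets[int(rng.choice(len(config.markets), p=market_w))]
        prevalence = recipe.added_prevalence
        if config.added_sugar_prevalence and key in config.added_sugar_prevalence:
            prevalence = config.added_sugar_prevalence[key]

        terms = _assemble_ingredients(recipe, prevalence, rng)
        n = len(terms)
        shares = config.position_decay ** np.arange(n)
        masses = 100.0 * shares / shares.sum()
        panel, true_added = _panel_from_masses(terms, masses)

        declared = None
        if market.declares_added_sugars:
            if config.noise_sd > 0 and true_added > 0:
                declared = float(
                    np.clip(
                        true_added + rng.normal(0.0, config.noise_sd),
                        0.0,
                        panel.total_sugars,
                    )
                )
            else:
                declared = float(true_added)
            declared = round(declared, 4)

        claims: set[str] = set()
        if rng.random() < market.claim_prevalence:
            if true_added == 0 and rng.random() < 0.6:
                claims.add("No Added Sugar")
            else:
                n_claims = int(rng.integers(1, 3))
                claims.update(
                    str(c) for c in rng.choice(CLAIM_VOCABULARY, size=n_claims, replace=False)
                )

        year_lo, year_hi = market.year_range
        record = ProductRecord(
            product_id=f"{config.id_prefix}-{i:06d}",
            market=market.name,
            category=recipe.category,
            sub_category=recipe.sub_category,
            launch_year=int(rng.integers(year_lo, year_hi + 1)),
            serving_size_g=round(float(rng.uniform(*recipe.serving_range)), 1),
            ingredient_text=_ingredient_text(terms, rng),
            panel=panel,
            declared_added_sugars=declared,
            claims=frozenset(claims),
        )

        corrupted = bool(rng.random() < config.corruption_rate)
        reason = None
        if corrupted:
            reason = _CORRUPTION_KINDS[int(rng.integers(len(_CORRUPTION_KINDS)))]
            record = _corrupt(record, reason)

        true_free = (
            panel.total_sugars
            if overrides.applies(recipe.category, recipe.sub_category)
            else true_added
        )
        sidecar[record.product_id] = {
            "product_id": record.product_id,
            "true_added_sugars": round(true_added, 4),
            "true_free_sugars": round(true_free, 4),
            "corrupted": corrupted,
            "corruption_reason": reason,
        }
        records.append(record)
    return records, sidecar


def write_sidecar(sidecar: Mapping[str, dict], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for pid in sidecar:
            fh.write(json.dumps(sidecar[pid]) + "\n")


@dataclass
class Benchmark:
    """Fixed-recipe benchmark: declared-market train/validation, undeclared test."""

    train: list[ProductRecord]
    validation: list[ProductRecord]
    test: list[ProductRecord]
    sidecar: dict[str, dict]


def make_benchmark(
    seed: int,
    n_train: int = 5000,
    n_validation: int = 1000,
    n_test: int = 1000,
    noise_sd: float = 0.5,
) -> Benchmark:
    """Build the train/validation/test benchmark with sidecar truth.

    Training and validation products come from a single market that
    declares added sugars; test products come from markets that do not,
    so test performance is always measured against sidecar ground truth
    (the train-at-home, predict-abroad protocol at desk scale).
    """
    us = GenConfig(
        n_products=n_train + n_validation,
        seed=seed,
        noise_sd=noise_sd,
        markets=(MarketConfig("United States", declares_added_sugars=True),),
        id_prefix=f"US{seed}",
    )
    intl = GenConfig(
        n_products=n_test,
        seed=seed + 1,
        noise_sd=noise_sd,
        markets=(
            MarketConfig("United Kingdom", weight=1.0),
            MarketConfig("Brazil", weight=1.0),
            MarketConfig("Germany", weight=1.0),
        ),
        id_prefix=f"INTL{seed}",
    )
    us_records, us_sidecar = generate_products(us)
    intl_records, intl_sidecar = generate_products(intl)
    return Benchmark(
        train=us_records[:n_train],
        validation=us_records[n_train:],
        test=intl_records,
        sidecar={**us_sidecar, **intl_sidecar},
    )
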