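import pytest

from sugarscope.ingredient_tagger import default_lexicon
from sugarscope.product_io import NutrientPanel, ProductRecord
from sugarscope.sugar_model import train_bundle
from sugarscope.synthetic_data import make_benchmark


@pytest.fixture(scope="session")
def lexicon():
    return default_lexicon()


def make_record(
    product_id="P1",
    market="United States",
    category="Cold Cereals",
    sub_category="Cold Cereals",
    launch_year=2019,
    serving_size_g=40.0,
    ingredient_text="wheat flour, sugar, salt",
    declared_added_sugars=None,
    claims=(),
    **panel_overrides,
):
    """Construct a consistent cleaned-style record; panel fields overridable."""
    panel_fields = dict(
        energy_kcal=0.0,
        total_fat=1.0,
        saturated_fat=0.2,
        carbohydrate=70.0,
        fiber=3.0,
        total_sugars=20.0,
        protein=8.0,
        sodium_mg=400.0,
    )
    panel_fields.update(panel_overrides)
    if "energy_kcal" not in panel_overrides:
        panel_fields["energy_kcal"] = (
            4 * panel_fields["carbohydrate"]
            + 9 * panel_fields["total_fat"]
            + 4 * panel_fields["protein"]
        )
    return ProductRecord(
        product_id=product_id,
        market=market,
        category=category,
        sub_category=sub_category,
        launch_year=launch_year,
        serving_size_g=serving_size_g,
        ingredient_text=ingredient_text,
        panel=NutrientPanel(**panel_fields),
        declared_added_sugars=declared_added_sugars,
        claims=frozenset(claims),
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """Reduced-size benchmark for fast unit tests of training/prediction."""
    return make_benchmark(7, n_train=1200, n_validation=300, n_test=300)


@pytest.fixture(scope="session")
def small_bundle(small_benchmark, lexicon):
    return train_bundle(
        small_benchmark.train, small_benchmark.validation, lexicon, seed=7
    )
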