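import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from sugarscope.product_io import (
    NUTRIENT_COLUMNS,
    CleaningRules,
    clean_products,
    normalize_to_100g,
    read_products,
    rejection_counts,
    write_products,
)
from sugarscope.synthetic_data import GenConfig, generate_products

from conftest import make_record


def _serving(carb=15.0, sodium=0.0, **kw):
    values = {c: 0.0 for c in NUTRIENT_COLUMNS}
    values["carbohydrate"] = carb
    values["sodium_mg"] = sodium
    values.update(kw)
    return values


class TestNormalize:
    @pytest.mark.parametrize(
        "values, serving, field, expected",
        [
            (_serving(carb=15.0), 50.0, "carbohydrate", 30.0),
            (_serving(sodium=120.0), 30.0, "sodium_mg", 400.0),
        ],
    )
    def test_linear_scaling(self, values, serving, field, expected):
        panel = normalize_to_100g(values, serving)
        assert getattr(panel, field) == pytest.approx(expected)

    def test_identity_at_100g(self):
        values = _serving(carb=12.5, sodium=80.0, protein=3.0, total_fat=1.5)
        panel = normalize_to_100g(values, 100.0)
        for col in NUTRIENT_COLUMNS:
            assert getattr(panel, col) == pytest.approx(values[col])

    @pytest.mark.parametrize("bad", [0.0, -5.0, float("nan"), float("inf")])
    def test_invalid_serving_rejected(self, bad):
        with pytest.raises(ValueError):
            normalize_to_100g(_serving(), bad)

    @given(
        scale=st.floats(0.1, 10.0),
        carb=st.floats(0.0, 80.0),
        serving=st.floats(5.0, 500.0),
    )
    @settings(deadline=None, derandomize=True, max_examples=50)
    def test_homogeneity(self, scale, carb, serving):
        """Degree 1 in the nutrient vector, degree -1 in serving size."""
        base = normalize_to_100g(_serving(carb=carb), serving)
        scaled_nutrients = normalize_to_100g(_serving(carb=carb * scale), serving)
        scaled_serving = normalize_to_100g(_serving(carb=carb), serving * scale)
        assert scaled_nutrients.carbohydrate == pytest.approx(
            base.carbohydrate * scale, rel=1e-9
        )
        assert scaled_serving.carbohydrate == pytest.approx(
            base.carbohydrate / scale, rel=1e-9
        )


class TestReadWrite:
    CSV_HEADER = (
        "product_id,market,category,sub_category,launch_year,serving_size_g,"
        "ingredient_text,energy_kcal,total_fat,saturated_fat,carbohydrate,fiber,"
        "total_sugars,protein,sodium_mg,declared_added_sugars,claims\n"
    )

    def _row(self, pid, carb="70"):
        return (
            f"{pid},US,Cold Cereals,Cold Cereals,2019,40,\"wheat flour, sugar\","
            f"321,1,0.2,{carb},3,20,8,400,,\n"
        )

    def test_wellformed_csv(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text(self.CSV_HEADER + "".join(self._row(f"P{i}") for i in range(3)))
        records, rejections = read_products(path)
        assert [r.product_id for r in records] == ["P0", "P1", "P2"]
        assert rejections == []

    def test_missing_nutrient_cell_rejected(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text(self.CSV_HEADER + self._row("P0") + self._row("BAD", carb=""))
        records, rejections = read_products(path)
        assert [r.product_id for r in records] == ["P0"]
        assert rejections[0].product_id == "BAD"
        assert rejections[0].reason == "missing nutrient"

    def test_unparseable_numeric_rejected_not_raised(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text(self.CSV_HEADER + self._row("BAD", carb="seventy"))
        records, rejections = read_products(path)
        assert records == []
        assert rejections[0].reason == "unparseable numeric"

    def test_missing_mandatory_column_is_config_error(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text("product_id,market\nP0,US\n")
        with pytest.raises(KeyError, match="mandatory"):
            read_products(path)

    def test_column_mapping(self, tmp_path):
        path = tmp_path / "in.csv"
        path.write_text(self.CSV_HEADER.replace("carbohydrate", "carbs") + self._row("P0"))
        records, _ = read_products(path, column_map={"carbohydrate": "carbs"})
        assert records[0].panel.carbohydrate == 70.0

    def test_jsonl_roundtrip_synthetic(self, tmp_path):
        records, _ = generate_products(GenConfig(n_products=10, seed=3))
        path = tmp_path / "products.jsonl"
        write_products(records, path)
        back, rejections = read_products(path)
        assert rejections == []
        assert back == records
        # second round trip is also exact
        path2 = tmp_path / "again.jsonl"
        write_products(back, path2)
        assert read_products(path2)[0] == records


class TestClean:
    def test_sugars_exceeding_carbohydrate_rejected(self):
        rec = make_record(total_sugars=40.0, carbohydrate=20.0, fiber=1.0)
        kept, rejected = clean_products([rec])
        assert kept == []
        assert rejected[0].reason == "sugars exceed carbohydrate"

    def test_consistent_product_kept(self):
        kept, rejected = clean_products([make_record()])
        assert len(kept) == 1 and rejected == []

    @pytest.mark.parametrize(
        "overrides, reason",
        [
            (dict(fiber=-1.0), "negative nutrient"),
            (dict(saturated_fat=5.0, total_fat=1.0), "saturated fat exceeds total fat"),
            (dict(fiber=30.0, carbohydrate=20.0, total_sugars=2.0), "fiber exceeds carbohydrate"),
            (dict(energy_kcal=900.0), "energy inconsistent with macronutrients"),
        ],
    )
    def test_rejection_reasons(self, overrides, reason):
        kept, rejected = clean_products([make_record(**overrides)])
        assert kept == []
        assert rejected[0].reason == reason

    def test_empty_ingredients_and_year_window(self):
        recs = [
            make_record(product_id="A", ingredient_text="  "),
            make_record(product_id="B", launch_year=2005),
        ]
        _, rejected = clean_products(recs)
        assert {r.product_id: r.reason for r in rejected} == {
            "A": "empty ingredient list",
            "B": "launch year outside window",
        }

    def test_corrupted_batch_bookkeeping(self):
        """Kept count equals the generator's own clean count at 10% corruption."""
        records, sidecar = generate_products(
            GenConfig(n_products=1000, seed=11, corruption_rate=0.1)
        )
        kept, rejected = clean_products(records)
        n_clean = sum(1 for row in sidecar.values() if not row["corrupted"])
        assert len(kept) == n_clean
        assert len(kept) + len(rejected) == 1000
        assert all(not sidecar[r.product_id]["corrupted"] for r in kept)
        assert sum(rejection_counts(rejected).values()) == len(rejected)

    def test_idempotent_and_partition(self):
        records, _ = generate_products(
            GenConfig(n_products=300, seed=5, corruption_rate=0.15)
        )
        kept, rejected = clean_products(records)
        assert len(kept) + len(rejected) == len(records)
        kept_ids = {r.product_id for r in kept}
        rej_ids = {r.product_id for r in rejected}
        assert kept_ids.isdisjoint(rej_ids)
        assert kept_ids | rej_ids == {r.product_id for r in records}
        kept2, rejected2 = clean_products(kept)
        assert kept2 == kept and rejected2 == []

    def test_declared_above_total_sugars_rejected(self):
        rec = make_record(declared_added_sugars=25.0, total_sugars=20.0)
        _, rejected = clean_products([rec])
        assert rejected[0].reason == "declared added sugars exceed total sugars"

    def test_energy_tolerance_is_relative(self):
        # 20% off passes at the default 25% relative tolerance
        rec = make_record(energy_kcal=(4 * 70 + 9 * 1 + 4 * 8) * 1.2)
        kept, _ = clean_products([rec])
        assert len(kept) == 1
        rules = CleaningRules(energy_rel_tol=0.1)
        kept, rejected = clean_products([rec], rules)
        assert kept == [] and rejected[0].reason == "energy inconsistent with macronutrients"
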