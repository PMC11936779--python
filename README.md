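# sugarscope

Free- and added-sugar prediction and carbohydrate-quality surveillance
for packaged-food label data.

## The problem

Total sugars are declared on virtually every nutrition facts panel, but
*added* sugars (caloric sweeteners introduced in processing) and *free*
sugars (added sugars plus the sugars of honey, syrups, fruit juices and
concentrates) are mandatory only in a handful of countries. Without
them, carbohydrate-quality metrics cannot be computed for most of the
world's packaged food supply. `sugarscope` infers them from what *is*
on pack — the ingredient list and the eight panel values (energy, total
fat, saturated fat, carbohydrate, fiber, total sugars, protein,
sodium, per 100 g) — and uses the result to monitor the **10:1|1:2
carbohydrate-quality ratio** across categories, countries and launch
years:

* **10:1** — at least 1 g dietary fiber per 10 g total carbohydrate:
  `fiber ≥ carbohydrate / 10` (inclusive);
* **1:2** — less than 2 g free sugars per 1 g fiber:
  `free_sugars < 2 · fiber` (strict);
* a product *meets the ratio* when both hold.

## The method

1. **Clean** (`product_io`): keep products whose panel is internally
   consistent — non-negative values, sugars/fiber ≤ carbohydrate,
   saturated ≤ total fat, and energy within 25 % of the Atwater 4/9/4
   reconstruction — and that carry a parseable ingredient list.
2. **Tag** (`ingredient_tagger`): parse the label's ingredient list
   (descending-quantity order) and tag each of the first six
   ingredients as added sugar, dairy sugar source, or fruit/vegetable
   sugar source, using curated case-insensitive regex lexicons with
   exclusion patterns for non-caloric sweeteners.
3. **Predict** (`sugar_model`): a gated two-stage predictor over a
   26-long feature vector (18 positional tag flags + 8 nutrients).
   Three tree-based binary classifiers (random forest, extremely
   randomized trees, gradient-boosted trees) decide *presence* of added
   sugars by majority vote at a validation-tuned threshold; if present,
   two tree-ensemble base regressors stacked under a linear
   meta-regressor estimate the amount, clipped into
   `[0, total_sugars]`. A presence-negative product gets exactly 0 g.
   A nutrients-only kNN regressor is included as the baseline.
4. **Score** (`carb_quality`): free sugars = declared added sugars when
   available, else the prediction — except in beverage/confectionery
   categories (Juice Drinks, Carbonated Soft Drinks, Sweeteners &
   Sugar, Sugar & Gum Confectionery, and sub-categories such as Honey,
   Syrups, Flavoured Water) where essentially all sugars are free and
   total sugars is used directly.
5. **Aggregate** (`surveillance`): per category/country/year summaries,
   pooled two-proportion z-tests comparing declared-based with
   predicted-based adherence, cumulative yearly trends, and claim
   counting.

Because real launch databases are proprietary, `synthetic_data`
generates label-realistic products with known ground truth: ingredient
lists ordered by quantity with geometric mass shares, panels that are
consistent by construction, category-dependent added-sugar prevalence,
market/year strata, and a sidecar file with the true added/free sugars
that never enters the visible records.

## Worked example

```python
import numpy as np
import sugarscope as s

lex = s.default_lexicon()

# tag a label
names = s.parse_ingredient_list("oat flakes, honey, raisins, salt")
tags = s.tag_ingredients(names, lex)
# names  -> ['oat flakes', 'honey', 'raisins', 'salt']
# added  -> (False, True, False, False, False, False)   honey @ position 2
# fruit  -> (False, False, True, False, False, False)   raisins @ position 3

# score a hot-cereal-like profile: 66 g carbohydrate, 8.8 g fiber, 10.2 g free sugars
v = s.meets_carb_ratio(66.0, 8.8, 10.2)
# meets_10_1=True (8.8 >= 6.6), meets_1_2=True (10.2 < 17.6) -> meets the ratio

# train on the declared market, predict abroad, compare against ground truth
bm = s.make_benchmark(42)                       # 5,000 / 1,000 / 1,000 products
bundle = s.train_bundle(bm.train, bm.validation, lex, seed=42)
preds = s.predict_records(bundle, bm.test, lex)
truth = np.array([bm.sidecar[r.product_id]["true_added_sugars"] for r in bm.test])
rep = s.evaluate(truth, np.array([p.added_sugars_pred for p in preds]))
print(f"MAE {rep.mae:.2f}  R2 {rep.r2:.3f}  MAPE {rep.mape:.1f}%")
# MAE 0.34  R2 0.998  MAPE 4.5%

# compare two adherence proportions (155/485 vs 162/485)
res = s.proportion_ztest(155, 485, 162, 485)
print(round(res.z, 3), round(res.p_value, 2))
# -0.479 0.63
```

The benchmark prediction above reads, for one test product
(`Snack/Cereal/Energy Bars`, ingredients "oat flakes, rice flour,
raisins, fruit juice concentrate, date paste (35%), cocoa powder,
inulin"): presence probability 1.00 → has added sugars, predicted
8.57 g/100 g against a ground truth of 7.58 g/100 g.

There is also a CLI mirroring the pipeline steps:

```bash
sugarscope simulate --n 1000 --seed 1 --out data/
sugarscope clean --in data/products.jsonl --out data/clean.jsonl --report data/rejects.csv
sugarscope train --in data/clean.jsonl --seed 1 --out data/bundle.joblib
sugarscope score --in data/clean.jsonl --bundle data/bundle.joblib --out data/scored.csv
sugarscope aggregate --in data/scored.csv --by market,category --out data/summary.csv
sugarscope ztest --a 155,485 --b 162,485
```

## Layout

| module | role |
| --- | --- |
| `sugarscope.product_io` | read/validate/clean product records, per-100 g normalization |
| `sugarscope.ingredient_tagger` | ingredient-list parsing, regex sugar lexicons, positional tagging |
| `sugarscope.sugar_model` | gated classifiers + stacked regressors, kNN baseline, metrics |
| `sugarscope.carb_quality` | free-sugar assignment, category overrides, 10:1\|1:2 verdicts |
| `sugarscope.surveillance` | group summaries, proportion z-tests, cumulative trends, claims |
| `sugarscope.synthetic_data` | ground-truth-bearing synthetic label data and the fixed benchmark |

See `docs/methods.md` for the modelling assumptions, generator design
and numerical conventions.
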