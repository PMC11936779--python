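# Methods

## Scope and data model

`sugarscope` estimates added- and free-sugar content of packaged foods
from on-pack information and scores carbohydrate quality with the
10:1|1:2 ratio. A product record carries identity metadata (market,
category, sub-category, launch year), a serving size, the raw
ingredient-list text, an eight-field nutrition panel normalized to
100 g (energy kcal, total fat, saturated fat, carbohydrate, fiber,
total sugars, protein in g; sodium in mg), an optional declared
added-sugar value, and a set of marketing claims. Launch dates are
reduced to calendar years because all trend reporting is yearly.

## Cleaning rules

Cleaning is a configurable rule set (`CleaningRules`), applied in a
fixed order so each rejection carries a single enumerable reason:

| check | default |
| --- | --- |
| all panel values present, finite, non-negative | — |
| saturated fat ≤ total fat | + 0.5 g tolerance |
| total sugars ≤ carbohydrate; fiber ≤ carbohydrate | + 0.5 g tolerance |
| fat + carbohydrate + protein | ≤ 105 g /100 g |
| energy vs Atwater 4/9/4 reconstruction | within 25 % relative |
| serving size | > 0 |
| launch year | 2014–2024 window |
| ingredient list | ≥ 1 parseable ingredient |
| declared added sugars | ≤ total sugars + 0.5 g |

The energy check uses 4/9/4 kcal/g for carbohydrate/fat/protein and
deliberately ignores fiber's lower energy contribution; the 25 %
relative tolerance absorbs both that simplification and label
rounding, which is country-specific and not modelled. The pairwise
0.5 g tolerances absorb rounding of individually declared values.
Cleaning is a partition (kept ∪ rejected = input, order preserved) and
is idempotent.

## Ingredient parsing and tagging

Labels list ingredients in descending order of quantity. The parser
splits on top-level commas/semicolons — separators inside balanced
parentheses or brackets belong to compound ingredients and are ignored
— then strips trailing parentheticals ("(cocoa mass, cocoa butter)",
"(35% fat)"), percentage annotations, and common leading qualifiers
("organic", "enriched"). Compound ingredients are *not* expanded into
their sub-ingredients: position semantics refer to the top-level list,
so "milk chocolate (sugar, …)" is one ingredient at its position.

Tagging applies three curated regex lexicons (added sugar, dairy sugar
source, fruit/vegetable sugar source) plus exclusion patterns to each
of the first six parsed ingredients. Exclusions veto all category
matches on that ingredient (sucralose, stevia, sugar alcohols,
"sugar-free" phrasing). Flags are not mutually exclusive: a fruit
juice concentrate is both a fruit term and a free-sugar source, and
both flags are set. The shipped English lexicon (58 added / 16 dairy /
43 fruit-veg / 21 exclusion patterns) is data, not code, and can be
enriched; adding a pattern can only add matches (monotonicity), which
is property-tested. Products with fewer than six ingredients pad the
remaining positions with all-false flags to keep the feature contract
fixed-width.

## Prediction model

Features are a fixed 26-vector: 18 positional tag flags (6 positions ×
3 categories) followed by the 8 panel nutrients. The declared
added-sugar value is the training target and never a feature.

**Presence gate.** Three binary tree-based classifiers — random
forest, extremely randomized trees, histogram gradient boosting (150
trees each for the forests; library defaults for boosting) — are
fitted on the training split to predict `declared > 0`. The combined
decision is a majority vote of the three probabilities thresholded at
a common value tuned on the validation split to maximize balanced
accuracy over a 0.05–0.95 grid. Majority voting was chosen over
probability averaging as the most auditable combination rule; both the
rule and the threshold are configurable (`ModelConfig`).

**Quantity stack.** Two base regressors (random forest, histogram
gradient boosting) are fitted *only* on added-sugar-positive training
records; a ridge meta-regressor is then fitted on their predictions
for the validation positives — held-out stacking, so the meta-weights
are estimated on data the bases never saw. At predict time a
presence-negative product receives exactly 0 g; a positive product
receives the meta-output clipped into `[0, total_sugars]` (the
physical bound that label data obeys by definition), with a flag
recording when clipping fired.

All estimators run single-threaded with seeds derived from the
caller's seed; identical (data, config, seed) gives bit-identical
predictions, and the serialized bundle records seed, split sizes and
hyperparameters and refuses to load across feature-contract versions.

**kNN baseline.** The reference approach regresses declared added
sugars on the 8 nutrients alone (no ingredient information):
Euclidean distance on training-standardized nutrients, mean of the
k = 5 nearest labels. It serves as the comparison point the stacked
pipeline must beat, and as a reminder of how much signal the
ingredient positions carry.

**Metrics.** MAE in g/100 g; MAPE in percent computed only over
positive truths (zero-truth products would make it undefined); R² as
1 − SSres/SStot, reported as missing when all truths are equal. MAPE
is the better ranking metric across categories because categories with
little added sugar have trivially small MAE.

## Free sugars and the 10:1|1:2 ratio

Free sugars = added sugars for most products. In categories where
essentially all sugars are free — Juice Drinks, Carbonated Soft
Drinks, Sweeteners & Sugar, Sugar & Gum Confectionery, and
sub-categories Flavoured Water, Honey, Syrups, Ready To Drink (Iced)
Tea, Water Based Ice Lollies, Pops & Sorbets — total sugars is used
directly, overriding both declared and predicted values. Otherwise the
declared value wins when present (and `prefer_declared` is set), else
the prediction; a product with no applicable source is excluded and
counted. Category matching is exact after whitespace normalization,
case-insensitive, since the lists come from a controlled vocabulary.

The ratio test is scale-invariant, so it is evaluated on the per-100 g
panel directly: 10:1 is inclusive (`fiber ≥ carbohydrate/10`, "at
least"), 1:2 is strict (`free_sugars < 2·fiber`, "less than"), and the
combined verdict is their conjunction. Two edge conventions are
explicit and configurable:

* zero free sugars satisfies 1:2 even at zero fiber (a product with no
  free sugars cannot violate a free-sugar limit);
* zero-carbohydrate products are scored by the same formula (10:1
  vacuously true) rather than excluded, because near-zero-carbohydrate
  beverages are legitimate members of the surveyed categories.

## Surveillance statistics

Group summaries report n, mean ± sample SD (n−1 denominator; SD
missing for single-product groups) for carbohydrate, fiber and free
sugars, and the three meeting-percentages; the combined percentage can
never exceed the smaller component percentage. Percentages are
reported raw; table-style formatting rounds half away from zero to one
decimal.

Declared-based and predicted-based adherence proportions are compared
with the pooled two-proportion z-test, two-sided, without continuity
correction: p̂ = (c_a+c_b)/(n_a+n_b), z = (p_a−p_b)/√(p̂(1−p̂)(1/n_a+1/n_b)).
Equal proportions give p = 1 by definition, which also covers the
zero-SE corner. A Yates-corrected variant is available behind a flag.
This exact variant reproduces published surveillance table p-values at
two decimals once the integer counts are recovered from the printed
n/percent pairs (`recover_count_from_percent` inverts 1-dp half-away
rounding and errors when the inversion is not unique). No
multiple-testing adjustment is applied across category rows, matching
per-row reporting practice. When both proportions are zero the test is
degenerate (p = 1); reporting layers may present it as not applicable.

Time trends are cumulative ("incremental"): the value at year Y is the
percentage meeting the ratio over all products launched up to and
including Y, with the cumulative n attached for marker sizing; the
final-year value equals the whole-window proportion exactly. Claim
counting uses set semantics — a product with several listed claims
counts once.

## Synthetic data generator

The generator defines the study conditions for all tests and the
benchmark; it emulates the *structure* of a commercial launch
database, not any real database's distributions.

Per product: a category recipe is drawn from a weighted mix of 17
categories (all override categories/sub-categories included), a market
and launch year from the market strata, and an ingredient list from
the recipe's term pools — mandatory base ingredients, optional
fillers, an added-sugar term with category-dependent prevalence
(0.25–0.97 by category; a second term with probability 0.3), and
dairy/fruit terms with category probabilities. Order comes from a
noisy type-dependent priority (lognormal jitter, σ = 0.35), so heavier
ingredient types usually but not always lead. The i-th ingredient
receives mass share ∝ 0.55^i of the 100 g basis, and every panel value
is the mass-weighted sum of fixed per-ingredient composition fractions
(sugar + starch + fiber = carbohydrate per ingredient; saturated fat a
fixed share of fat; energy exactly Atwater). Panels are therefore
internally consistent by construction, and true added sugars — the
mass-share sum over added-sugar ingredients — is known exactly and
emitted only in a sidecar keyed by product id.

Declared added sugars exist only in markets configured as declaring.
The declared value is truth plus Normal(0, 0.5 g) noise truncated to
[0, total sugars] when truth is positive, and exactly 0 when truth is
zero: a label for a product with no added-sugar ingredients declares
0 g, so label noise does not manufacture false positive presence
labels. With `noise_sd = 0` the declared value equals truth exactly.

Corruption (for cleaning tests) injects one named invariant violation
per selected record — sugars above carbohydrate, a negative nutrient,
saturated above total fat, inconsistent energy, macro sum above the
cap, or an emptied ingredient list — and flags it in the sidecar, so
the cleaner's kept count can be checked against the generator's
bookkeeping exactly.

**The benchmark** (`make_benchmark`): 5,000 training and 1,000
validation products from a single declaring market, 1,000 test
products from three non-declaring markets, same category mix. Test
performance is measured against sidecar truth, mirroring the
train-at-home / predict-abroad protocol at desk scale. These sizes
keep a full train-and-evaluate cycle around ten seconds on one CPU
while leaving ~750 positive test products for MAPE.

**What the generator does not emulate** — and hence what passing tests
do not show about real data: real category frequencies and nutrient
distributions; label rounding rules; multilingual or free-text
ingredient phrasing beyond the dressing the parser handles;
ingredient–panel inconsistencies (real labels disagree with their
ingredient lists more than truncated-normal noise does); and the
geometric mass-share profile overweights mid-list ingredients relative
to real recipes, making synthetic products systematically sweeter than
their real counterparts. Benchmark MAE (~0.3–0.4 g/100 g across seeds)
is therefore a statement about method consistency under the
generator's assumptions, not a forecast of accuracy on a commercial
database; the *ordering* of the stacked pipeline versus the
nutrients-only kNN baseline (~1.5–1.8 g/100 g) is the robust,
transferable observation.

## Numerical conventions and degenerate inputs

* Rounding for report formatting: half away from zero, 1 dp; all
  internal arithmetic unrounded.
* `normalize_to_100g` is linear (degree 1 in nutrients, −1 in serving
  size); sodium stays in mg; kJ inputs are converted at 4.184 kJ/kcal.
* Stratified splitting uses exact rounded sizes with presence
  stratification; an empty stratum is an error, not a silent fallback.
* Training requires ≥ 200 positive records (configurable); the ridge
  meta-regressor falls back to an equal-weight blend if the validation
  split has fewer than five positives.
* Standardization in the kNN baseline replaces zero SDs with 1 to keep
  constant nutrients from producing NaN distances.
* All randomness flows from caller-supplied integer seeds; derived
  seeds stay below 2^31.

## Known limitations

* The default lexicon is English-only; other languages are
  user-supplied lexicons.
* Compound-ingredient expansion is off by default; products that hide
  all sugars inside a compound ingredient ("chocolate chips (sugar,
  …)") can be tagged sugar-free, which mirrors a real failure mode of
  position-based tagging.
* Presence labelling uses `declared > 0`; jurisdictions that allow
  rounding small amounts to zero blur this boundary, and the threshold
  is configurable for that reason.
* The z-test is asymptotic; for very small groups an exact test would
  be preferable, but the pooled z matches surveillance reporting
  practice.
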