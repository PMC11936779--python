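"""Gated two-stage prediction of added-sugar content.

The predictor mirrors how a label reader reasons: first decide whether a
product contains added sugars at all (three tree-based binary
classifiers combined by majority vote), and only if so estimate the
amount (two tree-ensemble base regressors stacked under a linear
meta-regressor, trained on added-sugar-positive products only).
Features are the positional sugar tags of the first six ingredients
plus the eight panel nutrients per 100 g; the declared label never
enters the features.

A k-nearest-neighbours regressor on standardized nutrients alone is
provided as the reference baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import (
    ExtraTreesClassifier,
    HistGradientBoostingClassifier,
    HistGradientBoostingRegressor,
    RandomForestClassifier,
    RandomForestRegressor,
)
from sklearn.linear_model import Ridge
from sklearn.metrics import balanced_accuracy_score
from sklearn.model_selection import train_test_split
from sklearn.neighbors import NearestNeighbors

from .ingredient_tagger import (
    N_TAG_POSITIONS,
    IngredientTagVector,
    SugarLexicon,
    parse_ingredient_list,
    tag_ingredients,
)
from .product_io import NUTRIENT_COLUMNS, ProductRecord

__all__ = [
    "FEATURE_NAMES",
    "N_FEATURES",
    "ModelConfig",
    "TrainedBundle",
    "PredictionResult",
    "EvalReport",
    "build_features",
    "build_feature_matrix",
    "split_dataset",
    "train_bundle",
    "predict_added_sugars",
    "predict_records",
    "knn_baseline",
    "evaluate",
]

BUNDLE_FORMAT_VERSION = 1

#: Feature contract: 18 positional tag flags then the 8 panel nutrients.
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"pos{p + 1}_{cat}"
    for p in range(N_TAG_POSITIONS)
    for cat in ("added_sugar", "dairy", "fruit_veg")
) + NUTRIENT_COLUMNS

N_FEATURES = len(FEATURE_NAMES)  # 26
_N_TAG_FEATURES = 3 * N_TAG_POSITIONS


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the gated stack (all tree sizes deliberately modest).

    ``presence_threshold`` is tuned on the validation split over
    ``threshold_grid`` to maximize balanced accuracy of the majority
    vote unless fixed here.
    """

    n_estimators: int = 150
    min_positive_train: int = 200
    threshold_grid: tuple[float, ...] = tuple(np.round(np.arange(0.05, 0.96, 0.05), 2))
    presence_threshold: float | None = None
    positive_label_min_g: float = 0.0  # declared > this counts as presence
    knn_k: int = 5


@dataclass
class PredictionResult:
    presence_probability: float
    has_added_sugar: bool
    added_sugars_pred: float
    clipped: bool


@dataclass
class EvalReport:
    """MAE in g/100 g; MAPE in percent over truths > 0; R² unitless."""

    n: int
    mae: float
    mape: float | None
    r2: float | None
    residual_mean: float
    residual_sd: float
    per_group: dict[str, "EvalReport"] = field(default_factory=dict)


@dataclass
class TrainedBundle:
    """Serializable fitted predictor (classifiers + stack + metadata)."""

    classifiers: list
    presence_threshold: float
    base_regressors: list
    meta_regressor: Ridge
    feature_names: tuple[str, ...]
    metadata: dict
    format_version: int = BUNDLE_FORMAT_VERSION

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedBundle":
        bundle = joblib.load(path)
        if not isinstance(bundle, cls):
            raise TypeError(f"{path} does not contain a TrainedBundle")
        if bundle.format_version != BUNDLE_FORMAT_VERSION:
            raise ValueError(
                f"bundle format {bundle.format_version} incompatible with {BUNDLE_FORMAT_VERSION}"
            )
        if tuple(bundle.feature_names) != FEATURE_NAMES:
            raise ValueError("bundle was trained under a different feature contract")
        return bundle


def build_features(record: ProductRecord, tags: IngredientTagVector) -> np.ndarray:
    """Assemble the 26-long feature vector (tags then nutrients).

    The declared added-sugar label is deliberately absent: it is the
    training target, never a feature.
    """
    nutrients = record.panel.as_tuple()
    if any(not np.isfinite(v) for v in nutrients):
        raise ValueError(f"record {record.product_id}: non-finite nutrient (clean first)")
    vec = np.empty(N_FEATURES)
    vec[:_N_TAG_FEATURES] = tags.flags()
    vec[_N_TAG_FEATURES:] = nutrients
    return vec


def build_feature_matrix(
    records: Sequence[ProductRecord], lexicon: SugarLexicon
) -> np.ndarray:
    """Parse, tag and stack features for a batch of records."""
    rows = [
        build_features(r, tag_ingredients(parse_ingredient_list(r.ingredient_text), lexicon))
        for r in records
    ]
    return np.asarray(rows).reshape(len(rows), N_FEATURES)


def split_dataset(
    records: Sequence[ProductRecord],
    fractions: tuple[float, float, float] = (0.8, 0.1, 0.1),
    seed: int = 0,
    positive_label_min_g: float = 0.0,
) -> tuple[list[ProductRecord], list[ProductRecord], list[ProductRecord]]:
    """Reproducible stratified train/validation/test split.

    Stratifies on presence of added sugars (declared > threshold);
    splits are disjoint and exhaustive with sizes round(f·n).
    """
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    if any(r.declared_added_sugars is None for r in records):
        raise ValueError("every record needs declared_added_sugars to be split")
    n = len(records)
    labels = np.array(
        [int(r.declared_added_sugars > positive_label_min_g) for r in records]
    )
    if labels.min() == labels.max():
        raise ValueError("a presence stratum is empty; cannot stratify")
    idx = np.arange(n)
    n_test = int(round(fractions[2] * n))
    n_val = int(round(fractions[1] * n))
    rest, test_idx = train_test_split(
        idx, test_size=n_test, stratify=labels, random_state=seed
    )
    train_idx, val_idx = train_test_split(
        rest, test_size=n_val, stratify=labels[rest], random_state=seed + 1
    )
    pick = lambda ix: [records[i] for i in sorted(ix)]
    return pick(train_idx), pick(val_idx), pick(test_idx)


def _presence_votes(classifiers, X: np.ndarray) -> np.ndarray:
    """(n, 3) matrix of positive-class probabilities."""
    return np.column_stack([clf.predict_proba(X)[:, 1] for clf in classifiers])


def _majority(probs: np.ndarray, threshold: float) -> np.ndarray:
    return (probs >= threshold).sum(axis=1) >= 2


def train_bundle(
    train: Sequence[ProductRecord],
    validation: Sequence[ProductRecord],
    lexicon: SugarLexicon,
    config: ModelConfig | None = None,
    seed: int = 0,
) -> TrainedBundle:
    """Fit the gated stack on declared-label records.

    Presence classifiers (random forest, extremely randomized trees,
    gradient-boosted trees) are fitted on the training split; the
    majority-vote threshold is tuned on the validation split.  The
    quantity stack is fitted only on added-sugar-positive records: base
    ensembles on the training positives, the linear meta-regressor on
    their held-out validation predictions (classic stacking).
    """
    config = config or ModelConfig()
    X_tr = build_feature_matrix(train, lexicon)
    X_val = build_feature_matrix(validation, lexicon)
    y_tr = np.array([r.declared_added_sugars for r in train], dtype=float)
    y_val = np.array([r.declared_added_sugars for r in validation], dtype=float)
    pos_tr = y_tr > config.positive_label_min_g
    pos_val = y_val > config.positive_label_min_g
    if pos_tr.sum() < config.min_positive_train:
        raise ValueError(
            f"only {int(pos_tr.sum())} positive training records "
            f"(minimum {config.min_positive_train})"
        )

    classifiers = [
        RandomForestClassifier(
            n_estimators=config.n_estimators, random_state=seed, n_jobs=1
        ),
        ExtraTreesClassifier(
            n_estimators=config.n_estimators, random_state=seed + 1, n_jobs=1
        ),
        HistGradientBoostingClassifier(random_state=seed + 2),
    ]
    for clf in classifiers:
        clf.fit(X_tr, pos_tr.astype(int))

    if config.presence_threshold is not None:
        threshold = float(config.presence_threshold)
    else:
        val_probs = _presence_votes(classifiers, X_val)
        scores = [
            balanced_accuracy_score(pos_val, _majority(val_probs, t))
            for t in config.threshold_grid
        ]
        threshold = float(config.threshold_grid[int(np.argmax(scores))])

    base_regressors = [
        RandomForestRegressor(
            n_estimators=config.n_estimators, random_state=seed + 3, n_jobs=1
        ),
        HistGradientBoostingRegressor(random_state=seed + 4),
    ]
    for reg in base_regressors:
        reg.fit(X_tr[pos_tr], y_tr[pos_tr])

    meta = Ridge(alpha=1.0, random_state=seed)
    if pos_val.sum() >= 5:
        Z_val = np.column_stack([reg.predict(X_val[pos_val]) for reg in base_regressors])
        meta.fit(Z_val, y_val[pos_val])
    else:  # degenerate validation: fall back to an equal-weight blend
        meta.coef_ = np.array([0.5, 0.5])
        meta.intercept_ = 0.0

    metadata = {
        "seed": seed,
        "n_train": len(train),
        "n_validation": len(validation),
        "n_positive_train": int(pos_tr.sum()),
        "presence_threshold": threshold,
        "config": config.__dict__ | {"threshold_grid": list(config.threshold_grid)},
    }
    return TrainedBundle(
        classifiers=classifiers,
        presence_threshold=threshold,
        base_regressors=base_regressors,
        meta_regressor=meta,
        feature_names=FEATURE_NAMES,
        metadata=metadata,
    )


def predict_added_sugars(
    bundle: TrainedBundle,
    features: np.ndarray,
    total_sugars: float | np.ndarray,
) -> PredictionResult | list[PredictionResult]:
    """Apply the gate: presence vote first, quantity only if positive.

    A presence-negative product gets exactly 0 g.  A positive product's
    stacked estimate is clipped into [0, total_sugars]; the ``clipped``
    flag records when clipping fired.
    """
    single = features.ndim == 1
    X = np.atleast_2d(np.asarray(features, dtype=float))
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} features, got {X.shape[1]}")
    totals = np.broadcast_to(np.atleast_1d(np.asarray(total_sugars, dtype=float)), (X.shape[0],))
    probs = _presence_votes(bundle.classifiers, X)
    positive = _majority(probs, bundle.presence_threshold)
    mean_prob = probs.mean(axis=1)
    raw = np.zeros(X.shape[0])
    if positive.any():
        Z = np.column_stack([reg.predict(X[positive]) for reg in bundle.base_regressors])
        raw[positive] = bundle.meta_regressor.predict(Z)
    clipped_vals = np.clip(raw, 0.0, totals)
    results = [
        PredictionResult(
            presence_probability=float(mean_prob[i]),
            has_added_sugar=bool(positive[i]),
            added_sugars_pred=float(clipped_vals[i]) if positive[i] else 0.0,
            clipped=bool(positive[i] and clipped_vals[i] != raw[i]),
        )
        for i in range(X.shape[0])
    ]
    return results[0] if single else results


def predict_records(
    bundle: TrainedBundle,
    records: Sequence[ProductRecord],
    lexicon: SugarLexicon,
) -> list[PredictionResult]:
    """Convenience wrapper: parse/tag/featurize then predict per record."""
    if not records:
        return []
    X = build_feature_matrix(records, lexicon)
    totals = np.array([r.panel.total_sugars for r in records])
    return predict_added_sugars(bundle, X, totals)


def knn_baseline(
    train_nutrients: np.ndarray,
    train_labels: np.ndarray,
    query_nutrients: np.ndarray,
    k: int = 5,
) -> np.ndarray:
    """k-nearest-neighbours mean of declared added sugars.

    Distances are Euclidean on nutrients standardized by the training
    mean and standard deviation (ingredient tags deliberately unused --
    this is the nutrients-only reference approach).
    """
    train_nutrients = np.asarray(train_nutrients, dtype=float)
    train_labels = np.asarray(train_labels, dtype=float)
    query = np.atleast_2d(np.asarray(query_nutrients, dtype=float))
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(train_nutrients):
        raise ValueError(f"k={k} exceeds training size {len(train_nutrients)}")
    mu = train_nutrients.mean(axis=0)
    sd = train_nutrients.std(axis=0)
    sd[sd == 0] = 1.0
    nn = NearestNeighbors(n_neighbors=k).fit((train_nutrients - mu) / sd)
    _, idx = nn.kneighbors((query - mu) / sd)
    return train_labels[idx].mean(axis=1)


def evaluate(
    truths: Sequence[float],
    predictions: Sequence[float],
    groups: Sequence[str] | None = None,
) -> EvalReport:
    """MAE, MAPE (percent, over truths > 0) and R², with per-group breakdown.

    R² is reported as missing when all truths are equal (SStot = 0).
    """
    y = np.asarray(truths, dtype=float)
    p = np.asarray(predictions, dtype=float)
    if y.size == 0 or y.shape != p.shape:
        raise ValueError("need non-empty, equal-length truth/prediction arrays")
    resid = p - y
    mae = float(np.abs(resid).mean())
    positive = y > 0
    mape = (
        float((np.abs(resid[positive]) / y[positive]).mean() * 100.0)
        if positive.any()
        else None
    )
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float((resid**2).sum()) / ss_tot if ss_tot > 0 else None
    report = EvalReport(
        n=int(y.size),
        mae=mae,
        mape=mape,
        r2=r2,
        residual_mean=float(resid.mean()),
        residual_sd=float(resid.std(ddof=1)) if y.size > 1 else 0.0,
    )
    if groups is not None:
        garr = np.asarray(groups)
        for g in sorted(set(garr.tolist())):
            mask = garr == g
            report.per_group[str(g)] = evaluate(y[mask], p[mask])
    return report
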