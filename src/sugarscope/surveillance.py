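"""Surveillance aggregation: group summaries, proportion tests, trends.

Once every product carries a 10:1|1:2 verdict, the surveillance layer
answers the monitoring questions: what share of a category's (or
country's) launches meets the carbohydrate-quality ratio, do
declared-based and predicted-based shares differ (pooled two-proportion
z-test), and how does the cumulative share evolve by launch year.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm

from .product_io import ProductRecord

__all__ = [
    "GroupSummary",
    "ZTestResult",
    "AmbiguousPercentError",
    "summarize_groups",
    "proportion_ztest",
    "recover_count_from_percent",
    "trend_by_year",
    "count_claim_products",
    "round_half_away",
]

_NUTRIENTS = ("carbohydrate", "fiber", "free_sugars")
_FLAGS = ("meets_10_1", "meets_1_2", "meets_combined")


def round_half_away(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (table-report convention)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class GroupSummary:
    """Per-group sample size, nutrient mean±SD and ratio-meeting shares."""

    key: tuple
    n: int
    mean: dict[str, float]
    sd: dict[str, float | None]  # sample SD (n-1); None when n == 1
    pct_meeting_10_1: float
    pct_meeting_1_2: float
    pct_meeting_combined: float


@dataclass(frozen=True)
class ZTestResult:
    count_a: int
    n_a: int
    count_b: int
    n_b: int
    z: float
    p_value: float


class AmbiguousPercentError(ValueError):
    def __init__(self, pct: float, n: int, candidates: list[int]):
        self.candidates = candidates
        super().__init__(
            f"percent {pct} with n={n} maps to counts {candidates or 'none'}"
        )


def summarize_groups(scored: pd.DataFrame, keys: Sequence[str]) -> list[GroupSummary]:
    """Aggregate a scored frame by the given keys (market/category/year).

    Expects the columns produced by :func:`carb_quality.score_products`.
    Empty groups cannot occur (groupby omits them); single-product
    groups report SD as missing.
    """
    required = set(keys) | set(_NUTRIENTS) | set(_FLAGS)
    missing = required - set(scored.columns)
    if missing:
        raise KeyError(f"scored frame lacks columns: {sorted(missing)}")
    out: list[GroupSummary] = []
    for key, grp in scored.groupby(list(keys), sort=True):
        key = key if isinstance(key, tuple) else (key,)
        n = len(grp)
        mean = {c: float(grp[c].mean()) for c in _NUTRIENTS}
        sd = {c: (float(grp[c].std(ddof=1)) if n > 1 else None) for c in _NUTRIENTS}
        pct = {c: 100.0 * float(grp[c].mean()) for c in _FLAGS}
        out.append(
            GroupSummary(
                key=key,
                n=n,
                mean=mean,
                sd=sd,
                pct_meeting_10_1=pct["meets_10_1"],
                pct_meeting_1_2=pct["meets_1_2"],
                pct_meeting_combined=pct["meets_combined"],
            )
        )
    return out


def summaries_to_frame(summaries: Sequence[GroupSummary], keys: Sequence[str]) -> pd.DataFrame:
    rows = []
    for s in summaries:
        row = dict(zip(keys, s.key))
        row["n"] = s.n
        for c in _NUTRIENTS:
            row[f"{c}_mean"] = s.mean[c]
            row[f"{c}_sd"] = s.sd[c]
        row["pct_meeting_10_1"] = s.pct_meeting_10_1
        row["pct_meeting_1_2"] = s.pct_meeting_1_2
        row["pct_meeting_combined"] = s.pct_meeting_combined
        rows.append(row)
    return pd.DataFrame(rows)


def proportion_ztest(
    count_a: int, n_a: int, count_b: int, n_b: int, continuity: bool = False
) -> ZTestResult:
    """Pooled two-proportion z-test, two-sided, no continuity correction.

    p̂ = (count_a + count_b)/(n_a + n_b);
    z = (p_a − p_b) / sqrt(p̂(1−p̂)(1/n_a + 1/n_b)).
    Equal proportions give p = 1 by definition (covers the zero-SE
    corner where both pooled extremes coincide).  ``continuity`` applies
    the Yates correction to the numerator.
    """
    for count, n in ((count_a, n_a), (count_b, n_b)):
        if n < 1:
            raise ValueError("group sizes must be >= 1")
        if not 0 <= count <= n:
            raise ValueError(f"count {count} outside [0, {n}]")
    p_a, p_b = count_a / n_a, count_b / n_b
    if p_a == p_b:
        return ZTestResult(count_a, n_a, count_b, n_b, z=0.0, p_value=1.0)
    pooled = (count_a + count_b) / (n_a + n_b)
    se = math.sqrt(pooled * (1.0 - pooled) * (1.0 / n_a + 1.0 / n_b))
    diff = p_a - p_b
    if continuity:
        correction = 0.5 * (1.0 / n_a + 1.0 / n_b)
        diff = math.copysign(max(abs(diff) - correction, 0.0), diff)
    z = diff / se
    p = 2.0 * float(norm.sf(abs(z)))
    return ZTestResult(count_a, n_a, count_b, n_b, z=z, p_value=min(p, 1.0))


def recover_count_from_percent(pct: float, n: int) -> int:
    """Invert a printed 1-dp percentage back to the integer count.

    Returns the unique k in [0, n] with round(100k/n, 1) == pct
    (half-away rounding); raises :class:`AmbiguousPercentError` when no
    k or several k reproduce the printed figure.
    """
    if not 0 <= pct <= 100:
        raise ValueError("pct must be in [0, 100]")
    if n < 1:
        raise ValueError("n must be >= 1")
    target = round_half_away(pct, 1)
    candidates = [
        k for k in range(n + 1) if round_half_away(100.0 * k / n, 1) == target
    ]
    if len(candidates) != 1:
        raise AmbiguousPercentError(pct, n, candidates)
    return candidates[0]


def trend_by_year(
    scored: pd.DataFrame,
    window: tuple[int, int] = (2014, 2024),
    by: Sequence[str] | None = None,
    flag: str = "meets_combined",
) -> pd.DataFrame:
    """Cumulative adherence trend by launch year.

    For each year Y in the window, the value is the percentage meeting
    the ratio over all products launched up to and including Y (the
    incremental convention); ``cum_n`` is the matching cumulative count,
    suitable for sizing trend markers.  At the final year the cumulative
    value equals the whole-window proportion exactly.
    """
    lo, hi = window
    if lo > hi:
        return pd.DataFrame(columns=list(by or []) + ["launch_year", "cum_n", "cum_pct"])
    frame = scored[(scored["launch_year"] >= lo) & (scored["launch_year"] <= hi)]
    rows = []
    group_iter = (
        frame.groupby(list(by), sort=True) if by else [((), frame)]
    )
    for key, grp in group_iter:
        key = key if isinstance(key, tuple) else (key,)
        per_year = (
            grp.groupby("launch_year")[flag]
            .agg(["size", "sum"])
            .reindex(range(lo, hi + 1), fill_value=0)
        )
        cum_n = per_year["size"].cumsum()
        cum_meet = per_year["sum"].cumsum()
        for year in per_year.index:
            n = int(cum_n.loc[year])
            rows.append(
                dict(zip(by or (), key))
                | {
                    "launch_year": int(year),
                    "cum_n": n,
                    "cum_pct": (100.0 * float(cum_meet.loc[year]) / n) if n else float("nan"),
                }
            )
    return pd.DataFrame(rows)


def count_claim_products(
    records: Iterable[ProductRecord], claim_set: Iterable[str]
) -> pd.DataFrame:
    """Per-market count and percentage of products bearing >= 1 listed claim.

    A product counts once no matter how many of the listed claims it
    carries (set semantics).
    """
    claims = {c.strip().casefold() for c in claim_set}
    per_market: dict[str, list[int]] = {}
    for rec in records:
        n_total, n_claim = per_market.setdefault(rec.market, [0, 0])
        per_market[rec.market][0] = n_total + 1
        if any(c.strip().casefold() in claims for c in rec.claims):
            per_market[rec.market][1] = n_claim + 1
    rows = [
        {
            "market": market,
            "n": total,
            "n_with_claim": with_claim,
            "pct_with_claim": 100.0 * with_claim / total,
        }
        for market, (total, with_claim) in sorted(per_market.items())
    ]
    return pd.DataFrame(rows, columns=["market", "n", "n_with_claim", "pct_with_claim"])
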