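"""Ingredient-list parsing and regex-based sugar tagging.

Labels list ingredients in descending order of quantity, so the first
few positions carry most of the product's mass.  Each of the first six
ingredients is tagged as an added sugar, a dairy sugar source, or a
fruit/vegetable sugar source using curated regular-expression lexicons;
the resulting positional flags are the signal half of the prediction
feature vector.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import yaml

__all__ = [
    "SugarLexicon",
    "IngredientTagVector",
    "LexiconError",
    "compile_lexicon",
    "default_lexicon",
    "parse_ingredient_list",
    "tag_ingredients",
    "N_TAG_POSITIONS",
]

#: Number of leading ingredient positions that enter the feature contract.
N_TAG_POSITIONS = 6

_CATEGORIES = ("added_sugar", "dairy", "fruit_veg")


class LexiconError(ValueError):
    """A lexicon file failed validation (names the offending pattern)."""


@dataclass(frozen=True)
class SugarLexicon:
    """Compiled, order-preserving regex term sets.

    ``exclusions`` veto any category match on the same ingredient name
    (non-caloric sweeteners and similar false friends).
    """

    added_sugar: tuple[re.Pattern, ...]
    dairy: tuple[re.Pattern, ...]
    fruit_veg: tuple[re.Pattern, ...]
    exclusions: tuple[re.Pattern, ...] = ()

    def category_patterns(self, category: str) -> tuple[re.Pattern, ...]:
        return getattr(self, category)

    def matches(self, category: str, name: str) -> bool:
        """True when a category pattern hits and no exclusion vetoes it."""
        if any(p.search(name) for p in self.exclusions):
            return False
        return any(p.search(name) for p in self.category_patterns(category))


@dataclass(frozen=True)
class IngredientTagVector:
    """Per-position sugar flags for the first six parsed ingredients."""

    is_added_sugar: tuple[bool, ...]
    is_dairy: tuple[bool, ...]
    is_fruit_veg: tuple[bool, ...]
    n_ingredients_parsed: int = 0

    def __post_init__(self):
        for name in ("is_added_sugar", "is_dairy", "is_fruit_veg"):
            if len(getattr(self, name)) != N_TAG_POSITIONS:
                raise ValueError(f"{name} must have length {N_TAG_POSITIONS}")

    def flags(self) -> tuple[int, ...]:
        """Flattened 18-long 0/1 block, position-major: (added, dairy, fruit_veg) x 6."""
        out = []
        for p in range(N_TAG_POSITIONS):
            out += [int(self.is_added_sugar[p]), int(self.is_dairy[p]), int(self.is_fruit_veg[p])]
        return tuple(out)


def _compile_list(patterns: Iterable[str], key: str) -> tuple[re.Pattern, ...]:
    compiled: list[re.Pattern] = []
    seen: set[str] = set()
    for raw in patterns:
        if raw in seen:
            warnings.warn(f"duplicate lexicon pattern dropped: {raw!r}", stacklevel=3)
            continue
        seen.add(raw)
        try:
            pat = re.compile(raw, re.IGNORECASE)
        except re.error as exc:
            raise LexiconError(f"invalid regex in {key!r}: {raw!r} ({exc})") from exc
        if pat.search(""):
            raise LexiconError(f"pattern in {key!r} matches the empty string: {raw!r}")
        compiled.append(pat)
    return tuple(compiled)


def compile_lexicon(source: str | Path | Mapping[str, Sequence[str]]) -> SugarLexicon:
    """Compile a lexicon from a YAML file or an in-memory mapping.

    The file carries keys ``added_sugar``, ``dairy``, ``fruit_veg`` and
    optionally ``exclusions``, each a list of case-insensitive regex
    strings.  Duplicates are dropped with a warning; an invalid regex
    raises :class:`LexiconError` naming the pattern.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh)
    else:
        data = dict(source)
    if not isinstance(data, Mapping):
        raise LexiconError("lexicon source must be a mapping of category -> pattern list")
    for key in _CATEGORIES:
        if not data.get(key):
            raise LexiconError(f"lexicon category {key!r} is missing or empty")
    return SugarLexicon(
        added_sugar=_compile_list(data["added_sugar"], "added_sugar"),
        dairy=_compile_list(data["dairy"], "dairy"),
        fruit_veg=_compile_list(data["fruit_veg"], "fruit_veg"),
        exclusions=_compile_list(data.get("exclusions") or (), "exclusions"),
    )


def default_lexicon() -> SugarLexicon:
    """The shipped English lexicon (data/lexicon_en.yaml)."""
    ref = resources.files("sugarscope.data") / "lexicon_en.yaml"
    with resources.as_file(ref) as path:
        return compile_lexicon(path)


_LEADING_QUALIFIERS = re.compile(
    r"^(?:organic|enriched|unbleached|fortified|natural|fresh|dried|pure|refined)\s+",
    re.IGNORECASE,
)
_PERCENT_ANNOTATION = re.compile(r"\s*\(?\s*\d+(?:[.,]\d+)?\s*%\s*\)?")


def _split_top_level(text: str) -> list[str]:
    """Split on commas/semicolons outside balanced parentheses/brackets."""
    parts: list[str] = []
    depth = 0
    buf: list[str] = []
    for ch in text:
        if ch in "([":
            depth += 1
        elif ch in ")]":
            depth = max(0, depth - 1)
        if ch in ",;" and depth == 0:
            parts.append("".join(buf))
            buf = []
        else:
            buf.append(ch)
    parts.append("".join(buf))
    return parts


def _clean_name(raw: str) -> str:
    # drop a trailing parenthetical first (sub-ingredients, origin notes,
    # "(35% fat)") so bare percentage annotations are all that remain
    name = re.sub(r"\s*[\(\[][^)\]]*[\)\]]\s*$", "", raw.strip())
    name = _PERCENT_ANNOTATION.sub("", name).strip(" .\t\n")
    name = _LEADING_QUALIFIERS.sub("", name)
    return name.strip()


def parse_ingredient_list(text: str) -> list[str]:
    """Parse raw label text into an ordered list of ingredient names.

    Splits on top-level commas and semicolons (separators inside
    balanced parentheses or brackets belong to compound ingredients and
    are ignored), strips percentage annotations, trailing parentheticals
    and common leading qualifiers, and preserves label order.  An empty
    or unusable string yields an empty list.
    """
    if not text or not text.strip():
        return []
    stripped = re.sub(r"^\s*ingredients?\s*:\s*", "", text, flags=re.IGNORECASE)
    names = [_clean_name(part) for part in _split_top_level(stripped)]
    return [n for n in names if n]


def tag_ingredients(names: Sequence[str], lexicon: SugarLexicon) -> IngredientTagVector:
    """Tag the first six ingredient names against the lexicon.

    Deterministic: positions beyond the parsed count (or beyond six)
    carry all-false flags; an ingredient matching an exclusion pattern
    gets no flags at all.  Flags are not mutually exclusive — a fruit
    juice concentrate is both a fruit and a free-sugar source.
    """
    added = [False] * N_TAG_POSITIONS
    dairy = [False] * N_TAG_POSITIONS
    fruit = [False] * N_TAG_POSITIONS
    for pos, raw in enumerate(names[:N_TAG_POSITIONS]):
        name = raw.strip()
        if not name:
            continue
        added[pos] = lexicon.matches("added_sugar", name)
        dairy[pos] = lexicon.matches("dairy", name)
        fruit[pos] = lexicon.matches("fruit_veg", name)
    return IngredientTagVector(
        is_added_sugar=tuple(added),
        is_dairy=tuple(dairy),
        is_fruit_veg=tuple(fruit),
        n_ingredients_parsed=len(names),
    )
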