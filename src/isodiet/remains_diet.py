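"""Conventional diet analysis from food remains.

Each identified remain is classified into one of six categories
(landfill, livestock, wild_herbivores, carnivores, birds, others) by a
deterministic rule cascade, counted under taxon-group-specific counting
rules (minimum number of individuals for invertebrates and small/medium
vertebrates and birds; skeletal fragments for carnivores and ungulates),
and converted to per-nest-year diet proportions.

Classification rules:

* any remain with cut / butchery / cooking marks is of landfill origin;
* white rabbit hair is domestic (livestock); brown rabbit hair is
  assigned by hair length class (long = wild, short = domestic);
* black pig-family hair is wild boar (wild herbivore);
* remains whose origin cannot be resolved are 'undetermined' and are
  excluded from category totals.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from isodiet.types import (
    CATEGORIES,
    CATEGORIES_WITH_OTHERS,
    UNDETERMINED,
    CategoryCounts,
    DietProportions,
    RemainRecord,
    ValidationError,
)

logger = logging.getLogger(__name__)

# Taxon vocabularies driving the rule cascade.  Lowercased containment
# match; extend these sets to adapt the classifier to another system.
LIVESTOCK_TAXA = frozenset(
    {"sheep", "goat", "cattle", "cow", "calf", "horse", "donkey", "pig", "domestic_pig"}
)
WILD_UNGULATE_TAXA = frozenset(
    {"wild_boar", "boar", "roe_deer", "red_deer", "deer", "chamois", "ibex", "mouflon"}
)
RABBIT_TAXA = frozenset({"rabbit", "oryctolagus", "oryctolagus_cuniculus"})
PIG_FAMILY_TAXA = frozenset({"pig", "domestic_pig", "wild_boar", "boar", "sus", "sus_scrofa"})


def _norm(taxon: str) -> str:
    return taxon.strip().lower().replace(" ", "_")


def _is_rabbit(taxon: str) -> bool:
    return _norm(taxon) in RABBIT_TAXA


def _is_pig_family(taxon: str) -> bool:
    return _norm(taxon) in PIG_FAMILY_TAXA


def classify_remain(record: RemainRecord) -> str:
    """Assign one remain to a diet category (or 'undetermined').

    Total and deterministic: every valid record maps to exactly one of
    {landfill, livestock, wild_herbivores, carnivores, birds, others,
    undetermined}.
    """
    taxon = _norm(record.taxon)

    # Butchery / cooking traces mark human processing -> landfill origin,
    # whatever the taxon.
    if record.butchery_marks:
        return "landfill"

    if record.item_kind == "hair":
        if _is_rabbit(taxon):
            if record.hair_color == "white":
                return "livestock"
            if record.hair_color == "brown":
                if record.hair_length_class == "wild_long":
                    return "wild_herbivores"
                if record.hair_length_class == "domestic_short":
                    return "livestock"
                return UNDETERMINED
            return UNDETERMINED
        if _is_pig_family(taxon):
            if record.hair_color == "black":
                return "wild_herbivores"
            if record.hair_color in ("white", "brown"):
                return "livestock"
            return UNDETERMINED

    if _is_rabbit(taxon):
        return "wild_herbivores"
    if taxon in WILD_UNGULATE_TAXA:
        return "wild_herbivores"
    if taxon in LIVESTOCK_TAXA:
        return "livestock"

    group = record.taxon_group
    if group == "carnivore":
        return "carnivores"
    if group == "bird":
        return "birds"
    if group in ("invertebrate", "other"):
        return "others"
    if group == "small_medium_vertebrate":
        # micro-mammals, reptiles, amphibians, fish (rabbit handled above)
        return "others"
    if group == "ungulate":
        # ungulate of unresolved domestic/wild status
        return UNDETERMINED
    raise ValidationError(f"unclassifiable taxon_group {group!r}")


_FRAGMENT_GROUPS = ("carnivore", "ungulate")


def _mni(records: list[RemainRecord]) -> int:
    """Minimum number of individuals: max total count over diagnostic
    (element, side) classes, whole specimens counting individually."""
    by_element: dict[tuple[str | None, str | None], int] = defaultdict(int)
    for r in records:
        by_element[(r.element, r.side)] += r.count
    return max(by_element.values()) if by_element else 0


def _fragments(records: list[RemainRecord]) -> int:
    """Skeletal-fragment count: bones and skull fragments count per record;
    distal limb parts collapse up to three elements of one limb into one."""
    n = 0
    limb_parts: dict[str | None, int] = defaultdict(int)
    for r in records:
        if r.item_kind == "distal_limb_part":
            limb_parts[r.side] += r.count * r.n_elements
        else:
            n += r.count
    for total in limb_parts.values():
        n += math.ceil(total / 3)
    return n


def count_items(records: Iterable[RemainRecord]) -> list[CategoryCounts]:
    """Count classified remains per nest-year under the counting rules.

    The two sampling moments of one nest-year pool into a single
    observation.  Output sorted by (nest, year).
    """
    groups: dict[tuple[str, int], dict[tuple[str, str], list[RemainRecord]]] = defaultdict(
        lambda: defaultdict(list)
    )
    for r in records:
        category = classify_remain(r)
        groups[(str(r.nest_id), int(r.year))][(category, _norm(r.taxon))].append(r)

    out: list[CategoryCounts] = []
    for (nest, year), by_cat_taxon in sorted(groups.items()):
        counts: dict[str, int] = {c: 0 for c in CATEGORIES_WITH_OTHERS + (UNDETERMINED,)}
        for (category, _taxon), recs in by_cat_taxon.items():
            if recs[0].taxon_group in _FRAGMENT_GROUPS:
                counts[category] += _fragments(recs)
            else:
                counts[category] += _mni(recs)
        out.append(CategoryCounts(nest_id=nest, year=year, counts=counts))
    return out


def diet_proportions(counts: CategoryCounts, exclude_others: bool = False) -> DietProportions | None:
    """Convert category counts to proportions for one nest-year.

    'undetermined' never enters totals.  With ``exclude_others`` the
    'others' category is also dropped and the remaining five categories
    renormalized.  Returns None (with a warning) when the usable total
    is zero.
    """
    cats = CATEGORIES if exclude_others else CATEGORIES_WITH_OTHERS
    total = sum(counts.counts.get(c, 0) for c in cats)
    if total <= 0:
        logger.warning(
            "nest %s year %s: zero usable remains, excluded", counts.nest_id, counts.year
        )
        return None
    return DietProportions(
        nest_id=counts.nest_id,
        year=counts.year,
        proportions={c: counts.counts.get(c, 0) / total for c in cats},
        others_excluded=exclude_others,
    )


def diet_proportions_table(
    counts: Sequence[CategoryCounts], exclude_others: bool = False
) -> list[DietProportions]:
    """Proportions for every nest-year with a positive usable total."""
    out = []
    for c in counts:
        p = diet_proportions(c, exclude_others=exclude_others)
        if p is not None:
            out.append(p)
    return out


def population_conventional_summary(props: Sequence[DietProportions]) -> pd.DataFrame:
    """Across nest-years: mean and SD of per-nest proportions, in percent."""
    if not props:
        raise ValidationError("no diet proportions")
    cats = list(props[0].proportions.keys())
    mat = np.array([[p.proportions.get(c, 0.0) for c in cats] for p in props])
    return pd.DataFrame(
        {
            "category": cats,
            "mean_pct": mat.mean(axis=0) * 100.0,
            "sd_pct": (mat.std(axis=0, ddof=1) if len(props) > 1 else np.zeros(len(cats)))
            * 100.0,
            "n_nest_years": len(props),
        }
    )
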