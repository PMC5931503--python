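"""Core domain types shared across the pipeline stages."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

# Canonical category order used in every table and file the pipeline writes.
CATEGORIES = ("landfill", "livestock", "wild_herbivores", "carnivores", "birds")
CATEGORIES_WITH_OTHERS = CATEGORIES + ("others",)
UNDETERMINED = "undetermined"

# Plausibility windows for feather values; violations warn, never fail,
# so that exotic synthetic scenarios still run.
_D13C_RANGE = (-40.0, -5.0)
_D15N_RANGE = (-5.0, 25.0)


class ValidationError(ValueError):
    """Raised when an input record violates a hard invariant."""


@dataclass(frozen=True)
class IsotopeSample:
    """One feather measurement: nest territory, year, and the two delta values (permil)."""

    territory_id: str
    year: int
    delta13C: float
    delta15N: float

    def __post_init__(self) -> None:
        # NaN/None mark a missing isotope (handled pairwise downstream);
        # infinities are always invalid.
        for name, value in (("delta13C", self.delta13C), ("delta15N", self.delta15N)):
            if value is not None and math.isinf(value):
                raise ValidationError(f"{name} must be finite, got {value!r}")
        for name, value, lo_hi in (
            ("delta13C", self.delta13C, _D13C_RANGE),
            ("delta15N", self.delta15N, _D15N_RANGE),
        ):
            if value is None or math.isnan(value):
                continue
            if not lo_hi[0] <= value <= lo_hi[1]:
                warnings.warn(
                    f"{name}={value} outside plausible range {lo_hi}", stacklevel=2
                )


@dataclass(frozen=True)
class ConsumerObservation:
    """One statistical observation: sibling-averaged delta values for a nest-year."""

    territory_id: str
    year: int
    mean_delta13C: float
    mean_delta15N: float
    n_siblings: int = 1

    def __post_init__(self) -> None:
        if self.n_siblings < 1:
            raise ValidationError("n_siblings must be >= 1")


@dataclass(frozen=True)
class SourceSpec:
    """A food category's bivariate isotope distribution (means and SDs, permil).

    When the category aggregates several prey types, ``components`` holds
    the per-prey (name, mu13C, sd13C, mu15N, sd15N) tuples the summary was
    derived from.
    """

    name: str
    mu13C: float
    sd13C: float
    mu15N: float
    sd15N: float
    components: tuple[tuple[str, float, float, float, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.sd13C < 0 or self.sd15N < 0:
            raise ValidationError(f"source {self.name!r}: SDs must be >= 0")


@dataclass(frozen=True)
class TEFSpec:
    """Trophic enrichment factor: additive consumer-minus-diet shift per isotope."""

    mu13C: float
    sd13C: float
    mu15N: float
    sd15N: float

    def __post_init__(self) -> None:
        if self.sd13C < 0 or self.sd15N < 0:
            raise ValidationError("TEF SDs must be >= 0")


TAXON_GROUPS = (
    "invertebrate",
    "small_medium_vertebrate",
    "carnivore",
    "ungulate",
    "bird",
    "other",
)

ITEM_KINDS = (
    "bone",
    "skull_fragment",
    "distal_limb_part",
    "hair",
    "feather",
    "whole",
    "other",
)


@dataclass(frozen=True)
class RemainRecord:
    """One identified food remain collected at a nest.

    ``element`` and ``side`` identify diagnostic skeletal elements for
    minimum-number-of-individuals counting; ``n_elements`` records how many
    connected distal-limb elements (1-3) a single limb fragment comprises.
    """

    nest_id: str
    year: int
    taxon: str
    taxon_group: str
    item_kind: str = "bone"
    sampling_moment: str = "during_breeding"
    butchery_marks: bool = False
    hair_color: str | None = None
    hair_length_class: str | None = None
    element: str | None = None
    side: str | None = None
    n_elements: int = 1
    count: int = 1

    def __post_init__(self) -> None:
        if self.taxon_group not in TAXON_GROUPS:
            raise ValidationError(
                f"unknown taxon_group {self.taxon_group!r}; expected one of {TAXON_GROUPS}"
            )
        if self.item_kind not in ITEM_KINDS:
            raise ValidationError(
                f"unknown item_kind {self.item_kind!r}; expected one of {ITEM_KINDS}"
            )
        if self.sampling_moment not in ("during_breeding", "post_breeding"):
            raise ValidationError(f"unknown sampling_moment {self.sampling_moment!r}")
        if self.item_kind != "hair" and (self.hair_color or self.hair_length_class):
            raise ValidationError("hair attributes only allowed when item_kind='hair'")
        if self.item_kind == "distal_limb_part" and not 1 <= self.n_elements <= 3:
            raise ValidationError("distal_limb_part n_elements must be in 1..3")
        if self.count < 1:
            raise ValidationError("count must be >= 1")


@dataclass(frozen=True)
class CategoryCounts:
    """Per-nest-year item counts over the six conventional categories."""

    nest_id: str
    year: int
    counts: dict[str, float] = field(default_factory=dict)

    def total(self, include_others: bool = True) -> float:
        cats = CATEGORIES_WITH_OTHERS if include_others else CATEGORIES
        return float(sum(self.counts.get(c, 0) for c in cats))


@dataclass(frozen=True)
class DietProportions:
    """Per-nest-year diet proportions; sums to 1 over the included categories."""

    nest_id: str
    year: int
    proportions: dict[str, float]
    others_excluded: bool = False

    def __post_init__(self) -> None:
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.proportions.values()):
            raise ValidationError("proportions must be >= 0")
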