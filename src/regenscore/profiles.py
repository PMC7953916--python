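"""Domain records for producer questionnaires and coded scores.

A *practice profile* holds one operation's raw questionnaire answers in
natural units (booleans for cropland practices; applications per year,
animal units per hectare and days for rangeland).  A :class:`ScoreRecord`
holds the per-item rubric codes and their unweighted sum, the composite
regenerative score.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

from .errors import ValidationError

#: Cropland rubric items, in the column order of the practice matrix.
CROPLAND_ITEMS = (
    "fertilizers",
    "herbicides",
    "fungicides",
    "insecticides",
    "tillage",
    "cover_crops",
    "field_margins",
    "organic_amendments",
    "grazers",
)

#: Items not asked of the corn producers (fungicide use, organic
#: amendments and field margins/hedgerows were not described there).
CORN_UNASKED = ("fungicides", "field_margins", "organic_amendments")

CORN_ITEMS = tuple(i for i in CROPLAND_ITEMS if i not in CORN_UNASKED)

#: Rangeland ordinal rubric items.
RANGELAND_ITEMS = (
    "ivermectin",
    "stocking_density",
    "rotation_frequency",
    "rest_period",
)

MAX_POSSIBLE = {
    "cropland_full": len(CROPLAND_ITEMS),  # 9
    "cropland_corn": len(CORN_ITEMS),      # 6
    "rangeland": 2 * len(RANGELAND_ITEMS),  # 8
}


@dataclass
class PracticeProfile:
    """Raw cropland questionnaire answers for one operation.

    ``system`` is ``"cropland_full"`` (all nine items asked, e.g. almond
    orchards) or ``"cropland_corn"`` (six items; fungicides, field
    margins and organic amendments were not asked).  For the corn subset
    the three unasked answers must be ``None``.
    """

    operation_id: str
    system: str
    synthetic_fertilizer_used: bool
    herbicide_used: bool
    insecticide_used: bool
    tillage_used: bool
    cover_crop_or_resident_vegetation: bool
    livestock_integrated: bool
    fungicide_used: Optional[bool] = None
    field_margins_hedgerows: Optional[bool] = None
    organic_amendments_used: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.system not in ("cropland_full", "cropland_corn"):
            raise ValidationError(
                f"{self.operation_id}: unknown cropland system {self.system!r}"
            )
        optional = {
            "fungicide_used": self.fungicide_used,
            "field_margins_hedgerows": self.field_margins_hedgerows,
            "organic_amendments_used": self.organic_amendments_used,
        }
        if self.system == "cropland_corn":
            present = [k for k, v in optional.items() if v is not None]
            if present:
                raise ValidationError(
                    f"{self.operation_id}: corn profiles must leave unasked "
                    f"items absent, got answers for {present}"
                )
        else:
            missing = [k for k, v in optional.items() if v is None]
            if missing:
                raise ValidationError(
                    f"{self.operation_id}: cropland_full profile missing "
                    f"answers for {missing}"
                )
        for name in (
            "synthetic_fertilizer_used",
            "herbicide_used",
            "insecticide_used",
            "tillage_used",
            "cover_crop_or_resident_vegetation",
            "livestock_integrated",
        ):
            if not isinstance(getattr(self, name), (bool,)):
                raise ValidationError(
                    f"{self.operation_id}: {name} must be a boolean"
                )

    @property
    def items_asked(self) -> tuple:
        return CORN_ITEMS if self.system == "cropland_corn" else CROPLAND_ITEMS

    def answers(self) -> dict:
        """Map rubric item name -> boolean 'practice used' answer."""
        raw = {
            "fertilizers": self.synthetic_fertilizer_used,
            "herbicides": self.herbicide_used,
            "fungicides": self.fungicide_used,
            "insecticides": self.insecticide_used,
            "tillage": self.tillage_used,
            "cover_crops": self.cover_crop_or_resident_vegetation,
            "field_margins": self.field_margins_hedgerows,
            "organic_amendments": self.organic_amendments_used,
            "grazers": self.livestock_integrated,
        }
        return {k: raw[k] for k in self.items_asked}


@dataclass
class RangelandProfile:
    """Raw rangeland questionnaire answers for one ranch.

    Units: ivermectin applications per year (count), stocking density in
    animal units per hectare, rotation frequency in days between moves
    (``math.inf`` = never rotated), rest period in days (0 = continuously
    grazed over the growing season).
    """

    operation_id: str
    ivermectin_applications_per_year: int
    ivermectin_applied_during_grazing: bool
    stocking_density_au_per_ha: float
    rotation_frequency_days: float
    rest_period_days: float
    system: str = field(default="rangeland", init=False)

    def __post_init__(self) -> None:
        if self.ivermectin_applications_per_year < 0:
            raise ValidationError(
                f"{self.operation_id}: ivermectin applications must be >= 0"
            )
        if self.ivermectin_applied_during_grazing and (
            self.ivermectin_applications_per_year < 1
        ):
            raise ValidationError(
                f"{self.operation_id}: cannot apply ivermectin during grazing "
                "with zero annual applications"
            )
        if self.stocking_density_au_per_ha < 0:
            raise ValidationError(
                f"{self.operation_id}: stocking density must be >= 0 AU/ha"
            )
        if not self.rotation_frequency_days > 0:
            raise ValidationError(
                f"{self.operation_id}: rotation frequency must be > 0 days"
            )
        if self.rest_period_days < 0:
            raise ValidationError(
                f"{self.operation_id}: rest period must be >= 0 days"
            )

    @property
    def items_asked(self) -> tuple:
        return RANGELAND_ITEMS


@dataclass
class ScoreRecord:
    """Coded per-practice scores and their composite for one operation."""

    operation_id: str
    system: str
    item_codes: Mapping[str, int]
    composite_score: int
    max_possible: int

    def __post_init__(self) -> None:
        if self.system not in MAX_POSSIBLE:
            raise ValidationError(f"unknown system {self.system!r}")
        total = sum(self.item_codes.values())
        if total != self.composite_score:
            raise ValidationError(
                f"{self.operation_id}: composite {self.composite_score} does "
                f"not equal the sum of item codes ({total})"
            )
        if not 0 <= self.composite_score <= self.max_possible:
            raise ValidationError(
                f"{self.operation_id}: composite {self.composite_score} out of "
                f"range [0, {self.max_possible}]"
            )
        hi = 2 if self.system == "rangeland" else 1
        bad = {k: v for k, v in self.item_codes.items() if not 0 <= v <= hi}
        if bad:
            raise ValidationError(
                f"{self.operation_id}: item codes out of range: {bad}"
            )

    @property
    def items_asked(self) -> tuple:
        return tuple(self.item_codes)

    @property
    def normalized_score(self) -> float:
        """Composite divided by the maximum possible (cross-system display
        only; never used for classification)."""
        return self.composite_score / self.max_possible
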