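"""Practice rubrics: raw answers -> per-item codes -> composite score.

Cropland items are binary: eliminating synthetic fertilizers, herbicides,
fungicides, insecticides and tillage scores 1 (regenerative), while
including cover crops (or deliberately fostered resident vegetation),
diversified field margins/hedgerows, organic amendments and livestock
integration scores 1.  Rangeland items are ordinal 0-2 (ivermectin use,
stocking density, rotation frequency, rest period), with higher codes
reflecting practices that promote biodiversity and soil quality.  The
composite score is the unweighted sum of the coded items that were asked.
"""

from __future__ import annotations

import warnings
from typing import Iterable, Union

import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .errors import RubricError, ValidationError
from .profiles import (
    CROPLAND_ITEMS,
    MAX_POSSIBLE,
    RANGELAND_ITEMS,
    PracticeProfile,
    RangelandProfile,
    ScoreRecord,
)

# Items where *eliminating* the practice is the regenerative state.
_ELIMINATION_ITEMS = frozenset(
    {"fertilizers", "herbicides", "fungicides", "insecticides", "tillage"}
)
# Items where *including* the practice is the regenerative state.
_INCLUSION_ITEMS = frozenset(
    {"cover_crops", "field_margins", "organic_amendments", "grazers"}
)


def code_cropland_item(item: str, answer: bool) -> int:
    """Binary code for one cropland practice item.

    Elimination items (fertilizers, herbicides, fungicides, insecticides,
    tillage): used -> 0, not used -> 1.  Inclusion items (cover crops,
    field margins, organic amendments, grazers): used -> 1, not used -> 0.
    """
    if item not in _ELIMINATION_ITEMS and item not in _INCLUSION_ITEMS:
        raise RubricError(f"unknown cropland rubric item {item!r}")
    if answer is None or not isinstance(answer, bool):
        raise ValidationError(f"missing or non-boolean answer for {item!r}")
    if item in _ELIMINATION_ITEMS:
        return 0 if answer else 1
    return 1 if answer else 0


def code_ivermectin(applications_per_year: int, during_grazing: bool) -> int:
    """Ivermectin use: none -> 2; single annual application not during the
    grazing period -> 1; multiple applications, or any application during
    grazing -> 0."""
    if applications_per_year < 0:
        raise ValidationError("applications_per_year must be >= 0")
    if applications_per_year == 0:
        if during_grazing:
            raise ValidationError(
                "during_grazing cannot be true with zero applications"
            )
        return 2
    if applications_per_year == 1 and not during_grazing:
        return 1
    return 0


def code_stocking_density(au_per_ha: float) -> int:
    """Stocking density: < 5 AU/ha -> 0; 5-10 AU/ha (closed bin) -> 1;
    > 10 AU/ha -> 2."""
    if au_per_ha < 0:
        raise ValidationError("stocking density must be >= 0 AU/ha")
    if au_per_ha < 5:
        return 0
    if au_per_ha <= 10:
        return 1
    return 2


def code_rotation_frequency(days: float) -> int:
    """Rotation frequency: >= 30 d between moves (incl. never rotated)
    -> 0; 10-30 d -> 1; < 10 d -> 2."""
    if not days > 0:
        raise ValidationError("rotation frequency must be > 0 days")
    if days >= 30:
        return 0
    if days >= 10:
        return 1
    return 2


def code_rest_period(days: float) -> int:
    """Rest period: continuously grazed (0 d) -> 0; 1-30 d -> 1;
    > 30 d -> 2.

    A fractional rest shorter than one day is coded 1 with a warning: it
    is rested, but below the rubric's smallest stated bin edge.
    """
    if days < 0:
        raise ValidationError("rest period must be >= 0 days")
    if days == 0:
        return 0
    if days < 1:
        warnings.warn(
            f"rest period {days} d is shorter than the 1-day bin edge; "
            "coding as 1 (rested)",
            stacklevel=2,
        )
        return 1
    if days <= 30:
        return 1
    return 2


def _code_rangeland(profile: RangelandProfile) -> dict:
    return {
        "ivermectin": code_ivermectin(
            profile.ivermectin_applications_per_year,
            profile.ivermectin_applied_during_grazing,
        ),
        "stocking_density": code_stocking_density(
            profile.stocking_density_au_per_ha
        ),
        "rotation_frequency": code_rotation_frequency(
            profile.rotation_frequency_days
        ),
        "rest_period": code_rest_period(profile.rest_period_days),
    }


Profile = Union[PracticeProfile, RangelandProfile]


def composite_score(profile: Profile) -> ScoreRecord:
    """Code every asked item of *profile* and sum them into the composite
    regenerative score (max 9 full cropland, 6 corn subset, 8 rangeland)."""
    if isinstance(profile, RangelandProfile):
        codes = _code_rangeland(profile)
    elif isinstance(profile, PracticeProfile):
        codes = {
            item: code_cropland_item(item, ans)
            for item, ans in profile.answers().items()
        }
    else:
        raise ValidationError(
            f"expected a practice profile, got {type(profile).__name__}"
        )
    return ScoreRecord(
        operation_id=profile.operation_id,
        system=profile.system,
        item_codes=codes,
        composite_score=sum(codes.values()),
        max_possible=MAX_POSSIBLE[profile.system],
    )


# Representative raw answers that reproduce a given ordinal code; used to
# rebuild profiles from a coded practice matrix and by the simulator.
_RANGELAND_CODE_TO_ANSWER = {
    "ivermectin": {0: (2, False), 1: (1, False), 2: (0, False)},
    "stocking_density": {0: 3.0, 1: 7.5, 2: 12.0},
    "rotation_frequency": {0: 45.0, 1: 14.0, 2: 3.0},
    "rest_period": {0: 0.0, 1: 20.0, 2: 60.0},
}


def rangeland_profile_from_codes(
    operation_id: str, codes: Iterable[int]
) -> RangelandProfile:
    """Build a rangeland profile whose answers code back to *codes*
    (ivermectin, stocking density, rotation frequency, rest period)."""
    iv, sd, rot, rest = [int(c) for c in codes]
    apps, during = _RANGELAND_CODE_TO_ANSWER["ivermectin"][iv]
    return RangelandProfile(
        operation_id=operation_id,
        ivermectin_applications_per_year=apps,
        ivermectin_applied_during_grazing=during,
        stocking_density_au_per_ha=_RANGELAND_CODE_TO_ANSWER[
            "stocking_density"
        ][sd],
        rotation_frequency_days=_RANGELAND_CODE_TO_ANSWER[
            "rotation_frequency"
        ][rot],
        rest_period_days=_RANGELAND_CODE_TO_ANSWER["rest_period"][rest],
    )


def cropland_profile_from_codes(
    operation_id: str, system: str, codes: dict
) -> PracticeProfile:
    """Build a cropland profile whose answers code back to *codes*
    (a mapping rubric item -> 0/1 over the asked items)."""
    def used(item: str):
        if item not in codes:
            return None
        c = int(codes[item])
        return (c == 0) if item in _ELIMINATION_ITEMS else (c == 1)

    return PracticeProfile(
        operation_id=operation_id,
        system=system,
        synthetic_fertilizer_used=used("fertilizers"),
        herbicide_used=used("herbicides"),
        fungicide_used=used("fungicides"),
        insecticide_used=used("insecticides"),
        tillage_used=used("tillage"),
        cover_crop_or_resident_vegetation=used("cover_crops"),
        field_margins_hedgerows=used("field_margins"),
        organic_amendments_used=used("organic_amendments"),
        livestock_integrated=used("grazers"),
    )


class RegenerativeScorer(TransformerMixin, BaseEstimator):
    """Transformer from practice profiles to coded score records.

    ``transform`` accepts a list of profiles (or a DataFrame previously
    read with :func:`regenscore.io.read_survey`, via its ``profiles``
    attribute) and returns a tidy DataFrame with one row per operation:
    per-item codes, the composite score and the maximum possible.

    Parameters
    ----------
    normalized : bool, default False
        Also report ``normalized_score = composite / max_possible`` for
        cross-system display.  Never used for classification.
    """

    def __init__(self, normalized: bool = False):
        self.normalized = normalized

    def fit(self, X, y=None):  # stateless; rubric is fixed
        self.n_features_in_ = 1
        return self

    def transform(self, X) -> pd.DataFrame:
        records = [composite_score(p) for p in X]
        return self.records_to_frame(records)

    def score_records(self, X) -> list:
        """Like :meth:`transform` but returning :class:`ScoreRecord`\\ s."""
        return [composite_score(p) for p in X]

    def records_to_frame(self, records) -> pd.DataFrame:
        rows = []
        for rec in records:
            row = {
                "operation_id": rec.operation_id,
                "system": rec.system,
                **{f"code_{k}": v for k, v in rec.item_codes.items()},
                "items_asked": ";".join(rec.items_asked),
                "composite_score": rec.composite_score,
                "max_possible": rec.max_possible,
            }
            if self.normalized:
                row["normalized_score"] = rec.normalized_score
            rows.append(row)
        return pd.DataFrame(rows)
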