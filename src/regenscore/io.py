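"""Survey readers/writers, the profit ledger and report assembly.

Surveys are comma-separated tables, one row per operation.  A cropland
survey carries the boolean practice questions (booleans accepted as
yes/no/true/false/1/0, case-insensitive); a rangeland survey carries the
natural-unit grazing questions.  The reader detects which schema a file
follows from its columns and reports malformed rows with their row number
and offending column.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .classify import GapThreshold
from .errors import ValidationError
from .profiles import PracticeProfile, RangelandProfile

_TRUE = {"yes", "true", "1", "y", "t"}
_FALSE = {"no", "false", "0", "n", "f"}

CROPLAND_SURVEY_COLUMNS = (
    "operation_id",
    "system",
    "synthetic_fertilizer_used",
    "herbicide_used",
    "fungicide_used",
    "insecticide_used",
    "tillage_used",
    "cover_crop_or_resident_vegetation",
    "field_margins_hedgerows",
    "organic_amendments_used",
    "livestock_integrated",
)

RANGELAND_SURVEY_COLUMNS = (
    "operation_id",
    "ivermectin_applications_per_year",
    "ivermectin_applied_during_grazing",
    "stocking_density_au_per_ha",
    "rotation_frequency_days",
    "rest_period_days",
)

#: Significant digits for all numeric file output.
FLOAT_FORMAT = "%.6g"


def parse_bool(value, row: int, column: str) -> Optional[bool]:
    """Parse a survey boolean; blank cells return None."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip().lower()
    if text == "":
        return None
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise ValidationError(
        f"row {row}: column {column!r}: cannot parse boolean from {value!r}"
    )


def _parse_number(value, row: int, column: str, integer: bool = False):
    if value is None or (isinstance(value, float) and math.isnan(value)):
        raise ValidationError(f"row {row}: column {column!r}: missing value")
    text = str(value).strip().lower()
    if text in ("inf", "infinite", "never"):
        return math.inf
    try:
        num = float(text)
    except ValueError:
        raise ValidationError(
            f"row {row}: column {column!r}: cannot parse number from {value!r}"
        ) from None
    if integer:
        if num != int(num):
            raise ValidationError(
                f"row {row}: column {column!r}: expected an integer, got {value!r}"
            )
        return int(num)
    return num


def read_survey(path) -> list:
    """Read a cropland or rangeland survey into practice profiles.

    The schema is detected from the header.  Unknown columns, duplicate
    operation ids and malformed cells are schema errors naming the row.
    """
    df = pd.read_csv(path, dtype=str)
    if len(df) == 0:
        raise ValidationError(f"{path}: empty survey file")
    cols = set(df.columns)
    if cols == set(CROPLAND_SURVEY_COLUMNS):
        kind = "cropland"
    elif cols == set(RANGELAND_SURVEY_COLUMNS):
        kind = "rangeland"
    else:
        expected_c = set(CROPLAND_SURVEY_COLUMNS)
        expected_r = set(RANGELAND_SURVEY_COLUMNS)
        unknown = cols - expected_c - expected_r
        missing = min(expected_c - cols, expected_r - cols, key=len)
        raise ValidationError(
            f"{path}: unrecognized survey schema "
            f"(unknown columns {sorted(unknown)}, missing {sorted(missing)})"
        )
    dupes = df["operation_id"][df["operation_id"].duplicated()].tolist()
    if dupes:
        raise ValidationError(f"{path}: duplicate operation_id(s): {dupes}")

    profiles = []
    for i, row in df.iterrows():
        rownum = i + 2  # 1-based with header
        try:
            if kind == "cropland":
                profiles.append(
                    PracticeProfile(
                        operation_id=row["operation_id"],
                        system=str(row["system"]).strip(),
                        synthetic_fertilizer_used=parse_bool(
                            row["synthetic_fertilizer_used"], rownum,
                            "synthetic_fertilizer_used"),
                        herbicide_used=parse_bool(
                            row["herbicide_used"], rownum, "herbicide_used"),
                        fungicide_used=parse_bool(
                            row["fungicide_used"], rownum, "fungicide_used"),
                        insecticide_used=parse_bool(
                            row["insecticide_used"], rownum,
                            "insecticide_used"),
                        tillage_used=parse_bool(
                            row["tillage_used"], rownum, "tillage_used"),
                        cover_crop_or_resident_vegetation=parse_bool(
                            row["cover_crop_or_resident_vegetation"], rownum,
                            "cover_crop_or_resident_vegetation"),
                        field_margins_hedgerows=parse_bool(
                            row["field_margins_hedgerows"], rownum,
                            "field_margins_hedgerows"),
                        organic_amendments_used=parse_bool(
                            row["organic_amendments_used"], rownum,
                            "organic_amendments_used"),
                        livestock_integrated=parse_bool(
                            row["livestock_integrated"], rownum,
                            "livestock_integrated"),
                    )
                )
            else:
                profiles.append(
                    RangelandProfile(
                        operation_id=row["operation_id"],
                        ivermectin_applications_per_year=_parse_number(
                            row["ivermectin_applications_per_year"], rownum,
                            "ivermectin_applications_per_year", integer=True),
                        ivermectin_applied_during_grazing=parse_bool(
                            row["ivermectin_applied_during_grazing"], rownum,
                            "ivermectin_applied_during_grazing"),
                        stocking_density_au_per_ha=_parse_number(
                            row["stocking_density_au_per_ha"], rownum,
                            "stocking_density_au_per_ha"),
                        rotation_frequency_days=_parse_number(
                            row["rotation_frequency_days"], rownum,
                            "rotation_frequency_days"),
                        rest_period_days=_parse_number(
                            row["rest_period_days"], rownum,
                            "rest_period_days"),
                    )
                )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {rownum}: {exc}") from None
    return profiles


def write_survey(path, profiles: Sequence) -> None:
    """Write profiles back to the survey schema (round-trips with
    :func:`read_survey`)."""
    rows = []
    for p in profiles:
        if isinstance(p, PracticeProfile):
            rows.append({c: getattr(p, c) for c in CROPLAND_SURVEY_COLUMNS})
        elif isinstance(p, RangelandProfile):
            rows.append({c: getattr(p, c) for c in RANGELAND_SURVEY_COLUMNS})
        else:
            raise ValidationError(f"not a profile: {type(p).__name__}")
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FORMAT)


def write_scores(path, records) -> None:
    """Write score records as a tidy table: operation_id, per-item codes,
    items asked, composite and maximum."""
    from .rubric import RegenerativeScorer

    frame = RegenerativeScorer().records_to_frame(records)
    frame.to_csv(path, index=False, float_format=FLOAT_FORMAT)


@dataclass
class LedgerEntry:
    """One direct cost or revenue line, in currency per hectare."""

    operation_id: str
    kind: str  # "revenue" | "cost"
    category: str
    amount_per_ha: float

    def __post_init__(self) -> None:
        if self.kind not in ("revenue", "cost"):
            raise ValidationError(
                f"{self.operation_id}: kind must be 'revenue' or 'cost'"
            )
        if self.amount_per_ha < 0:
            raise ValidationError(
                f"{self.operation_id}: amounts are positive magnitudes; use "
                "kind='cost' for outgoings"
            )


def net_profit(entries: Sequence[LedgerEntry], operation_id: str) -> float:
    """Direct net profitability: sum of revenues minus sum of direct
    costs for one operation (currency/ha; sign free)."""
    mine = [e for e in entries if e.operation_id == operation_id]
    if not mine:
        raise ValidationError(f"no ledger entries for {operation_id!r}")
    revenue = sum(e.amount_per_ha for e in mine if e.kind == "revenue")
    cost = sum(e.amount_per_ha for e in mine if e.kind == "cost")
    return revenue - cost


def build_report(
    threshold: GapThreshold,
    labels: pd.DataFrame,
    validation_table: Optional[pd.DataFrame] = None,
) -> dict:
    """Assemble the JSON report: the fitted threshold, per-operation
    labels, and (optionally) the validation model summaries."""
    report = {
        "threshold": threshold.to_dict(),
        "operations": labels.to_dict(orient="records"),
    }
    if validation_table is not None:
        clean = validation_table.replace({np.nan: None})
        report["validation"] = clean.to_dict(orient="records")
        report["n_models_fitted"] = validation_table.attrs.get(
            "n_models_fitted", len(validation_table)
        )
    return report


def write_report(path, report: dict) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=float)
        fh.write("\n")
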