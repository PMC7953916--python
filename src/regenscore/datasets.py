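"""Packaged practice-matrix fixtures.

The published cropland matrix (36 operations: 16 almond orchards scored
on nine binary items, 20 cornfields on six) and rangeland matrix (52
ranches on four ordinal items) ship as CSV fixtures keyed by location
label, each row carrying the per-item codes and the composite score as
printed.

Two printed composites are arithmetic errata — their practice codes sum
to a different value than the printed composite (``ERRATA`` below).
Recomputing composites from the codes reproduces the remaining 86 rows
exactly.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .profiles import CORN_ITEMS, CROPLAND_ITEMS
from .rubric import cropland_profile_from_codes, rangeland_profile_from_codes

#: (fixture, operation_id) -> (printed composite, sum of printed codes)
ERRATA = {
    ("cropland", "row34-Gary, SD"): (4, 5),
    ("rangeland", "row44-Castlewood, SD"): (2, 3),
}


def _read(name: str) -> pd.DataFrame:
    with resources.files("regenscore.data").joinpath(name).open("rb") as fh:
        df = pd.read_csv(fh)
    df.insert(
        0,
        "operation_id",
        [f"row{i + 1:02d}-{loc}" for i, loc in enumerate(df["location"])],
    )
    return df


def load_cropland_matrix() -> pd.DataFrame:
    """Published cropland practice matrix (codes + printed composites)."""
    return _read("cropland_matrix.csv")


def load_rangeland_matrix() -> pd.DataFrame:
    """Published rangeland practice matrix (codes + printed composites)."""
    return _read("rangeland_matrix.csv")


def cropland_profiles():
    """Practice profiles reconstructed from the cropland matrix codes."""
    df = load_cropland_matrix()
    profiles = []
    for _, row in df.iterrows():
        items = (
            CORN_ITEMS if row["system"] == "cropland_corn" else CROPLAND_ITEMS
        )
        codes = {item: int(row[item]) for item in items}
        profiles.append(
            cropland_profile_from_codes(
                row["operation_id"], row["system"], codes
            )
        )
    return profiles


def rangeland_profiles():
    """Ranch profiles whose natural-unit answers code back to the
    rangeland matrix codes."""
    df = load_rangeland_matrix()
    return [
        rangeland_profile_from_codes(
            row["operation_id"],
            (
                int(row["ivermectin"]),
                int(row["stocking_density"]),
                int(row["rotation_frequency"]),
                int(row["rest_period"]),
            ),
        )
        for _, row in df.iterrows()
    ]


def almond_scores() -> list:
    """Printed composites of the 16 almond (full cropland) rows."""
    df = load_cropland_matrix()
    return df.loc[
        df["system"] == "cropland_full", "composite_printed"
    ].astype(int).tolist()


def corn_scores() -> list:
    """Printed composites of the 20 corn rows."""
    df = load_cropland_matrix()
    return df.loc[
        df["system"] == "cropland_corn", "composite_printed"
    ].astype(int).tolist()


def rangeland_scores() -> list:
    """Printed composites of the 52 ranch rows."""
    return load_rangeland_matrix()["composite_printed"].astype(int).tolist()
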