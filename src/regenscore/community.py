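"""Biodiversity and vegetation response metrics.

Specimen counts arrive as morphospecies -> count maps with trophic-guild
labels (coprophage, predator, parasitoid, herbivore, pest, other).
Diversity is summarized by Shannon H (natural log) and the Gini-Simpson
index; vegetation by cover classes and the disc-pasture-meter compression
height (a biomass index, not calibrated mass).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence

import numpy as np

from .errors import ValidationError

GUILDS = ("coprophage", "predator", "parasitoid", "herbivore", "pest", "other")
STRATA = ("epigeal", "soil_core", "foliar", "dung")
COVER_CLASSES = ("0-25", "25-50", "50-75", "75-100")


@dataclass
class CommunitySample:
    """Specimen counts by morphospecies for one sample."""

    sample_id: str
    operation_id: str
    stratum: str
    counts: Dict[str, int]
    guilds: Dict[str, str]
    month: Optional[str] = None
    biomass_mg: Optional[float] = None

    def __post_init__(self) -> None:
        if self.stratum not in STRATA:
            raise ValidationError(
                f"sample {self.sample_id}: unknown stratum {self.stratum!r}"
            )
        for sp, n in self.counts.items():
            if not (isinstance(n, (int, np.integer)) and n >= 0):
                raise ValidationError(
                    f"sample {self.sample_id}: count for {sp!r} must be a "
                    "nonnegative integer"
                )
            if n > 0 and sp not in self.guilds:
                raise ValidationError(
                    f"sample {self.sample_id}: species {sp!r} has no guild label"
                )
        bad = {g for g in self.guilds.values() if g not in GUILDS}
        if bad:
            raise ValidationError(
                f"sample {self.sample_id}: unknown guilds {sorted(bad)}"
            )
        if self.biomass_mg is not None and self.biomass_mg < 0:
            raise ValidationError(
                f"sample {self.sample_id}: biomass must be nonnegative"
            )


@dataclass
class VegetationRecord:
    """Ground-cover and disc-pasture-meter observations for one visit."""

    operation_id: str
    month: str
    cover_percent: float
    compression_heights_cm: List[float] = field(default_factory=list)
    species_present: frozenset = frozenset()

    def __post_init__(self) -> None:
        if not 0 <= self.cover_percent <= 100:
            raise ValidationError("cover percent must be within [0, 100]")
        if any(h < 0 for h in self.compression_heights_cm):
            raise ValidationError("compression heights must be nonnegative")

    @property
    def cover_class_label(self) -> str:
        return cover_class(self.cover_percent)


def _proportions(counts) -> np.ndarray:
    values = np.asarray(
        list(counts.values()) if isinstance(counts, Mapping) else counts,
        dtype=float,
    )
    if np.any(values < 0):
        raise ValidationError("counts must be nonnegative")
    values = values[values > 0]
    total = values.sum()
    if total == 0:
        raise ValidationError(
            "diversity is undefined for an all-zero count vector"
        )
    return values / total


def shannon_h(counts) -> float:
    """Shannon diversity H = -sum(p_i ln p_i), natural log."""
    p = _proportions(counts)
    return float(-np.sum(p * np.log(p)))


def simpson_ds(counts, inverse: bool = False) -> float:
    """Gini-Simpson diversity 1 - sum(p_i^2); ``inverse=True`` returns the
    inverse form 1/sum(p_i^2) instead."""
    p = _proportions(counts)
    ss = float(np.sum(p**2))
    return 1.0 / ss if inverse else 1.0 - ss


def richness(counts) -> int:
    """Number of morphospecies with at least one specimen."""
    values = (
        list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    )
    return int(sum(1 for v in values if v > 0))


def abundance(counts) -> int:
    """Total specimens across morphospecies."""
    values = (
        list(counts.values()) if isinstance(counts, Mapping) else list(counts)
    )
    if any(v < 0 for v in values):
        raise ValidationError("counts must be nonnegative")
    return int(sum(values))


def guild_abundance(sample: CommunitySample, guild: str) -> int:
    """Total specimens in one trophic guild for a sample."""
    if guild not in GUILDS:
        raise ValidationError(f"unknown guild {guild!r}")
    return int(
        sum(
            n
            for sp, n in sample.counts.items()
            if n > 0 and sample.guilds[sp] == guild
        )
    )


def biomass_index(record: VegetationRecord) -> float:
    """Mean disc-pasture-meter compression height (cm); an index of
    standing vegetation biomass, not calibrated mass."""
    if not record.compression_heights_cm:
        raise ValidationError("no compression heights recorded")
    return float(np.mean(record.compression_heights_cm))


def cover_class(percent: float) -> str:
    """Ground-cover class with half-open bins [0,25), [25,50), [50,75)
    and the closed top bin [75,100]."""
    if not 0 <= percent <= 100:
        raise ValidationError("cover percent must be within [0, 100]")
    if percent < 25:
        return "0-25"
    if percent < 50:
        return "25-50"
    if percent < 75:
        return "50-75"
    return "75-100"


def pool_samples(samples: Sequence[CommunitySample]) -> CommunitySample:
    """Pool replicate samples of one operation by summing counts.

    Per-operation community metrics are computed on pooled counts
    (replicates composited into a single value); see
    :func:`operation_metrics` for the per-sample-then-average alternative.
    """
    if not samples:
        raise ValidationError("no samples to pool")
    ops = {s.operation_id for s in samples}
    if len(ops) > 1:
        raise ValidationError(
            f"cannot pool samples across operations: {sorted(ops)}"
        )
    counts: Dict[str, int] = {}
    guilds: Dict[str, str] = {}
    for s in samples:
        for sp, n in s.counts.items():
            counts[sp] = counts.get(sp, 0) + int(n)
            if sp in s.guilds:
                prev = guilds.setdefault(sp, s.guilds[sp])
                if prev != s.guilds[sp]:
                    raise ValidationError(
                        f"conflicting guild labels for {sp!r}"
                    )
    return CommunitySample(
        sample_id=f"{samples[0].operation_id}:pooled",
        operation_id=samples[0].operation_id,
        stratum=samples[0].stratum,
        counts=counts,
        guilds=guilds,
    )


def operation_metrics(
    samples: Sequence[CommunitySample], mode: str = "pooled"
) -> dict:
    """Diversity summary for one operation.

    ``mode="pooled"`` (default) sums counts across replicate samples
    before computing indices; ``mode="mean"`` computes indices per sample
    and averages them (sensitivity option).
    """
    if mode == "pooled":
        pooled = pool_samples(samples)
        return {
            "richness": richness(pooled.counts),
            "abundance": abundance(pooled.counts),
            "shannon_h": shannon_h(pooled.counts),
            "simpson_ds": simpson_ds(pooled.counts),
        }
    if mode == "mean":
        keys = ("richness", "abundance", "shannon_h", "simpson_ds")
        per = [
            {
                "richness": richness(s.counts),
                "abundance": abundance(s.counts),
                "shannon_h": shannon_h(s.counts),
                "simpson_ds": simpson_ds(s.counts),
            }
            for s in samples
        ]
        return {k: float(np.mean([d[k] for d in per])) for k in keys}
    raise ValidationError("mode must be 'pooled' or 'mean'")
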