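"""Synthetic farm-data generator.

Emulates the statistical structure the validation pipeline assumes so
that every stage is testable without field data:

* bimodal practice adoption — each operation is latently regenerative or
  conventional, and adopts individual regenerative practices with a
  class-specific probability, correlated within an operation through a
  per-operation adoption propensity (``adoption_coupling``), producing
  the two-cluster composite-score distribution observed on real farms;
* linear score -> outcome effects with a clay covariate, farm (and
  optionally field) random intercepts, month fixed offsets, and
  score-proportional inflation of the residual SD for yield/profit-like
  outcomes;
* score-dependent community richness with heavy-tailed (log-normal)
  abundances and configurable trophic-guild proportions.

All draws descend from a single integer seed through named substreams,
so adding an outcome never perturbs the draws of another.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .community import GUILDS, CommunitySample
from .errors import ConfigError
from .profiles import (
    CORN_ITEMS,
    CROPLAND_ITEMS,
    MAX_POSSIBLE,
    PracticeProfile,
    RangelandProfile,
)
from .rubric import (
    composite_score,
    cropland_profile_from_codes,
    rangeland_profile_from_codes,
)
from .soil import SoilLayer


@dataclass
class OutcomeEffect:
    """Linear effect of the composite score on one outcome.

    ``sd_inflation_per_score`` multiplies the residual SD by
    ``1 + inflation * score`` — variability that grows with the score.
    """

    intercept: float
    slope_per_score_unit: float
    farm_sd: float
    residual_sd: float
    clay_slope: float = 0.0
    field_sd: float = 0.0
    sd_inflation_per_score: float = 0.0

    def __post_init__(self) -> None:
        for name in ("farm_sd", "residual_sd", "field_sd",
                     "sd_inflation_per_score"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")


@dataclass
class CommunityConfig:
    """Score-dependent richness with log-normal abundances."""

    base_richness: int = 8
    richness_slope_per_score: float = 1.5
    abundance_lognormal_mu: float = 1.5
    abundance_lognormal_sigma: float = 1.0
    guild_proportions: Dict[str, float] = field(
        default_factory=lambda: {
            "coprophage": 0.15,
            "predator": 0.25,
            "parasitoid": 0.10,
            "herbivore": 0.30,
            "pest": 0.15,
            "other": 0.05,
        }
    )

    def __post_init__(self) -> None:
        if self.base_richness < 1:
            raise ConfigError("base_richness must be >= 1")
        if self.abundance_lognormal_sigma < 0:
            raise ConfigError("abundance sigma must be nonnegative")
        bad = set(self.guild_proportions) - set(GUILDS)
        if bad:
            raise ConfigError(f"unknown guilds in proportions: {sorted(bad)}")
        total = sum(self.guild_proportions.values())
        if not math.isclose(total, 1.0, rel_tol=1e-6):
            raise ConfigError(f"guild proportions must sum to 1, got {total}")


def default_effects() -> Dict[str, OutcomeEffect]:
    """Default outcome effects: the qualitative sign pattern seen on real
    operations (soil carbon up, yield down, pests flat, profit up with
    score-inflated variability), with field-plausible magnitudes."""
    return {
        "soil_carbon": OutcomeEffect(
            intercept=40.0, slope_per_score_unit=2.0, clay_slope=0.4,
            farm_sd=3.0, residual_sd=4.0,
        ),
        "yield": OutcomeEffect(
            intercept=11.5, slope_per_score_unit=-0.15,
            farm_sd=0.6, residual_sd=0.9,
        ),
        "pest_abundance": OutcomeEffect(
            intercept=20.0, slope_per_score_unit=0.0,
            farm_sd=3.0, residual_sd=6.0,
        ),
        # inflation must outpace the relative mean growth (60/250 = 0.24
        # per score point) for SD/mean to rise with the score, which is
        # the variability structure the generator emulates
        "profit": OutcomeEffect(
            intercept=250.0, slope_per_score_unit=60.0,
            farm_sd=80.0, residual_sd=120.0, sd_inflation_per_score=0.4,
        ),
    }


@dataclass
class SimulationConfig:
    """Study conditions for one synthetic bundle."""

    n_operations: int = 200
    system: str = "cropland_full"
    p_regenerative: float = 0.5
    adoption_coupling: float = 1.0
    regen_adoption: float = 0.90
    conv_adoption: float = 0.08
    effects: Dict[str, OutcomeEffect] = field(default_factory=default_effects)
    community: CommunityConfig = field(default_factory=CommunityConfig)
    n_fields_per_operation: int = 1
    months: Optional[List[str]] = None
    month_effects: Optional[Dict[str, float]] = None
    clay_range: Tuple[float, float] = (10.0, 40.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_operations < 1:
            raise ConfigError("n_operations must be >= 1")
        if self.system not in MAX_POSSIBLE:
            raise ConfigError(f"unknown system {self.system!r}")
        if not 0 <= self.p_regenerative <= 1:
            raise ConfigError("p_regenerative must be in [0, 1]")
        if self.adoption_coupling < 0:
            raise ConfigError("adoption_coupling must be >= 0")
        for p in (self.regen_adoption, self.conv_adoption):
            if not 0 <= p <= 1:
                raise ConfigError("adoption probabilities must be in [0, 1]")
        if self.clay_range[0] > self.clay_range[1]:
            raise ConfigError("clay_range must be (low, high)")
        if self.n_fields_per_operation < 1:
            raise ConfigError("n_fields_per_operation must be >= 1")
        cc = self.community
        min_mean = cc.base_richness + cc.richness_slope_per_score * 0
        max_score = MAX_POSSIBLE[self.system]
        if min(min_mean,
               cc.base_richness + cc.richness_slope_per_score * max_score) < 1:
            raise ConfigError(
                "community richness model yields < 1 species on the score range"
            )


def _substream(seed: int, name: str) -> np.random.Generator:
    """Independent named substream of the run's master seed."""
    return np.random.default_rng(
        np.random.SeedSequence([seed & 0x7FFFFFFF, zlib.crc32(name.encode())])
    )


def _adoption_propensity(
    rng: np.random.Generator, is_regen: bool, config: SimulationConfig
) -> float:
    """Per-operation probability of adopting each regenerative practice.

    At zero coupling every operation adopts each practice independently
    at its class base rate.  As ``adoption_coupling`` grows, a
    per-operation Beta draw spreads the propensities (practices bundle:
    an operation tends to adopt many or few together) while the mean is
    pulled toward the class extreme (1 for regenerative, 0 for
    conventional); infinite coupling pins every operation at its
    extreme, so all-regenerative operations score the maximum.
    """
    base = config.regen_adoption if is_regen else config.conv_adoption
    extreme = 1.0 if is_regen else 0.0
    c = config.adoption_coupling
    if math.isinf(c):
        return extreme
    m = (base + c * extreme) / (1.0 + c)
    if c == 0.0 or m <= 0.0 or m >= 1.0:
        return min(max(m, 0.0), 1.0)
    kappa = 8.0 * (1.0 + c) / c
    return float(rng.beta(m * kappa, (1.0 - m) * kappa))


def generate_profiles(
    config: SimulationConfig, return_truth: bool = False
):
    """Draw practice profiles with a bimodal composite-score structure.

    With ``return_truth=True`` also returns the latent class array
    (True = regenerative) for measuring classification agreement.
    """
    rng = _substream(config.seed, "profiles")
    profiles = []
    truth = np.zeros(config.n_operations, dtype=bool)
    for i in range(config.n_operations):
        is_regen = bool(rng.random() < config.p_regenerative)
        truth[i] = is_regen
        p = _adoption_propensity(rng, is_regen, config)
        op_id = f"op{i:04d}"
        if config.system == "rangeland":
            codes = rng.binomial(2, p, size=4)
            profiles.append(rangeland_profile_from_codes(op_id, codes))
        else:
            items = (
                CORN_ITEMS if config.system == "cropland_corn"
                else CROPLAND_ITEMS
            )
            codes = {
                item: int(rng.random() < p) for item in items
            }
            profiles.append(
                cropland_profile_from_codes(op_id, config.system, codes)
            )
    if return_truth:
        return profiles, truth
    return profiles


def score_profiles(profiles) -> pd.DataFrame:
    """Composite scores for a list of profiles, one row per operation."""
    rows = []
    for p in profiles:
        rec = composite_score(p)
        rows.append(
            {
                "operation_id": rec.operation_id,
                "system": rec.system,
                "composite_score": rec.composite_score,
                "max_possible": rec.max_possible,
            }
        )
    return pd.DataFrame(rows)


def generate_outcomes(
    profiles, config: SimulationConfig
) -> pd.DataFrame:
    """Long-format outcome table for the configured effects.

    ``outcome = intercept + slope*score + clay_slope*clay + farm_effect
    (+ field_effect + month_offset) + eps`` with
    ``eps ~ N(0, (residual_sd * (1 + inflation*score))^2)``.  Clay is
    drawn once per operation (a soil property, not a replicate one).
    """
    if not config.effects:
        raise ConfigError("no outcome effects configured")
    scores = {
        p.operation_id: composite_score(p).composite_score for p in profiles
    }
    clay_rng = _substream(config.seed, "clay")
    clay = {
        p.operation_id: float(
            clay_rng.uniform(config.clay_range[0], config.clay_range[1])
        )
        for p in profiles
    }
    months = config.months if config.months else [None]
    month_fx = config.month_effects or {}
    unknown = set(month_fx) - {m for m in months if m is not None}
    if unknown:
        raise ConfigError(f"month effects for unlisted months: {sorted(unknown)}")
    rows = []
    for name in sorted(config.effects):
        eff = config.effects[name]
        rng = _substream(config.seed, f"outcome:{name}")
        for p in profiles:
            s = scores[p.operation_id]
            farm_u = rng.normal(0.0, eff.farm_sd) if eff.farm_sd else 0.0
            resid_sd = eff.residual_sd * (
                1.0 + eff.sd_inflation_per_score * s
            )
            for f in range(config.n_fields_per_operation):
                field_u = (
                    rng.normal(0.0, eff.field_sd) if eff.field_sd else 0.0
                )
                for month in months:
                    value = (
                        eff.intercept
                        + eff.slope_per_score_unit * s
                        + eff.clay_slope * clay[p.operation_id]
                        + farm_u
                        + field_u
                        + month_fx.get(month, 0.0)
                        + (rng.normal(0.0, resid_sd) if resid_sd else 0.0)
                    )
                    rows.append(
                        {
                            "operation_id": p.operation_id,
                            "field_or_plot_id": f"{p.operation_id}-f{f}",
                            "month": month,
                            "score": s,
                            "outcome_name": name,
                            "outcome_value": value,
                            "clay_pct": clay[p.operation_id],
                        }
                    )
    return pd.DataFrame(rows)


def generate_communities(
    profiles, config: SimulationConfig, stratum: str = "epigeal"
) -> List[CommunitySample]:
    """One community sample per operation: species count Poisson around
    ``base_richness + slope*score`` (floored at 1) and per-species
    abundances log-normal, rounded up to whole specimens."""
    cc = config.community
    rng = _substream(config.seed, "communities")
    guild_names = sorted(cc.guild_proportions)
    guild_p = np.array([cc.guild_proportions[g] for g in guild_names])
    samples = []
    for p in profiles:
        s = composite_score(p).composite_score
        mean_rich = cc.base_richness + cc.richness_slope_per_score * s
        if mean_rich < 1:
            raise ConfigError(
                f"richness model yields {mean_rich:.2f} < 1 species at score {s}"
            )
        n_species = max(1, int(rng.poisson(mean_rich)))
        abund = np.maximum(
            1,
            np.round(
                rng.lognormal(
                    cc.abundance_lognormal_mu,
                    cc.abundance_lognormal_sigma,
                    size=n_species,
                )
            ),
        ).astype(int)
        species = [f"{p.operation_id}-sp{j:03d}" for j in range(n_species)]
        guilds = {
            sp: guild_names[g]
            for sp, g in zip(species, rng.choice(len(guild_names),
                                                 size=n_species, p=guild_p))
        }
        samples.append(
            CommunitySample(
                sample_id=f"{p.operation_id}-s0",
                operation_id=p.operation_id,
                stratum=stratum,
                counts=dict(zip(species, (int(a) for a in abund))),
                guilds=guilds,
            )
        )
    return samples


def generate_soil_profile(
    n_layers: int,
    depth_cm: float,
    bd_range: Tuple[float, float] = (1.0, 1.3),
    c_range: Tuple[float, float] = (1.2, 3.0),
    decay_per_cm: Tuple[float, float] = (0.015, 0.035),
    seed: int = 0,
) -> List[SoilLayer]:
    """Contiguous probe-style soil layers totalling *depth_cm*.

    Emulates a sampled mineral-soil profile: layer thicknesses are
    even with moderate jitter (depth-increment sampling, not arbitrary
    slicing), surface %C is uniform in *c_range* and declines
    exponentially with depth at a rate uniform in *decay_per_cm* (each
    layer carries its analytic depth-mean), bulk density starts uniform
    in *bd_range* and rises slowly with depth (compaction), and %N
    follows a 10:1 C:N ratio.
    """
    if n_layers < 1 or depth_cm <= 0:
        raise ConfigError("need >= 1 layer and positive depth")
    if bd_range[0] > bd_range[1] or c_range[0] > c_range[1]:
        raise ConfigError("ranges must be (low, high)")
    rng = _substream(seed, "soil")
    weights = rng.uniform(0.7, 1.3, size=n_layers)
    bounds = np.concatenate([[0.0], np.cumsum(weights)]) / weights.sum()
    bounds *= depth_cm
    c0 = float(rng.uniform(*c_range))
    k = float(rng.uniform(*decay_per_cm))
    bd0 = float(rng.uniform(*bd_range))
    layers = []
    for top, bottom in zip(bounds[:-1], bounds[1:]):
        # depth-mean of c0 * exp(-k z) over the layer
        if k < 1e-12:
            c = c0
        else:
            c = c0 * (math.exp(-k * top) - math.exp(-k * bottom)) / (
                k * (bottom - top)
            )
        bd = min(bd0 + 0.005 * (top + bottom) / 2.0, 1.8)
        layers.append(
            SoilLayer(
                top_cm=float(top),
                bottom_cm=float(bottom),
                bulk_density_g_cm3=bd,
                carbon_pct=c,
                nitrogen_pct=c / 10.0,
            )
        )
    return layers


def community_outcome_table(
    profiles, samples: Sequence[CommunitySample]
) -> pd.DataFrame:
    """Diversity metrics of the generated communities as outcome rows, so
    they run through the same validation models as any other response."""
    from .community import abundance, richness, shannon_h, simpson_ds

    scores = {
        p.operation_id: composite_score(p).composite_score for p in profiles
    }
    rows = []
    for s in samples:
        metrics = {
            "shannon_h": shannon_h(s.counts),
            "simpson_ds": simpson_ds(s.counts),
            "richness": float(richness(s.counts)),
            "invert_abundance": float(abundance(s.counts)),
        }
        for name, value in metrics.items():
            rows.append(
                {
                    "operation_id": s.operation_id,
                    "field_or_plot_id": s.sample_id,
                    "month": None,
                    "score": scores[s.operation_id],
                    "outcome_name": name,
                    "outcome_value": value,
                    "clay_pct": np.nan,
                }
            )
    return pd.DataFrame(rows)


def simulate_bundle(config: SimulationConfig) -> dict:
    """Full synthetic bundle: profiles, latent classes, scores, outcomes
    and community samples, plus a manifest of the run."""
    profiles, truth = generate_profiles(config, return_truth=True)
    scores = score_profiles(profiles)
    outcomes = generate_outcomes(profiles, config)
    communities = generate_communities(profiles, config)
    outcomes = pd.concat(
        [outcomes, community_outcome_table(profiles, communities)],
        ignore_index=True,
    )
    manifest = {
        "seed": config.seed,
        "n_operations": config.n_operations,
        "system": config.system,
        "p_regenerative": config.p_regenerative,
        "outcomes": sorted(config.effects),
    }
    return {
        "profiles": profiles,
        "latent_regenerative": truth,
        "scores": scores,
        "outcomes": outcomes,
        "communities": communities,
        "manifest": manifest,
    }
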