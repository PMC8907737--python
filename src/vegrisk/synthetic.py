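"""Synthetic monitoring scenarios with planted risk tiers.

Generates the three input tables the pipeline consumes — per-sample
concentration records, a region x category consumption table, and a category
limit table — from a compact scenario description. Every (region, category)
combination is assigned to a planted risk *tier*; concentrations are drawn
lognormal with tier-specific log-mean/log-sd and left-censored at a scalar
LOD, reproducing the right-skewed, heavily censored character of national
contaminant monitoring data (the real 2019 programme collected ~11,456
samples over 20 provinces/cities and nine vegetable categories).

The planted tier labels are returned (and written as a sidecar CSV) so that
end-to-end tests can score how well the classification recovers the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import constants
from .errors import ConfigurationError
from .ingest import ToxRefs

__all__ = [
    "TierParams",
    "ScenarioConfig",
    "generate_sampling_table",
    "generate_consumption_table",
    "generate_limit_table",
    "write_scenario",
]

# Sub-stream indices so the three generators draw from independent,
# individually reproducible streams of the scenario seed.
_STREAM_SAMPLING = 0
_STREAM_CONSUMPTION = 1


@dataclass(frozen=True)
class TierParams:
    """Lognormal concentration and mean consumption for one planted tier.

    ``log_mean`` / ``log_sd`` parameterise ln(concentration in mg/kg);
    ``mean_consumption`` is the expected daily intake mass (kg/day) for
    combinations in this tier.
    """

    log_mean: float
    log_sd: float
    mean_consumption: float


@dataclass(frozen=True)
class ScenarioConfig:
    """Full description of a synthetic monitoring scenario.

    ``tier_assignment`` maps every (region, category) combination to a tier
    label present in ``tier_params``. ``limits`` is either the string
    ``"preset"`` (the national 0.3/0.2/0.1 mg/kg scheme keyed by the nine
    standard category names), a scalar applied to every category, or an
    explicit category -> mg/kg mapping.
    """

    regions: tuple[str, ...]
    categories: tuple[str, ...]
    samples_per_combination: int
    tier_assignment: dict[tuple[str, str], int]
    tier_params: dict[int, TierParams]
    lod: float = 0.0095
    limits: str | float | dict[str, float] = "preset"
    consumption_shape: float = 400.0
    tox: ToxRefs = field(
        default_factory=lambda: ToxRefs(
            rfd=constants.RFD_UG_PER_KG_DAY,
            bmdl01=constants.BMDL01_UG_PER_KG_DAY,
            body_weight=constants.BODY_WEIGHT_KG,
        )
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.regions) < 2:
            raise ConfigurationError("need at least 2 regions")
        if len(self.categories) < 1:
            raise ConfigurationError("need at least 1 category")
        if self.samples_per_combination < 2:
            raise ConfigurationError("need at least 2 samples per combination")
        if self.lod < 0:
            raise ConfigurationError("lod must be non-negative")
        if self.consumption_shape <= 0:
            raise ConfigurationError("consumption_shape must be strictly positive")
        combos = {(r, c) for r in self.regions for c in self.categories}
        if set(self.tier_assignment) != combos:
            raise ConfigurationError(
                "tier_assignment must cover every (region, category) combination exactly"
            )
        for combo, tier in self.tier_assignment.items():
            if tier not in self.tier_params:
                raise ConfigurationError(f"combination {combo} assigned unknown tier {tier}")
        for tier, tp in self.tier_params.items():
            if not np.isfinite(tp.log_mean):
                raise ConfigurationError(f"tier {tier}: log_mean must be finite")
            if tp.log_sd <= 0:
                raise ConfigurationError(f"tier {tier}: log_sd must be strictly positive")
            if tp.mean_consumption <= 0:
                raise ConfigurationError(f"tier {tier}: mean_consumption must be strictly positive")
        if isinstance(self.limits, (int, float)) and self.limits <= 0:
            raise ConfigurationError("scalar limit must be strictly positive")
        if isinstance(self.limits, dict):
            for cat, s in self.limits.items():
                if s <= 0:
                    raise ConfigurationError(f"limit for category {cat!r} must be strictly positive")

    @property
    def combinations(self) -> list[tuple[str, str]]:
        """All (region, category) pairs in lexicographic order."""
        return sorted((r, c) for r in self.regions for c in self.categories)

    @classmethod
    def default(
        cls,
        n_regions: int = 20,
        n_categories: int = 9,
        samples_per_combination: int = 30,
        n_tiers: int = 5,
        seed: int = 0,
        *,
        log_sd: float = 0.08,
        tier_spacing_log_sd: float = 3.0,
        base_log_mean: float = float(np.log(0.01)),
        consumption_range: tuple[float, float] = (0.1, 0.1),
        lod: float = 0.0095,
        limit: float = 0.1,
    ) -> "ScenarioConfig":
        """Reference scenario: planted tiers on the national-programme grid.

        Tier t has concentration log-mean ``base_log_mean + (t-1) *
        tier_spacing_log_sd * log_sd`` — tiers separated by 3 log-sd by
        default, the separation regime under which the full pipeline is
        expected to recover the planted structure. Mean daily consumption
        runs geometrically from ``consumption_range[0]`` (lowest tier) to
        ``consumption_range[1]`` (highest); the default is flat at
        0.1 kg/day so the planted contamination tiers are the only
        structure. The LOD sits just below the lowest tier's median, so
        left-censoring concentrates there. A single uniform regulatory
        limit is used: category-specific limits would modulate the
        pollution index across categories independently of the planted
        tier. Combinations are cycled through tiers so every tier is
        populated. When the grid matches the real programme (20 x 9) the
        paper-standard region/category names are used.
        """
        if n_tiers < 1:
            raise ConfigurationError("need at least 1 tier")
        if n_regions <= len(constants.REGIONS):
            regions = constants.REGIONS[:n_regions]
        else:
            regions = tuple(f"region_{i:02d}" for i in range(n_regions))
        if n_categories <= len(constants.CATEGORIES):
            categories = constants.CATEGORIES[:n_categories]
        else:
            categories = tuple(f"category_{i:02d}" for i in range(n_categories))
        combos = sorted((r, c) for r in regions for c in categories)
        assignment = {combo: 1 + i % n_tiers for i, combo in enumerate(combos)}
        fc_lo, fc_hi = consumption_range
        if fc_lo <= 0 or fc_hi <= 0:
            raise ConfigurationError("consumption_range must be strictly positive")
        fc_ratio = (fc_hi / fc_lo) ** (1 / (n_tiers - 1)) if n_tiers > 1 else 1.0
        tiers = {
            t: TierParams(
                log_mean=base_log_mean + (t - 1) * tier_spacing_log_sd * log_sd,
                log_sd=log_sd,
                mean_consumption=fc_lo * fc_ratio ** (t - 1),
            )
            for t in range(1, n_tiers + 1)
        }
        return cls(
            regions=regions,
            categories=categories,
            samples_per_combination=samples_per_combination,
            tier_assignment=assignment,
            tier_params=tiers,
            lod=lod,
            limits=float(limit),
            seed=seed,
        )

    def with_seed(self, seed: int) -> "ScenarioConfig":
        return replace(self, seed=seed)


def _rng(config: ScenarioConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


def generate_sampling_table(config: ScenarioConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-sample concentrations and censor them at the scenario LOD.

    Returns ``(sampling, planted)``: the sampling table in the ingest schema
    (non-detect concentrations stored as NaN) and a sidecar frame of planted
    tier labels per combination.
    """
    rng = _rng(config, _STREAM_SAMPLING)
    n = config.samples_per_combination
    records = []
    planted = []
    for region, category in config.combinations:
        tier = config.tier_assignment[(region, category)]
        tp = config.tier_params[tier]
        draws = rng.lognormal(mean=tp.log_mean, sigma=tp.log_sd, size=n)
        detected = draws >= config.lod
        records.append(
            pd.DataFrame(
                {
                    "region": region,
                    "category": category,
                    "concentration_mg_per_kg": np.where(detected, draws, np.nan),
                    "detected": detected.astype(int),
                    "lod_mg_per_kg": config.lod if config.lod > 0 else np.finfo(float).tiny,
                }
            )
        )
        planted.append({"region": region, "category": category, "tier": tier})
    sampling = pd.concat(records, ignore_index=True)
    sampling["detected"] = sampling["detected"].astype(bool)
    return sampling, pd.DataFrame(planted)


def generate_consumption_table(config: ScenarioConfig) -> pd.DataFrame:
    """Draw strictly positive mean daily consumption (kg/day) per combination.

    Gamma-distributed (shape ``config.consumption_shape``) around the tier's
    mean consumption: positive, unimodal, mildly right-skewed, as population
    mean intakes are.
    """
    rng = _rng(config, _STREAM_CONSUMPTION)
    shape = config.consumption_shape
    rows = []
    for region, category in config.combinations:
        tier = config.tier_assignment[(region, category)]
        mean = config.tier_params[tier].mean_consumption
        fc = rng.gamma(shape, mean / shape)
        rows.append(
            {
                "region": region,
                "category": category,
                "fc_kg_per_day": max(fc, np.finfo(float).tiny),
            }
        )
    return pd.DataFrame(rows)


def generate_limit_table(config: ScenarioConfig) -> pd.DataFrame:
    """Build the category -> regulatory limit table (mg/kg).

    In ``"preset"`` mode the national lead scheme is applied (0.3 mg/kg for
    Brassica and leafy vegetables, 0.2 for legume vegetables, 0.1 for all
    other categories); category names outside the standard nine raise a
    configuration error.
    """
    if config.limits == "preset":
        unknown = [c for c in config.categories if c not in constants.LIMIT_PRESET_MG_PER_KG]
        if unknown:
            raise ConfigurationError(f"preset limits undefined for categories {unknown}")
        values = {c: constants.LIMIT_PRESET_MG_PER_KG[c] for c in config.categories}
    elif isinstance(config.limits, dict):
        missing = [c for c in config.categories if c not in config.limits]
        if missing:
            raise ConfigurationError(f"no limit configured for categories {missing}")
        values = {c: float(config.limits[c]) for c in config.categories}
    else:
        values = {c: float(config.limits) for c in config.categories}
    return pd.DataFrame(
        {"category": list(values), "limit_mg_per_kg": list(values.values())}
    ).sort_values("category", ignore_index=True)


def write_scenario(config: ScenarioConfig, outdir: str | Path) -> dict[str, Path]:
    """Materialise the scenario as the CSV/YAML files the CLI consumes.

    Writes ``sampling.csv``, ``consumption.csv``, ``limits.csv``, ``tox.yaml``
    and the ``planted_tiers.csv`` sidecar; returns the path of each.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sampling, planted = generate_sampling_table(config)
    paths = {
        "sampling": outdir / "sampling.csv",
        "consumption": outdir / "consumption.csv",
        "limits": outdir / "limits.csv",
        "tox": outdir / "tox.yaml",
        "planted": outdir / "planted_tiers.csv",
    }
    sampling.assign(detected=sampling["detected"].astype(int)).to_csv(
        paths["sampling"], index=False
    )
    generate_consumption_table(config).to_csv(paths["consumption"], index=False)
    generate_limit_table(config).to_csv(paths["limits"], index=False)
    planted.to_csv(paths["planted"], index=False)
    with open(paths["tox"], "w") as fh:
        yaml.safe_dump(
            {
                "rfd_ug_per_kg_day": config.tox.rfd,
                "bmdl01_ug_per_kg_day": config.tox.bmdl01,
                "body_weight_kg": config.tox.body_weight,
            },
            fh,
        )
    return paths
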