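"""Model/Results interface tying the pipeline stages together.

:class:`LeadRiskModel` holds the per-combination risk features (pc, hi, moe)
plus the supporting tables; :meth:`LeadRiskModel.fit` runs the spectral
clustering grid search and returns a :class:`RiskClassificationResults`
carrying the selected kernel width and cluster count, the full CH score
table (the model-selection diagnostics), the ordered risk levels, and a
``summary()`` text table.

Typical use::

    sampling = ingest.substitute_nondetects(ingest.read_sampling_csv("sampling.csv"))
    model = LeadRiskModel.from_tables(sampling, consumption, limits, tox)
    res = model.fit(seed=0)
    print(res.summary())
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from . import grading, indices, ingest, spectral
from .errors import DomainError
from .ingest import ToxRefs

__all__ = ["LeadRiskModel", "RiskClassificationResults"]

DEFAULT_GAMMAS = tuple(range(1, 11))
DEFAULT_KS = tuple(range(3, 8))


class LeadRiskModel:
    """Dietary-contaminant risk classification over region x food combinations.

    Parameters
    ----------
    features : DataFrame
        Columns ``region, category, pc, hi, moe`` — one row per combination,
        as produced by :func:`vegrisk.indices.build_feature_matrix`.
    stats, limits : DataFrame, optional
        Combination summaries and the regulatory-limit table; when supplied,
        results can report exceedance factors alongside high-risk
        combinations.
    """

    def __init__(
        self,
        features: pd.DataFrame,
        *,
        stats: pd.DataFrame | None = None,
        limits: pd.DataFrame | None = None,
    ) -> None:
        missing = [c for c in ("region", "category", *indices.FEATURE_COLUMNS) if c not in features.columns]
        if missing:
            raise DomainError(f"feature table missing column(s) {missing}")
        if features[indices.FEATURE_COLUMNS].isna().any().any():
            raise DomainError("feature table contains missing values")
        self.features = features.sort_values(["region", "category"], ignore_index=True)
        self.stats = stats
        self.limits = limits

    @classmethod
    def from_tables(
        cls,
        sampling: pd.DataFrame,
        consumption: pd.DataFrame,
        limits: pd.DataFrame,
        tox: ToxRefs,
        *,
        lod_scope: str = "global",
        quantile_method: str = "linear",
    ) -> "LeadRiskModel":
        """Build the model from raw monitoring tables.

        Applies the LOD substitution rule (over ``lod_scope``), summarises
        each combination and computes the (pc, hi, moe) features.
        """
        completed = ingest.substitute_nondetects(sampling, scope=lod_scope)
        stats = ingest.summarize_combinations(completed, quantile_method=quantile_method)
        features = indices.build_feature_matrix(stats, consumption, limits, tox)
        return cls(features, stats=stats, limits=limits)

    @classmethod
    def from_scenario(cls, config) -> tuple["LeadRiskModel", pd.DataFrame]:
        """Build the model from a synthetic scenario; also returns the
        planted tier labels for validation."""
        from . import synthetic

        sampling, planted = synthetic.generate_sampling_table(config)
        consumption = synthetic.generate_consumption_table(config)
        limits = synthetic.generate_limit_table(config)
        model = cls.from_tables(sampling, consumption, limits, config.tox)
        return model, planted

    @property
    def exog(self) -> np.ndarray:
        """The n x 3 (pc, hi, moe) array in combination order."""
        return self.features[indices.FEATURE_COLUMNS].to_numpy(float)

    def fit(
        self,
        gammas=DEFAULT_GAMMAS,
        ks=DEFAULT_KS,
        seed: int = 0,
        *,
        embedding: str = "laplacian",
        n_restarts: int = 10,
    ) -> "RiskClassificationResults":
        """Grid-search (gamma, k) by the CH index and grade the clusters.

        Defaults follow the national-study configuration: kernel widths 1-10
        and 3-7 clusters.
        """
        search = spectral.grid_search(
            self.exog, gammas, ks, seed=seed, embedding=embedding, n_restarts=n_restarts
        )
        Z = spectral.standardize_features(self.exog)
        level_map = grading.order_clusters_by_risk(Z, search.assignment.labels)
        levels = grading.assign_levels(self.features, search.assignment, level_map, Z=Z)
        return RiskClassificationResults(
            model=self, search=search, level_map=level_map, risk_levels=levels, seed=seed
        )


@dataclass
class RiskClassificationResults:
    """Fitted classification: selected (gamma, k), CH diagnostics, levels."""

    model: LeadRiskModel
    search: spectral.GridSearchResult
    level_map: dict[int, int]
    risk_levels: pd.DataFrame = field(repr=False)
    seed: int = 0

    @property
    def gamma_(self) -> float:
        return self.search.best[0]

    @property
    def k_(self) -> int:
        return self.search.best[1]

    @property
    def ch_scores(self) -> pd.DataFrame:
        """Full (gamma, k, ch_score) table from model selection."""
        return self.search.table

    @property
    def labels_(self) -> np.ndarray:
        return self.search.assignment.labels

    def level_summary(self) -> pd.DataFrame:
        return grading.level_proportions(self.risk_levels)

    def high_risk(self, threshold_level: int = 3) -> pd.DataFrame:
        return grading.rank_high_risk(
            self.risk_levels,
            threshold_level=threshold_level,
            limits=self.model.limits,
            stats=self.model.stats,
        )

    def summary(self) -> str:
        """Plain-text summary: selection, CH score, level proportions, top risks."""
        best_score = float(
            self.ch_scores.query("gamma == @self.gamma_ and k == @self.k_")["ch_score"].iloc[0]
        )
        lines = [
            "Dietary contaminant risk classification (spectral clustering)",
            "=" * 62,
            f"combinations: {len(self.risk_levels):>5d}    features: pc, hi, moe",
            f"selected kernel width gamma: {self.gamma_:g}",
            f"selected number of risk levels k: {self.k_}",
            f"Calinski-Harabasz score at optimum: {best_score:.1f}",
            "",
            "Risk level proportions",
            "-" * 62,
        ]
        for row in self.level_summary().itertuples(index=False):
            lines.append(f"  {row.group:>10s}: {row.count:>4d}  ({row.percent:6.2f}%)")
        top = self.high_risk()
        lines += ["", f"Combinations at level >= 3: {len(top)}", "-" * 62]
        for row in top.head(10).itertuples(index=False):
            lines.append(f"  level {row.risk_level}: {row.category} - {row.region}")
        if len(top) > 10:
            lines.append(f"  ... ({len(top) - 10} more)")
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write indices, CH scores, cluster labels, levels, high-risk report
        and the JSON summary into ``outdir``; returns each path."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "indices": outdir / "indices.csv",
            "ch_scores": outdir / "ch_scores.csv",
            "clusters": outdir / "clusters.csv",
            "risk_levels": outdir / "risk_levels.csv",
            "high_risk": outdir / "high_risk.csv",
            "summary": outdir / "summary.json",
        }
        indices.write_indices_csv(self.model.features, paths["indices"])
        self.ch_scores.to_csv(paths["ch_scores"], index=False)
        self.risk_levels[["region", "category", "cluster_id"]].to_csv(
            paths["clusters"], index=False
        )
        self.risk_levels.to_csv(paths["risk_levels"], index=False)
        self.high_risk().to_csv(paths["high_risk"], index=False)
        summary = {
            "software_version": _version,
            "seed": self.seed,
            "selected_gamma": self.gamma_,
            "selected_k": self.k_,
            "levels": self.level_summary().to_dict(orient="records"),
            "ch_table": str(paths["ch_scores"]),
        }
        with open(paths["summary"], "w") as fh:
            json.dump(summary, fh, indent=2)
        return paths
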