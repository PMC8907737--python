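"""End-to-end orchestration: configuration, validation, one reproducible run.

A :class:`RunConfig` names either the four input files (sampling,
consumption, limits, toxicology) or a synthetic scenario, plus the grid
ranges and the root seed; :func:`run_pipeline` executes
ingest -> indices -> clustering grid search -> risk grading, writes every
intermediate artifact into the output directory and returns a
:class:`RunReport` sufficient to re-run the pipeline bit-identically.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__ as _version
from . import ingest, synthetic
from .errors import ConfigurationError
from .model import DEFAULT_GAMMAS, DEFAULT_KS, LeadRiskModel

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "validate_config", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one pipeline run depends on.

    Exactly one of ``scenario`` (synthetic inputs) or the four file paths
    must be set.
    """

    sampling_path: str | None = None
    consumption_path: str | None = None
    limits_path: str | None = None
    tox_path: str | None = None
    scenario: synthetic.ScenarioConfig | None = None
    lod_scope: str = "global"
    quantile_method: str = "linear"
    gammas: tuple = DEFAULT_GAMMAS
    ks: tuple = DEFAULT_KS
    embedding: str = "laplacian"
    seed: int = 0
    outdir: str = "vegrisk_out"

    def echo(self) -> dict:
        """JSON-serialisable config echo (sufficient to reproduce the run)."""
        d = dataclasses.asdict(self)
        if self.scenario is not None:
            sc = d["scenario"]
            sc["tier_assignment"] = {f"{r}|{c}": t for (r, c), t in sc["tier_assignment"].items()}
        d["gammas"] = list(self.gammas)
        d["ks"] = list(self.ks)
        return d


@dataclass
class RunReport:
    """What a completed run produced, echoed back for reproducibility."""

    config: dict
    software_version: str
    seed: int
    n_samples: int
    n_combinations: int
    selected_gamma: float
    selected_k: int
    output_files: dict[str, str]
    warnings: list[str] = field(default_factory=list)


def validate_config(config: RunConfig) -> list[str]:
    """Return the list of problems preventing a run (empty iff runnable)."""
    problems: list[str] = []
    file_paths = [
        config.sampling_path,
        config.consumption_path,
        config.limits_path,
        config.tox_path,
    ]
    files_given = any(p is not None for p in file_paths)
    if config.scenario is not None and files_given:
        problems.append("exactly one of file inputs or a synthetic scenario may be active, not both")
    elif config.scenario is None:
        if not files_given:
            problems.append("no inputs: provide the four file paths or a synthetic scenario")
        else:
            for name, p in zip(("sampling", "consumption", "limits", "tox"), file_paths):
                if p is None:
                    problems.append(f"{name}_path is required when running from files")
                elif not Path(p).exists():
                    problems.append(f"{name}_path does not exist: {p}")
    if config.lod_scope not in ("global", "per_combination"):
        problems.append(f"lod_scope must be 'global' or 'per_combination', got {config.lod_scope!r}")
    if config.embedding not in ("laplacian", "affinity"):
        problems.append(f"embedding must be 'laplacian' or 'affinity', got {config.embedding!r}")
    if not config.gammas:
        problems.append("gammas grid is empty")
    elif any(g <= 0 for g in config.gammas):
        problems.append("gammas must be strictly positive")
    if not config.ks:
        problems.append("ks grid is empty")
    elif any(k < 2 for k in config.ks):
        problems.append("ks must all be >= 2 (the CH index is undefined for k < 2)")
    return problems


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the full pipeline and write all artifacts to ``config.outdir``."""
    problems = validate_config(config)
    if problems:
        raise ConfigurationError("; ".join(problems))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if config.scenario is not None:
        scenario = config.scenario.with_seed(config.seed)
        scenario_paths = synthetic.write_scenario(scenario, outdir / "inputs")
        sampling = ingest.read_sampling_csv(scenario_paths["sampling"])
        consumption = ingest.read_consumption_csv(scenario_paths["consumption"])
        limits = ingest.read_limits_csv(scenario_paths["limits"])
        tox = scenario.tox
    else:
        sampling = ingest.read_sampling_csv(config.sampling_path)
        consumption = ingest.read_consumption_csv(config.consumption_path)
        limits = ingest.read_limits_csv(config.limits_path)
        tox = ingest.read_tox_config(config.tox_path)

    logger.info("ingest: %d sampling records", len(sampling))
    model = LeadRiskModel.from_tables(
        sampling,
        consumption,
        limits,
        tox,
        lod_scope=config.lod_scope,
        quantile_method=config.quantile_method,
    )
    logger.info("indices: %d combinations", len(model.features))
    results = model.fit(config.gammas, config.ks, seed=config.seed, embedding=config.embedding)
    logger.info("selected gamma=%g, k=%d", results.gamma_, results.k_)
    paths = results.save(outdir)
    model.stats.to_csv(outdir / "combination_stats.csv", index=False)
    paths["combination_stats"] = outdir / "combination_stats.csv"

    report = RunReport(
        config=config.echo(),
        software_version=_version,
        seed=config.seed,
        n_samples=len(sampling),
        n_combinations=len(model.features),
        selected_gamma=results.gamma_,
        selected_k=results.k_,
        output_files={k: str(v) for k, v in paths.items()},
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(dataclasses.asdict(report), fh, indent=2)
    return report
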