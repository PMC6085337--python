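"""End-to-end orchestration: simulate/ingest → RLQ → FD → niches → SEM.

`run_pipeline` executes the full analysis from a :class:`PipelineConfig`
(round-trippable through YAML), writes every stage's tables under the
output directory and finishes with a manifest recording inputs, seeds
and SHA-256 checksums of all outputs, so a re-run with the same config
is verifiably identical.  Stage failures abort with the stage name and
cause; partial outputs are kept next to a ``FAILED`` marker.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._utils import spawn_seed
from . import core_data, niche_metrics
from .hier_sem import MCMCConfig, run_both_models
from .niche_metrics import niche_pipeline
from .rlq_fourthcorner import permutation_test, rlq, select_axes, trait_axis_correlations
from .synthetic_data import ScenarioConfig, simulate_dataset
from .functional_diversity import fd_pipeline

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    """Everything needed to run (or exactly re-run) the pipeline."""

    output_dir: str = "pipeline_out"
    seed: int = 0
    # either a scenario (simulate) or paths to the input CSV bundle
    scenario: dict | None = None
    inputs: dict | None = None  # plant_traits, plant_meta, animal_traits, animal_meta, interactions, covariates
    n_permutations: int = 999
    permutation_model: int = 6
    coverage: float = 0.99
    trait_sets: tuple = ("all", "matching", "energy", "foraging")
    mcmc: dict = field(default_factory=lambda: {"chains": 4, "iterations": 5000, "thin": 10})
    run_sem: bool = True
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        if raw.get("trait_sets") is not None:
            raw["trait_sets"] = tuple(raw["trait_sets"])
        return cls(**raw)

    def stage_seed(self, stage: str) -> int:
        return spawn_seed(self.seed, "pipeline", stage)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _read_traits(inputs: dict, key: str, level: str) -> core_data.TraitTable:
    meta = pd.read_csv(inputs[f"{key}_meta"])
    type_map = dict(zip(meta["trait"], meta["trait_type"]))
    units = dict(zip(meta["trait"], meta.get("units", "")))
    return core_data.read_trait_table(inputs[key], type_map, level, units)


def run_pipeline(config: PipelineConfig) -> Path:
    """Run all stages; returns the artifact directory.

    Stages: ``ingest`` (or ``simulate``), ``metaweb``, ``rlq``, ``fd``,
    ``niche`` and optionally ``sem``.  Every numeric output is written
    as CSV/JSON and checksummed into ``manifest.json``.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    stage = "configure"
    try:
        stage = "ingest"
        if config.scenario is not None:
            scenario = ScenarioConfig(**{**config.scenario, "seed": config.stage_seed("simulate")})
            plants, animals, interactions, covariates, truth = simulate_dataset(scenario)
            truth_path = outdir / "truth.json"
            truth.to_json(truth_path)
            written["truth"] = truth_path
        elif config.inputs is not None:
            for key, p in config.inputs.items():
                if not Path(p).exists():
                    raise FileNotFoundError(f"missing input file {p!r} ({key})")
            plants = _read_traits(config.inputs, "plant_traits", "plant")
            animals = _read_traits(config.inputs, "animal_traits", "animal")
            interactions = core_data.read_interactions(config.inputs["interactions"])
            covariates = core_data.read_covariates(config.inputs["covariates"])
        else:
            raise ValueError("config needs either a scenario or input paths")
        covariates, r2 = core_data.impute_climate(covariates)
        plants_t = core_data.sqrt_transform(plants)
        animals_t = core_data.sqrt_transform(animals)

        stage = "rlq"
        rlq_rows, pvals = [], {}
        for mutualism in sorted(interactions.records["mutualism"].unique()):
            L = interactions.metaweb(mutualism)
            fit = rlq(plants_t, L, animals_t)
            k_star = select_axes(fit, config.coverage)
            corr = trait_axis_correlations(fit, plants_t, animals_t)
            corr.insert(0, "mutualism", mutualism)
            rlq_rows.append(
                (
                    mutualism,
                    fit,
                    k_star,
                    corr,
                    permutation_test(
                        plants_t,
                        L,
                        animals_t,
                        statistic="sum_eigenvalues",
                        n_perm=config.n_permutations,
                        model=config.permutation_model,
                        seed=config.stage_seed(f"perm-{mutualism}"),
                    ),
                )
            )
        eig = pd.DataFrame(
            [
                {
                    "mutualism": m,
                    "axis": i + 1,
                    "eigenvalue": fit.eigenvalues[i],
                    "percent_covariance": fit.percent_covariance[i],
                    "selected": i < k_star,
                }
                for m, fit, k_star, _, _ in rlq_rows
                for i in range(fit.k)
            ]
        )
        _write_csv(written, outdir / "rlq_eigenvalues.csv", eig)
        _write_csv(
            written,
            outdir / "rlq_trait_correlations.csv",
            pd.concat([c for _, _, _, c, _ in rlq_rows], ignore_index=True),
        )
        pvals = {
            m: {"observed_sum_eigenvalues": t.observed, "p_model2": t.p_model2, "p_model4": t.p_model4, "p_model6": t.p_model6}
            for m, _, _, _, t in rlq_rows
        }
        _write_json(written, outdir / "fourthcorner_pvalues.json", pvals)

        stage = "fd"
        fd = fd_pipeline(plants_t, animals_t, interactions.records, trait_sets=config.trait_sets)
        _write_csv(written, outdir / "functional_dispersion.csv", fd)

        stage = "niche"
        metrics = niche_pipeline(plants_t, animals_t, interactions.records, covariates)
        _write_csv(written, outdir / "site_metrics.csv", metrics)

        if config.run_sem:
            stage = "sem"
            sem_metrics = niche_metrics.zscale_metrics(metrics)
            models = run_both_models(
                sem_metrics,
                mcmc=MCMCConfig.desk(**config.mcmc) if config.mcmc else None,
                seed=config.stage_seed("sem"),
            )
            for name, res in models.items():
                _write_csv(written, outdir / f"sem_{name}_path_support.csv", res["support"])
                _write_csv(written, outdir / f"sem_{name}_r2.csv", res["r2"])

        stage = "manifest"
        _validate_outputs(written)
        manifest = {
            "seed": config.seed,
            "stage_seeds": {s: config.stage_seed(s) for s in ("simulate", "sem")},
            "climate_imputation_r2": r2,
            "config": asdict(config),
            "outputs": {k: {"path": str(p), "sha256": _sha256(p)} for k, p in written.items()},
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    except Exception as exc:  # noqa: BLE001 - re-raised with stage context
        (outdir / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise StageError(stage, exc) from exc
    failed = outdir / "FAILED"
    if failed.exists():
        failed.unlink()
    return outdir


def _write_csv(written: dict, path: Path, df: pd.DataFrame) -> None:
    df.to_csv(path, index=False)
    written[path.stem] = path


def _write_json(written: dict, path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=2, default=float))
    written[path.stem] = path


def _validate_outputs(written: dict) -> None:
    """Schema check: every CSV re-parses with at least one row, JSON loads."""
    for name, p in written.items():
        if p.suffix == ".csv":
            df = pd.read_csv(p)
            if df.empty:
                raise ValueError(f"output {name} is empty")
        elif p.suffix == ".json":
            json.loads(p.read_text())
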