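"""End-to-end pipeline: configuration, stage chaining and artifact output.

Stage order is fixed: (generate or read) -> NNI augmentation -> K-means +
Borderline-SMOTE balancing -> surrogate fit (optional learning-curve tuning)
-> repeated-split evaluation -> Shapley attribution -> response surface.
Each stage draws its randomness from an independent substream of the single
global seed, every tabular artifact is written as CSV, and a run log records
the seed and the row count at each stage.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import balance, evaluation, interpret, models, nni, synthetic
from .data import FeatureTable, read_table, write_table
from .errors import NRSurrogateError, StageError
from .seeding import stage_seed

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Validated bundle of all stage specs plus I/O locations.

    With ``input_path`` unset the packaged synthetic benchmark is generated
    in-place (n = 86 by default), which makes the default config a complete,
    runnable study.
    """

    seed: int = 0
    input_path: str | None = None
    outdir: str = "nrsurrogate_out"
    design: synthetic.DesignSpec = field(default_factory=synthetic.DesignSpec)
    surface_params: synthetic.SurfaceParams = field(
        default_factory=synthetic.SurfaceParams
    )
    augmentation: nni.AugmentationSpec = field(default_factory=nni.AugmentationSpec)
    smote: balance.SmoteSpec = field(default_factory=balance.SmoteSpec)
    smote_enabled: bool = True
    surrogate: models.SurrogateSpec = field(default_factory=models.SurrogateSpec)
    tune_grids: dict | None = None  # None = no tuning; {} = full default grids
    evaluation: evaluation.EvalSpec = field(default_factory=evaluation.EvalSpec)
    baselines: tuple[str, ...] = ("mlr", "svr")
    eps_nh_fixed: float = 0.38
    grid_points: int = 200
    explain_max_background: int = 256

    def __post_init__(self) -> None:
        if self.seed < 0:
            raise StageError("config", "seed must be >= 0")

    # -- (de)serialization -------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        def build(factory, key):
            sub = raw.pop(key, None)
            if sub is None:
                return factory()
            if key == "design":
                for tup_key in ("mixture_weights", "feature_names"):
                    if tup_key in sub:
                        sub[tup_key] = tuple(sub[tup_key])
                for nest in ("centers", "spreads", "bounds"):
                    if nest in sub:
                        sub[nest] = tuple(tuple(v) for v in sub[nest])
            return factory(**sub)

        kwargs = dict(
            design=build(synthetic.DesignSpec, "design"),
            surface_params=build(synthetic.SurfaceParams, "surface_params"),
            augmentation=build(nni.AugmentationSpec, "augmentation"),
            smote=build(balance.SmoteSpec, "smote"),
            surrogate=build(models.SurrogateSpec, "surrogate"),
            evaluation=build(evaluation.EvalSpec, "evaluation"),
        )
        if "baselines" in raw:
            raw["baselines"] = tuple(raw["baselines"])
        kwargs.update(raw)
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """All artifacts of one pipeline run."""

    input_table: FeatureTable
    augmented: FeatureTable
    balanced: FeatureTable
    assignment: balance.ClusterAssignment | None
    model: models.Model
    tuned_spec: models.SurrogateSpec | None
    report: evaluation.EvaluationReport
    attribution: interpret.AttributionReport
    surface: interpret.SurfaceGrid


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise with the stage name attached."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and not isinstance(exc, StageError):
                raise StageError(name, str(exc)) from exc
            return False

    return _Ctx()


def run_pipeline(config: PipelineConfig, write: bool = True) -> PipelineResult:
    """Execute all stages in order; optionally write artifacts to
    ``config.outdir``."""
    outdir = Path(config.outdir)
    if write:
        outdir.mkdir(parents=True, exist_ok=True)
        handler = logging.FileHandler(outdir / "run.log", mode="w")
        handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)
    try:
        return _run(config, outdir, write)
    finally:
        if write:
            logger.removeHandler(handler)
            handler.close()


def _run(config: PipelineConfig, outdir: Path, write: bool) -> PipelineResult:
    seed = config.seed
    logger.info("pipeline start, global seed %d", seed)

    with _stage("input"):
        if config.input_path:
            table = read_table(config.input_path, has_target=True)
        else:
            table = synthetic.generate_dataset(
                config.design, config.surface_params, seed=seed
            )
    logger.info("input: %d rows (seed %d)", table.n, stage_seed(seed, "generate"))

    with _stage("nni"):
        augmented = nni.nni_augment(table, config.augmentation, seed=seed)
    logger.info("nni: %d rows (seed %d)", augmented.n, stage_seed(seed, "nni"))

    assignment = None
    balanced = augmented
    if config.smote_enabled and augmented.n >= config.smote.n_clusters:
        with _stage("smote"):
            assignment = balance.cluster(
                augmented, K=config.smote.n_clusters, seed=seed
            )
            balanced = balance.smote_augment(
                augmented, assignment, config.smote, seed=seed
            )
        logger.info(
            "smote: cluster sizes %s -> %d rows (seed %d)",
            assignment.sizes.tolist(), balanced.n, stage_seed(seed, "smote"),
        )

    tuned_spec = None
    spec = config.surrogate
    if config.tune_grids is not None:
        with _stage("tune"):
            grids = config.tune_grids or None  # {} -> full default grids
            tuned_spec, _ = models.tune(balanced, grids, seed=seed)
            spec = tuned_spec
        logger.info("tune: selected %s", spec)

    with _stage("fit"):
        model = models.fit_gbt(balanced, spec, seed=seed)
    logger.info("fit: gbt on %d rows (seed %d)", balanced.n, stage_seed(seed, "fit"))

    with _stage("evaluate"):
        fitters = {"gbt": lambda t, s: models.fit_gbt(t, spec, seed=s)}
        for kind in config.baselines:
            fitters[kind] = (
                lambda t, s, k=kind: models.fit_baseline(t, k, seed=s)
            )
        report = evaluation.robustness(
            balanced, fitters, config.evaluation, seed=stage_seed(seed, "evaluate")
        )
    logger.info("evaluate: %d splits x %d models",
                config.evaluation.n_splits, len(report.model_names))

    with _stage("explain"):
        attribution = interpret.explain_table(
            model, balanced,
            max_background=config.explain_max_background,
            seed=stage_seed(seed, "explain"),
        )
    logger.info("explain: ranking %s", attribution.ranking())

    with _stage("surface"):
        g = config.grid_points
        surface = interpret.predict_surface(
            model,
            eps_nh_fixed=config.eps_nh_fixed,
            eps_h=(config.design.bounds[1][0], config.design.bounds[1][1], g),
            omega=(config.design.bounds[0][0], config.design.bounds[0][1], g),
        )
    logger.info("surface: %dx%d grid at eps_nh=%.3f", g, g, config.eps_nh_fixed)

    result = PipelineResult(
        input_table=table,
        augmented=augmented,
        balanced=balanced,
        assignment=assignment,
        model=model,
        tuned_spec=tuned_spec,
        report=report,
        attribution=attribution,
        surface=surface,
    )
    if write:
        _write_artifacts(result, config, outdir)
    return result


def _write_artifacts(
    result: PipelineResult, config: PipelineConfig, outdir: Path
) -> None:
    write_table(result.input_table, outdir / "input.csv")
    write_table(result.augmented, outdir / "augmented_nni.csv")
    write_table(result.balanced, outdir / "augmented_full.csv")
    models.save_model(result.model, outdir / "model_gbt.json")
    result.report.to_frame().to_csv(outdir / "evaluation_splits.csv", index=False)
    (outdir / "evaluation_summary.txt").write_text(
        result.report.summary_text() + "\n", encoding="utf-8"
    )
    result.attribution.to_frame().to_csv(outdir / "shapley_values.csv", index=False)
    ranking = result.attribution.ranking()
    with open(outdir / "importance.csv", "w", encoding="utf-8") as fh:
        fh.write("feature,mean_abs_shap\n")
        for name, val in ranking:
            fh.write(f"{name},{val:.10g}\n")
    result.surface.to_frame().to_csv(outdir / "surface.csv", index=False)
    config.to_yaml(outdir / "config_resolved.yaml")
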