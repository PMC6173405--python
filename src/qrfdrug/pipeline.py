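"""Three-step workflow: screen -> importance-select -> quantile regression forest.

Stage 1 keeps features marginally correlated with the response (raw Pearson
p < alpha_screen).  Stage 2 fits a bagged regression forest on the screened
features and keeps those whose OOB permutation importance exceeds
mean + c * SD of all importances.  Stage 3 fits the quantile regression forest
on the selected features and reports OOB point predictions (mean and median),
the full quantile grid, prediction intervals and evaluation metrics (Pearson
accuracy, per-tau check loss, interval average length and coverage).

:class:`ThreeStepQRF` runs the workflow on an in-memory Dataset and returns a
:class:`PipelineResults`; :func:`run_pipeline` is the file-based front end that
reads the delimited inputs, runs the model and writes the TSV artifacts plus a
JSON manifest.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .forest import (
    ImportanceVector,
    default_mtry,
    fit_forest,
    permutation_importance,
    select_by_importance,
)
from .io import (
    Dataset,
    FeatureKind,
    assemble_dataset,
    read_feature_matrix,
    read_response_table,
)
from .metrics import accuracy, evaluate_intervals, evaluate_quantiles
from .qrf import DEFAULT_TAUS, QRFResults, QuantileRegressionForest
from .screening import ScreenResult, screen_features

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "PipelineError", "PipelineResults", "ThreeStepQRF", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name in its message."""


@dataclass
class PipelineConfig:
    """All knobs of the three-step workflow (defaults mirror the reference analysis)."""

    # file-based inputs (optional when running on an in-memory Dataset)
    expression: str | None = None
    mutation: str | None = None
    cnv: str | None = None
    response: str | None = None
    drug_id: str | None = None
    outdir: str | None = None
    orientation: str = "samples_in_columns"

    # method parameters
    alpha_screen: float = 0.05
    trees_select: int = 25000
    trees_qrf: int = 15000
    min_node: int = 10
    mtry: int | None = None  # None -> M/3 rule at each stage
    taus: tuple[float, ...] = DEFAULT_TAUS
    alpha_pi: float = 0.05
    importance_c: float = 2.0
    k_levene: int = 500
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha_screen <= 1:
            raise ValueError("alpha_screen must lie in (0, 1]")
        if self.trees_select < 1 or self.trees_qrf < 1:
            raise ValueError("tree counts must be >= 1")
        if self.min_node < 2:
            raise ValueError("min_node must be >= 2")
        if not 0 < self.alpha_pi < 1:
            raise ValueError("alpha_pi must lie in (0, 1)")
        self.taus = tuple(float(t) for t in self.taus)
        if any(not 0 < t < 1 for t in self.taus):
            raise ValueError("all taus must lie strictly in (0, 1)")
        if self.k_levene < 2:
            raise ValueError("k_levene must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["taus"] = list(self.taus)
        return d


@dataclass
class PipelineResults:
    """Artifacts of one three-step run on a single drug."""

    config: PipelineConfig
    dataset: Dataset
    drug_id: str
    screen: ScreenResult
    importance: ImportanceVector
    selected_features: list[str]
    qrf: QRFResults
    predictions: pd.DataFrame
    quantile_errors: pd.DataFrame
    metrics: pd.DataFrame
    counts: dict
    timings: dict = field(default_factory=dict)

    def summary(self) -> str:
        c = self.counts
        lines = [
            f"Three-step QRF results for drug {self.drug_id!r}",
            "=" * 56,
            f"Samples:                      {c['n_samples']}",
            f"Features (input):             {c['n_features']}",
            f"Features after screening:     {c['n_screened']}",
            f"Features after selection:     {c['n_selected']}",
            "-" * 56,
        ]
        for _, row in self.metrics.iterrows():
            lines.append(f"{row['metric']:<28s} {row['value']:.4f}")
        lines.append("-" * 56)
        lines.append("Selected features (importance-ranked):")
        for f in self.selected_features:
            lines.append(f"  {f}")
        lines.append("=" * 56)
        return "\n".join(lines)

    def save(self, outdir: str | Path) -> dict[str, Path]:
        """Write all TSV artifacts plus the JSON run manifest.

        On failure, files already written by this call are removed so no
        partial artifact bundle is left behind.
        """
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []
        try:
            paths = {}
            for name, frame in (
                ("screening", self.screen.to_frame()),
                ("importance", self.importance.ranked()),
                ("selected_features", pd.DataFrame({"feature_id": self.selected_features})),
                ("predictions", self.predictions),
                ("quantile_errors", self.quantile_errors),
                ("metrics", self.metrics),
            ):
                path = outdir / f"{name}.tsv"
                frame.to_csv(path, sep="\t", index=False)
                written.append(path)
                paths[name] = path
            manifest = {
                "package": "qrfdrug",
                "version": __version__,
                "drug_id": self.drug_id,
                "config": self.config.to_dict(),
                "counts": self.counts,
                "timings_sec": {k: round(v, 3) for k, v in self.timings.items()},
            }
            path = outdir / "manifest.json"
            with open(path, "w") as fh:
                json.dump(manifest, fh, indent=2, sort_keys=True)
                fh.write("\n")
            written.append(path)
            paths["manifest"] = path
            return paths
        except Exception:
            for p in written:
                p.unlink(missing_ok=True)
            raise


class ThreeStepQRF:
    """The three-step model on an in-memory Dataset; ``fit`` runs all stages."""

    def __init__(self, dataset: Dataset, config: PipelineConfig | None = None,
                 drug_id: str | None = None) -> None:
        self.dataset = dataset
        self.config = config or PipelineConfig()
        self.drug_id = drug_id or self.config.drug_id or "drug"

    def fit(self, seed: int | None = None) -> PipelineResults:
        cfg = self.config
        seed = cfg.seed if seed is None else seed
        data = self.dataset
        timings: dict[str, float] = {}

        def stage(name, fn):
            t0 = time.perf_counter()
            try:
                out = fn()
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
            timings[name] = time.perf_counter() - t0
            logger.info("stage %s done in %.2fs", name, timings[name])
            return out

        screen = stage("screen", lambda: screen_features(data, cfg.alpha_screen))
        screened = stage(
            "screen", lambda: data.subset_features(screen.selected_ids)
        )

        def _select():
            forest = fit_forest(
                screened,
                T=cfg.trees_select,
                m=cfg.mtry,
                min_node=cfg.min_node,
                seed=seed,
            )
            imp = permutation_importance(forest, screened, seed=seed + 1)
            return imp, select_by_importance(imp, c=cfg.importance_c)

        importance, selected = stage("select", _select)
        selected_data = data.subset_features(selected)

        def _fit_qrf():
            model = QuantileRegressionForest.from_dataset(
                selected_data,
                n_trees=cfg.trees_qrf,
                mtry=cfg.mtry,
                min_node=cfg.min_node,
            )
            return model.fit(seed=seed + 2)

        qrf = stage("qrf", _fit_qrf)

        def _predict():
            taus = sorted(
                set(cfg.taus)
                | {cfg.alpha_pi / 2, 1 - cfg.alpha_pi / 2, 0.5, 0.1, 0.9, 0.025, 0.975}
            )
            oob = qrf.oob_predictions(taus=taus, include_mean=True)
            pred = oob.reset_index()
            pred.insert(1, "drug_id", self.drug_id)
            pred.insert(2, "observed", data.y)
            lo, hi = f"q{cfg.alpha_pi / 2:g}", f"q{1 - cfg.alpha_pi / 2:g}"
            pred["pi_lower"] = pred[lo]
            pred["pi_upper"] = pred[hi]
            pred["pi_length"] = pred[hi] - pred[lo]
            return taus, pred

        taus, predictions = stage("predict", _predict)

        def _evaluate():
            qcols = [f"q{t:g}" for t in cfg.taus]
            qerr = evaluate_quantiles(
                data.y, predictions[qcols].to_numpy(), cfg.taus
            )
            rows = [
                {"metric": "oob_accuracy_mean", "value": accuracy(data.y, predictions["mean"])},
                {"metric": "oob_accuracy_median", "value": accuracy(data.y, predictions["q0.5"])},
            ]
            for alpha, label in ((0.05, "95"), (0.2, "80")):
                lo, hi = f"q{alpha / 2:g}", f"q{1 - alpha / 2:g}"
                im = evaluate_intervals(
                    data.y, (predictions[lo].to_numpy(), predictions[hi].to_numpy())
                )
                rows.append({"metric": f"pi{label}_average_length", "value": im.average_length})
                rows.append({"metric": f"pi{label}_coverage", "value": im.coverage_probability})
            return qerr, pd.DataFrame(rows)

        quantile_errors, metrics_df = stage("evaluate", _evaluate)

        counts = {
            "n_samples": data.n,
            "n_features": data.M,
            "n_screened": screen.n_selected,
            "n_selected": len(selected),
        }
        logger.info(
            "pipeline counts: M=%d -> screened=%d -> selected=%d",
            data.M, screen.n_selected, len(selected),
        )
        return PipelineResults(
            config=cfg,
            dataset=data,
            drug_id=self.drug_id,
            screen=screen,
            importance=importance,
            selected_features=selected,
            qrf=qrf,
            predictions=predictions,
            quantile_errors=quantile_errors,
            metrics=metrics_df,
            counts=counts,
            timings=timings,
        )


def run_pipeline(config: PipelineConfig) -> PipelineResults:
    """File-based front end: read inputs, run the three-step model, write artifacts."""
    matrices = []
    for attr, kind in (
        ("expression", FeatureKind.expression),
        ("mutation", FeatureKind.mutation),
        ("cnv", FeatureKind.cnv),
    ):
        path = getattr(config, attr)
        if path:
            matrices.append(read_feature_matrix(path, kind, config.orientation))
    if not matrices:
        raise PipelineError("stage 'read' failed: no feature matrix paths configured")
    if not config.response or not config.drug_id:
        raise PipelineError("stage 'read' failed: response path and drug_id are required")
    try:
        responses = read_response_table(config.response)
        data = assemble_dataset(matrices, responses, config.drug_id)
    except Exception as exc:
        raise PipelineError(f"stage 'assemble' failed: {exc}") from exc

    results = ThreeStepQRF(data, config, drug_id=config.drug_id).fit()
    if config.outdir:
        results.save(config.outdir)
    return results
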