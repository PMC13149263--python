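"""End-to-end orchestration: harmonize -> induce -> split -> train -> report.

The run order mirrors the framework's controlled formulation:

1. the cohort is validated and harmonized on all records, and the continuous
   risk index (and its quantile classes) is computed once, before any
   partitioning, so the target stays fixed;
2. records are split 70/30 stratified by the induced class;
3. harmonization statistics are re-fitted on the training partition alone and
   applied to the evaluation partition, so no evaluation statistic leaks into
   modeling;
4. the hybrid model is trained (5-fold convex weight search) on the training
   partition and scored on the evaluation partition;
5. diagnostics are emitted: per-model metrics, trivial-baseline checks,
   R(x)-vs-index correlation, fold stability, attribution and perturbation
   sensitivity.

Every artifact is a plain CSV/JSON file plus a single joblib model archive.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import attribution as attr
from . import evaluation as ev
from . import harmonize as hz
from . import risk_induction as ri
from .hybrid import HybridConfig, HybridModel, fit_base_models, make_split
from .manifest import VariableManifest

logger = logging.getLogger("riskstrat")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (defaults are the study settings)."""

    data: str | None = None
    manifest: str | None = None
    outdir: str = "riskstrat_run"
    tau_m: float = 0.3
    K: int = 3
    split_ratio: float = 0.7
    seed: int = 0
    index_weights: dict[str, float] | None = None
    model: HybridConfig = field(default_factory=HybridConfig)
    compute_stability: bool = True
    attribution_partition: str = "test"  # test | train | all
    perturbation_targets: list[str] | None = None
    outcome_variable: str | None = None  # optional threshold-outcome side path
    outcome_tau: float | None = None

    def to_dict(self) -> dict:
        d = asdict(self)
        return d


@dataclass
class RunResult:
    """In-memory artifacts of one pipeline run."""

    cleaned: pd.DataFrame
    exclusion_report: dict
    signals_full: hz.SignalMatrix
    labels: ri.InducedRiskLabels
    split: object
    signals_train: hz.SignalMatrix
    signals_test: hz.SignalMatrix
    model: HybridModel
    metrics: dict
    stability: ev.StabilityReport | None
    attribution: attr.AttributionReport
    perturbation: list[attr.PerturbationSummary]
    outcome: ri.OutcomeLabels | None
    run_manifest: dict


def _evaluate_models(
    model: HybridModel,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    classes: np.ndarray,
) -> dict:
    out = {}
    Xa = model._align(X_test)
    for name, proba in (
        ("linear", model.linear_.predict_proba(Xa)),
        ("nonlinear", model.forest_.predict_proba(Xa)),
        ("hybrid", model.predict_proba(X_test)),
    ):
        pred = classes[np.argmax(proba, axis=1)]
        report = ev.classification_metrics(y_test, pred, proba, classes=classes)
        out[name] = report.scalars()
        out[name]["confusion_normalized"] = report.confusion_normalized.to_numpy().tolist()
    return out


def run(table: pd.DataFrame, manifest: VariableManifest, config: RunConfig) -> RunResult:
    """Execute the full pipeline on an in-memory cohort table."""
    cfg = config

    logger.info("stage=validate records_in=%d", len(table))
    cleaned, report = hz.validate_cohort(table, manifest)
    logger.info("stage=validate records_out=%d report=%s", len(cleaned), report)

    # --- induce the target once, on the full cohort, before partitioning
    signals_full = hz.fit_transform_signals(cleaned, manifest, cfg.tau_m)
    scores, weights = ri.build_risk_index(
        signals_full, manifest.directions(), cfg.index_weights
    )
    labels = ri.discretize_by_quantiles(scores, cfg.K)
    labels.index_weights = weights
    logger.info(
        "stage=induce signals=%d dropped=%s classes=%s",
        len(signals_full.signal_names),
        signals_full.dropped,
        np.bincount(labels.class_labels).tolist(),
    )

    split = make_split(
        labels.class_labels, ratio=cfg.split_ratio, seed=cfg.seed, folds=cfg.model.cv_folds
    )
    train_rows = cleaned.iloc[split.train_indices]
    test_rows = cleaned.iloc[split.test_indices]
    logger.info("stage=split train=%d test=%d", len(train_rows), len(test_rows))

    # --- strict fit/apply separation for modeling
    signals_train = hz.fit_transform_signals(train_rows, manifest, cfg.tau_m)
    signals_test = hz.apply_transform(test_rows, signals_train)
    y_train = labels.class_labels[split.train_indices]
    y_test = labels.class_labels[split.test_indices]

    model = HybridModel(config=cfg.model, seed=cfg.seed)
    model.fit(signals_train.data, y_train, fold_assignments=split.fold_assignments)
    logger.info(
        "stage=train w_linear=%.2f w_nonlinear=%.2f C=%s",
        model.w_,
        1 - model.w_,
        model.training_metadata["C"],
    )

    classes = model.classes_
    metrics: dict = {"models": _evaluate_models(model, signals_test.data, y_test, classes)}

    # trivial baseline: perfect on the partition its edges were fitted on,
    # and near-perfect on held-out records via train-partition edges
    baseline_fit_pred = ri.trivial_baseline(labels, labels.risk_index)
    metrics["trivial_baseline"] = {
        "fit_partition_accuracy": float(
            np.mean(baseline_fit_pred == labels.class_labels)
        )
    }
    train_edges = ri.discretize_by_quantiles(
        labels.risk_index[split.train_indices], cfg.K
    )
    test_pred = ri.trivial_baseline(train_edges, labels.risk_index[split.test_indices])
    metrics["trivial_baseline"]["heldout_accuracy"] = float(np.mean(test_pred == y_test))

    R_test = model.representation(signals_test.data)
    metrics["representation_correlation"] = ev.representation_correlation(
        R_test, labels.risk_index[split.test_indices]
    )

    stability = None
    if cfg.compute_stability:
        fold_values: dict[str, list[float]] = {}
        for name, fit_fn in (
            (
                "linear",
                lambda X, y: fit_base_models(
                    X, y, cfg.model, seed=cfg.seed, C=model.training_metadata["C"]
                )[0],
            ),
            (
                "nonlinear",
                lambda X, y: fit_base_models(
                    X, y, cfg.model, seed=cfg.seed, C=model.training_metadata["C"]
                )[1],
            ),
        ):
            vals = ev.fold_metric_values(
                signals_train.data, y_train, split.fold_assignments, fit_fn
            )
            for metric, v in vals.items():
                fold_values[f"{name}.{metric}"] = v
        stability = ev.cv_stability(fold_values)
        metrics["stability"] = {
            k: {"mean": stability.mean[k], "std": stability.std[k]}
            for k in stability.fold_values
        }

    part = {
        "test": signals_test,
        "train": signals_train,
    }.get(cfg.attribution_partition)
    if part is None:
        part = hz.apply_transform(cleaned, signals_train)
    report_attr = attr.attribute(model, part, signals_train.reference_values)
    targets = cfg.perturbation_targets or list(part.signal_names)
    perturbation = attr.perturb_sensitivity(model, part, targets)

    outcome = None
    if cfg.outcome_variable is not None and cfg.outcome_tau is not None:
        outcome = ri.threshold_outcome(
            cleaned[cfg.outcome_variable], cfg.outcome_tau, cfg.outcome_variable
        )
        metrics["outcome"] = {
            "variable": outcome.source_signal,
            "tau": outcome.threshold,
            "positive_rate": float(outcome.y.mean()),
            "n": int(len(outcome.y)),
        }

    import sklearn

    run_manifest = {
        "config": cfg.to_dict(),
        "index_weights": weights.to_dict(),
        "quantile_edges": labels.quantile_edges.tolist(),
        "selected_w_linear": model.w_,
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "sklearn": sklearn.__version__,
        },
    }
    return RunResult(
        cleaned=cleaned,
        exclusion_report=report,
        signals_full=signals_full,
        labels=labels,
        split=split,
        signals_train=signals_train,
        signals_test=signals_test,
        model=model,
        metrics=metrics,
        stability=stability,
        attribution=report_attr,
        perturbation=perturbation,
        outcome=outcome,
        run_manifest=run_manifest,
    )


def run_pipeline(config: RunConfig) -> RunResult:
    """Load inputs from ``config`` paths, run the pipeline, persist artifacts."""
    if config.data is None or config.manifest is None:
        raise ValueError("config.data and config.manifest paths are required")
    table = pd.read_csv(config.data)
    manifest = VariableManifest.from_yaml(config.manifest)
    result = run(table, manifest, config)

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    result.signals_full.data.to_csv(outdir / "harmonized.csv", index=False)
    with open(outdir / "transform_params.json", "w") as fh:
        json.dump(hz.sidecar_payload(result.signals_train, result.exclusion_report), fh, indent=2)

    labels_df = pd.DataFrame(
        {
            "record": np.arange(len(result.labels.risk_index)),
            "risk_index": result.labels.risk_index,
            "risk_class": result.labels.class_labels,
        }
    )
    labels_df.to_csv(outdir / "labels.csv", index=False)
    with open(outdir / "labels.json", "w") as fh:
        json.dump(
            {
                "quantile_edges": result.labels.quantile_edges.tolist(),
                "K": result.labels.K,
                "index_weights": result.labels.index_weights.to_dict(),
            },
            fh,
            indent=2,
        )

    result.model.save(outdir / "model.joblib")
    with open(outdir / "metrics.json", "w") as fh:
        json.dump(result.metrics, fh, indent=2)
    if result.stability is not None:
        result.stability.frame().to_csv(outdir / "stability.csv", index=False)

    attr_df = pd.DataFrame(
        {
            "signal": result.attribution.mean_abs_phi.index,
            "mean_abs_phi": result.attribution.mean_abs_phi.to_numpy(),
            "normalized_contribution": result.attribution.normalized_contribution.to_numpy(),
        }
    )
    attr_df["rank"] = (
        attr_df["normalized_contribution"].rank(ascending=False, method="first").astype(int)
    )
    attr_df.sort_values("rank").to_csv(outdir / "attribution.csv", index=False)
    pd.DataFrame([vars(p) for p in result.perturbation]).to_csv(
        outdir / "perturbation.csv", index=False
    )
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(result.run_manifest, fh, indent=2)
    logger.info("stage=persist outdir=%s", outdir)
    return result
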