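"""Desk-scale reproducibility experiments on synthetic cohorts.

These functions run the full pipeline under the generator's study conditions
and measure the structural quantities the framework is built around: the
trivial baseline's perfect reconstruction of the induced classes, recovery of
the planted latent risk factor by the hybrid representation, the
linear-vs-nonlinear gap under planted threshold structure, and the
fold-dispersion contrast between large and small cohorts.  They are shared
by the test suite and the reproduction script.
"""

from __future__ import annotations

import numpy as np

from . import harmonize as hz
from . import risk_induction as ri
from . import synthetic as sy
from .evaluation import classification_metrics, cv_stability, fold_metric_values
from .hybrid import HybridConfig, fit_base_models, make_split
from .pipeline import RunConfig, run


def baseline_reconstruction_accuracy(n: int = 3000, seed: int = 0) -> float:
    """Accuracy of the trivial baseline on the partition its edges fit.

    Generates an integrated-archetype cohort, builds the direction-signed
    equal-weight risk index, fits tertile edges on the full cohort and
    classifies the same records.  With a tie-free index this is exactly 1.0
    by construction.
    """
    spec = sy.CohortSpec(n=n, archetype="integrated", seed=seed, missing_rate=0.0)
    table, _ = sy.generate(spec)
    manifest = sy.make_manifest(spec)
    cleaned, _ = hz.validate_cohort(table, manifest)
    signals = hz.fit_transform_signals(cleaned, manifest)
    scores, _ = ri.build_risk_index(signals, manifest.directions())
    labels = ri.discretize_by_quantiles(scores, K=3)
    pred = ri.trivial_baseline(labels, scores)
    return float(np.mean(pred == labels.class_labels))


def latent_recovery_correlation(
    n: int = 5000, seed: int = 0, config: HybridConfig | None = None
) -> float:
    """Held-out Pearson correlation between R(x) and the planted latent.

    Linear planted structure at the generator defaults (loading 0.8, noise
    SD 0.5); the full pipeline (harmonize, induce, split, weight search,
    retrain) runs at its study settings and R(x) is evaluated on the test
    partition.
    """
    spec = sy.CohortSpec(n=n, archetype="integrated", seed=seed)
    table, truth = sy.generate(spec)
    manifest = sy.make_manifest(spec)
    cfg = RunConfig(seed=seed, compute_stability=False)
    if config is not None:
        cfg.model = config
    result = run(table, manifest, cfg)
    u = truth["u"][result.cleaned.index.to_numpy()]
    R_test = result.model.representation(result.signals_test.data)
    r = np.corrcoef(R_test, u[result.split.test_indices])[0, 1]
    return float(r)


def nonlinear_gap_trial(
    seed: int, n: int = 2000, config: HybridConfig | None = None
) -> tuple[float, float]:
    """Held-out macro-F1 of the linear and nonlinear models on one cohort
    whose classes come from the planted threshold-nonlinear score."""
    config = config or HybridConfig()
    spec = sy.CohortSpec(n=n, archetype="clinical", seed=seed, nonlinearity="threshold")
    table, truth = sy.generate(spec)
    manifest = sy.make_manifest(spec)
    cleaned, _ = hz.validate_cohort(table, manifest)
    labels = ri.discretize_by_quantiles(truth["true_score"][cleaned.index.to_numpy()], 3)
    y = labels.class_labels
    split = make_split(y, ratio=0.7, seed=seed, folds=config.cv_folds)
    sm_train = hz.fit_transform_signals(cleaned.iloc[split.train_indices], manifest)
    sm_test = hz.apply_transform(cleaned.iloc[split.test_indices], sm_train)
    linear, forest = fit_base_models(
        sm_train.data.to_numpy(), y[split.train_indices], config, seed=seed
    )
    X_test = sm_test.data.to_numpy()
    y_test = y[split.test_indices]
    f1_linear = classification_metrics(y_test, linear.predict(X_test)).f1_macro
    f1_forest = classification_metrics(y_test, forest.predict(X_test)).f1_macro
    return f1_linear, f1_forest


def nonlinear_gap_experiment(
    n_seeds: int = 20, n: int = 2000, seed0: int = 0
) -> dict:
    """Run the threshold-nonlinearity gap over many seeds."""
    gaps = []
    wins = 0
    for k in range(n_seeds):
        f1_lin, f1_rf = nonlinear_gap_trial(seed0 + k, n=n)
        gaps.append(f1_rf - f1_lin)
        wins += f1_rf > f1_lin
    return {"wins": wins, "n_seeds": n_seeds, "gaps": gaps, "mean_gap": float(np.mean(gaps))}


def fold_dispersion(
    archetype: str, n: int, seed: int, metric: str = "f1_macro"
) -> float:
    """Sample std of a linear model's 5-fold validation metric on one cohort."""
    spec = sy.CohortSpec(n=n, archetype=archetype, seed=seed)
    table, _ = sy.generate(spec)
    manifest = sy.make_manifest(spec)
    cleaned, _ = hz.validate_cohort(table, manifest)
    signals = hz.fit_transform_signals(cleaned, manifest)
    scores, _ = ri.build_risk_index(signals, manifest.directions())
    labels = ri.discretize_by_quantiles(scores, 3)
    split = make_split(labels.class_labels, ratio=0.7, seed=seed)
    sm_train = hz.fit_transform_signals(cleaned.iloc[split.train_indices], manifest)
    y_train = labels.class_labels[split.train_indices]
    cfg = HybridConfig()
    fold_vals = fold_metric_values(
        sm_train.data,
        y_train,
        split.fold_assignments,
        lambda X, y: fit_base_models(X, y, cfg, seed=seed, C=1.0)[0],
    )
    return cv_stability(fold_vals).std[metric]


def stability_direction_experiment(
    n_seeds: int = 20,
    n_large: int = 1500,
    n_small: int = 500,
    seed0: int = 0,
    metric: str = "f1_macro",
) -> dict:
    """Compare fold dispersion of the large-n integrated archetype against
    the small-n clinical archetype across seeds."""
    wins = 0
    pairs = []
    for k in range(n_seeds):
        big = fold_dispersion("integrated", n_large, seed0 + k, metric)
        small = fold_dispersion("clinical", n_small, seed0 + k, metric)
        pairs.append((big, small))
        wins += big < small
    return {"wins": wins, "n_seeds": n_seeds, "pairs": pairs}
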