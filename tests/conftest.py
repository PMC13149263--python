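import numpy as np
import pandas as pd
import pytest

import riskstrat as rs
from riskstrat.hybrid import HybridConfig

# small forest everywhere speed matters; the convexity/attribution/metric
# machinery under test is independent of ensemble size
FAST_MODEL = dict(n_estimators=60)


def fast_config(**overrides) -> HybridConfig:
    params = {**FAST_MODEL, **overrides}
    return HybridConfig(**params)


@pytest.fixture(scope="session")
def integrated_cohort():
    """Synthetic integrated-archetype cohort with manifest and ground truth."""
    spec = rs.CohortSpec(n=900, archetype="integrated", seed=7)
    table, truth = rs.generate(spec)
    manifest = rs.make_manifest(spec)
    return table, truth, manifest


@pytest.fixture(scope="session")
def harmonized(integrated_cohort):
    table, truth, manifest = integrated_cohort
    cleaned, report = rs.validate_cohort(table, manifest)
    signals = rs.fit_transform_signals(cleaned, manifest)
    return cleaned, signals, manifest


@pytest.fixture(scope="session")
def fitted_run(integrated_cohort):
    """One full pipeline run with a small forest, shared across tests."""
    table, truth, manifest = integrated_cohort
    cfg = rs.RunConfig(seed=11)
    cfg.model = fast_config()
    return rs.run(table, manifest, cfg), truth
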