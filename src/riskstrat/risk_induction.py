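"""Construction and quantile discretization of the continuous risk index.

The pipeline does not predict an external clinical outcome.  Instead it
induces its own target: a continuous risk index built as a direction-signed
linear combination of harmonized signals, discretized into K ordinal classes
at empirical quantiles.  Because the classes are a deterministic function of
the index, a trivial classifier that pipes a record's index value through the
fitted quantile edges reconstructs the labels perfectly on the partition the
edges were fitted on — it is the upper bound of the induced task, not a
predictive model.

A threshold-based binary outcome on a raw clinical column (e.g. glucose
above a diagnostic cut-off) is also provided as an optional, independent
label path; it reads raw values only and is untouched by any transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .harmonize import SignalMatrix


@dataclass
class InducedRiskLabels:
    """Continuous risk index plus its quantile discretization."""

    risk_index: np.ndarray
    class_labels: np.ndarray
    quantile_edges: np.ndarray
    K: int
    index_weights: pd.Series | None = None
    meta: dict = field(default_factory=dict)


@dataclass
class OutcomeLabels:
    """Binary outcome from thresholding a raw clinical variable."""

    y: np.ndarray
    source_signal: str
    threshold: float
    record_index: np.ndarray  # positions of the non-missing records used


def build_risk_index(
    signals: SignalMatrix | pd.DataFrame,
    directions: Mapping[str, int],
    weights: Mapping[str, float] | None = None,
) -> tuple[np.ndarray, pd.Series]:
    """Direction-signed weighted sum of signals.

    score_i = sum_j w_j * d_j * s_ij over signals with direction d_j != 0.
    Default weights are uniform 1/p over the contributing signals.  Returns
    the raw (unnormalized) scores and the weights used.
    """
    data = signals.data if isinstance(signals, SignalMatrix) else signals
    active = [c for c in data.columns if directions.get(c, 0) != 0]
    if not active:
        raise ValueError("risk index undefined: every signal has direction 0")
    if weights is None:
        w = pd.Series(1.0 / len(active), index=active)
    else:
        w = pd.Series({c: float(weights[c]) for c in active})
        if not np.all(np.isfinite(w.to_numpy())):
            raise ValueError("index weights must be finite")
    d = pd.Series({c: directions[c] for c in active})
    scores = (data[active].to_numpy(dtype=float) * (w * d).to_numpy()).sum(axis=1)
    return scores, w


def discretize_by_quantiles(scores: np.ndarray, K: int = 3) -> InducedRiskLabels:
    """Cut a score vector into K ordinal classes at k/K empirical quantiles.

    Interior edges are the k/K order-statistic quantiles (linear
    interpolation).  A record's class is the number of edges strictly below
    its score, so a score exactly on an edge falls in the lower class.
    """
    scores = np.asarray(scores, dtype=float)
    if K < 2:
        raise ValueError("K must be at least 2")
    if len(scores) < K:
        raise ValueError("need at least K records to form K quantile classes")
    edges = np.quantile(scores, [k / K for k in range(1, K)], method="linear")
    if np.min(scores) == np.max(scores):
        raise ValueError(
            "risk index is constant; quantile edges are degenerate — "
            "inspect the index construction"
        )
    if not np.all(np.diff(edges) > 0):
        raise ValueError(
            "quantile edges are not strictly increasing (heavy ties in the "
            "risk index); inspect the index construction"
        )
    labels = (scores[:, None] > edges[None, :]).sum(axis=1)
    return InducedRiskLabels(
        risk_index=scores,
        class_labels=labels.astype(int),
        quantile_edges=edges,
        K=K,
        meta={"quantile_estimator": "linear order-statistic interpolation"},
    )


def trivial_baseline(
    labels_fit: InducedRiskLabels, scores_eval: np.ndarray
) -> np.ndarray:
    """Classify scores by the quantile edges fitted on another partition.

    No learning occurs; this reconstructs the induced class boundaries
    directly and upper-bounds any model on the induced task.
    """
    scores_eval = np.asarray(scores_eval, dtype=float)
    edges = labels_fit.quantile_edges
    return (scores_eval[:, None] > edges[None, :]).sum(axis=1).astype(int)


def threshold_outcome(
    raw_column: Sequence[float] | pd.Series, tau: float, name: str = ""
) -> OutcomeLabels:
    """Binary outcome y_i = 1 iff the raw clinical value strictly exceeds tau.

    Missing values are excluded; their positions are recorded so the outcome
    can be aligned back to the cohort.
    """
    if not np.isfinite(tau):
        raise ValueError("tau must be finite")
    col = pd.Series(raw_column, dtype=float)
    observed = col.dropna()
    if observed.empty:
        raise ValueError(f"all values of {name or 'outcome column'} are missing")
    y = (observed.to_numpy() > tau).astype(int)
    positions = np.flatnonzero(col.notna().to_numpy())
    return OutcomeLabels(
        y=y,
        source_signal=name or (col.name if col.name is not None else ""),
        threshold=float(tau),
        record_index=positions,
    )
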