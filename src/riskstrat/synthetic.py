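"""Seeded synthetic survey cohorts with known ground truth.

Real inputs to the pipeline are public-health survey extracts mixing
continuous laboratory/biometric measurements, ordinal self-report scales and
binary condition indicators.  This module emulates that structure so every
stage is testable without downloads:

* a single latent risk factor ``u ~ N(0, 1)`` per respondent;
* continuous signals ``loading * u + noise`` rescaled to plausible clinical
  ranges (glucose-like, blood-pressure-like, ...);
* ordinal and binary signals obtained by monotone thresholding of the same
  latent construction, emitted with survey-style codes (1 = yes, 2 = no);
* missingness planted completely at random per variable;
* three archetypes mirroring typical dataset compositions: ``clinical``
  (continuous-dominated, no behavioral scales), ``behavioral``
  (self-report-dominated) and ``integrated`` (mixed).

Optionally a nonlinear component (threshold jumps or pairwise interactions
in the signal space) is added to the planted risk score, so that the
linear/nonlinear model gap the framework is designed to expose can be
reproduced in kind.  The generator returns the latent factor, the planted
score and the missingness mask as ground truth for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .manifest import VariableManifest, VariableSpec

ARCHETYPES = {
    # (n_continuous, n_ordinal, n_binary)
    "clinical": (6, 0, 5),
    "behavioral": (2, 4, 3),
    "integrated": (2, 3, 4),
}

# plausible-range templates for continuous signals (fixture constants)
_CONTINUOUS_TEMPLATES = (
    ("glucose", 100.0, 25.0, (40.0, 600.0)),
    ("systolic_bp", 120.0, 15.0, (70.0, 250.0)),
    ("bmi", 27.5, 5.0, (10.0, 80.0)),
    ("total_chol", 190.0, 35.0, (80.0, 400.0)),
    ("diastolic_bp", 72.0, 10.0, (40.0, 150.0)),
    ("hdl", 53.0, 14.0, (10.0, 120.0)),
)

_ORDINAL_NAMES = ("phys_activity", "general_health", "poor_health_days", "alcohol_freq")
_BINARY_NAMES = ("smoking", "hypertension", "diabetes", "heart_disease", "high_chol")

_ORDINAL_LEVELS = 4
_BINARY_THRESHOLD_Q = 0.60  # risk-present above the 60th percentile of the latent
_NONLINEAR_GAIN = 1.2  # size of the planted threshold jump / interaction term
_THRESHOLD_CUT = 0.4  # standardized-latent cut point of planted jumps


@dataclass
class CohortSpec:
    """Recipe for one synthetic cohort."""

    n: int
    archetype: str = "integrated"
    n_continuous: int | None = None
    n_ordinal: int | None = None
    n_binary: int | None = None
    missing_rate: float | dict[str, float] = 0.05
    loading: float | dict[str, float] = 0.8
    nonlinearity: str = "none"  # none | threshold | interaction
    noise_sd: float = 0.5
    seed: int = 0
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.archetype not in ARCHETYPES:
            raise ValueError(f"unknown archetype {self.archetype!r}")
        defaults = ARCHETYPES[self.archetype]
        if self.n_continuous is None:
            self.n_continuous = defaults[0]
        if self.n_ordinal is None:
            self.n_ordinal = defaults[1]
        if self.n_binary is None:
            self.n_binary = defaults[2]
        total = self.n_continuous + self.n_ordinal + self.n_binary
        if min(self.n_continuous, self.n_ordinal, self.n_binary) < 0 or total < 1:
            raise ValueError("signal counts must be non-negative with total >= 1")
        if self.nonlinearity not in ("none", "threshold", "interaction"):
            raise ValueError(f"unknown nonlinearity {self.nonlinearity!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        rates = (
            self.missing_rate.values()
            if isinstance(self.missing_rate, dict)
            else [self.missing_rate]
        )
        if any(not 0.0 <= r < 1.0 for r in rates):
            raise ValueError("missing rates must lie in [0, 1)")


def _signal_plan(spec: CohortSpec) -> list[dict]:
    """Deterministic per-signal layout shared by generate and make_manifest."""
    plan: list[dict] = []

    def _loading(name: str, idx: int) -> float:
        if isinstance(spec.loading, dict):
            base = spec.loading.get(name, 0.8)
        else:
            base = spec.loading
        # plant one protective (negatively loaded) signal per four signals so
        # direction handling is always exercised
        sign = -1.0 if idx % 4 == 3 else 1.0
        return sign * abs(base)

    idx = 0
    for j in range(spec.n_continuous):
        name, center, scale, rng = _CONTINUOUS_TEMPLATES[j % len(_CONTINUOUS_TEMPLATES)]
        if j >= len(_CONTINUOUS_TEMPLATES):
            name = f"{name}_{j // len(_CONTINUOUS_TEMPLATES) + 1}"
        plan.append(
            {
                "name": name,
                "kind": "continuous",
                "loading": _loading(name, idx),
                "center": center,
                "scale": scale,
                "range": rng,
            }
        )
        idx += 1
    for j in range(spec.n_ordinal):
        name = _ORDINAL_NAMES[j % len(_ORDINAL_NAMES)]
        if j >= len(_ORDINAL_NAMES):
            name = f"{name}_{j // len(_ORDINAL_NAMES) + 1}"
        plan.append({"name": name, "kind": "ordinal", "loading": _loading(name, idx)})
        idx += 1
    for j in range(spec.n_binary):
        name = _BINARY_NAMES[j % len(_BINARY_NAMES)]
        if j >= len(_BINARY_NAMES):
            name = f"{name}_{j // len(_BINARY_NAMES) + 1}"
        plan.append({"name": name, "kind": "binary", "loading": _loading(name, idx)})
        idx += 1
    return plan


def generate(spec: CohortSpec) -> tuple[pd.DataFrame, dict]:
    """Draw one cohort table plus its ground truth.

    Returns the raw coded table (with planted missing cells as NaN) and a
    truth record holding the latent factor ``u``, the planted risk score
    (equal to ``u`` unless a nonlinearity is requested), the per-signal
    loadings and the missingness mask.
    """
    rng = np.random.default_rng(spec.seed)
    plan = _signal_plan(spec)
    n = spec.n
    u = rng.standard_normal(n)

    latent_sd = float(np.sqrt(np.mean([p["loading"] ** 2 for p in plan]) + 0.0))
    columns: dict[str, np.ndarray] = {}
    latents: dict[str, np.ndarray] = {}
    for p in plan:
        lam = p["loading"]
        latent = lam * u + spec.noise_sd * rng.standard_normal(n)
        latents[p["name"]] = latent
        sd = float(np.sqrt(lam**2 + spec.noise_sd**2))
        if p["kind"] == "continuous":
            raw = p["center"] + p["scale"] * latent
            lo, hi = p["range"]
            columns[p["name"]] = np.clip(raw, lo, hi)
        elif p["kind"] == "ordinal":
            # survey-style codes 1..L, level rising with the latent
            cuts = sd * np.array([-0.6744898, 0.0, 0.6744898])  # latent quartiles
            columns[p["name"]] = 1.0 + (latent[:, None] > cuts[None, :]).sum(axis=1)
        else:  # binary, survey coding 1 = yes(risk level), 2 = no
            cut = sd * 0.2533471  # 60th percentile of the latent
            columns[p["name"]] = np.where(latent > cut, 1.0, 2.0)

    true_score = u.copy()
    nonlinear_terms: list[str] = []
    if spec.nonlinearity != "none":
        contributors = [p for p in plan if p["kind"] == "continuous"] or plan
        contributors = contributors[:3]

        def _std(p: dict) -> np.ndarray:
            sd = float(np.sqrt(p["loading"] ** 2 + spec.noise_sd**2))
            return latents[p["name"]] / sd

        if spec.nonlinearity == "threshold":
            if len(contributors) >= 2:
                # risk jumps when exactly one of two key signals crosses its
                # cut: a conjunction of threshold effects that no single
                # hyperplane in the signal space can reproduce
                a, b = contributors[:2]
                term = (_std(a) > _THRESHOLD_CUT) ^ (_std(b) > _THRESHOLD_CUT)
                nonlinear_terms.append(f"step({a['name']}) xor step({b['name']})")
            else:
                term = _std(contributors[0]) > _THRESHOLD_CUT
                nonlinear_terms.append(f"step({contributors[0]['name']})")
            true_score = true_score + _NONLINEAR_GAIN * term
        else:  # interaction
            for a, b in zip(contributors, contributors[1:] + contributors[:1]):
                if a is b:
                    break
                true_score = true_score + _NONLINEAR_GAIN * _std(a) * _std(b)
                nonlinear_terms.append(f"{a['name']}*{b['name']}")

    table = pd.DataFrame(columns)
    mask = pd.DataFrame(False, index=table.index, columns=table.columns)
    for p in plan:
        rate = (
            spec.missing_rate.get(p["name"], 0.0)
            if isinstance(spec.missing_rate, dict)
            else spec.missing_rate
        )
        if rate > 0:
            hit = rng.random(n) < rate
            mask[p["name"]] = hit
            table.loc[hit, p["name"]] = np.nan

    truth = {
        "u": u,
        "true_score": true_score,
        "loadings": {p["name"]: p["loading"] for p in plan},
        "missing_mask": mask,
        "nonlinear_terms": nonlinear_terms,
        "latent_sd": latent_sd,
    }
    return table, truth


def make_manifest(spec: CohortSpec) -> VariableManifest:
    """Manifest consistent with :func:`generate`'s columns for the same spec."""
    entries = []
    for p in _signal_plan(spec):
        direction = int(np.sign(p["loading"])) or 0
        if p["kind"] == "continuous":
            entries.append(
                VariableSpec(
                    name=p["name"],
                    kind="continuous",
                    direction=direction,
                    valid_range=p["range"],
                    harmonized_name=p["name"],
                    source_tag="synthetic",
                )
            )
        elif p["kind"] == "ordinal":
            codes = {float(level): level - 1 for level in range(1, _ORDINAL_LEVELS + 1)}
            entries.append(
                VariableSpec(
                    name=p["name"],
                    kind="ordinal",
                    direction=direction,
                    codes=codes,
                    harmonized_name=p["name"],
                    source_tag="synthetic",
                )
            )
        else:
            entries.append(
                VariableSpec(
                    name=p["name"],
                    kind="binary",
                    direction=direction,
                    codes={1.0: 1, 2.0: 0},
                    harmonized_name=p["name"],
                    source_tag="synthetic",
                )
            )
    return VariableManifest(entries)
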