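"""Harmonization of heterogeneous cohort tables into a risk signal space.

Raw survey tables mix continuous laboratory measurements, ordinal self-report
scales and binary condition indicators, each with its own coding scheme,
refusal codes and missingness.  This module turns such a table into a
complete numeric signal matrix:

1. :func:`validate_cohort` removes duplicate records, masks sentinel codes
   and sets physiologically implausible continuous values to missing.
2. :func:`filter_by_missingness` drops variables whose missing fraction
   strictly exceeds the tolerance ``tau_m`` (default 0.3).
3. :func:`fit_transform_signals` imputes (median for continuous, mode for
   categorical), standardizes continuous variables to z-scores using
   population moments, and encodes categorical variables; all fitted
   statistics are retained so that :func:`apply_transform` can project new
   records into the same space without re-estimating anything.

The fit/apply split matters: evaluation partitions must be transformed with
statistics estimated on the training partition only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Mapping

import numpy as np
import pandas as pd

from .manifest import DEFAULT_SENTINELS, VariableManifest, VariableSpec

DEFAULT_TAU_M = 0.3


class HarmonizationError(ValueError):
    """Raised when a cohort table violates the manifest contract."""


@dataclass
class SignalMatrix:
    """A complete, numeric, harmonized feature space.

    Attributes
    ----------
    data:
        n x p frame of transformed signals (no missing entries).
    transform_params:
        Per-signal fitted transformation record.  Continuous signals store
        ``{"kind", "source", "median", "mu", "sigma", "sd_convention"}``;
        categorical signals store ``{"kind", "source", "codes", "mode"}``.
    reference_values:
        Per-signal training reference on the transformed scale: median of
        the transformed signal for continuous variables, mode of the encoded
        signal for categorical ones.  Used by perturbation attribution.
    missing_fraction:
        Pre-imputation missing fraction of each retained signal's source
        variable, measured on the fit data.
    dropped:
        Source variables removed by the missingness filter.
    flags:
        Diagnostic flags (e.g. ``zero_variance`` signal list).
    manifest:
        The manifest the matrix was fitted under.
    """

    data: pd.DataFrame
    transform_params: dict[str, dict]
    reference_values: pd.Series
    missing_fraction: pd.Series
    dropped: list[str] = field(default_factory=list)
    flags: dict = field(default_factory=dict)
    manifest: VariableManifest | None = None

    @property
    def signal_names(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_records(self) -> int:
        return len(self.data)

    def kinds(self) -> dict[str, str]:
        return {name: p["kind"] for name, p in self.transform_params.items()}


# --------------------------------------------------------------------------
# validation


def _mask_sentinels(col: pd.Series, spec: VariableSpec) -> pd.Series:
    sentinels = set(DEFAULT_SENTINELS) | set(spec.sentinels)
    as_str = col.astype("string").str.strip()
    masked = col.mask(as_str.isin(sentinels))
    return masked


def validate_cohort(
    raw_table: pd.DataFrame, manifest: VariableManifest
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Clean a raw cohort table against its manifest.

    Removes exact duplicate rows (after string normalization), masks
    per-variable sentinel codes, and sets continuous values outside the
    manifest's plausibility range to missing.

    Returns the cleaned table (manifest columns only, numeric where
    possible) and a report counting affected rows/cells.
    """
    missing_cols = [s.name for s in manifest if s.name not in raw_table.columns]
    if missing_cols:
        raise HarmonizationError(
            f"cohort table lacks manifest column(s): {', '.join(missing_cols)}"
        )
    if len(raw_table) == 0:
        raise HarmonizationError("cohort table is empty")

    table = raw_table[manifest.names()].copy()

    # duplicate detection on normalized string form: "1" and 1 are the same
    norm = table.astype("string").apply(lambda c: c.str.strip())
    dup_mask = norm.duplicated(keep="first")
    n_dup = int(dup_mask.sum())
    table = table.loc[~dup_mask]

    report = {"duplicates": n_dup, "implausible": 0, "sentinel_missing": 0}
    for spec in manifest:
        col = _mask_sentinels(table[spec.name], spec)
        report["sentinel_missing"] += int(
            col.isna().sum() - table[spec.name].isna().sum()
        )
        col = pd.to_numeric(col, errors="coerce")
        if spec.kind == "continuous":
            lo, hi = spec.valid_range  # type: ignore[misc]
            bad = col.notna() & ((col < lo) | (col > hi))
            report["implausible"] += int(bad.sum())
            col = col.mask(bad)
        table[spec.name] = col

    if len(table) == 0:
        raise HarmonizationError("no records remain after exclusion filtering")
    return table.reset_index(drop=True), report


# --------------------------------------------------------------------------
# missingness filter


def filter_by_missingness(
    cleaned: pd.DataFrame,
    tau_m: float = DEFAULT_TAU_M,
    columns: list[str] | None = None,
) -> tuple[list[str], list[str]]:
    """Partition variables into retained/dropped by missing fraction.

    A variable is dropped iff its missing fraction strictly exceeds
    ``tau_m``; a fraction exactly equal to the threshold is retained.
    """
    if not 0.0 <= tau_m <= 1.0:
        raise ValueError("tau_m must lie in [0, 1]")
    cols = columns if columns is not None else list(cleaned.columns)
    frac = cleaned[cols].isna().mean()
    retained = [c for c in cols if frac[c] <= tau_m]
    dropped = [c for c in cols if frac[c] > tau_m]
    if not retained:
        warnings.warn("missingness filter removed every variable", stacklevel=2)
    return retained, dropped


# --------------------------------------------------------------------------
# fitting the transforms


def _mode_smallest(values: pd.Series) -> Any:
    """Mode of the observed values; ties resolved to the smallest value."""
    counts = values.value_counts()
    top = counts.max()
    return min(v for v, c in counts.items() if c == top)


def _fit_continuous(col: pd.Series) -> tuple[np.ndarray, dict, bool]:
    med = float(col.median())
    filled = col.fillna(med).to_numpy(dtype=float)
    mu = float(filled.mean())
    sigma = float(filled.std(ddof=0))
    params = {
        "kind": "continuous",
        "median": med,
        "mu": mu,
        "sigma": sigma,
        "sd_convention": "population",
    }
    if sigma > 0:
        return (filled - mu) / sigma, params, False
    return np.zeros_like(filled), params, True


def _encode_categorical(col: pd.Series, spec: VariableSpec) -> pd.Series:
    """Map raw codes to encoded values; unknown codes become missing."""
    mapping = {float(k): v for k, v in spec.codes.items()}  # type: ignore[union-attr]
    return col.map(lambda v: mapping.get(float(v)) if pd.notna(v) else np.nan)


def fit_transform_signals(
    cleaned: pd.DataFrame,
    manifest: VariableManifest,
    tau_m: float = DEFAULT_TAU_M,
) -> SignalMatrix:
    """Fit the harmonization transforms and return the signal matrix.

    Continuous variables are imputed with the fit-data median and then
    standardized with moments computed on the completed column; ordinal and
    binary variables are code-mapped and mode-imputed; nominal variables are
    expanded to 0/1 indicators against their most frequent level.
    """
    frac_all = cleaned[manifest.names()].isna().mean()
    retained, dropped = filter_by_missingness(cleaned, tau_m, manifest.names())
    if not retained:
        raise HarmonizationError("no variables survive the missingness filter")

    signals: dict[str, np.ndarray] = {}
    params: dict[str, dict] = {}
    references: dict[str, float] = {}
    missing_fraction: dict[str, float] = {}
    zero_var: list[str] = []

    for spec in manifest:
        if spec.name not in retained:
            continue
        col = cleaned[spec.name]
        if spec.kind == "continuous":
            z, p, degenerate = _fit_continuous(col)
            p["source"] = spec.name
            name = spec.target_name
            signals[name] = z
            params[name] = p
            references[name] = float(np.median(z))
            missing_fraction[name] = float(frac_all[spec.name])
            if degenerate:
                zero_var.append(name)
        elif spec.kind in ("ordinal", "binary"):
            enc = _encode_categorical(col, spec).astype(float)
            mode = _mode_smallest(enc.dropna()) if enc.notna().any() else 0
            filled = enc.fillna(mode).to_numpy(dtype=float)
            name = spec.target_name
            signals[name] = filled
            params[name] = {
                "kind": spec.kind,
                "source": spec.name,
                "codes": dict(spec.codes),  # type: ignore[arg-type]
                "mode": float(mode),
            }
            references[name] = float(mode)
            missing_fraction[name] = float(frac_all[spec.name])
        else:  # nominal: indicator per non-reference level
            enc = _encode_categorical(col, spec)
            mode = _mode_smallest(enc.dropna()) if enc.notna().any() else None
            filled = enc.fillna(mode)
            levels = sorted(set(spec.codes.values()), key=str)  # type: ignore[union-attr]
            for level in levels:
                if level == mode:
                    continue
                name = f"{spec.target_name}__{level}"
                ind = (filled == level).astype(float).to_numpy()
                signals[name] = ind
                params[name] = {
                    "kind": "nominal_indicator",
                    "source": spec.name,
                    "codes": dict(spec.codes),  # type: ignore[arg-type]
                    "level": level,
                    "reference_level": mode,
                    "mode": float(_mode_smallest(pd.Series(ind))),
                }
                references[name] = params[name]["mode"]
                missing_fraction[name] = float(frac_all[spec.name])

    data = pd.DataFrame(signals, index=cleaned.index)
    flags = {"zero_variance": zero_var, "tau_m": tau_m}
    if zero_var:
        warnings.warn(
            f"zero-variance continuous signal(s) emitted as constant 0: {zero_var}",
            stacklevel=2,
        )
    return SignalMatrix(
        data=data,
        transform_params=params,
        reference_values=pd.Series(references).reindex(data.columns),
        missing_fraction=pd.Series(missing_fraction).reindex(data.columns),
        dropped=dropped,
        flags=flags,
        manifest=manifest,
    )


def apply_transform(records: pd.DataFrame, fitted: SignalMatrix) -> SignalMatrix:
    """Project new records into a previously fitted signal space.

    Every statistic (medians, moments, modes, encodings) comes from the fit
    data; nothing is re-estimated.  Unknown categorical codes and missing
    cells are imputed with the stored fit-data statistics.
    """
    if fitted.manifest is None:
        raise HarmonizationError("fitted SignalMatrix lacks its manifest")
    signals: dict[str, np.ndarray] = {}
    for name, p in fitted.transform_params.items():
        source = p["source"]
        if source not in records.columns:
            raise HarmonizationError(f"records lack source column {source!r} for signal {name!r}")
        spec = fitted.manifest.get(source)
        col = _mask_sentinels(records[source], spec)
        col = pd.to_numeric(col, errors="coerce")
        if p["kind"] == "continuous":
            lo, hi = spec.valid_range  # type: ignore[misc]
            col = col.mask(col.notna() & ((col < lo) | (col > hi)))
            filled = col.fillna(p["median"]).to_numpy(dtype=float)
            if p["sigma"] > 0:
                signals[name] = (filled - p["mu"]) / p["sigma"]
            else:
                signals[name] = np.zeros(len(filled))
        elif p["kind"] in ("ordinal", "binary"):
            enc = _encode_categorical(col, spec).astype(float)
            signals[name] = enc.fillna(p["mode"]).to_numpy(dtype=float)
        else:
            enc = _encode_categorical(col, spec)
            filled = enc.fillna(p["reference_level"])
            signals[name] = (filled == p["level"]).astype(float).to_numpy()

    data = pd.DataFrame(signals, index=records.index)[fitted.signal_names]
    return SignalMatrix(
        data=data,
        transform_params=fitted.transform_params,
        reference_values=fitted.reference_values,
        missing_fraction=fitted.missing_fraction,
        dropped=list(fitted.dropped),
        flags=dict(fitted.flags),
        manifest=fitted.manifest,
    )


# --------------------------------------------------------------------------
# I/O helpers


def sidecar_payload(matrix: SignalMatrix, report: Mapping[str, int] | None = None) -> dict:
    """JSON-serializable record of the fitted transforms."""
    return {
        "transform_params": matrix.transform_params,
        "reference_values": matrix.reference_values.to_dict(),
        "missing_fraction": matrix.missing_fraction.to_dict(),
        "dropped": matrix.dropped,
        "flags": matrix.flags,
        "exclusion_report": dict(report) if report else None,
    }
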