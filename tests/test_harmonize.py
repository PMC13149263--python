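"""Harmonization: validation, missingness filtering, transforms, fit/apply."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import riskstrat.harmonize as hz
from riskstrat.harmonize import HarmonizationError
from riskstrat.manifest import VariableManifest, VariableSpec


def continuous_manifest(name="glucose", lo=40.0, hi=600.0, **kw):
    return VariableManifest(
        [VariableSpec(name=name, kind="continuous", valid_range=(lo, hi), **kw)]
    )


# ---------------------------------------------------------------- validation


def test_duplicate_rows_collapse_to_one():
    man = continuous_manifest()
    table = pd.DataFrame({"glucose": [100.0, 100.0]})
    cleaned, report = hz.validate_cohort(table, man)
    assert len(cleaned) == 1
    assert report["duplicates"] == 1


def test_implausible_continuous_value_becomes_missing():
    man = continuous_manifest()
    table = pd.DataFrame({"glucose": [100.0, 9999.0]})
    cleaned, report = hz.validate_cohort(table, man)
    assert report["implausible"] == 1
    assert cleaned["glucose"].isna().sum() == 1


def test_exclusion_report_matches_hand_count_on_planted_fixture():
    # 10 rows, 3 planted violations: one duplicate pair, two implausible cells
    man = VariableManifest(
        [
            VariableSpec(name="glucose", kind="continuous", valid_range=(40, 600)),
            VariableSpec(name="sbp", kind="continuous", valid_range=(70, 250)),
        ]
    )
    glucose = [90, 90, 110, 120, 9999, 130, 140, 150, 160, 170]
    sbp = [120, 120, 118, 125, 119, 260, 130, 121, 122, 123]
    table = pd.DataFrame({"glucose": glucose, "sbp": sbp})
    cleaned, report = hz.validate_cohort(table, man)
    assert report["duplicates"] == 1
    assert report["implausible"] == 2
    assert report["duplicates"] + report["implausible"] == 3
    assert len(cleaned) == 9


def test_missing_manifest_column_is_named_in_error():
    man = continuous_manifest(name="glucose")
    with pytest.raises(HarmonizationError, match="glucose"):
        hz.validate_cohort(pd.DataFrame({"other": [1.0]}), man)


def test_sentinel_codes_become_missing():
    man = VariableManifest(
        [
            VariableSpec(
                name="glucose",
                kind="continuous",
                valid_range=(40, 600),
                sentinels=("7777", "9999"),
            )
        ]
    )
    cleaned, report = hz.validate_cohort(
        pd.DataFrame({"glucose": ["100", "7777", "NA"]}), man
    )
    assert cleaned["glucose"].isna().sum() == 2
    assert report["sentinel_missing"] == 2


# ---------------------------------------------------------- missingness rule


def test_missingness_filter_uses_strict_inequality():
    n = 100
    cols = {}
    for frac in (0.0, 0.10, 0.29, 0.30, 0.31, 1.0):
        k = int(round(frac * n))
        cols[f"m{int(frac * 100):03d}"] = [np.nan] * k + [1.0] * (n - k)
    frame = pd.DataFrame(cols)
    retained, dropped = hz.filter_by_missingness(frame, tau_m=0.3)
    assert dropped == ["m031", "m100"]
    assert "m030" in retained  # boundary retained: drop iff fraction > tau_m


def test_complete_variable_always_retained():
    frame = pd.DataFrame({"x": [1.0, 2.0, 3.0]})
    retained, dropped = hz.filter_by_missingness(frame, tau_m=0.0)
    assert retained == ["x"] and dropped == []


def test_filter_monotone_in_tau():
    rng = np.random.default_rng(5)
    frame = pd.DataFrame(
        {f"v{i}": np.where(rng.random(200) < i / 10, np.nan, 1.0) for i in range(10)}
    )
    previous: set = set()
    for tau in (0.0, 0.2, 0.5, 0.8, 1.0):
        retained, _ = hz.filter_by_missingness(frame, tau)
        assert previous <= set(retained)
        previous = set(retained)


# ----------------------------------------------------------------- transforms


def test_standardization_matches_hand_computed_zscores():
    man = continuous_manifest(lo=0, hi=10)
    cleaned = pd.DataFrame({"glucose": [1.0, 2.0, 3.0]})
    sm = hz.fit_transform_signals(cleaned, man)
    # mu = 2, population sd = sqrt(2/3)
    expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0 / 3.0)
    np.testing.assert_allclose(sm.data["glucose"].to_numpy(), expected, atol=1e-12)
    assert sm.transform_params["glucose"]["sd_convention"] == "population"


def test_zero_variance_signal_is_constant_zero_and_flagged():
    man = continuous_manifest(lo=0, hi=10)
    cleaned = pd.DataFrame({"glucose": [5.0, 5.0, 5.0]})
    with pytest.warns(UserWarning, match="zero-variance"):
        sm = hz.fit_transform_signals(cleaned, man)
    assert (sm.data["glucose"] == 0).all()
    assert "glucose" in sm.flags["zero_variance"]


def test_binary_codes_map_to_indicator_without_third_level():
    man = VariableManifest(
        [
            VariableSpec(
                name="smoking", kind="binary", codes={1: 1, 2: 0}, direction=1
            )
        ]
    )
    cleaned = pd.DataFrame({"smoking": [1.0, 2.0, 1.0, 2.0]})
    sm = hz.fit_transform_signals(cleaned, man)
    assert set(sm.data["smoking"]) == {0.0, 1.0}


def test_ordinal_codes_keep_order_and_mode_ties_take_smallest():
    man = VariableManifest(
        [
            VariableSpec(
                name="activity",
                kind="ordinal",
                codes={1: 0, 2: 1, 3: 2},
            )
        ]
    )
    cleaned = pd.DataFrame({"activity": [1.0, 3.0, np.nan, np.nan]})
    sm = hz.fit_transform_signals(cleaned, man, tau_m=0.5)
    # observed {0, 2} tie -> mode 0 imputed
    assert sm.transform_params["activity"]["mode"] == 0.0
    np.testing.assert_array_equal(sm.data["activity"], [0.0, 2.0, 0.0, 0.0])


def test_imputation_preserves_median_for_odd_observed_count():
    man = continuous_manifest(lo=0, hi=100)
    col = pd.Series([10.0, 20.0, 30.0, np.nan, np.nan])
    cleaned = pd.DataFrame({"glucose": col})
    sm = hz.fit_transform_signals(cleaned, man, tau_m=0.5)
    med_before = col.median()
    filled = (
        sm.data["glucose"] * sm.transform_params["glucose"]["sigma"]
        + sm.transform_params["glucose"]["mu"]
    )
    assert filled.median() == pytest.approx(med_before)


# ----------------------------------------------------------------- fit/apply


def test_apply_on_fit_data_is_identical(harmonized):
    cleaned, signals, manifest = harmonized
    reapplied = hz.apply_transform(cleaned, signals)
    np.testing.assert_allclose(
        reapplied.data.to_numpy(), signals.data.to_numpy(), atol=1e-12
    )


def test_record_at_fit_medians_maps_to_stored_closed_form():
    man = continuous_manifest(lo=0, hi=100)
    cleaned = pd.DataFrame({"glucose": [10.0, 20.0, 30.0, 40.0, 80.0]})
    sm = hz.fit_transform_signals(cleaned, man)
    p = sm.transform_params["glucose"]
    new = pd.DataFrame({"glucose": [p["median"]]})
    out = hz.apply_transform(new, sm)
    assert out.data["glucose"].iloc[0] == pytest.approx(
        (p["median"] - p["mu"]) / p["sigma"], abs=1e-12
    )


def test_apply_imputes_with_fit_median_not_new_data():
    man = continuous_manifest(lo=0, hi=100)
    sm = hz.fit_transform_signals(pd.DataFrame({"glucose": [10.0, 20.0, 30.0]}), man)
    new = pd.DataFrame({"glucose": [80.0, np.nan]})
    out = hz.apply_transform(new, sm)
    p = sm.transform_params["glucose"]
    assert out.data["glucose"].iloc[1] == pytest.approx((20.0 - p["mu"]) / p["sigma"])


def test_apply_missing_source_column_names_signal():
    man = continuous_manifest()
    sm = hz.fit_transform_signals(pd.DataFrame({"glucose": [90.0, 110.0]}), man)
    with pytest.raises(HarmonizationError, match="glucose"):
        hz.apply_transform(pd.DataFrame({"other": [1.0]}), sm)


def test_unknown_categorical_code_at_apply_time_is_imputed():
    man = VariableManifest(
        [VariableSpec(name="smoking", kind="binary", codes={1: 1, 2: 0})]
    )
    sm = hz.fit_transform_signals(pd.DataFrame({"smoking": [1.0, 2.0, 2.0]}), man)
    out = hz.apply_transform(pd.DataFrame({"smoking": [9.0]}), sm)
    assert out.data["smoking"].iloc[0] == sm.transform_params["smoking"]["mode"]


# ------------------------------------------------------------------ property


@settings(derandomize=True, max_examples=40)
@given(
    values=st.lists(
        st.integers(min_value=-50, max_value=50), min_size=3, max_size=30, unique=True
    ),
    shift=st.floats(min_value=-100, max_value=100, allow_nan=False),
    scale=st.floats(min_value=0.1, max_value=10),
)
def test_zscores_invariant_to_affine_rescaling(values, shift, scale):
    values = [float(v) for v in values]
    man = VariableManifest(
        [
            VariableSpec(
                name="x", kind="continuous", valid_range=(-2000.0, 2000.0)
            )
        ]
    )
    base = hz.fit_transform_signals(pd.DataFrame({"x": values}), man)
    moved = hz.fit_transform_signals(
        pd.DataFrame({"x": [v * scale + shift for v in values]}), man
    )
    np.testing.assert_allclose(
        base.data["x"].to_numpy(), moved.data["x"].to_numpy(), atol=1e-7
    )
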