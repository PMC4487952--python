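"""Index-system operations: normalization, weighting, scoring, grading,
projection — worked examples and invariants."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import lcckit as L
from lcckit.errors import (
    ConfigurationError,
    DegenerateColumnWarning,
    ValidationError,
)
from lcckit.ism import (
    LAYERS,
    score_normalized,
    validate_meta,
)


def _meta(polarities: dict[str, str]) -> pd.DataFrame:
    return validate_meta(
        pd.DataFrame(
            {
                "indicator_id": list(polarities),
                "layer": ["B1"] * len(polarities),
                "polarity": list(polarities.values()),
            }
        )
    )


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------


@pytest.mark.parametrize(
    "polarity, expected",
    [("positive", [0.0, 0.5, 1.0]), ("negative", [1.0, 0.5, 0.0])],
)
def test_minmax_normalization_with_polarity(polarity, expected):
    matrix = pd.DataFrame({"x": [2.0, 4.0, 6.0]}, index=[2000, 2001, 2002])
    out = L.normalize(matrix, _meta({"x": polarity}))
    assert list(out["x"]) == pytest.approx(expected)


def test_constant_column_normalizes_to_half_with_warning():
    matrix = pd.DataFrame({"x": [3.0, 3.0, 3.0]}, index=[2000, 2001, 2002])
    with pytest.warns(DegenerateColumnWarning):
        out = L.normalize(matrix, _meta({"x": "negative"}))
    assert (out["x"] == 0.5).all()


def test_normalize_requires_metadata_for_every_column():
    matrix = pd.DataFrame(
        {"x": [1.0, 2.0], "y": [3.0, 4.0]}, index=[2000, 2001]
    )
    with pytest.raises(ConfigurationError):
        L.normalize(matrix, _meta({"x": "positive"}))


# ---------------------------------------------------------------------------
# Weights
# ---------------------------------------------------------------------------


def test_equal_dispersion_gives_equal_weights():
    norm = pd.DataFrame(
        {"a": [0.0, 1.0], "b": [1.0, 0.0]}, index=[2000, 2001]
    )
    assert list(L.mse_weights(norm)) == pytest.approx([0.5, 0.5])


def test_zero_dispersion_column_gets_zero_weight():
    norm = pd.DataFrame(
        {"a": [0.0, 0.5, 1.0], "b": [0.5, 0.5, 0.5]}, index=[2000, 2001, 2002]
    )
    assert list(L.mse_weights(norm)) == pytest.approx([1.0, 0.0])


def test_weights_from_hand_computed_standard_deviations():
    # population sd of [0,1] is 0.5; of [0,0.5] is 0.25 -> weights 2/3, 1/3
    norm = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 0.5]}, index=[2000, 2001])
    assert list(L.mse_weights(norm)) == pytest.approx([2 / 3, 1 / 3])


def test_dispersion_convention_changes_weights():
    norm = pd.DataFrame({"a": [0.0, 1.0], "b": [0.0, 0.5]}, index=[2000, 2001])
    rmsd = L.mse_weights(norm, dispersion="rmsd")
    msd = L.mse_weights(norm, dispersion="msd")
    assert msd.sum() == pytest.approx(1.0)
    # without the root, the more dispersed column is weighted more heavily
    assert msd["a"] > rmsd["a"]
    with pytest.raises(ConfigurationError):
        L.mse_weights(norm, dispersion="bogus")


def test_all_constant_matrix_cannot_be_weighted():
    norm = pd.DataFrame({"a": [0.5, 0.5], "b": [0.2, 0.2]}, index=[2000, 2001])
    with pytest.raises(ValidationError):
        L.mse_weights(norm)


# ---------------------------------------------------------------------------
# Scores and grades
# ---------------------------------------------------------------------------


def test_layer_score_reproduces_published_2000_values(reference):
    """Weighted sums of the published 2000 normalized values give the
    published ecological (0.10) and economic (0.07) layer scores."""
    row = reference.weights_nv["nv_2000"]
    weights = reference.weights_nv["weight"]
    meta = reference.indicator_meta
    assert round(L.layer_score(row, weights, meta, "B2"), 2) == 0.10
    assert round(L.layer_score(row, weights, meta, "B3"), 2) == 0.07


def test_layer_score_of_perfect_layer_is_its_weight_sum(reference):
    weights = reference.weights_nv["weight"]
    meta = reference.indicator_meta
    ones = pd.Series(1.0, index=weights.index)
    for layer in LAYERS:
        members = meta.index[meta["layer"] == layer]
        assert L.layer_score(ones, weights, meta, layer) == pytest.approx(
            weights[members].sum()
        )


def test_integrated_lcc_extremes(reference):
    weights = reference.weights_nv["weight"]
    years = [2000, 2001]
    ones = pd.DataFrame(1.0, index=years, columns=weights.index)
    zeros = pd.DataFrame(0.0, index=years, columns=weights.index)
    assert L.integrated_lcc(ones, weights).tolist() == pytest.approx(
        [weights.sum()] * 2
    )
    assert L.integrated_lcc(zeros, weights).tolist() == pytest.approx([0, 0])


def test_integrated_lcc_matches_double_loop_oracle():
    rng = np.random.default_rng(42)
    for _ in range(20):
        norm = pd.DataFrame(
            rng.uniform(size=(5, 20)),
            index=range(2000, 2005),
            columns=[f"C{j+1}" for j in range(20)],
        )
        weights = pd.Series(
            rng.uniform(0.1, 1.0, size=20), index=norm.columns
        )
        weights /= weights.sum()
        got = L.integrated_lcc(norm, weights)
        for year in norm.index:
            expected = 0.0
            for col in norm.columns:
                expected += norm.loc[year, col] * weights[col]
            assert got.loc[year] == pytest.approx(expected, abs=1e-12)


@pytest.mark.parametrize(
    "score, label",
    [
        (0.0, "Weakest"),
        (0.58, "Medium"),
        (0.758, "Strong"),
        (1.0, "Strongest"),
        # boundary scores take the higher class
        (0.2, "Weak"),
        (0.6, "Strong"),
        (0.8, "Strongest"),
    ],
)
def test_grading(reference, score, label):
    assert L.grade(score, reference.grade_scale) == label


def test_grade_rejects_out_of_range(reference):
    for score in (-0.1, 1.1):
        with pytest.raises(ValidationError):
            L.grade(score, reference.grade_scale)


def test_grade_bins_partition_unit_interval(reference):
    bins = reference.grade_scale.bins
    assert len(bins) == 5
    assert bins[0].lower == 0 and bins[-1].upper == 1
    assert all(a.upper == b.lower for a, b in zip(bins, bins[1:]))


# ---------------------------------------------------------------------------
# Projection
# ---------------------------------------------------------------------------


def test_projection_extends_exact_line():
    matrix = pd.DataFrame(
        {"x": [1.0, 2.0, 3.0], "const": [5.0, 5.0, 5.0]},
        index=[2000, 2001, 2002],
    )
    out = L.project_indicators(matrix, [2003, 2010])
    assert out.loc[2003, "x"] == pytest.approx(4.0)
    assert out.loc[2010, "x"] == pytest.approx(11.0)
    assert out.loc[2010, "const"] == pytest.approx(5.0)
    # history unchanged
    pd.testing.assert_frame_equal(out.loc[[2000, 2001, 2002]], matrix)


def test_projection_recovers_noisy_slope_within_three_se():
    rng = np.random.default_rng(11)
    years = np.arange(2000, 2013, dtype=float)
    slope, intercept, sigma = 2.5, 10.0, 1.0
    values = intercept + slope * (years - 2000) + rng.normal(0, sigma, 13)
    matrix = pd.DataFrame({"x": values}, index=years.astype(int))
    out = L.project_indicators(matrix, [2030])
    # closed-form OLS slope standard error
    sx = np.sum((years - years.mean()) ** 2)
    se_slope = sigma / np.sqrt(sx)
    fitted_slope = (out.loc[2030, "x"] - out.loc[2012, "x"]) / 18  # noqa: not exact; use fit
    est = np.polyfit(years, values, 1)[0]
    assert abs(est - slope) < 3 * se_slope
    # projection is the fitted line evaluated at the target
    pred = np.polyval(np.polyfit(years, values, 1), 2030)
    assert out.loc[2030, "x"] == pytest.approx(pred)


def test_projection_input_validation():
    matrix = pd.DataFrame({"x": [1.0]}, index=[2000])
    with pytest.raises(ValidationError):
        L.project_indicators(matrix, [2003])
    two = pd.DataFrame({"x": [1.0, 2.0]}, index=[2000, 2001])
    with pytest.raises(ValidationError):
        L.project_indicators(two, [2001])


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def test_run_ism_monotone_for_uniform_improvement(reference):
    years = range(2000, 2010)
    meta = validate_meta(
        pd.DataFrame(
            {
                "indicator_id": ["up", "down"],
                "layer": ["B1", "B2"],
                "polarity": ["positive", "negative"],
            }
        )
    )
    matrix = pd.DataFrame(
        {
            "up": np.linspace(10, 20, 10),
            "down": np.linspace(8, 2, 10),
        },
        index=years,
    )
    series = L.run_ism(matrix, meta, scale=reference.grade_scale)
    assert (np.diff(series.scores["F"]) > 0).all()


def test_run_ism_layer_sum_identity_and_bounds(lcc_series):
    scores = lcc_series.scores
    assert np.allclose(
        scores["F"], scores[["B1", "B2", "B3"]].sum(axis=1), atol=1e-12
    )
    assert ((scores["F"] >= 0) & (scores["F"] <= 1)).all()
    assert lcc_series.weights.sum() == pytest.approx(1.0, abs=1e-9)


def test_run_ism_deterministic(ism_inputs, reference, lcc_series):
    matrix, meta = ism_inputs
    again = L.run_ism(
        matrix, meta, target_years=(2015, 2020, 2030),
        scale=reference.grade_scale,
    )
    pd.testing.assert_frame_equal(lcc_series.scores, again.scores)
    pd.testing.assert_series_equal(lcc_series.weights, again.weights)


def test_published_fixture_path_skips_normalization(reference):
    """Scoring the published normalized values + weights directly (the
    pipeline tail) reproduces the published-layer checks."""
    nv = reference.weights_nv[
        ["nv_2000", "nv_2005", "nv_2012", "nv_2015", "nv_2020", "nv_2030"]
    ].T
    nv.index = [2000, 2005, 2012, 2015, 2020, 2030]
    scores = score_normalized(
        nv, reference.weights_nv["weight"], reference.indicator_meta,
        reference.grade_scale,
    )
    assert round(scores.loc[2000, "B2"], 2) == 0.10
    assert round(scores.loc[2000, "B3"], 2) == 0.07
    assert np.allclose(
        scores["F"], scores[["B1", "B2", "B3"]].sum(axis=1), atol=1e-12
    )


# ---------------------------------------------------------------------------
# Property tests
# ---------------------------------------------------------------------------


@st.composite
def _matrices(draw):
    n_years = draw(st.integers(3, 8))
    n_cols = draw(st.integers(1, 6))
    values = draw(
        arrays(
            float,
            (n_years, n_cols),
            elements=st.floats(-100, 100, allow_nan=False, width=32),
        )
    )
    polarity = draw(
        st.lists(
            st.sampled_from(["positive", "negative"]),
            min_size=n_cols,
            max_size=n_cols,
        )
    )
    cols = [f"C{j}" for j in range(n_cols)]
    matrix = pd.DataFrame(values, index=range(2000, 2000 + n_years), columns=cols)
    meta = validate_meta(
        pd.DataFrame(
            {"indicator_id": cols, "layer": ["B1"] * n_cols, "polarity": polarity}
        )
    )
    return matrix, meta


@settings(deadline=None, max_examples=60, derandomize=True)
@given(data=_matrices())
def test_normalized_columns_span_unit_interval(data):
    matrix, meta = data
    import warnings as w

    with w.catch_warnings():
        w.simplefilter("ignore", DegenerateColumnWarning)
        out = L.normalize(matrix, meta)
    assert ((out >= 0) & (out <= 1)).all().all()
    for col in out.columns:
        if matrix[col].nunique() > 1:
            assert out[col].min() == pytest.approx(0.0, abs=1e-12)
            assert out[col].max() == pytest.approx(1.0, abs=1e-12)


@settings(deadline=None, max_examples=60, derandomize=True)
@given(data=_matrices(), shift=st.floats(-50, 50, allow_nan=False))
def test_weights_invariant_to_translating_a_column(data, shift):
    matrix, meta = data
    import warnings as w

    with w.catch_warnings():
        w.simplefilter("ignore", DegenerateColumnWarning)
        base_norm = L.normalize(matrix, meta)
        shifted = matrix.copy()
        shifted[shifted.columns[0]] = shifted[shifted.columns[0]] + shift
        shifted_norm = L.normalize(shifted, meta)
    pd.testing.assert_frame_equal(base_norm, shifted_norm, atol=1e-9, rtol=0)
    if base_norm.std(ddof=0).sum() > 1e-9:
        w1 = L.mse_weights(base_norm)
        w2 = L.mse_weights(shifted_norm)
        assert np.allclose(w1, w2, atol=1e-9)


@pytest.mark.parametrize("trial_seed", range(10))
def test_raising_an_interior_positive_value_never_lowers_f(
    reference, trial_seed
):
    rng = np.random.default_rng(trial_seed)
    cols = [f"C{j+1}" for j in range(20)]
    meta = reference.indicator_meta
    matrix = pd.DataFrame(
        rng.uniform(10, 20, size=(8, 20)), index=range(2000, 2008), columns=cols
    )
    positive_cols = [c for c in cols if meta.loc[c, "polarity"] == "positive"]
    target = positive_cols[int(rng.integers(len(positive_cols)))]
    # bump a strictly interior value, keeping the column extremes
    col = matrix[target]
    interior_year = col.drop([col.idxmin(), col.idxmax()]).index[0]
    bumped = matrix.copy()
    bumped.loc[interior_year, target] = col.loc[interior_year] + 0.5 * (
        col.max() - col.loc[interior_year]
    )
    base = L.run_ism(matrix, meta, scale=reference.grade_scale)
    more = L.run_ism(bumped, meta, scale=reference.grade_scale)
    assert (
        more.scores.loc[interior_year, "F"]
        >= base.scores.loc[interior_year, "F"] - 1e-12
    )
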