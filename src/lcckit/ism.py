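"""Composite index scoring of land carrying capacity.

Implements the index-system route: a year x indicator judgement matrix
``X`` is normalized column-wise to [0, 1] by min-max scaling with
polarity (for positive indicators larger raw values are better; for
negative indicators smaller is better), each indicator receives a
weight proportional to the dispersion of its normalized column, and the
weighted sum gives a per-year integrated score

    F_i = sum_j Y_ij * W_j,          W_j = sigma_j / sum_k sigma_k

where ``sigma_j`` is the standard deviation (root mean squared
deviation, ddof=0) of the normalized column.  The 20 default indicators
are grouped into three criterion layers — B1 social-developmental,
B2 ecological-environmental, B3 economic-productive — and the layer
score is the weight-inclusive partial sum over the layer's indicators,
so the three layer scores add up to F exactly.  F is graded on a
five-class scale from Weakest to Strongest.

Raw indicators can be projected to future years by ordinary
least-squares straight lines in time; projections are normalized
jointly with history so that future best/worst years can pin the 0/1
ends of a column.
"""
from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import (
    ConfigurationError,
    DegenerateColumnWarning,
    ValidationError,
)

LAYERS = ("B1", "B2", "B3")
LAYER_NAMES = {
    "B1": "social-developmental",
    "B2": "ecological-environmental",
    "B3": "economic-productive",
}
POLARITIES = ("positive", "negative")

#: Normalized value assigned to a constant (information-free) column.
#: Such a column gets zero dispersion weight, so the 0.5 is inert.
DEGENERATE_VALUE = 0.5


def validate_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Check an indicator-metadata table (index indicator_id)."""
    if "indicator_id" in meta.columns:
        meta = meta.set_index("indicator_id")
    if not {"layer", "polarity"}.issubset(meta.columns):
        raise ValidationError("indicator meta needs columns layer,polarity")
    bad_layer = set(meta["layer"]) - set(LAYERS)
    if bad_layer:
        raise ConfigurationError(f"unknown layers {sorted(bad_layer)}")
    bad_pol = set(meta["polarity"]) - set(POLARITIES)
    if bad_pol:
        raise ConfigurationError(f"unknown polarities {sorted(bad_pol)}")
    return meta


def validate_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    """Check a judgement matrix (index years, columns indicators)."""
    if matrix.isna().any().any():
        raise ValidationError("judgement matrix has missing cells")
    return matrix.sort_index()


# ---------------------------------------------------------------------------
# Normalization and weighting
# ---------------------------------------------------------------------------


def normalize(matrix: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    """Min-max normalize each column to [0, 1] with polarity.

    Positive columns: (x - min) / (max - min); negative columns:
    (max - x) / (max - min).  A constant column is mapped to 0.5
    everywhere with a :class:`DegenerateColumnWarning` — it carries no
    ranking information and will receive zero weight downstream.
    """
    matrix = validate_matrix(matrix)
    meta = validate_meta(meta)
    if len(matrix) < 2:
        raise ValidationError("need at least two years to normalize")
    missing = set(matrix.columns) - set(meta.index)
    if missing:
        raise ConfigurationError(
            f"no metadata for indicators {sorted(missing)}"
        )
    out = {}
    for col in matrix.columns:
        x = matrix[col].astype(float)
        lo, hi = x.min(), x.max()
        if hi == lo:
            warnings.warn(
                f"indicator {col!r} is constant; normalized to "
                f"{DEGENERATE_VALUE} with zero dispersion weight",
                DegenerateColumnWarning,
                stacklevel=2,
            )
            out[col] = pd.Series(DEGENERATE_VALUE, index=x.index)
        elif meta.loc[col, "polarity"] == "positive":
            out[col] = (x - lo) / (hi - lo)
        else:
            out[col] = (hi - x) / (hi - lo)
    return pd.DataFrame(out, index=matrix.index)


def mse_weights(
    normalized: pd.DataFrame, dispersion: str = "rmsd"
) -> pd.Series:
    """Dispersion-based indicator weights W_j = sigma_j / sum sigma.

    ``dispersion`` selects the measure: ``"rmsd"`` (default) uses the
    population standard deviation of each normalized column; ``"msd"``
    uses the mean squared deviation (no square root).  The two yield
    different weight vectors (the normalization in the ratio does not
    cancel the root), so the choice is explicit.
    """
    normalized = validate_matrix(normalized)
    if len(normalized) < 2:
        raise ValidationError("need at least two years to weight")
    if dispersion == "rmsd":
        sigma = normalized.std(ddof=0)
    elif dispersion == "msd":
        sigma = normalized.var(ddof=0)
    else:
        raise ConfigurationError(
            f"dispersion must be 'rmsd' or 'msd', got {dispersion!r}"
        )
    total = sigma.sum()
    if total == 0:
        raise ValidationError(
            "every indicator column is constant; weights are undefined"
        )
    return sigma / total


def layer_score(
    normalized_row: pd.Series,
    weights: pd.Series,
    meta: pd.DataFrame,
    layer: str,
) -> float:
    """Weight-inclusive partial sum over one criterion layer.

    Because the weights are global (they sum to 1 over all indicators),
    the three layer scores add up to the integrated score F for the
    same year.
    """
    meta = validate_meta(meta)
    if layer not in LAYERS:
        raise ConfigurationError(f"unknown layer {layer!r}")
    members = meta.index[meta["layer"] == layer]
    missing = [m for m in members if m not in normalized_row.index or m not in weights.index]
    if missing:
        raise ConfigurationError(
            f"layer {layer} indicators missing from row/weights: {missing}"
        )
    return float(
        sum(normalized_row[m] * weights[m] for m in members)
    )


def integrated_lcc(
    normalized: pd.DataFrame, weights: pd.Series
) -> pd.Series:
    """Per-year integrated score F_i = sum_j Y_ij * W_j."""
    normalized = validate_matrix(normalized)
    if set(normalized.columns) != set(weights.index):
        raise ValidationError("weights do not match matrix columns")
    return (normalized * weights).sum(axis=1).rename("F")


# ---------------------------------------------------------------------------
# Grading
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GradeBin:
    lower: float
    upper: float
    label: str


@dataclass(frozen=True)
class GradeScale:
    """Ordered bins partitioning [0, 1] into ordinal carrying-capacity
    classes.  Bins are closed below and open above; the top bin is
    closed at 1, so each boundary score takes the higher class.
    """

    bins: tuple[GradeBin, ...]

    def __post_init__(self) -> None:
        if not self.bins:
            raise ValidationError("grade scale needs at least one bin")
        ordered = sorted(self.bins, key=lambda b: b.lower)
        object.__setattr__(self, "bins", tuple(ordered))
        if self.bins[0].lower != 0 or self.bins[-1].upper != 1:
            raise ValidationError("grade bins must span [0, 1]")
        for a, b in zip(self.bins, self.bins[1:]):
            if a.upper != b.lower:
                raise ValidationError(
                    f"grade bins must be contiguous: {a} then {b}"
                )
        for b in self.bins:
            if not b.upper > b.lower:
                raise ValidationError(f"empty grade bin {b}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GradeScale":
        spec = yaml.safe_load(Path(path).read_text())
        return cls(
            tuple(
                GradeBin(float(b["lower"]), float(b["upper"]), str(b["label"]))
                for b in spec["bins"]
            )
        )


def grade(score: float, scale: GradeScale) -> str:
    """Class label of the bin containing ``score`` (boundaries go up)."""
    if not 0 <= score <= 1:
        raise ValidationError(f"score must be in [0, 1], got {score}")
    label = scale.bins[0].label
    for b in scale.bins:
        if score >= b.lower:
            label = b.label
    return label


# ---------------------------------------------------------------------------
# Projection and pipeline
# ---------------------------------------------------------------------------


def project_indicators(
    matrix: pd.DataFrame, target_years: Sequence[int]
) -> pd.DataFrame:
    """Extend the raw matrix to future years by per-indicator OLS lines.

    Each indicator is regressed on calendar year (ordinary least
    squares, straight line) and the fitted line is evaluated at each
    target year.  Historical rows are returned unchanged.
    """
    matrix = validate_matrix(matrix)
    if len(matrix) < 2:
        raise ValidationError("need at least two years to project")
    target_years = [int(y) for y in target_years]
    overlap = set(target_years) & set(matrix.index)
    if overlap:
        raise ValidationError(
            f"target years already in matrix: {sorted(overlap)}"
        )
    if not target_years:
        return matrix
    years = matrix.index.to_numpy(dtype=float)
    preds = {}
    for col in matrix.columns:
        slope, intercept = np.polyfit(years, matrix[col].to_numpy(float), 1)
        preds[col] = [slope * y + intercept for y in target_years]
    future = pd.DataFrame(preds, index=pd.Index(target_years, name=matrix.index.name))
    return pd.concat([matrix, future]).sort_index()


@dataclass(frozen=True)
class LCCSeries:
    """Scored time series: per-year layer scores, F and grade, plus the
    indicator weights and the normalized matrix they came from."""

    scores: pd.DataFrame  # index year; columns B1,B2,B3,F,grade
    weights: pd.Series  # index indicator_id
    normalized: pd.DataFrame

    @property
    def years(self) -> tuple[int, ...]:
        return tuple(int(y) for y in self.scores.index)

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        out = self.scores.reset_index()
        out = out.rename(columns={out.columns[0]: "year"})
        out.to_csv(outdir / "lcc_series.csv", index=False)
        self.weights.rename("weight").rename_axis("indicator_id").reset_index().to_csv(
            outdir / "weights.csv", index=False
        )
        payload = {
            "series": {
                str(year): {
                    "B1": float(row["B1"]),
                    "B2": float(row["B2"]),
                    "B3": float(row["B3"]),
                    "F": float(row["F"]),
                    "grade": str(row["grade"]),
                }
                for year, row in self.scores.iterrows()
            },
            "weights": {k: float(v) for k, v in self.weights.items()},
        }
        (outdir / "lcc_series.json").write_text(
            json.dumps(payload, indent=2, sort_keys=True) + "\n"
        )

    @classmethod
    def read(cls, series_csv: str | Path) -> "LCCSeries":
        scores = pd.read_csv(series_csv).set_index("year")
        return cls(scores, pd.Series(dtype=float), pd.DataFrame())


def score_normalized(
    normalized: pd.DataFrame,
    weights: pd.Series,
    meta: pd.DataFrame,
    scale: GradeScale,
) -> pd.DataFrame:
    """Layer scores, F and grade per year from already-normalized data.

    This is the tail of the pipeline; it is also the entry point when
    starting from published normalized values and weights instead of
    raw indicators.
    """
    meta = validate_meta(meta)
    rows = {}
    for year, row in normalized.iterrows():
        scores = {
            layer: layer_score(row, weights, meta, layer) for layer in LAYERS
        }
        f = integrated_lcc(normalized.loc[[year]], weights).iloc[0]
        rows[year] = {**scores, "F": f, "grade": grade(f, scale)}
    return pd.DataFrame.from_dict(rows, orient="index").rename_axis(
        normalized.index.name
    )


def run_ism(
    matrix: pd.DataFrame,
    meta: pd.DataFrame,
    target_years: Sequence[int] = (),
    scale: GradeScale | None = None,
    dispersion: str = "rmsd",
) -> LCCSeries:
    """Full index-system pipeline.

    Order: project raw indicators to ``target_years`` -> min-max
    normalize jointly over history and projections -> dispersion
    weights from the full normalized matrix (one weight per indicator
    across all years) -> layer and integrated scores -> grades.
    """
    if scale is None:
        from .fixtures import load_grade_scale

        scale = load_grade_scale()
    meta = validate_meta(meta)
    extended = project_indicators(matrix, target_years)
    normalized = normalize(extended, meta)
    weights = mse_weights(normalized, dispersion=dispersion)
    scores = score_normalized(normalized, weights, meta, scale)
    return LCCSeries(scores=scores, weights=weights, normalized=normalized)


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_indicators_csv(path: str | Path) -> pd.DataFrame:
    """Long-format indicators.csv (year,indicator_id,value) -> matrix."""
    frame = pd.read_csv(path)
    required = {"year", "indicator_id", "value"}
    if not required.issubset(frame.columns):
        raise ValidationError(f"indicator table needs columns {sorted(required)}")
    matrix = frame.pivot(index="year", columns="indicator_id", values="value")
    if matrix.isna().any().any():
        raise ValidationError("indicator panel is not rectangular")
    return matrix


def write_indicators_csv(matrix: pd.DataFrame, path: str | Path) -> None:
    long = matrix.rename_axis("year").reset_index().melt(
        id_vars="year", var_name="indicator_id", value_name="value"
    )
    long.sort_values(["year", "indicator_id"]).to_csv(path, index=False)


def read_meta_csv(path: str | Path) -> pd.DataFrame:
    return validate_meta(pd.read_csv(path))
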