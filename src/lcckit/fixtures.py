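"""Bundled reference tables.

The package ships, as plain-text data files, the published constants of
the Xiamen City carrying-capacity case study that the default pipelines
use:

* ``default_factors.csv`` — yield factors (Fujian-province NPP-based)
  and equivalence factors for the six land categories;
* ``indicator_meta.csv`` — the 20-indicator framework (layer and
  polarity per indicator);
* ``grade_scale.yaml`` — the five-class grading standard on [0, 1];
* ``reference_weights_nv.csv`` — the published index weights and
  normalized indicator values for 2000, 2005, 2012 and the projected
  years 2015, 2020, 2030.

These are constants, not computed output; loaders return them exactly
as printed.
"""
from __future__ import annotations

from importlib import resources
from typing import NamedTuple

import pandas as pd

from .efa import FactorTable
from .errors import LCCError
from .ism import GradeScale, validate_meta

_DATA = resources.files("lcckit") / "data"


def _path(name: str):
    p = _DATA / name
    if not p.is_file():
        raise LCCError(f"packaged data file {name!r} is missing")
    return p


def load_factor_table() -> FactorTable:
    """Default yield/equivalence factors for the six land categories."""
    with resources.as_file(_path("default_factors.csv")) as p:
        return FactorTable.from_csv(p)


def load_indicator_meta() -> pd.DataFrame:
    """The 20-indicator framework: layer, polarity, description."""
    with resources.as_file(_path("indicator_meta.csv")) as p:
        return validate_meta(pd.read_csv(p))


def load_grade_scale() -> GradeScale:
    """Five-class grading standard (Weakest ... Strongest)."""
    with resources.as_file(_path("grade_scale.yaml")) as p:
        return GradeScale.from_yaml(p)


def load_reference_weights_nv() -> pd.DataFrame:
    """Published index weights and normalized values, indexed by
    indicator, with columns ``weight`` and ``nv_<year>``."""
    with resources.as_file(_path("reference_weights_nv.csv")) as p:
        frame = pd.read_csv(p).set_index("indicator_id")
    expected = {"weight", "nv_2000", "nv_2005", "nv_2012", "nv_2015",
                "nv_2020", "nv_2030"}
    if set(frame.columns) != expected or len(frame) != 20:
        raise LCCError("reference weight table is corrupted")
    return frame


class ReferenceTables(NamedTuple):
    factors: FactorTable
    weights_nv: pd.DataFrame
    grade_scale: GradeScale
    indicator_meta: pd.DataFrame


def load_reference_tables() -> ReferenceTables:
    """All bundled case-study constants in one call."""
    return ReferenceTables(
        factors=load_factor_table(),
        weights_nv=load_reference_weights_nv(),
        grade_scale=load_grade_scale(),
        indicator_meta=load_indicator_meta(),
    )
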