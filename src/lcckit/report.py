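"""Comparative report across the two assessment routes.

The footprint ledger and the index-system series answer different
questions about the same city — which land categories are overdrawn,
and whether the socio-economic system is trending towards or away from
carrying capacity.  This module classifies per-category surplus/deficit
trends and assembles a side-by-side report; it never computes new
quantities, only reads cells from the two pipelines' outputs.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

from .efa import LAND_CATEGORIES, FootprintLedger
from .errors import ValidationError
from .ism import LCCSeries

#: Default threshold (ha/ca) below which a balance change counts as stable.
DEFAULT_TREND_TOL = 1e-6

TREND_LABELS = (
    "widening deficit",
    "narrowing deficit",
    "widening surplus",
    "narrowing surplus",
    "stable",
)


def _classify_series(first: float, last: float, tol: float) -> str:
    change = last - first
    if abs(change) < tol:
        return "stable"
    reference = last if abs(last) >= tol else first
    if reference < 0:
        return "widening deficit" if change < 0 else "narrowing deficit"
    return "widening surplus" if change > 0 else "narrowing surplus"


def classify_trends(
    ledger: FootprintLedger, tol: float = DEFAULT_TREND_TOL
) -> dict[str, str]:
    """Per-category surplus/deficit trend from first vs last balance."""
    if len(ledger.years) < 2:
        raise ValidationError("need at least two years to classify trends")
    trends = {}
    for category in LAND_CATEGORIES:
        series = ledger.series(category, "balance")
        if series.empty:
            continue
        trends[category] = _classify_series(
            float(series.iloc[0]), float(series.iloc[-1]), tol
        )
    return trends


@dataclass(frozen=True)
class ComparisonReport:
    """Side-by-side footprint vs index-system view over common years."""

    years: tuple[int, ...]
    # per-year: {"balance_II": ..., "F": ..., "grade": ...}
    table: dict[int, dict[str, float | str]]
    trends: dict[str, str]  # per land category; empty if < 2 years
    notes: tuple[str, ...]


def compare(
    ledger: FootprintLedger,
    series: LCCSeries,
    tol: float = DEFAULT_TREND_TOL,
) -> ComparisonReport:
    """Assemble the comparative report over the overlapping years."""
    common = sorted(set(ledger.years) & set(series.years))
    if not common:
        raise ValidationError(
            "ledger and series have no years in common"
        )
    table: dict[int, dict[str, float | str]] = {}
    for year in common:
        table[year] = {
            "balance_II": float(ledger.totals.loc[year, "balance_II"]),
            "F": float(series.scores.loc[year, "F"]),
            "grade": str(series.scores.loc[year, "grade"]),
        }
    trends = classify_trends(ledger, tol) if len(ledger.years) >= 2 else {}

    notes: list[str] = []
    if len(common) >= 2:
        f_first = float(series.scores.loc[common[0], "F"])
        f_last = float(series.scores.loc[common[-1], "F"])
        f_dir = (
            "rises" if f_last > f_first else
            "falls" if f_last < f_first else "is flat"
        )
        notes.append(
            f"integrated LCC score {f_dir} from {f_first:.2f} "
            f"({common[0]}) to {f_last:.2f} ({common[-1]})"
        )
        for category, label in trends.items():
            if label == "widening deficit":
                notes.append(
                    f"{category}: ecological deficit widens while the "
                    f"integrated score {f_dir} — the two assessments "
                    "describe complementary aspects of carrying capacity"
                )
    return ComparisonReport(
        years=tuple(common),
        table=table,
        trends=trends,
        notes=tuple(notes),
    )


# ---------------------------------------------------------------------------
# Serialization (canonical, round-trip stable)
# ---------------------------------------------------------------------------


def to_json(report: ComparisonReport) -> str:
    payload = {
        "years": list(report.years),
        "table": {str(y): report.table[y] for y in report.years},
        "trends": report.trends,
        "notes": list(report.notes),
    }
    return json.dumps(payload, indent=2, sort_keys=True) + "\n"


def from_json(text: str) -> ComparisonReport:
    payload = json.loads(text)
    return ComparisonReport(
        years=tuple(int(y) for y in payload["years"]),
        table={int(y): row for y, row in payload["table"].items()},
        trends=dict(payload["trends"]),
        notes=tuple(payload["notes"]),
    )


def to_markdown(report: ComparisonReport) -> str:
    lines = [
        "# Land carrying capacity: footprint vs index comparison",
        "",
        "| Year | Balance II (ha/ca) | F | Grade |",
        "| --- | --- | --- | --- |",
    ]
    for year in report.years:
        row = report.table[year]
        lines.append(
            f"| {year} | {row['balance_II']:.2f} | {row['F']:.2f} "
            f"| {row['grade']} |"
        )
    if report.trends:
        lines += ["", "## Per-category balance trends", ""]
        for category in LAND_CATEGORIES:
            if category in report.trends:
                lines.append(f"- {category}: {report.trends[category]}")
    if report.notes:
        lines += ["", "## Notes", ""]
        lines += [f"- {note}" for note in report.notes]
    return "\n".join(lines) + "\n"


def write_report(report: ComparisonReport, path: str | Path) -> None:
    """Write the report as .md or .json depending on the suffix."""
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(to_json(report))
    else:
        path.write_text(to_markdown(report))
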