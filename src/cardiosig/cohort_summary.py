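"""Descriptive cohort tables: per-PT shares, demographic strata and
outcome rates.

Conventions match the published table layout: denominators are distinct
reports per PT; age bands are <60 (strict), 60–80 (both endpoints
included), >80 (strict) plus unknown; each report contributes exactly one
outcome under the severity precedence
death > life_threatening > disabled > hospitalization > other; percentages
are rounded half-up to two decimals.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from cardiosig.report_store import OUTCOMES, REGIONS, SEXES, AdverseEventReport

DIMENSIONS = ("sex", "age_band", "outcome", "region", "year")
AGE_BANDS = ("<60", "60-80", ">80", "unknown")
#: severity order used to collapse multi-outcome reports to a single class
OUTCOME_PRECEDENCE = ("death", "life_threatening", "disabled", "hospitalization", "other")
#: display order mirrors the published table
OUTCOME_DISPLAY = ("death", "disabled", "life_threatening", "hospitalization", "other")


class IntegrityError(KeyError):
    """A pair references a report id absent from the report collection."""


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal half-up rounding (Python's round() is half-even)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def percent(count: int, total: int) -> float:
    return round_half_up(100.0 * count / total, 2)


@dataclass
class StratumTable:
    """One PT stratified along one dimension."""

    pt: str
    dimension: str
    rows: list[tuple[object, int, float]]  # (level, count, percent of PT total)

    @property
    def total(self) -> int:
        return sum(n for _, n, _ in self.rows)


def age_band(age_years: float | None) -> str:
    if age_years is None:
        return "unknown"
    if age_years < 60:
        return "<60"
    if age_years <= 80:
        return "60-80"
    return ">80"


def primary_outcome(outcomes: Iterable[str]) -> str:
    """Collapse a report's outcome set to its most severe class."""
    outcomes = set(outcomes)
    for level in OUTCOME_PRECEDENCE:
        if level in outcomes:
            return level
    return "other"


def _report_index(
    reports: Iterable[AdverseEventReport],
) -> dict[str, AdverseEventReport]:
    return {r.report_id: r for r in reports}


def _level_of(report: AdverseEventReport, dimension: str):
    if dimension == "sex":
        return report.sex
    if dimension == "age_band":
        return age_band(report.age_years)
    if dimension == "outcome":
        return primary_outcome(report.outcomes)
    if dimension == "region":
        return report.region
    if dimension == "year":
        return report.year_received if report.year_received is not None else "unknown"
    raise ValueError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")


def _levels_for(dimension: str, observed: set) -> list:
    if dimension == "sex":
        return list(SEXES)
    if dimension == "age_band":
        return list(AGE_BANDS)
    if dimension == "outcome":
        return list(OUTCOME_DISPLAY)
    if dimension == "region":
        return list(REGIONS)
    # year: ascending years, unknown last
    years = sorted(v for v in observed if v != "unknown")
    return years + (["unknown"] if "unknown" in observed else [])


def stratify(
    pairs: Sequence[tuple[str, str]],
    reports: Iterable[AdverseEventReport],
    dimension: str,
) -> list[StratumTable]:
    """Per-PT counts and percentages along one demographic dimension.

    ``pairs`` are (report_id, PT) as produced by
    :func:`cardiosig.report_store.select_soc_events`; denominators are
    distinct reports per PT.
    """
    if dimension not in DIMENSIONS:
        raise ValueError(f"unknown dimension {dimension!r}; expected one of {DIMENSIONS}")
    index = _report_index(reports)
    per_pt: dict[str, dict] = {}
    for rid, pt in sorted(set(pairs)):
        if rid not in index:
            raise IntegrityError(f"pair references unknown report id {rid!r}")
        level = _level_of(index[rid], dimension)
        bucket = per_pt.setdefault(pt, {})
        bucket[level] = bucket.get(level, 0) + 1
    out = []
    for pt in sorted(per_pt):
        counts = per_pt[pt]
        total = sum(counts.values())
        rows = [
            (level, counts.get(level, 0), percent(counts.get(level, 0), total))
            for level in _levels_for(dimension, set(counts))
        ]
        out.append(StratumTable(pt=pt, dimension=dimension, rows=rows))
    return out


def outcome_rates(
    pairs: Sequence[tuple[str, str]],
    reports: Iterable[AdverseEventReport],
) -> pd.DataFrame:
    """Per-PT outcome percentages (one severity-collapsed outcome per
    report; rows sum to 100 up to rounding).  Indexed by PT with one
    column per outcome class plus the report count."""
    tables = stratify(pairs, reports, "outcome")
    rows = {}
    for t in tables:
        rec = {level: pct for level, _, pct in t.rows}
        rec["n_reports"] = t.total
        rows[t.pt] = rec
    df = pd.DataFrame.from_dict(rows, orient="index")
    return df[["n_reports", *OUTCOME_DISPLAY]]


def share_table(
    pairs: Sequence[tuple[str, str]],
    total_cardiac: int,
    total_included: int,
) -> pd.DataFrame:
    """Per-PT counts with shares of the SOC cohort and of the full extract.

    ``total_cardiac`` / ``total_included`` are the external denominators
    (the SOC report total and the full included-report total).
    """
    if total_cardiac <= 0 or total_included <= 0:
        raise ValueError("totals must be positive")
    counts: dict[str, int] = {}
    for _, pt in set(pairs):
        counts[pt] = counts.get(pt, 0) + 1
    if counts and max(counts.values()) > min(total_cardiac, total_included):
        raise ValueError("a per-PT count exceeds the stated totals")
    rows = [
        {
            "pt": pt,
            "n": n,
            "pct_cardiac": percent(n, total_cardiac),
            "pct_all": percent(n, total_included),
        }
        for pt, n in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    ]
    return pd.DataFrame(rows).set_index("pt")
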