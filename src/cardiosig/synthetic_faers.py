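"""Synthetic spontaneous-report generator with analytic ground truth.

Two distinct jobs live here:

* :func:`generate_reports` draws report collections from a known joint
  drug–event distribution — an independence background
  p(d, e) ∝ P(d)·P(e) with multiplicative relative-risk signals λ injected
  into chosen cells — so that disproportionality statistics can be
  calibrated against a null and checked for signal recovery.
* :func:`fixture_from_table2` deterministically rebuilds the published
  osimertinib cardiac cohort: per-PT report counts, demographics, outcomes
  and years exactly as printed, with the unpublished background 2x2 cells
  recovered analytically from the printed confidence intervals.

Each synthetic report carries one primary-suspect drug and one PT, which
keeps every report in exactly one cell of the drug-by-event matrix and the
ground-truth cell probabilities exact.  Demographics and outcome are drawn
independently of the drug–event cell.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from cardiosig import reference_tables as ref
from cardiosig.report_store import (
    OUTCOMES,
    REGIONS,
    SEXES,
    AdverseEventReport,
    PTLexicon,
)

CARDIAC_SOC = "cardiac disorders"

#: default categorical distributions, chosen to resemble the published
#: cardiac cohort margins (sex ~54% female, ages concentrated 60-80 with a
#: large unknown fraction, reports dominated by Asia/Americas,
#: hospitalization the most common outcome)
DEFAULT_DEMOGRAPHICS = {
    "sex": {"female": 0.54, "male": 0.29, "unknown": 0.17},
    "age_band": {"<60": 0.08, "60-80": 0.44, ">80": 0.13, "unknown": 0.35},
    "region": {"Asia": 0.38, "Americas": 0.18, "Europe": 0.11,
               "Australia": 0.01, "unknown": 0.32},
    "year": {2020: 0.25, 2021: 0.24, 2022: 0.25, 2023: 0.26},
}
DEFAULT_OUTCOMES = {
    "death": 0.16, "disabled": 0.01, "life_threatening": 0.11,
    "hospitalization": 0.44, "other": 0.28,
}

_AGE_RANGES = {"<60": (25, 59), "60-80": (60, 80), ">80": (81, 99)}


def _check_dist(name: str, dist: dict) -> None:
    total = sum(dist.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {total}, not 1")
    if any(p < 0 for p in dist.values()):
        raise ValueError(f"{name} has negative probabilities")


@dataclass
class SimulationConfig:
    """Conditions for one synthetic report collection.

    ``drug_catalog`` / ``event_catalog`` give names with marginal reporting
    probabilities; ``signals`` lists (drug, PT, λ) cells whose joint
    probability is multiplied by λ before renormalization (λ = 1 is the
    independence null, λ = 0 removes the cell).
    """

    n_reports: int
    drug_catalog: list[tuple[str, float]]
    event_catalog: list[tuple[str, float]]
    signals: list[tuple[str, str, float]] = field(default_factory=list)
    demographics: dict = field(default_factory=lambda: {
        k: dict(v) for k, v in DEFAULT_DEMOGRAPHICS.items()
    })
    outcome_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_OUTCOMES)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_reports < 1:
            raise ValueError("n_reports must be >= 1")
        for label, catalog in (("drug", self.drug_catalog),
                               ("event", self.event_catalog)):
            if not catalog:
                raise ValueError(f"{label} catalog is empty")
            _check_dist(f"{label} catalog", dict(catalog))
        names = [d for d, _ in self.drug_catalog]
        if len(set(names)) != len(names):
            raise ValueError("duplicate drug names in catalog")
        names = [e for e, _ in self.event_catalog]
        if len(set(names)) != len(names):
            raise ValueError("duplicate event names in catalog")
        for _, _, lam in self.signals:
            if lam < 0:
                raise ValueError("relative risk λ must be >= 0")
        for key, dist in self.demographics.items():
            _check_dist(f"demographics[{key}]", dist)
        _check_dist("outcome_distribution", self.outcome_distribution)


@dataclass
class GroundTruth:
    """What the generator actually drew, plus the analytic cell law."""

    drugs: list[str]
    events: list[str]
    #: renormalized joint cell probabilities, shape (n_drugs, n_events)
    cell_probs: np.ndarray
    #: per-report sampled cell indices
    drug_idx: np.ndarray
    event_idx: np.ndarray
    #: per-report sampled strata (sex, age_band, region, year, outcome)
    strata: pd.DataFrame

    def cell_probability(self, drug: str, event: str) -> float:
        return float(
            self.cell_probs[self.drugs.index(drug), self.events.index(event)]
        )

    def cell_counts(self) -> np.ndarray:
        """Exhaustive tally of sampled cells (drug-by-event matrix)."""
        n_d, n_e = self.cell_probs.shape
        flat = np.bincount(self.drug_idx * n_e + self.event_idx,
                           minlength=n_d * n_e)
        return flat.reshape(n_d, n_e)


def cell_distribution(config: SimulationConfig) -> tuple[list[str], list[str], np.ndarray]:
    """Renormalized joint drug-event probabilities p(d,e) ∝ P(d)·P(e)·λ."""
    drugs = [d for d, _ in config.drug_catalog]
    events = [e for e, _ in config.event_catalog]
    pd_ = np.array([p for _, p in config.drug_catalog])
    pe = np.array([p for _, p in config.event_catalog])
    cells = np.outer(pd_, pe)
    for drug, event, lam in config.signals:
        try:
            i, j = drugs.index(drug), events.index(event)
        except ValueError as exc:
            raise ValueError(f"signal cell ({drug}, {event}) not in catalog") from exc
        cells[i, j] *= lam
    total = cells.sum()
    if total <= 0:
        raise ValueError("joint distribution has zero total probability")
    return drugs, events, cells / total


def _sample_categorical(rng: np.random.Generator, dist: dict, size: int) -> np.ndarray:
    levels = np.array(list(dist.keys()), dtype=object)
    probs = np.array(list(dist.values()), dtype=float)
    return rng.choice(levels, size=size, p=probs / probs.sum())


def generate_reports(
    config: SimulationConfig,
) -> tuple[list[AdverseEventReport], GroundTruth]:
    """Draw a report collection from the configured joint distribution.

    One named pseudo-random stream is derived from ``config.seed``;
    identical seed + config reproduce the collection exactly.
    """
    rng = np.random.default_rng(config.seed)
    drugs, events, cells = cell_distribution(config)
    n_d, n_e = cells.shape
    flat_idx = rng.choice(n_d * n_e, size=config.n_reports, p=cells.ravel())
    drug_idx, event_idx = np.divmod(flat_idx, n_e)

    n = config.n_reports
    sex = _sample_categorical(rng, config.demographics["sex"], n)
    band = _sample_categorical(rng, config.demographics["age_band"], n)
    region = _sample_categorical(rng, config.demographics["region"], n)
    year = _sample_categorical(rng, config.demographics["year"], n)
    outcome = _sample_categorical(rng, config.outcome_distribution, n)
    age_draw = rng.random(n)

    strata = pd.DataFrame({
        "sex": sex, "age_band": band, "region": region,
        "year": year, "outcome": outcome,
    })
    reports = []
    for i in range(n):
        b = band[i]
        if b == "unknown":
            age = None
        else:
            lo, hi = _AGE_RANGES[b]
            age = lo + age_draw[i] * (hi - lo)
        reports.append(AdverseEventReport(
            report_id=f"S{i:07d}",
            drugs=[(drugs[drug_idx[i]], "primary_suspect")],
            events=[events[event_idx[i]]],
            sex=str(sex[i]),
            age_years=age,
            region=str(region[i]),
            year_received=int(year[i]),
            outcomes={str(outcome[i])},
        ))
    truth = GroundTruth(
        drugs=drugs, events=events, cell_probs=cells,
        drug_idx=drug_idx, event_idx=event_idx, strata=strata,
    )
    return reports, truth


def skewed_catalog(prefix: str, n: int) -> list[tuple[str, float]]:
    """A mildly heavy-tailed marginal catalog (probability ∝ 1/(rank+1)),
    mimicking the very uneven reporting frequencies of real PT and drug
    margins."""
    weights = 1.0 / (np.arange(n) + 1.0)
    probs = weights / weights.sum()
    return [(f"{prefix}{i:04d}", float(p)) for i, p in enumerate(probs)]


# ---------------------------------------------------------------------------
# deterministic fixture reproducing the published cohort tables

#: filler cardiac PTs covering the cardiac reports outside the top five
#: (counts < 24 so the published top-5 ranking is preserved)
FILLER_CARDIAC = {
    "Atrial fibrillation": 20,
    "Palpitations": 20,
    "Tachycardia": 20,
    "Bradycardia": 17,
}
#: non-cardiac decoy PTs with their SOC, used for the remaining reports
DECOY_PTS = {
    "Diarrhoea": "gastrointestinal disorders",
    "Rash": "skin and subcutaneous tissue disorders",
    "Paronychia": "infections and infestations",
    "Stomatitis": "gastrointestinal disorders",
    "Decreased appetite": "metabolism and nutrition disorders",
    "Dry skin": "skin and subcutaneous tissue disorders",
}

DRUG = "osimertinib"


def fixture_lexicon() -> PTLexicon:
    """PT → SOC lexicon covering every PT the fixture emits."""
    mapping = {pt: CARDIAC_SOC for pt in ref.TABLE2}
    mapping.update({pt: CARDIAC_SOC for pt in FILLER_CARDIAC})
    mapping.update(DECOY_PTS)
    return PTLexicon(mapping)


def _expand_counts(counts: dict, total: int, fill) -> list:
    """Expand a {level: count} dict to a list of length *total*, padding
    the unprinted remainder with *fill*."""
    out: list = []
    for level, k in counts.items():
        out.extend([level] * k)
    if len(out) > total:
        raise ValueError(f"strata counts {counts} exceed total {total}")
    out.extend([fill] * (total - len(out)))
    return out


_BAND_AGE = {"<60": 45.0, "60-80": 70.0, ">80": 85.0, "unknown": None}


def fixture_from_table2() -> tuple[list[AdverseEventReport], pd.DataFrame]:
    """The published cardiac cohort as a concrete report collection.

    Emits the 15,382 osimertinib primary-suspect reports: 197 carrying the
    five top cardiac PTs with demographics/outcomes/years assigned exactly
    per the printed strata, 77 further cardiac reports on filler PTs
    (cardiac total 274), and 15,108 non-cardiac reports on decoy PTs.

    Returns the collection together with the expected per-PT signal table:
    cells (a, b) from the printed counts, (c, d) recovered from the printed
    CI by :func:`cardiosig.disproportionality.reconstruct_background`, and
    the forward ROR/BCPNN statistics on the reconstructed table.
    """
    from cardiosig.disproportionality import reconstruct_background, score_table

    reports: list[AdverseEventReport] = []
    counter = 0

    def next_id() -> str:
        nonlocal counter
        counter += 1
        return f"F{counter:06d}"

    for pt, row in ref.TABLE2.items():
        n = row["n"]
        strata = ref.TABLE3[pt]
        sexes = _expand_counts(strata["sex"], n, "unknown")
        bands = _expand_counts(strata["age_band"], n, "unknown")
        outcomes = _expand_counts(strata["outcome"], n, "other")
        years = _expand_counts(strata["year"], n, None)
        regions = _expand_counts(strata["region"], n, "unknown")
        for i in range(n):
            reports.append(AdverseEventReport(
                report_id=next_id(),
                drugs=[(DRUG, "primary_suspect")],
                events=[pt],
                sex=sexes[i],
                age_years=_BAND_AGE[bands[i]],
                region=regions[i],
                year_received=years[i],
                outcomes={outcomes[i]},
            ))
    for pt, n in FILLER_CARDIAC.items():
        for _ in range(n):
            reports.append(AdverseEventReport(
                report_id=next_id(),
                drugs=[(DRUG, "primary_suspect")],
                events=[pt],
                outcomes={"other"},
            ))
    n_noncardiac = ref.TOTAL_INCLUDED - ref.TOTAL_CARDIAC
    decoys = list(DECOY_PTS)
    for i in range(n_noncardiac):
        reports.append(AdverseEventReport(
            report_id=next_id(),
            drugs=[(DRUG, "primary_suspect")],
            events=[decoys[i % len(decoys)]],
            outcomes={"other"},
        ))
    assert len(reports) == ref.TOTAL_INCLUDED

    rows = []
    for pt, row in ref.TABLE2.items():
        a = row["n"]
        b = ref.TOTAL_INCLUDED - a
        table = reconstruct_background(a, b, *row["ci"])
        score = score_table(table)
        rows.append({
            "pt": pt, "a": table.a, "b": table.b, "c": table.c, "d": table.d,
            "ror": score.ror, "ror_l": score.ror_l, "ror_u": score.ror_u,
            "ic": score.ic, "ic_sd": score.ic_sd, "ic025": score.ic025,
            "ic_minus_2sd": score.ic_minus_2sd,
            "ror_positive": score.ror_positive,
            "bcpnn_positive": score.bcpnn_positive,
            "strength_ror": score.strength_ror,
            "strength_bcpnn": score.strength_bcpnn,
            "printed_ror": row["ror"],
            "printed_ci_l": row["ci"][0], "printed_ci_u": row["ci"][1],
        })
    expected = pd.DataFrame(rows).set_index("pt")
    return reports, expected
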