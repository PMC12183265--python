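"""Disproportionality statistics for spontaneous-report signal detection.

For a drug–event pair the 2x2 table is::

                    target event   other events
    target drug          a              b
    other drugs          c              d

with the drug axis restricted to primary-suspect reports.  Two statistics
are computed:

* the reporting odds ratio, ROR = (a·d)/(b·c), with a Woolf log-scale 95%
  confidence interval, se(ln ROR) = sqrt(1/a + 1/b + 1/c + 1/d); zero cells
  trigger the Haldane–Anscombe +0.5 correction;
* the BCPNN information component, IC = log2 p(d,e)/(p(d)p(e)), with
  conjugate Beta posteriors for the cell and both margins
  (cell prior weight γ11 = 1 with γ = (N+2)²/((a+b+1)(a+c+1)), margin
  priors Beta(1, 1) with total prior weight 2).  Posterior moments are
  exact (digamma/trigamma) by default; the classical delta-method
  approximation of the same model is available as ``method="approx"``.

Positivity follows the usual dual rule: ROR-positive when n >= 3 and the
CI lower bound exceeds 1; BCPNN-positive when n >= 3 and IC025 > 0.
Strength tiers use the CI lower bound (ROR scale) and IC − 2·SD (bits).

:func:`reconstruct_background` inverts a printed (a, ROR CI) row back to
integer background cells (c, d) — the forward statistic on the
reconstructed table reproduces the printed ROR to its 2-dp precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import numpy as np
from scipy.special import polygamma, psi

from cardiosig.report_store import AdverseEventReport, normalize

Z95 = 1.96
_LN2 = math.log(2.0)


class InfeasibleTableError(ValueError):
    """The printed (n, CI) row admits no non-negative background cells."""


@dataclass(frozen=True)
class ContingencyTable:
    """2x2 drug-by-event report counts (a, b, c, d)."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or int(v) != v:
                raise ValueError(f"cell {name} must be a non-negative integer, got {v}")
        if self.n_total < 1:
            raise ValueError("table must contain at least one report")

    @property
    def n_total(self) -> int:
        return self.a + self.b + self.c + self.d

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


class RorResult(NamedTuple):
    ror: float
    ror_l: float
    ror_u: float
    se_ln_ror: float
    corrected: bool


class IcResult(NamedTuple):
    ic: float
    ic_sd: float
    ic025: float
    ic_minus_2sd: float


@dataclass
class SignalScore:
    """Full per-pair signal summary (ROR + BCPNN + rules)."""

    n_cases: int
    ror: float
    ror_l: float
    ror_u: float
    se_ln_ror: float
    ic: float
    ic_sd: float
    ic025: float
    ic_minus_2sd: float
    ror_positive: bool = False
    bcpnn_positive: bool = False
    strength_ror: str = "none"
    strength_bcpnn: str = "none"
    corrected: bool = False
    table: ContingencyTable | None = field(default=None, repr=False)


# ---------------------------------------------------------------------------
# vectorized cores (plain ndarrays; the dataclass API wraps them)

def ror_components(a, b, c, d):
    """Vectorized ROR, Woolf CI and se(ln ROR); Haldane-corrects any table
    with a zero cell.  Returns (ror, lo, hi, se, corrected_mask)."""
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    corrected = (a == 0) | (b == 0) | (c == 0) | (d == 0)
    shift = np.where(corrected, 0.5, 0.0)
    aa, bb, cc, dd = a + shift, b + shift, c + shift, d + shift
    ror = (aa * dd) / (bb * cc)
    se = np.sqrt(1 / aa + 1 / bb + 1 / cc + 1 / dd)
    lo = np.exp(np.log(ror) - Z95 * se)
    hi = np.exp(np.log(ror) + Z95 * se)
    return ror, lo, hi, se, corrected


def _bcpnn_params(a, b, c, d):
    a, b, c, d = (np.asarray(x, dtype=float) for x in (a, b, c, d))
    n = a + b + c + d
    gamma11 = 1.0
    gamma = gamma11 * (n + 2) ** 2 / ((a + b + 1) * (a + c + 1))
    cell = (a + gamma11, n - a + gamma - gamma11)
    row = (a + b + 1, n - (a + b) + 1)  # Beta(1,1) prior, total weight 2
    col = (a + c + 1, n - (a + c) + 1)
    return cell, row, col


def ic_components(a, b, c, d, method: str = "exact"):
    """Vectorized information component and posterior SD (bits).

    ``method="exact"`` uses digamma/trigamma moments of
    log2(p11 / (p_row p_col)) under independent Beta posteriors;
    ``method="approx"`` the log-of-means / delta-method closed form of the
    same model.
    """
    cell, row, col = _bcpnn_params(a, b, c, d)
    if method == "exact":
        def mean_ln(p):
            return psi(p[0]) - psi(p[0] + p[1])

        def var_ln(p):
            return polygamma(1, p[0]) - polygamma(1, p[0] + p[1])

        ic = (mean_ln(cell) - mean_ln(row) - mean_ln(col)) / _LN2
        var = (var_ln(cell) + var_ln(row) + var_ln(col)) / _LN2**2
    elif method == "approx":
        def mean(p):
            return p[0] / (p[0] + p[1])

        def relvar(p):
            tot = p[0] + p[1]
            return p[1] / (p[0] * (tot + 1))

        ic = np.log2(mean(cell) / (mean(row) * mean(col)))
        var = (relvar(cell) + relvar(row) + relvar(col)) / _LN2**2
    else:
        raise ValueError(f"unknown BCPNN method {method!r}")
    sd = np.sqrt(var)
    return ic, sd


# ---------------------------------------------------------------------------
# table-level API

def ror_statistic(t: ContingencyTable) -> RorResult:
    """ROR with 95% CI for one table (Haldane-corrected if any cell is 0)."""
    ror, lo, hi, se, corr = ror_components(*t.as_tuple())
    return RorResult(float(ror), float(lo), float(hi), float(se), bool(corr))


def bcpnn_ic(t: ContingencyTable, method: str = "exact") -> IcResult:
    """Information component with posterior SD, IC025 and IC − 2SD."""
    ic, sd = ic_components(*t.as_tuple(), method=method)
    ic, sd = float(ic), float(sd)
    return IcResult(ic, sd, ic - Z95 * sd, ic - 2.0 * sd)


def classify_signal(score: SignalScore, n_cases: int | None = None) -> SignalScore:
    """Apply the positivity gates and strength tiers in place.

    ROR: positive when n >= 3 and the 95% CI lower bound > 1; tiers on that
    bound: (1, 50) weak, [50, 1000) moderate, >= 1000 strong.
    BCPNN: positive when n >= 3 and IC025 > 0; tiers on IC − 2SD:
    (0, 1.5] weak, (1.5, 3.0] moderate, > 3.0 strong.
    """
    n = score.n_cases if n_cases is None else n_cases
    score.n_cases = n
    score.ror_positive = n >= 3 and score.ror_l > 1.0
    score.bcpnn_positive = n >= 3 and score.ic025 > 0.0

    score.strength_ror = "none"
    if score.ror_positive:
        if 1.0 < score.ror_l < 50.0:
            score.strength_ror = "weak"
        elif 50.0 <= score.ror_l < 1000.0:
            score.strength_ror = "moderate"
        elif score.ror_l >= 1000.0:
            score.strength_ror = "strong"

    score.strength_bcpnn = "none"
    if score.bcpnn_positive:
        x = score.ic_minus_2sd
        if 0.0 < x <= 1.5:
            score.strength_bcpnn = "weak"
        elif 1.5 < x <= 3.0:
            score.strength_bcpnn = "moderate"
        elif x > 3.0:
            score.strength_bcpnn = "strong"
    return score


def score_table(t: ContingencyTable, method: str = "exact") -> SignalScore:
    """Full SignalScore (both statistics plus rules) for one table."""
    r = ror_statistic(t)
    i = bcpnn_ic(t, method=method)
    score = SignalScore(
        n_cases=t.a,
        ror=r.ror, ror_l=r.ror_l, ror_u=r.ror_u, se_ln_ror=r.se_ln_ror,
        ic=i.ic, ic_sd=i.ic_sd, ic025=i.ic025, ic_minus_2sd=i.ic_minus_2sd,
        corrected=r.corrected, table=t,
    )
    return classify_signal(score)


# ---------------------------------------------------------------------------
# building tables from reports

def build_contingency(
    reports: Sequence[AdverseEventReport], drug: str, event: str
) -> ContingencyTable:
    """Count distinct reports into the 2x2 table for (drug, event).

    The drug axis is "names *drug* as primary suspect"; the event axis is
    "lists *event* among its PTs".  Both matches are case-insensitive.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("at least one report is required")
    a = b = c = d = 0
    for r in reports:
        has_d = r.has_drug(drug, role="primary_suspect")
        has_e = r.has_event(event)
        if has_d and has_e:
            a += 1
        elif has_d:
            b += 1
        elif has_e:
            c += 1
        else:
            d += 1
    return ContingencyTable(a, b, c, d)


def contingency_matrix(
    reports: Iterable[AdverseEventReport],
) -> tuple[list[str], list[str], np.ndarray]:
    """Distinct-report counts for every (primary-suspect drug, PT) pair.

    Returns (drugs, events, counts) with counts[i, j] the number of
    distinct reports naming drug i as primary suspect and listing PT j.
    """
    pair_sets: dict[tuple[str, str], set[str]] = {}
    for r in reports:
        for drug, role in r.drugs:
            if role != "primary_suspect":
                continue
            dkey = normalize(drug)
            for pt in r.events:
                pair_sets.setdefault((dkey, normalize(pt)), set()).add(r.report_id)
    drugs = sorted({d for d, _ in pair_sets})
    events = sorted({e for _, e in pair_sets})
    di = {d: i for i, d in enumerate(drugs)}
    ei = {e: j for j, e in enumerate(events)}
    counts = np.zeros((len(drugs), len(events)), dtype=np.int64)
    for (dkey, ekey), ids in pair_sets.items():
        counts[di[dkey], ei[ekey]] = len(ids)
    return drugs, events, counts


def tables_from_matrix(counts: np.ndarray):
    """All-pairs 2x2 cells from a drug-by-event count matrix.

    Valid when each report contributes to exactly one cell (one primary
    suspect drug, one PT), as produced by the synthetic generator.
    Returns broadcastable arrays (a, b, c, d) of the matrix shape.
    """
    counts = np.asarray(counts, dtype=np.int64)
    row = counts.sum(axis=1, keepdims=True)
    col = counts.sum(axis=0, keepdims=True)
    n = counts.sum()
    a = counts
    b = row - counts
    c = col - counts
    d = n - row - col + counts
    return a, b, c, d


# ---------------------------------------------------------------------------
# inverse reconstruction of printed rows

def reconstruct_background(
    a: int, b: int, ror_l: float, ror_u: float
) -> ContingencyTable:
    """Recover integer background cells (c, d) from a printed CI row.

    The printed 95% CI determines the point ROR (geometric mean of the
    bounds) and se(ln ROR) = (ln u − ln l)/(2·1.96); the Woolf identity
    1/c + 1/d = se² − 1/a − 1/b and the odds identity c/d = (a/b)/ROR then
    fix c and d, which are rounded to integers at the very end.
    """
    if not (0 < ror_l < ror_u):
        raise ValueError("require 0 < ror_l < ror_u")
    if a < 1 or b < 1:
        raise ValueError("require a >= 1 and b >= 1")
    ror = math.sqrt(ror_l * ror_u)
    se = (math.log(ror_u) - math.log(ror_l)) / (2 * Z95)
    slack = se**2 - 1.0 / a - 1.0 / b
    if slack <= 0:
        raise InfeasibleTableError(
            f"se²={se**2:.6g} does not exceed 1/a+1/b={1/a + 1/b:.6g} "
            f"(slack {slack:.3g}); no non-negative background exists"
        )
    ratio = a / (b * ror)  # c/d
    c = (1.0 + ratio) / slack
    d = c / ratio
    return ContingencyTable(a, b, int(round(c)), int(round(d)))
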