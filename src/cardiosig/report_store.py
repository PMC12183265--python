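"""Data model, I/O and filtering for FAERS-like spontaneous adverse-event
reports.

One :class:`AdverseEventReport` is one spontaneous report: the drugs it
names (with their reporter-assigned roles), the MedDRA preferred terms (PTs)
of the events, demographics, and outcome flags.  A flat PT → system-organ-
class (SOC) lexicon stands in for the MedDRA hierarchy; cohort selection is
"primary-suspect drug" + "PT in the cardiac SOC", matching the usual
OpenVigil-style extraction.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

ROLES = ("primary_suspect", "secondary_suspect", "concomitant")
SEXES = ("female", "male", "unknown")
REGIONS = ("Asia", "Americas", "Europe", "Australia", "unknown")
OUTCOMES = ("death", "disabled", "life_threatening", "hospitalization", "other")

#: default column names for the tabular report dialect
DEFAULT_DIALECT = {
    "report_id": "report_id",
    "drug": "drug",
    "role": "role",
    "pt": "pt",
    "sex": "sex",
    "age": "age",
    "region": "region",
    "year": "year",
    "outcomes": "outcomes",
}
_REQUIRED = ("report_id", "drug", "role", "pt")


class ConfigurationError(ValueError):
    """A required column or lexicon entry is missing."""


def normalize(s: str) -> str:
    """Whitespace-collapse and lowercase a name for matching purposes."""
    return " ".join(str(s).split()).lower()


@dataclass
class AdverseEventReport:
    """One spontaneous adverse-event report.

    ``drugs`` is a list of ``(drug_name, role)`` pairs; ``events`` the PTs
    reported; ``outcomes`` a subset of :data:`OUTCOMES`.  Unknown values are
    ``"unknown"`` for categorical fields and ``None`` for age/year.
    """

    report_id: str
    drugs: list[tuple[str, str]]
    events: list[str]
    sex: str = "unknown"
    age_years: float | None = None
    region: str = "unknown"
    year_received: int | None = None
    outcomes: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.report_id:
            raise ValueError("report_id must be non-empty")
        if not self.events:
            raise ValueError(f"report {self.report_id}: events must be non-empty")
        if self.age_years is not None and not (0 <= self.age_years < 130):
            raise ValueError(f"report {self.report_id}: implausible age {self.age_years}")
        for _, role in self.drugs:
            if role not in ROLES:
                raise ValueError(f"report {self.report_id}: unknown drug role {role!r}")
        bad = self.outcomes - set(OUTCOMES)
        if bad:
            raise ValueError(f"report {self.report_id}: unknown outcomes {sorted(bad)}")

    def has_drug(self, drug_name: str, role: str | None = None) -> bool:
        key = normalize(drug_name)
        return any(
            normalize(d) == key and (role is None or r == role) for d, r in self.drugs
        )

    def has_event(self, pt: str) -> bool:
        key = normalize(pt)
        return any(normalize(e) == key for e in self.events)


class PTLexicon:
    """Flat mapping from preferred term to system-organ-class label.

    Lookup is case-insensitive after whitespace normalization; each PT maps
    to exactly one SOC.
    """

    def __init__(self, mapping: Mapping[str, str]):
        self._canonical: dict[str, str] = {}  # normalized pt -> canonical spelling
        self._soc: dict[str, str] = {}  # normalized pt -> soc
        for pt, soc in mapping.items():
            key = normalize(pt)
            if key in self._soc and self._soc[key] != soc:
                raise ConfigurationError(f"PT {pt!r} mapped to multiple SOCs")
            self._canonical[key] = " ".join(str(pt).split())
            self._soc[key] = soc

    @classmethod
    def from_tsv(cls, path: str | Path) -> "PTLexicon":
        """Read a two-column (pt, soc) TSV; a header row is optional."""
        mapping: dict[str, str] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or not row[0].strip():
                    continue
                if normalize(row[0]) == "pt":
                    continue
                if len(row) < 2:
                    raise ConfigurationError(f"lexicon row {row!r} lacks a SOC column")
                mapping[row[0]] = row[1].strip()
        return cls(mapping)

    def soc_of(self, pt: str) -> str | None:
        return self._soc.get(normalize(pt))

    def canonical(self, pt: str) -> str:
        return self._canonical.get(normalize(pt), " ".join(str(pt).split()))

    @property
    def socs(self) -> set[str]:
        return set(self._soc.values())

    def __contains__(self, pt: str) -> bool:
        return normalize(pt) in self._soc

    def __len__(self) -> int:
        return len(self._soc)


@dataclass
class LoadResult:
    """Reports parsed from a tabular file, plus parse diagnostics.

    Iterates like a plain sequence of reports.
    """

    reports: list[AdverseEventReport]
    n_malformed: int = 0
    warnings: list[str] = field(default_factory=list)

    def __iter__(self) -> Iterator[AdverseEventReport]:
        return iter(self.reports)

    def __len__(self) -> int:
        return len(self.reports)

    def __getitem__(self, i):
        return self.reports[i]


def _parse_optional_float(s: str) -> float | None:
    s = s.strip()
    if not s or normalize(s) in {"unknown", "na", "nan", ""}:
        return None
    return float(s)


def _parse_optional_int(s: str) -> int | None:
    v = _parse_optional_float(s)
    return None if v is None else int(v)


def load_reports(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> LoadResult:
    """Load a long-format report table into merged per-report records.

    Multiple rows sharing a report id are merged: drugs, events and outcomes
    are unioned; conflicting demographics keep the first non-unknown value
    (with a warning).  Rows with an empty id, drug, role or PT are counted
    as malformed and skipped.

    Parameters
    ----------
    path : str or Path
        Delimited text file; the delimiter is sniffed from the header
        (tab if present, else comma).
    dialect : mapping, optional
        Maps the logical column names of :data:`DEFAULT_DIALECT` to the
        file's column names.
    """
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    path = Path(path)
    with open(path, newline="") as fh:
        head = fh.readline()
        delim = "\t" if "\t" in head else ","
        fh.seek(0)
        reader = csv.DictReader(fh, delimiter=delim)
        header = reader.fieldnames or []
        for logical in _REQUIRED:
            if cols[logical] not in header:
                raise ConfigurationError(
                    f"required column {cols[logical]!r} (for {logical}) "
                    f"missing from {path.name}; header = {header}"
                )
        rows = list(reader)

    warnings: list[str] = []
    n_malformed = 0
    acc: dict[str, dict] = {}
    order: list[str] = []
    for i, row in enumerate(rows, start=2):
        rid = (row.get(cols["report_id"]) or "").strip()
        drug = (row.get(cols["drug"]) or "").strip()
        role = (row.get(cols["role"]) or "").strip()
        pt = (row.get(cols["pt"]) or "").strip()
        if not rid or not drug or not pt or role not in ROLES:
            n_malformed += 1
            continue
        if rid not in acc:
            acc[rid] = {
                "drugs": [],
                "events": [],
                "sex": "unknown",
                "age": None,
                "region": "unknown",
                "year": None,
                "outcomes": set(),
            }
            order.append(rid)
        rec = acc[rid]
        if (drug, role) not in rec["drugs"]:
            rec["drugs"].append((drug, role))
        if normalize(pt) not in {normalize(e) for e in rec["events"]}:
            rec["events"].append(" ".join(pt.split()))
        for logical, parse, unknown in (
            ("sex", lambda s: normalize(s) if s.strip() else "unknown", "unknown"),
            ("region", lambda s: s.strip() if s.strip() else "unknown", "unknown"),
        ):
            raw = row.get(cols[logical], "") or ""
            val = parse(raw)
            if val in ("", "unknown", None):
                continue
            if rec[logical] == unknown:
                rec[logical] = val
            elif rec[logical] != val:
                warnings.append(
                    f"line {i}: conflicting {logical} for report {rid}; keeping first"
                )
        try:
            age = _parse_optional_float(row.get(cols["age"], "") or "")
        except ValueError:
            n_malformed += 1
            continue
        if age is not None:
            if rec["age"] is None:
                rec["age"] = age
            elif rec["age"] != age:
                warnings.append(f"line {i}: conflicting age for report {rid}; keeping first")
        try:
            year = _parse_optional_int(row.get(cols["year"], "") or "")
        except ValueError:
            n_malformed += 1
            continue
        if year is not None:
            if rec["year"] is None:
                rec["year"] = year
            elif rec["year"] != year:
                warnings.append(f"line {i}: conflicting year for report {rid}; keeping first")
        raw_out = row.get(cols["outcomes"], "") or ""
        for o in raw_out.split(";"):
            o = normalize(o)
            if o and o != "unknown":
                if o not in OUTCOMES:
                    warnings.append(f"line {i}: unknown outcome {o!r} ignored")
                else:
                    rec["outcomes"].add(o)

    reports = [
        AdverseEventReport(
            report_id=rid,
            drugs=acc[rid]["drugs"],
            events=acc[rid]["events"],
            sex=acc[rid]["sex"] if acc[rid]["sex"] in SEXES else "unknown",
            age_years=acc[rid]["age"],
            region=acc[rid]["region"] if acc[rid]["region"] in REGIONS else "unknown",
            year_received=acc[rid]["year"],
            outcomes=acc[rid]["outcomes"],
        )
        for rid in order
    ]
    return LoadResult(reports=reports, n_malformed=n_malformed, warnings=warnings)


def write_reports(
    reports: Iterable[AdverseEventReport],
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write reports in the long row-per-(drug, event) dialect read by
    :func:`load_reports` (tab-delimited, canonical column order)."""
    cols = dict(DEFAULT_DIALECT)
    if dialect:
        cols.update(dialect)
    logical_order = list(DEFAULT_DIALECT)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t")
        w.writerow([cols[c] for c in logical_order])
        for r in reports:
            out = ";".join(sorted(r.outcomes))
            for drug, role in r.drugs:
                for pt in r.events:
                    w.writerow(
                        [
                            r.report_id,
                            drug,
                            role,
                            pt,
                            r.sex,
                            "" if r.age_years is None else r.age_years,
                            r.region,
                            "" if r.year_received is None else r.year_received,
                            out,
                        ]
                    )


def filter_primary_suspect(
    reports: Iterable[AdverseEventReport], drug_name: str
) -> list[AdverseEventReport]:
    """Reports naming *drug_name* as primary suspect (case-insensitive),
    in input order."""
    if not drug_name:
        raise ValueError("drug_name must be non-empty")
    return [r for r in reports if r.has_drug(drug_name, role="primary_suspect")]


def select_soc_events(
    reports: Iterable[AdverseEventReport],
    lexicon: PTLexicon,
    soc: str,
) -> tuple[list[tuple[str, str]], int]:
    """Distinct (report_id, PT) pairs whose PT maps to *soc*.

    A report with k PTs in the SOC yields k pairs; PTs absent from the
    lexicon are skipped and counted in the returned warning tally.

    Returns
    -------
    pairs : list of (report_id, canonical PT)
    n_unknown_pt : int
        Number of (report, PT) observations skipped for lacking a lexicon
        entry.
    """
    if soc not in lexicon.socs:
        raise ConfigurationError(f"SOC {soc!r} not present in lexicon")
    pairs: list[tuple[str, str]] = []
    n_unknown = 0
    for r in reports:
        seen: set[str] = set()
        for pt in r.events:
            key = normalize(pt)
            if key in seen:
                continue
            seen.add(key)
            mapped = lexicon.soc_of(pt)
            if mapped is None:
                n_unknown += 1
            elif mapped == soc:
                pairs.append((r.report_id, lexicon.canonical(pt)))
    return pairs, n_unknown


def top_k_events(
    pairs: Sequence[tuple[str, str]], k: int
) -> list[tuple[str, int]]:
    """Top-k PTs by distinct-report count (count desc, then PT asc)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    counts = Counter(pt for _, pt in set(pairs))
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return ranked[:k]
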