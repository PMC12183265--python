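"""Arithmetic ledger for docking and MM/PBSA outputs.

The endpoint free-energy decomposition obeys three additivity identities:

    ΔG_gas  = ΔE_vdw + ΔE_elec
    ΔG_solv = ΔE_GB  + ΔE_surf
    ΔTotal  = ΔG_gas + ΔG_solv

:func:`check_additivity` verifies them against a printed table, reporting
signed residuals; the default tolerance of 0.02 kJ/mol absorbs two-decimal
print rounding.  :func:`classify_binding` applies the conventional docking
activity cuts (good binding at or below −5.0, strong at or below −7.5).

Values are handled in kJ/mol as printed; docking tools conventionally
report kcal/mol, so a converter is provided but never applied implicitly.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

KCAL_TO_KJ = 4.184

COMPONENTS = ("vdw", "elec", "e_gb", "e_surf", "g_gas", "g_solv", "total")
#: aliases accepted in CSV input, mapping printed row labels to components
_ALIASES = {
    "vdwaals": "vdw", "delta_vdwaals": "vdw", "vdw": "vdw",
    "eel": "elec", "e_elec": "elec", "elec": "elec",
    "egb": "e_gb", "e_gb": "e_gb",
    "esurf": "e_surf", "e_surf": "e_surf",
    "g_gas": "g_gas", "ggas": "g_gas",
    "g_solv": "g_solv", "gsolv": "g_solv", "g_solvation": "g_solv",
    "total": "total", "dtotal": "total", "delta_total": "total",
}

IDENTITIES = (
    ("g_gas", ("vdw", "elec")),
    ("g_solv", ("e_gb", "e_surf")),
    ("total", ("g_gas", "g_solv")),
)

BINDING_TIERS = ("not_bound", "good", "strong")
GOOD_CUTOFF = -5.0   # kJ/mol
STRONG_CUTOFF = -7.5


class MissingComponentError(ValueError):
    """An additivity check was requested with components absent."""


@dataclass
class EnergyDecomposition:
    """MM/PBSA component terms (kJ/mol) with uncertainties for one complex."""

    label: str
    values: dict[str, float]
    uncertainties: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for comp, v in self.values.items():
            if comp not in COMPONENTS:
                raise ValueError(f"{self.label}: unknown component {comp!r}")
            if v != v or abs(v) == float("inf"):
                raise ValueError(f"{self.label}: non-finite value for {comp}")
        for comp, sd in self.uncertainties.items():
            if sd < 0:
                raise ValueError(f"{self.label}: negative uncertainty for {comp}")

    def to_kj(self, from_units: str = "kJ/mol") -> "EnergyDecomposition":
        """Return a kJ/mol copy; converts only when from_units='kcal/mol'."""
        if from_units == "kJ/mol":
            return self
        if from_units != "kcal/mol":
            raise ValueError(f"unknown units {from_units!r}")
        return EnergyDecomposition(
            label=self.label,
            values={k: v * KCAL_TO_KJ for k, v in self.values.items()},
            uncertainties={k: v * KCAL_TO_KJ for k, v in self.uncertainties.items()},
        )


@dataclass
class IdentityCheck:
    identity: str       # e.g. "g_gas = vdw + elec"
    reported: float
    component_sum: float
    residual: float     # reported − sum, signed
    passed: bool


@dataclass
class DockingScore:
    ligand: str
    target: str
    binding_energy: float  # kJ/mol as printed

    def __post_init__(self) -> None:
        e = self.binding_energy
        if e != e or abs(e) == float("inf"):
            raise ValueError("binding energy must be finite")


def check_additivity(
    d: EnergyDecomposition, tol: float = 0.02
) -> list[IdentityCheck]:
    """Verify the three decomposition identities; pass iff |residual| <= tol."""
    missing = [c for c in COMPONENTS if c not in d.values]
    if missing:
        raise MissingComponentError(
            f"{d.label}: missing components {missing}"
        )
    checks = []
    for target, parts in IDENTITIES:
        s = sum(d.values[p] for p in parts)
        resid = d.values[target] - s
        checks.append(IdentityCheck(
            identity=f"{target} = {' + '.join(parts)}",
            reported=d.values[target],
            component_sum=s,
            residual=resid,
            passed=abs(resid) <= tol,
        ))
    return checks


def classify_binding(score: DockingScore | float) -> str:
    """Docking activity tier from the binding energy (kJ/mol).

    <= −7.5 → "strong"; (−7.5, −5.0] → "good"; > −5.0 → "not_bound".
    Boundaries belong to the stronger tier.
    """
    e = score.binding_energy if isinstance(score, DockingScore) else float(score)
    if e <= STRONG_CUTOFF:
        return "strong"
    if e <= GOOD_CUTOFF:
        return "good"
    return "not_bound"


def load_decompositions(path: str | Path) -> dict[str, EnergyDecomposition]:
    """Read a long-format CSV (complex, component, value, sd) into
    per-complex decompositions.  Component labels are matched through the
    usual MM/PBSA aliases (VDWAALS, EEL, EGB, ESURF, ...)."""
    rows: dict[str, dict[str, float]] = {}
    sds: dict[str, dict[str, float]] = {}
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            comp_raw = (rec.get("component") or "").strip().lower().replace("δ", "")
            comp = _ALIASES.get(comp_raw.strip("_ "))
            if comp is None:
                raise ValueError(f"unrecognised component label {rec.get('component')!r}")
            label = (rec.get("complex") or "").strip()
            rows.setdefault(label, {})[comp] = float(rec["value"])
            if rec.get("sd") not in (None, ""):
                sds.setdefault(label, {})[comp] = float(rec["sd"])
    return {
        label: EnergyDecomposition(label=label, values=vals,
                                   uncertainties=sds.get(label, {}))
        for label, vals in rows.items()
    }


def reference_decompositions() -> dict[str, EnergyDecomposition]:
    """The two published MD complexes as EnergyDecomposition objects."""
    from cardiosig import reference_tables as ref

    return {
        label: EnergyDecomposition(
            label=label,
            values={k: v for k, (v, _) in comps.items()},
            uncertainties={k: sd for k, (_, sd) in comps.items()},
        )
        for label, comps in ref.TABLE4.items()
    }
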