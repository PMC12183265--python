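"""Published reference values for the osimertinib cardiac-safety cohort.

These constants transcribe the printed summary tables of a FAERS/OpenVigil
extract (Q4 2015 – Q4 2024, osimertinib as primary suspect): per-PT report
counts with ROR and 95% CI, demographic and outcome strata, MM/GBSA energy
decompositions for the osimertinib–AKT1 and –ALB complexes, and docking
binding energies for the ten hub targets.  They are inputs to the
deterministic fixture builder and the reconstruction of the unpublished
background 2x2 cells; nothing in the package fits to them at run time.
"""

from __future__ import annotations

#: reports included in the extract after screening
TOTAL_INCLUDED = 15_382
#: reports in the cardiac-disorders SOC
TOTAL_CARDIAC = 274

#: the five most frequent cardiac PTs: count, share of cardiac reports (%),
#: share of all included reports (%), and printed ROR with 95% CI
TABLE2: dict[str, dict] = {
    "Pericardial effusion": {
        "n": 59, "pct_cardiac": 21.53, "pct_all": 0.38,
        "ror": 3.90, "ci": (3.02, 5.04),
    },
    "Cardiomyopathy": {
        "n": 47, "pct_cardiac": 17.15, "pct_all": 0.31,
        "ror": 5.31, "ci": (3.98, 7.08),
    },
    "Cardiotoxicity": {
        "n": 42, "pct_cardiac": 15.33, "pct_all": 0.27,
        "ror": 5.03, "ci": (3.71, 6.83),
    },
    "Cardiac failure acute": {
        "n": 25, "pct_cardiac": 9.12, "pct_all": 0.16,
        "ror": 5.15, "ci": (3.47, 7.64),
    },
    "Cardiac dysfunction": {
        "n": 24, "pct_cardiac": 8.76, "pct_all": 0.16,
        "ror": 6.02, "ci": (4.02, 9.00),
    },
}

#: per-PT strata counts; within each dimension counts sum to the PT total
#: except ``year``, where the unprinted remainder is treated as unknown
TABLE3: dict[str, dict[str, dict]] = {
    "Pericardial effusion": {
        "sex": {"female": 35, "male": 19, "unknown": 5},
        "age_band": {"<60": 9, "60-80": 21, ">80": 3, "unknown": 26},
        "outcome": {"death": 10, "disabled": 1, "life_threatening": 8,
                    "hospitalization": 34, "other": 6},
        "year": {2020: 8, 2021: 5, 2022: 5, 2023: 10},
        "region": {"Asia": 18, "Americas": 10, "Europe": 8, "Australia": 0},
    },
    "Cardiomyopathy": {
        "sex": {"female": 26, "male": 9, "unknown": 12},
        "age_band": {"<60": 1, "60-80": 22, ">80": 6, "unknown": 18},
        "outcome": {"death": 6, "disabled": 1, "life_threatening": 4,
                    "hospitalization": 17, "other": 19},
        "year": {2020: 5, 2021: 4, 2022: 5, 2023: 8},
        "region": {"Asia": 13, "Americas": 15, "Europe": 4, "Australia": 0},
    },
    "Cardiotoxicity": {
        "sex": {"female": 21, "male": 13, "unknown": 8},
        "age_band": {"<60": 3, "60-80": 17, ">80": 6, "unknown": 16},
        "outcome": {"death": 4, "disabled": 0, "life_threatening": 3,
                    "hospitalization": 9, "other": 26},
        "year": {2020: 7, 2021: 6, 2022: 6, 2023: 11},
        "region": {"Asia": 22, "Americas": 8, "Europe": 9, "Australia": 0},
    },
    "Cardiac failure acute": {
        "sex": {"female": 14, "male": 11, "unknown": 0},
        "age_band": {"<60": 1, "60-80": 16, ">80": 7, "unknown": 1},
        "outcome": {"death": 5, "disabled": 0, "life_threatening": 3,
                    "hospitalization": 17, "other": 0},
        "year": {2020: 2, 2021: 3, 2022: 3, 2023: 2},
        "region": {"Asia": 10, "Americas": 2, "Europe": 1, "Australia": 0},
    },
    "Cardiac dysfunction": {
        "sex": {"female": 11, "male": 5, "unknown": 8},
        "age_band": {"<60": 1, "60-80": 11, ">80": 3, "unknown": 9},
        "outcome": {"death": 6, "disabled": 0, "life_threatening": 4,
                    "hospitalization": 9, "other": 5},
        "year": {2020: 2, 2021: 1, 2022: 3, 2023: 3},
        "region": {"Asia": 12, "Americas": 1, "Europe": 0, "Australia": 1},
    },
}

#: MM/GBSA decomposition (kJ/mol, mean ± sd) for the two MD complexes
TABLE4: dict[str, dict[str, tuple[float, float]]] = {
    "AKT1": {
        "vdw": (-59.19, 0.32),
        "elec": (-21.90, 1.43),
        "e_gb": (44.24, 1.76),
        "e_surf": (-7.79, 0.06),
        "g_gas": (-81.09, 1.47),
        "g_solv": (36.46, 1.76),
        "total": (-44.63, 2.29),
    },
    "ALB": {
        "vdw": (-60.67, 1.43),
        "elec": (-5.32, 2.07),
        "e_gb": (30.03, 0.62),
        "e_surf": (-6.96, 0.03),
        "g_gas": (-65.99, 2.52),
        "g_solv": (23.08, 0.62),
        "total": (-42.92, 2.59),
    },
}

#: vina binding energies (kJ/mol as printed) for the two strongest binders
DOCKING_ENERGIES: dict[str, float] = {"AKT1": -9.9, "ALB": -8.4}

#: the ten hub targets reported for the osimertinib-CAR intersection network
HUB_TARGETS = ("AKT1", "EGFR", "SRC", "ESR1", "ALB",
               "CASP3", "MMP9", "IGF1", "IL2", "PPARG")
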