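"""Generate a synthetic spontaneous-report extract and select the cardiac
cohort, exercising the full report-store chain: generation with known
ground truth, primary-suspect filtering, SOC selection and top-k ranking.

Writes results/simulated_cohort.json; the raw report table goes to
scratch/ (regenerate with this script).
"""

import json
from pathlib import Path

from cardiosig import report_store as rs
from cardiosig import synthetic_faers as sf

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"
SCRATCH = ROOT / "scratch"

CARDIAC_EVENTS = ["Pericardial effusion", "Cardiomyopathy", "Cardiotoxicity",
                  "Cardiac failure acute", "Cardiac dysfunction"]
DECOY_EVENTS = ["Diarrhoea", "Rash", "Paronychia", "Stomatitis"]


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    SCRATCH.mkdir(exist_ok=True)

    # one target drug against a comparator background; cardiac PTs carry
    # injected relative risks in the 4-6 range seen for the real signals
    events = [(pt, 0.02) for pt in CARDIAC_EVENTS] + [
        (pt, (1 - 0.02 * len(CARDIAC_EVENTS)) / len(DECOY_EVENTS))
        for pt in DECOY_EVENTS
    ]
    drugs = [("osimertinib", 0.15)] + [
        (f"comparator{i:02d}", 0.85 / 10) for i in range(10)
    ]
    config = sf.SimulationConfig(
        n_reports=20_000,
        drug_catalog=drugs,
        event_catalog=events,
        signals=[("osimertinib", pt, lam) for pt, lam in
                 zip(CARDIAC_EVENTS, (3.9, 5.3, 5.0, 5.2, 6.0))],
        seed=1,
    )
    reports, truth = sf.generate_reports(config)
    rs.write_reports(reports, SCRATCH / "simulated_reports.tsv")

    lexicon = sf.fixture_lexicon()
    cohort = rs.filter_primary_suspect(reports, "osimertinib")
    pairs, n_unknown = rs.select_soc_events(cohort, lexicon, sf.CARDIAC_SOC)
    top = rs.top_k_events(pairs, 5)

    summary = {
        "n_reports": len(reports),
        "n_primary_suspect_osimertinib": len(cohort),
        "n_cardiac_pairs": len(pairs),
        "n_unknown_pts": n_unknown,
        "top5_cardiac_events": [{"pt": pt, "n": n} for pt, n in top],
        "injected_relative_risks": {pt: lam for pt, lam in
                                    zip(CARDIAC_EVENTS, (3.9, 5.3, 5.0, 5.2, 6.0))},
    }
    (RESULTS / "simulated_cohort.json").write_text(json.dumps(summary, indent=2) + "\n")

    print(f"generated {len(reports)} reports "
          f"({len(cohort)} osimertinib primary-suspect)")
    print(f"cardiac pairs: {len(pairs)}; top-5 PTs:")
    for pt, n in top:
        print(f"  {pt:<24s} {n}")


if __name__ == "__main__":
    main()
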