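"""Descriptive tables for the cardiac cohort: per-PT shares of the SOC and
of the full extract, demographic strata, and outcome rates.

Writes results/share_table.csv, results/strata.csv and
results/outcome_rates.csv.
"""

from pathlib import Path

import pandas as pd

from cardiosig import cohort_summary as cs
from cardiosig import reference_tables as ref
from cardiosig import synthetic_faers as sf
from cardiosig.report_store import select_soc_events

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    reports, _ = sf.fixture_from_table2()
    pairs, _ = select_soc_events(reports, sf.fixture_lexicon(), sf.CARDIAC_SOC)

    shares = cs.share_table(pairs, ref.TOTAL_CARDIAC, ref.TOTAL_INCLUDED)
    shares.to_csv(RESULTS / "share_table.csv")

    rows = []
    for dim in cs.DIMENSIONS:
        for t in cs.stratify(pairs, reports, dim):
            for level, n, pct in t.rows:
                rows.append({"dimension": dim, "pt": t.pt, "level": level,
                             "count": n, "percent": pct})
    pd.DataFrame(rows).to_csv(RESULTS / "strata.csv", index=False)

    rates = cs.outcome_rates(pairs, reports)
    rates.to_csv(RESULTS / "outcome_rates.csv")

    top5 = shares.head(5)
    print("per-PT shares (top 5):")
    print(top5.to_string())
    print("\nmortality by PT (%):")
    print(rates["death"].sort_values(ascending=False).to_string())
    print(f"\nhighest mortality: {rates['death'].idxmax()} "
          f"({rates['death'].max():.2f}%); "
          f"highest life-threatening rate: "
          f"{rates['life_threatening'].idxmax()} "
          f"({rates['life_threatening'].max():.2f}%)")


if __name__ == "__main__":
    main()
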