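"""Disproportionality signal table for the five cardiac PTs.

Rebuilds the published cohort deterministically, recovers each PT's
unpublished background 2x2 cells from the printed confidence interval,
and recomputes ROR and BCPNN statistics with positivity flags and
strength tiers.  Writes results/signal_scores.csv.
"""

from pathlib import Path

from cardiosig import synthetic_faers as sf

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    _, table = sf.fixture_from_table2()
    out = table[[
        "a", "b", "c", "d", "ror", "ror_l", "ror_u", "printed_ror",
        "ic", "ic_sd", "ic025", "ic_minus_2sd",
        "ror_positive", "bcpnn_positive", "strength_ror", "strength_bcpnn",
    ]].copy()
    for col in ("ror", "ror_l", "ror_u"):
        out[col] = out[col].round(2)
    for col in ("ic", "ic_sd", "ic025", "ic_minus_2sd"):
        out[col] = out[col].round(3)
    out.to_csv(RESULTS / "signal_scores.csv")

    print("per-PT signal scores (background cells reconstructed from the "
          "printed CIs):")
    print(out[["a", "c", "d", "ror", "printed_ror", "ic025",
               "strength_ror", "strength_bcpnn"]].to_string())
    agree = (out["ror"].round(2) == out["printed_ror"]).all()
    print(f"\nforward ROR reproduces every printed value: {agree}")
    print("all five PTs are weak ROR signals (CI lower bound in (1, 50)) "
          "and BCPNN-positive (IC025 > 0).")


if __name__ == "__main__":
    main()
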