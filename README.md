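# cardiosig

Pharmacovigilance signal detection and network pharmacology for
drug-induced cardiac adverse reactions, built around the osimertinib
cardiac-safety cohort (FAERS/OpenVigil extract, Q4 2015 – Q4 2024).

Osimertinib, a third-generation EGFR kinase inhibitor, is associated with
disproportionately reported cardiac adverse events — pericardial
effusion, cardiomyopathy, cardiotoxicity, acute cardiac failure and
cardiac dysfunction.  `cardiosig` is for pharmacoepidemiologists and
computational pharmacologists who want that analysis chain as tested,
reusable code: spontaneous-report cohort selection, disproportionality
statistics with the standard positivity rules, descriptive strata,
protein-interaction hub ranking, gene-set enrichment, and an arithmetic
audit of binding-energy tables.

## What it computes

For a drug–event pair with 2x2 report counts (a, b, c, d):

* **Reporting odds ratio** — ROR = (a·d)/(b·c), Woolf interval
  se(ln ROR) = √(1/a + 1/b + 1/c + 1/d), CI = exp(ln ROR ± 1.96 se);
  Haldane–Anscombe +0.5 on zero cells.  Signal: n ≥ 3 and CI lower
  bound > 1; tiers weak/moderate/strong at lower bound 50 and 1000.
* **BCPNN information component** — IC = log2 p(d,e)/(p(d)p(e)) under
  conjugate Beta posteriors; exact digamma/trigamma posterior moments
  (delta-method closed form available as an option).  Signal: n ≥ 3 and
  IC025 > 0; tiers on IC − 2SD at 1.5 and 3.0 bits.
* **Inverse table reconstruction** — printed (n, ROR CI) rows are
  inverted back to integer background cells via the Woolf identity, so
  unpublished 2x2 tables can be recovered and re-analyzed.
* **Network centralities** — degree, betweenness, closeness and maximal
  clique centrality MCC(v) = Σ_C (|C|−1)! over maximal cliques C ∋ v,
  on STRING-dialect networks thresholded at combined score ≥ 900.
* **Enrichment** — one-sided hypergeometric P(X ≥ k) on GMT gene sets
  with Benjamini–Hochberg correction.
* **Energy ledger** — MM/GBSA additivity (ΔG_gas = ΔE_vdw + ΔE_elec,
  ΔG_solv = ΔE_GB + ΔE_surf, ΔTotal = ΔG_gas + ΔG_solv) and docking
  activity tiers (good ≤ −5.0, strong ≤ −7.5 kJ/mol).

A synthetic report generator (independence background + injected
relative-risk signals, analytic ground truth) supports null calibration
and signal-recovery experiments; a deterministic fixture rebuilds the
published cohort tables exactly.  See `docs/methods.md` for assumptions
and limitations.

## Worked example

Recover the background cells behind the printed cardiac-dysfunction row
(24 cases among 15,382 drug reports, CI 4.02–9.00) and score the pair:

```python
from cardiosig.disproportionality import reconstruct_background, score_table

t = reconstruct_background(a=24, b=15_382 - 24, ror_l=4.02, ror_u=9.00)
print(t)                      # ContingencyTable(a=24, b=15358, c=1857, d=7148290)
s = score_table(t)
print(round(s.ror, 2))        # 6.02
print(round(s.ic025, 3))      # 1.706
print(s.strength_ror, s.strength_bcpnn)   # weak moderate
```

The forward ROR on the reconstructed integer table reproduces the printed
6.02; the pair is ROR-positive (weak, lower bound 4.02 ∈ (1, 50)) and
BCPNN-positive (IC025 > 0, moderate at IC − 2SD ≈ 1.7 bits).

The numbered drivers under `analysis/` run the full chain and write
tables to `results/`:

```
python analysis/01_simulate_cohort.py    # synthetic extract + cohort selection
python analysis/02_signal_scores.py      # per-PT ROR/BCPNN signal table
python analysis/03_cohort_tables.py      # shares, strata, outcome rates
python analysis/04_network_hubs.py       # target merge, PPI hubs, enrichment
python analysis/05_energy_ledger.py      # MM/GBSA additivity + docking tiers
```

For example `02_signal_scores.py` prints, per PT, the reconstructed
cells and forward statistics — pericardial effusion: a=59, c=18,169,
d=18,409,871, ROR 3.90, IC025 1.509, weak/moderate — and confirms the
forward ROR matches every printed value.  `03_cohort_tables.py` reports
pericardial effusion at 21.53% of cardiac reports (0.38% of the full
extract) and cardiac dysfunction as the deadliest PT (25.00% mortality,
16.67% life-threatening).

There is also a thin CLI (`cardiosig cohort|simulate|signals|summarize|
network|enrich|ledger`); run any subcommand with `--help`.

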