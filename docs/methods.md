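# Methods

## Scope and data model

`cardiosig` implements the desk-scale statistical chain of a
pharmacovigilance + network-pharmacology study of osimertinib-induced
cardiac adverse reactions (CAR).  The unit of observation is the
spontaneous adverse-event report: drugs with reporter-assigned roles
(primary suspect / secondary suspect / concomitant), MedDRA preferred
terms (PTs) for the events, sex, age, region, year received, and outcome
flags.  The cohort rule is the standard OpenVigil-style extraction:
reports naming the target drug as *primary suspect*, with events selected
through a flat PT → system-organ-class (SOC) lexicon supplied as input
(the package ships no MedDRA content; the packaged fixture lexicon covers
only the PTs its fixture emits).  Name matching is case-insensitive after
whitespace normalization; no synonym or drug-name standardization is
attempted.

The original extract (FAERS via OpenVigil, Q4 2015 – Q4 2024; 15,382
included reports, 274 cardiac) is not deposited, so two substitutes are
provided and clearly separated:

* a **synthetic generator** with analytic ground truth, used for
  calibration and recovery experiments;
* a **deterministic fixture** that rebuilds the published cohort tables
  exactly (counts, strata, outcomes), with the unpublished background
  cells of each 2x2 recovered analytically (below).

## Disproportionality statistics

For each drug–event pair the 2x2 table (a, b, c, d) counts distinct
reports: a = target drug & target event, b = drug & other events,
c = other drugs & event, d = neither.

**ROR.** ROR = (a·d)/(b·c) with the Woolf log-scale interval,
se(ln ROR) = √(1/a + 1/b + 1/c + 1/d), CI = exp(ln ROR ± 1.96·se).  Any
zero cell triggers the Haldane–Anscombe correction (+0.5 to all four
cells), flagged on the result.  Positivity: n ≥ 3 cases and CI lower
bound > 1.  Strength tiers on the lower bound: (1, 50) weak, [50, 1000)
moderate, ≥ 1000 strong.  The tier statistic "ROR − 1.96SE" is read as
the lower 95% bound on the ROR scale, exp(ln ROR − 1.96·se) — the only
reading consistent with a printed CI column; tier gaps are half-open
[lower, upper).

**BCPNN information component.**  IC = log2 p(d,e)/(p(d)·p(e)) with the
classical conjugate parametrization: independent Beta posteriors for the
cell, p11 ~ Beta(a + γ11, N − a + γ − γ11) with γ11 = 1 and
γ = (N + 2)²/((a+b+1)(a+c+1)), and for the margins,
p_d ~ Beta(a+b+1, N−(a+b)+1), p_e ~ Beta(a+c+1, N−(a+c)+1).
Posterior moments of IC are computed **exactly** via digamma/trigamma:

    E[IC]   = [ψ(α11) − ψ(α11+β11) − ψ(αd) + ψ(αd+βd) − ψ(αe) + ψ(αe+βe)] / ln 2
    V[IC]   = [ψ′(α11) − ψ′(α11+β11) + ψ′(αd) − ψ′(αd+βd) + ψ′(αe) − ψ′(αe+βe)] / (ln 2)²

The familiar closed form log2 of the ratio of posterior means with a
delta-method variance is the first-order approximation of the same model;
it is exposed as `method="approx"`.  The exact moments are the default
because they are what a posterior-sampling oracle converges to: at table
(25, 75, 900, 9000) the approximation sits ≈ 0.02 bits from the true
posterior mean, two orders of magnitude beyond the Monte-Carlo error of a
10⁶-draw check, while the exact moments agree within sampling error (the
test suite verifies this on a 5x5 grid).  Positivity: n ≥ 3 and
IC025 = E[IC] − 1.96·SD > 0 (the moment-based bound; a posterior-quantile
variant would require sampling and is not implemented).  Tiers on
IC − 2·SD: (0, 1.5] weak, (1.5, 3.0] moderate, > 3.0 strong, with the
quoted boundary inclusivity.

**Inverse reconstruction.**  Published per-PT rows give (a, CI) but not
the background cells.  With b fixed by the drug total, the printed CI
determines the point ROR (geometric mean of the bounds) and
se = (ln u − ln l)/(2·1.96); the Woolf identity
1/c + 1/d = se² − 1/a − 1/b and the odds identity c/d = (a/b)/ROR then
fix c and d, carried at full floating precision and rounded to integers
once at the end.  Infeasible rows (se² ≤ 1/a + 1/b) raise an explicit
error naming the slack.  A closure property holds: inverting the forward
CI of any all-cells ≥ 3 table recovers (c, d) exactly.  The per-PT
reconstructions imply mutually inconsistent full-database sizes (2-dp CI
rounding dominates), so each PT's table is treated independently; no
global N is asserted.

## Synthetic generator

Each synthetic report draws one (drug, PT) cell from
p(d, e) ∝ P(d)·P(e)·λ(d, e), λ = 1 off the injected signal cells, then
demographics and one outcome independently of the cell.  One PT per
report keeps the ground-truth cell law analytic (multi-PT merging is
exercised separately by the report-store I/O tests).  A single
`numpy.random.default_rng(seed)` stream drives everything; identical
seed + config reproduce the collection exactly.

Default catalogs use harmonic (1/rank) marginal weights, mimicking the
very uneven reporting frequencies of real drug and PT margins.  Default
demographic distributions follow the published cardiac cohort margins
(54% female / 29% male; ages concentrated in 60–80 with ≈ 35% unknown;
Asia > Americas > Europe; hospitalization the modal outcome, death 16%).
Study-condition experiments fix: null calibration at 200 drugs x 50
events, 200,000 reports, 20 seeds, eligibility expected a ≥ 5; signal
recovery at λ = 10 cells with expected a ≥ 20, 200 replicates.  The
generator does **not** emulate FAERS duplication, rechallenge,
polypharmacy interaction terms, reporting-rate drift, or
demographics–event dependence; passing calibration here shows the
statistics behave under the stated sampling law, not that real FAERS
backgrounds are this clean.

The deterministic fixture assigns strata per dimension independently in
printed-count order (dimensions are marginal in the source tables; joint
structure is not recoverable).  The five top PTs sum to 197 of 274
cardiac reports; four filler cardiac PTs (counts 20/20/20/17, all below
the fifth-ranked 24) cover the remainder without disturbing the top-5
ranking.  Published year rows do not sum to the PT totals (the final year
column is printed empty), so the unprinted remainder is year = unknown
and the year dimension carries no sum check against the printed rows.

## Cohort summaries

Denominators are distinct reports per PT.  Age bands are <60 (strict),
60–80 (both endpoints included, matching the "60∼80" notation), >80
(strict), unknown.  Reports can carry several outcome flags while the
published rows are mutually exclusive; each report is collapsed to its
most severe outcome under death > life-threatening > disabled >
hospitalization > other, which makes the outcome rows sum to 100% up to
rounding.  All percentages are rounded half-up to 2 dp (Python's
built-in `round` is half-even and reproduces the printed values
incorrectly in boundary cases).

## Network pharmacology

Disease-target merging follows floor-then-pooled-median screening: drop
entries with relevance score < 10, pool the survivors across keyword
lists, drop entries strictly below the pooled median, deduplicate keeping
the maximum score.  (The screening prose this formalizes is ambiguous;
this is the reading that uses both the floor and the median, and both
parameters are arguments.)  Intersections match uppercased symbols.

STRING-dialect TSVs keep the 0–1000 integer combined score; the "highest
confidence" 0.9 threshold is `min_score=900`, boundary inclusive.
Duplicate edges collapse to the maximum score; self-loops are dropped and
counted.  Centralities: degree = incident edge count; betweenness =
unnormalized undirected shortest-path count (ordered pairs / 2);
closeness = Wasserman–Faust within-component form scaled by
(reachable − 1)/(n − 1), 0 for isolates; MCC(v) = Σ (|C| − 1)! over
maximal cliques C containing v (an isolated node's maximal clique is
{v}, so MCC ≥ 1).  Maximal cliques come from the Bron–Kerbosch
enumerator in networkx; the test suite checks the factorial sum against
an independent subset-enumeration oracle on graphs ≤ 10 nodes.  Hub
ranking is metric desc, symbol asc.

Enrichment replaces the Metascape web service with the one-sided
hypergeometric test on user-supplied GMT collections: p = P(X ≥ k) for
population M (universe), K (term ∩ universe), n (query ∩ universe);
Benjamini–Hochberg across all terms; significance at p < 0.01 by
default.  Kappa-similarity term clustering is out of scope.

## Energy ledger

MM/GBSA decompositions obey ΔG_gas = ΔE_vdw + ΔE_elec,
ΔG_solv = ΔE_GB + ΔE_surf, ΔTotal = ΔG_gas + ΔG_solv.  The ledger
reports signed residuals (reported − component sum) and passes at
|residual| ≤ 0.02 kJ/mol, absorbing 2-dp print rounding; whether a
0.01 residual reflects rounding or independent computation upstream is
not decidable from a printed table, so the ledger reports rather than
asserts.  Docking tiers: ≤ −7.5 kJ/mol strong, (−7.5, −5.0] good,
> −5.0 not bound; boundaries go to the stronger tier ("falls below" read
as inclusive).  Units are kJ/mol as printed — docking tools usually print
kcal/mol, so an explicit kcal→kJ converter (×4.184) is provided and never
applied implicitly.

## Problem sizes and numerical choices

Calibration and recovery experiments run at the sizes stated above and
complete in well under a minute each on one core; the posterior-sampling
check uses 10⁶ draws per table on a 5x5 grid.  All randomized tests and
scripts take a single integer seed; there is no global random state.
Degenerate inputs fail loudly: empty catalogs, zero-probability joint
laws, missing lexicon SOCs, unresolvable report ids, missing energy
components and infeasible CI rows all raise typed errors rather than
returning silent defaults.

## Known limitations

* The published 33,744 → 15,382 screening split is reproduced as a
  filter chain surface only; the concrete exclusion rule is unstated in
  the source tables and is not modeled.
* Published target-list memberships (359 / 1,097 / 74) and term counts
  depend on live database versions; the package demonstrates the
  pipeline on synthetic stand-ins with planted truth of the same sizes.
* Docking poses, MD trajectories and their statistics (RMSD, RMSF, Rg,
  SASA, free-energy landscapes) are out of scope; the energy ledger
  audits printed-table arithmetic only.
* IC025 is the moment-based bound, not a posterior quantile.
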