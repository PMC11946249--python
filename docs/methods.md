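# Methods

## Analysis unit and data model

The unit of every count is the deduplicated safety report. Raw FAERS
quarterly extracts are "$"-delimited tables (DEMO, DRUG, REAC, OUTC,
INDI, THER) joined on PRIMARYID; one case (CASEID) may appear under
several PRIMARYIDs as follow-ups are submitted. The pipeline:

1. **Ingest** — parses each table with a column-alias map so both the
   pre-2014Q3 (ISR/CASE/GNDR_COD) and the current dialect load; rows
   with a wrong field count or an invalid key/code are skipped and
   tallied, never silently repaired.
2. **Assemble** — one `CaseReport` per DEMO row; child rows grouped by
   PRIMARYID; reports without any reaction row are dropped (the
   analysis object is a report–event pair); ages normalized to years
   with the FAERS unit conventions (DEC×10, YR×1, MON÷12, WK÷52.1775,
   DY÷365.25, HR÷8766).
3. **Deduplicate** — within each CASEID keep the submission with the
   latest FDA receipt date; ties go to the numerically higher
   PRIMARYID (zero-padded lexicographic comparison, exact for FAERS's
   numeric-string ids). A missing receipt date loses every tie-break
   rather than aborting the run. The rule pair is idempotent, and on
   synthetic data recovers the generator's distinct-case count exactly.
4. **DILI consolidation** — before any drug search, every PT in the
   liver-injury lexicon is rewritten to the single event "DILI" and the
   report's PT set deduplicated, so a report listing ALT and AST
   elevations contributes one DILI event, not two. The lexicon (~40
   PTs: transaminase/bilirubin/enzyme elevations, hepatic failure and
   necrosis, hepatitis terms, cholestasis and jaundice, hepatomegaly,
   hepatic encephalopathy, …) ships as an editable YAML config because
   the case definition is exactly as strong as its term list.
5. **Drug identification** — verbatim drug strings are matched
   case-insensitively, after whitespace normalization, against a
   dictionary of generic and brand names per study drug; unmatched
   names stay verbatim and simply fall into the background. Only
   primary-suspect (PS) rows qualify a report for a drug cohort by
   default (configurable), keeping the counting unit unambiguous.

## Contingency tables

For drug D and event X (a PT, a SOC, or the consolidated DILI event),
a = reports with D and X, b = D without X, c = X without D, d =
neither; the comparator is the full ingested dataset. A report counts
once in the drug margin regardless of how many qualifying PTs it
lists; at SOC level it is in the event margin if at least one PT maps
to that SOC. Cells therefore partition the report set for every pair,
and all of a drug's tables share the same N.

## Signal statistics

ROR = ad/bc with the 95% Wald interval on the log scale; PRR in cohort
form with Pearson χ² without continuity correction (a Yates variant is
available by configuration). Any zero cell makes ROR undefined, and
c = 0 makes PRR undefined — statistics are never continuity-corrected
silently; the a ≥ 3 flagging rule makes the zero-cell region
practically irrelevant anyway.

MGPS follows DuMouchel: a ~ Poisson(λE), λ from a two-component gamma
mixture. The five hyperparameters are fitted once per run, pooled over
every drug's PT-level tables (at least 50 tables with E > 0 are
required; smaller runs fall back to the default prior
(0.2, 0.1, 2.0, 4.0, 1/3) with a run-log note). Fitting maximizes the
exact negative-binomial marginal likelihood with multi-start L-BFGS-B
in unconstrained coordinates (log shapes/rates, logit weight) from the
default start plus three fixed alternatives — deterministic given the
data. The posterior over λ is again a two-gamma mixture with
components Gamma(αk + a, βk + E); EBGM = exp(E[ln λ]) via the digamma
function, and EBGM05 solves the mixture CDF = 0.05 by bracketed root
finding (the component quantiles bound the mixture quantile
analytically; tolerance 1e−10, validated against quadrature to 1e−6).

BCPNN IC is reported on the shrunk observed-to-expected scale. The
default `paper_compat` mode sets IC = log₂(EBGM) and IC025 = IC − 1.66:
in the published tables this package mirrors, every (IC, EBGM) pair
satisfies the log₂ identity and every (IC, IC025) pair differs by a
constant 1.66 regardless of the report count, so the mode encodes the
de-facto convention without endorsing it — no standard credible
interval produces a count-independent offset. The `credible_interval`
mode is the statistically preferred alternative: IC025 = log₂ of the
posterior 2.5th percentile of λ.

Flags: ROR requires a ≥ 3 and CI low > 1; PRR requires a ≥ 3, PRR ≥ 2,
χ² ≥ 4; BCPNN requires IC025 > 0; MGPS requires EBGM05 > 2. The
combined signal is the conjunction of all four — a deliberately
conservative intersection whose type-I behaviour the acceptance checks
measure directly. No multiple-testing adjustment is applied, matching
standard practice for threshold-based signal counts. Ranking drops PTs
matching the exclusion lists (defaults: death terms, COVID terms, and
an explicit, editable malignancy-progression list — metastasis PTs are
often the indication, not the drug effect, but practice varies), keeps
combined-flag rows, sorts by report count with EBGM then PT name as
tie-breaks, and returns the top k (default 30). Reported statistics
round to 2 decimals, half away from zero.

## Descriptive profiles

Sex, country (United States/Japan/China/Other), reporter occupation
(Physician, Pharmacist, Consumer, Other health professionals), outcome
and time-to-onset blocks, overall and for the DILI subset. FAERS allows
several outcome codes per report, but a table summing to 100% needs one
outcome per report, so a severity precedence is applied: Death >
Hospitalization > Life threatening > Disability > Other serious
(pooling OT, CA, RI) > Unknown. Onset = event date − earliest therapy
start, binned half-open [0,7), [7,28), [28,60), [60,∞); a boundary
onset of exactly 7 days belongs to 7–28, and negative or missing onsets
go to Unknown. Every block's Unknown category absorbs all missingness,
so counts always sum to the cohort total; age mean ± SD uses
non-missing normalized ages only (a single-report cohort reports SD 0
with a degeneracy flag).

## Synthetic report generator

The generator emulates the multi-table FAERS structure end to end:
per report one PS drug (marginals over five study drugs, remainder a
background-drug pool), 1 + Poisson(pts_per_report − 1) distinct PTs
sampled without replacement with drug-conditional probabilities
q_d(pt) ∝ background(pt)·rrr(d,pt), demographics with FAERS unit codes
and configurable missingness, outcome codes, therapy dates with an
exponential onset (mean 30 days), and case re-submissions: with
probability `duplicate_rate` a case reappears under a higher PRIMARYID
with a strictly later FDA_DT and all child rows copied verbatim, making
dedup correctness decidable from keys alone. Everything is
deterministic given the seed.

`expected_table` returns the exact expected 2×2 cells under this model
for one-PT-per-report configurations, where the closed form is clean;
multi-PT without-replacement sampling has no tractable closed form, so
the oracle refuses rather than approximate.

### Reference study conditions

`default_study_config` is the package's reference scenario: five drugs
with report-share marginals echoing their relative cohort sizes (3.5%,
1.6%, 2.1%, 1.3%, 1.5% of reports), a 68-PT background vocabulary with
liver terms at ~0.5% combined share (≈1% of reports at the default two
PTs per report), duplicate rate 8%, 10% missing ages and 55% missing
dates. Injected signals: graded liver-injury associations specified as
drug-level observed-to-expected targets (3.45, 5.03, 4.34, 2.37, 1.48
— strongest for ceritinib, weakest for lorlatinib) applied uniformly
across all liver PTs, plus distinctive non-liver signals (ocular terms
for crizotinib, GI/CNS-metastasis for ceritinib, constipation and
hemolytic anemia for alectinib, CPK elevation for brigatinib, lipid
and psychiatric terms for lorlatinib).

Because PT shares renormalize within a report, a raw multiplier does
not realize its nominal ratio: strong competing signals drag the other
shares down, and the other study cohorts sit in the comparator with
elevated liver rates. The config therefore calibrates the raw
multipliers by a deterministic fixed point on the closed-form
multinomial model so the *realized* per-PT share ratio hits the target.
A residual attenuation of order 5–10% remains at the report level
(multi-PT draws are without replacement, which lifts the comparator's
event rate slightly more than the cohort's), so the weakest flagged
association — crizotinib's, with an expected IC025 within one standard
error of zero at n = 10⁵ — is marginal and seed-dependent, much as a
borderline real-world signal would be.

### What the generator does not emulate

No confounding by age/sex/indication (demographics are independent of
drug and event), no drug–drug interaction structure, no secular
reporting trends or Weber effect, no verbatim-name misspellings, and a
68-term vocabulary instead of MedDRA's ~25,000 PTs. Passing tests
therefore demonstrate that the machinery counts, shrinks and classifies
correctly under a known model — not that the thresholds have any
particular operating characteristics on real FAERS data, where
confounding and reporting artefacts dominate.

## Verification strategy

Every statistic has an independent oracle: exact rational (Fraction)
arithmetic for ROR/PRR/χ²/O-E; closed-form gamma posteriors (digamma,
χ² quantile) and adaptive quadrature of the posterior mixture for
EBGM/EBGM05; the generator's closed-form expected cells for the
counting path; and the generator's manifest for dedup. Operating
characteristics are measured, not assumed: on all-null data (every
rrr = 1, n = 10⁵, 20 seeds) the combined-flag rate across observed
drug–PT pairs stays ≤ 1%, and injected rrr = 5 pairs with expected
a ≥ 20 are recovered in ≥ 95% of 20 seeded runs. Problem sizes in the
test suite (n between 400 and 10⁶ per test, chosen to keep each oracle
sharp at modest runtime) are stated in the tests themselves.

## Known limitations

- The DILI lexicon is a curated default, not a licensed SMQ; the case
  definition is exactly as good as the configured term list.
- The bundled PT→SOC hierarchy is synthetic; real analyses must supply
  a MedDRA mapping.
- `paper_compat` IC025 is a literature-compatibility convention, not a
  credible bound; use `credible_interval` for inference.
- Exact drug-name matching only — no fuzzy matching or RxNorm
  normalization.
- No stratification, time-slicing or regression adjustment; comparator
  contamination by the other study cohorts is inherent to the
  all-database background and becomes material when study drugs are a
  large fraction of the database (as in compact synthetic runs).
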