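# Methods

## Problem and model

`faerskit` screens a spontaneous-report database for drug–event signals by
disproportionality. The unit of analysis is the unique report. For a target
event (a MedDRA preferred term, matched exactly after case-folding and
whitespace normalization — no SMQ expansion) and each candidate drug, the
database partitions into the four-fold table (a, b, c, d): a multi-drug
report contributes to the `a` cell of every drug it names, and a report
naming a drug more than once still counts once. The statistics are

- ROR = ad/bc with SE(ln ROR) = √(1/a + 1/b + 1/c + 1/d) and the Wald 95% CI
  exp(ln ROR ± 1.96·SE); 1.96 is used literally as the normal quantile;
- PRR = [a/(a+b)]/[c/(c+d)] with the Yates-corrected
  χ² = (|ad − bc| − N/2)²·N/[(a+b)(c+d)(a+c)(b+d)], clamped to 0 when the
  correction overshoots (|ad − bc| ≤ N/2), since a squared corrected
  statistic cannot be negative;
- signal ⇔ a ≥ 3 and (ROR CI lower bound > 1, or PRR ≥ 2 and χ² ≥ 4).

Zero cells leave the ROR undefined by default (the ratio ad/bc is
degenerate, and the a ≥ 3 gate already excludes the pathological cases); a
Haldane–Anscombe +0.5 correction is available as an opt-in policy. The PRR
is undefined when a+b = 0, c+d = 0 or c = 0. Undefined results are encoded
(`defined=False`, NaN fields), never raised.

Screening ranks drugs by `a` descending (name ascending on ties) and keeps
the top *n* (default 30, the scale at which such screens are typically
read); signal-strength ordering by ROR is a view on the result. Category
rollup rebuilds the table per therapeutic category by set-union: a report
counts once toward a category however many member drugs it names, and a
report spanning several categories counts in each. Every category table
therefore partitions the full dataset (category N = dataset N), and
category `a` is bounded by the sum of member-drug `a` values.

No multiplicity adjustment is applied: the thresholds above are the
conventional operating points of frequentist pharmacovigilance screening,
and the package reports per-pair decisions, not family-wise error control.

## Cleaning

1. **Standardization** — exact case-insensitive synonym lookup against a
   user-supplied map; unresolved names keep their verbatim form (flagged,
   never dropped); combination products keep a single combined identity.
   Standardization runs before deduplication so duplicate keys compare
   standardized names (configurable; the alternative order is exposed
   because source descriptions of such pipelines leave it open).
2. **Deduplication** — records are grouped by (case identifier, set of
   standardized drug names); within a group only the latest receipt date
   survives, with missing dates sorting earliest (dated evidence preferred)
   and exact ties broken by the lexicographically greatest report id
   (deterministic and order-independent). This single rule subsumes both
   exact duplicates (same case/date/drugs) and superseded versions of a
   case's report for the same medication. The grouping uses the full drug
   set rather than individual drugs: dropping a multi-drug record because
   one of its drugs reappears later would discard evidence about the
   others. Idempotent by construction.
3. **Exclusion** — drug entries on the exclusion list are removed; records
   left drug-less are dropped and counted.

Stage counts (input, after dedup, after exclusion, event-matched) are
returned as a cleaning report and are monotone non-increasing.

Multi-outcome reports reduce to the most severe code under
DE > LT > HO > DS > CA > RI > OT (death worst). This conventional
seriousness hierarchy is a package choice — the reduction "keep the most
severe outcome" requires *some* total order, and this is the standard one.

## Descriptives

Sex {F, M, OTHER, NA}, age bands {<18, [18, 60), ≥60, NA} (half-open at 60
to resolve the boundary deterministically), reporter occupation, reporter
country, receipt year and most-severe outcome are tabulated with percents
recomputed as 100·count/total and rounded half-up to one decimal (display
statistics round half-up throughout; internal computation keeps full
precision). Every tabulation, NA strata included, sums to the dataset
total.

## Synthetic-report generator

The generator emulates the structure of a FAERS extract so every stage is
testable with known ground truth:

- **Exposure**: each report draws each catalog drug independently with its
  marginal reporting probability; empty draws are redrawn (≥1 drug). The
  default catalog is the 30 drugs of the worked angioedema screen with
  marginals of a few percent (common analgesics/antihypertensives higher),
  giving ≈1 drug per report on average; `mean_drugs_per_report` rescales
  the marginals when a different polypharmacy level is wanted.
- **Event**: per-report logistic odds — baseline odds from
  `background_event_rate` (default 0.02) multiplied by a true odds ratio θ
  for each exposed signal drug. With a single signal drug the population
  reporting OR equals θ exactly, making injected signals analytically
  recoverable; with several signal drugs or common events the observed ROR
  attenuates (odds-ratio non-collapsibility), which the defaults illustrate.
  Default θ: ≈46, 43.5, 31, 29, 21 for lisinopril, enalapril, perindopril,
  alteplase and ramipril (the magnitudes such a screen reports), 1
  elsewhere.
- **Demographics**: i.i.d. categorical draws patterned on a large
  angioedema case series — sex 46.9% F / 44.0% M / 0.8% other / 8.3% NA;
  age bands 4.9% <18 / 37.6% 18–60 / 36.2% ≥60 / 21.3% NA with uniform age
  within band; occupation 72.8% health-professional / 13.8% consumer;
  country led by US/FR/GB/CA; years uniform 2004–2023; most-severe-outcome
  mixture 30.1% hospitalization, 13.6% death, remainder spread over the
  other codes and none.
- **Duplicates**: ⌊dup_rate·n⌋ exact copies of randomly chosen primaries
  with fresh report ids but identical case/date/drugs — exactly the
  duplicate definition the cleaner targets. Default 12%, matching the
  typical shrinkage of a raw extract under deduplication.
- **Determinism**: one seeded `numpy.random.Generator` threads through all
  draws; identical configs give bit-identical datasets.

What the generator does *not* emulate: misspelled or verbatim trade names
(standardization is exercised with hand-built cases instead), reporting
trends over time, correlated polypharmacy, indication-channeling bias, and
country-specific demographics. Passing tests therefore demonstrate the
statistical machinery and bookkeeping, not robustness to real-world coding
noise.

`sample_tables` shares the exposure/event core with `generate` but skips
record materialisation, so calibration studies over hundreds of simulated
databases run in seconds; a test asserts statistical consistency between
the two paths.

## Validation design and problem sizes

- Contingency counts are checked against an independent double loop over
  reports (10⁴ synthetic reports for the acceptance check; 5·10³ in unit
  tests).
- ROR/SE and χ² are checked to 1e-9 relative against statsmodels'
  `Table2x2` and scipy's Yates-corrected `chi2_contingency` over randomized
  tables.
- Null calibration: with θ = 1 everywhere and expected a ≈ 55 (n = 5,000,
  exposure ≈ 11%, event rate 10%), the ROR criterion (CI lower bound > 1)
  is a one-sided 2.5% test; its firing rate over 500 simulated databases
  must fall in [1%, 4%].
- Coverage: with a single injected θ ∈ {2, 5, 20} at n = 10⁵, the 95% CI
  covers θ in 90–99% of 200 replicates.
- Published-value self-consistency: the seven printed ROR (95% CI) triplets
  of a reference angioedema screen are regenerated from their own bounds by
  `point_from_ci` to within ±0.02 (the rounding slack of two-decimal
  bounds).
- The standard test dataset is 2,000 reports at seed 42 (plus 240 injected
  duplicates), generated at test time; marginal-recovery tests use 2·10⁴
  reports with 3–4 standard-error binomial bounds.

## Known limitations

- Exact-lookup standardization only; no fuzzy matching or RxNorm/ATC
  resolution. Category and synonym maps are user-supplied inputs (the
  packaged 30-drug map is a best-effort standard therapeutic classing).
- Drug role (suspect vs concomitant) is not modelled; all reported drugs
  count. This matches extracts that do not carry a role field and is the
  conservative choice for screening.
- Frequentist ROR/PRR only — no Bayesian shrinkage (BCPNN, EBGM), no
  time-to-onset analysis, no record linkage across manufacturers.
- Disproportionality quantifies reporting imbalance, not incidence or
  causation; signals are hypotheses for clinical review.
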