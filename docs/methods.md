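# Methods

## Deduplication and parsing

FAERS quarterly extracts are dollar-delimited ASCII with no quoting or
escaping; files are decoded as UTF-8 with replacement because legacy
extracts contain stray bytes.  Ragged lines are skipped and counted, never
silently repaired.  Deduplication follows the FDA guidance: one record per
CASE_ID keeping the most recent FDA_DT, one record per PRIMARY_ID keeping
the higher id.  Two choices make the rule total and deterministic: FDA_DT
ties fall back to the higher primary id (numeric comparison when the id
parses as an integer, lexicographic otherwise), and residual ties fall back
to full record content, so the operation is idempotent and invariant under
permutation of its input.  Partial dates (YYYY or YYYYMM) keep their year
for report-year tabulation but are treated as absent for any day-resolution
arithmetic — no day of month is ever fabricated.

Age normalisation to years uses DEC×10, YR×1, MO÷12, WK÷52.143, DY÷365.25,
HR÷8766; a value without a unit is taken as years (logged), negative values
become absent with a warning.

## Counting unit for the 2×2 tables

The cell `a` is always the number of *unique* cohort reports carrying at
least one PT in the event class, so multi-PT reports never double count at
the report level.  The margins are report–event **pairs** by default
(`a+b` = total cohort pairs, `c+d` = total background pairs), the
convention that reproduces the additive structure of published FAERS signal
tables, whose SOC-level case totals exceed the number of cohort reports.
`margin="reports"` switches both margins to unique report counts; both
conventions share every downstream statistic.  Age bands are half-open —
[0,18), [18,65), [65,85), [85,∞) — because the published band labels
overlap at their edges; the half-open convention makes the partition well
defined, with boundary ages assigned to the older-starting band.
Percentages are rounded half-up at one decimal, matching how published
tables are typeset (note that a printed table can still disagree with its
own counts by one unit in the last digit; the summary here always reports
the exact quotient).

## Disproportionality statistics

* **ROR** `ad/bc` with the Wald CI `exp(ln ROR ± 1.96·√(1/a+1/b+1/c+1/d))`.
  No continuity correction is applied to zero cells: corrections silently
  change what the published thresholds mean, so non-computable results are
  flagged and excluded from ranking instead (the Bayesian detectors handle
  `a = 0` gracefully on their own).
* **PRR** with the Pearson χ² of the table (Yates correction off by
  default, switchable), computed through `scipy.stats.chi2_contingency`.
* **BCPNN IC**: default is the shrinkage formulation
  `IC = log₂((a+0.5)/(E+0.5))`, `E = (a+b)(a+c)/n`, with credibility bound
  `IC025 = IC − 3.3(a+0.5)^−1/2 − 2(a+0.5)^−3/2`, finite even at `a = 0`.
  The closed-form Dirichlet expectation/variance approximation of the
  original BCPNN is available as `method="bate"`.  The defaults reproduce
  the empirical near-identity `IC ≈ log₂(EBGM)` visible in large-count rows
  of published tables (asserted in the tests within 0.02 bits at a ≥ 10³).
* **MGPS/EBGM**: the relative reporting rate λ has the DuMouchel
  two-component gamma-mixture prior.  Integrating λ out of
  `a ~ Poisson(λE)` gives a two-component negative-binomial marginal; the
  five hyperparameters are fitted over *all* drug–event pairs of the
  database by bounded L-BFGS-B on log-shapes/rates and logit weight,
  started from the classic values (0.2, 0.1, 2, 4, 1/3).  Fewer than 50
  usable pairs, or optimizer failure, falls back to the classic values with
  a warning so a run always completes.  The posterior is again a
  two-component gamma mixture; `EBGM = 2^{E[log₂ λ | a]}` has a digamma
  closed form and `EBGM05` is found by Brent root-finding on the mixture
  CDF.  The tests pin both against an independent dense-grid quadrature of
  the explicit posterior density.

Thresholds (ROR: a ≥ 3 and lower CI > 1; PRR: a ≥ 3, PRR ≥ 2, χ² ≥ 4;
BCPNN: IC025 > 0; MGPS: EBGM05 > 2) are the community-standard set and are
config-overridable.  **No multiple-testing correction is applied**; the
all-four conjunction is the false-positive control, and the type-I test on
null synthetic databases shows it flags ≤ 2% of events.

Subgroup analyses restrict cohort *and* background to the stratum (sex
M/F, or the four age bands) and refit the MGPS prior on the stratum's own
pairs, falling back to the classic prior for thin strata.

## Time to onset and Weibull classification

TTO is `event date − earliest therapy start` in whole days, one interval
per report; negative intervals and partial dates are excluded with explicit
statuses.  Bins are [0,30], [31,60], [61,90], [91,120], [121,180], >180
days.  The Weibull fit maximises the likelihood over (log α, log β) by
Nelder-Mead from a moment-based start (sd(ln x) = π/(√6 β)); 95% CIs are
Wald intervals on the log-parameters from the finite-difference observed
information, with a nonparametric percentile bootstrap (1000 resamples)
behind a flag for small samples.  Same-day onsets are shifted to 0.5 day
for the likelihood only — the Weibull density is degenerate at zero for
shape < 1 — and stay 0 in the bins.  The hazard label reads the shape CI:
`early` if the upper bound is below 1, `wear-out` if the lower bound
exceeds 1, `random` otherwise, `indeterminate` on fit failure.  The fit
requires ≥ 10 valid intervals with ≥ 2 distinct values.

## The synthetic generator

Defaults are the study conditions, chosen once: 8000 background + 500
target-drug reports, 40 drugs, 150 PTs with a Zipf(1.0) rank-frequency
profile, an average of ≈ 4.3 PT draws per report (matching the events-per-
report ratio of the published cohort), demographics tables mirroring the
published Table-1 proportions (58.7/27.9/13.4 F/M/missing sex, 82.8% US,
37.8/58.3/3.9 reporter mix, the 2006–2025 report-year profile), onset times
from Weibull(38.05 d, 0.41) — the published early-failure law — a 5%
duplicate-injection rate, and 55%/30% missingness on EVENT_DT/START_DT so
that roughly a tenth of the full cohort yields a valid onset interval, the
order of magnitude seen in real spontaneous data.  Three signals are
implanted at mid-frequency ranks with relative reporting rates 10, 8 and 5;
their analytic expected counts (`SimConfig.expected_event_count`) are
178, 94 and 44 reports, all comfortably above the a ≥ 30 regime where the
conjunction should fire.  Because target-report PT probabilities are
renormalised after boosting, the realised per-draw observed/expected ratio
is mildly diluted below the nominal rate (≈ 8.5 for the nominal 10);
the generator exposes this analytically via `expected_relative_rate`.

Draws use one `SeedSequence` per run spawned into named sub-streams per
table, so output is byte-identical across runs and adding a field to one
table never perturbs another's draws.  Duplicates are emitted as an
*earlier* FDA_DT version of the case under a *higher* fresh primary id, so
deduplication must pick by date rather than id order.

What the generator does **not** emulate — and hence what green tests do not
demonstrate about real data: free-text drug-name misspellings beyond
punctuation/casing, real MedDRA hierarchies (the PT→SOC map is a flat
27-class assignment), reporting-rate secular trends within a year,
correlated demographics, indication bias, or masking between co-reported
drugs.  Detection performance on real FAERS data will be worse than on
these clean implants.

## Numerical and design notes

* Exact formulations of the four algorithms vary across the literature;
  the set implemented here (and its selectable variants: Yates on/off,
  shrinkage vs. Bate IC, fitted vs. classic MGPS prior) is the one whose
  internal identities match published signal tables.
* The pipeline itself is deterministic given (config, seed); every
  stochastic test and the generator take explicit seeds.
* Problem sizes in the test suite (e.g. 5000-pair prior simulations,
  n = 5000 Weibull recoveries, 20-seed operating-characteristic sweeps at
  the default database scale) were chosen so the whole suite documents the
  statistical claims at meaningful power while remaining quick to run on a
  laptop.
* Known limitations: no masking-adjusted or duplicate-aware
  disproportionality, no competing-risk or interval-censored onset
  modelling, no INDI/OUTC/RPSR tables, and signal detection identifies
  reporting associations, never causation.
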