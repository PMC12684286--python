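# Methods

`srsignal` implements the standard pharmacovigilance workflow for detecting
drug–adverse-event signals in spontaneous reporting system (SRS) databases,
specialised here to fibrate-associated biliary events (cholecystitis and
cholelithiasis) but configurable for any drug lexicon and MedDRA PT set.
This note records the models, the numerical choices, and what the synthetic
validation does and does not demonstrate.

## Data model and counting rules

An individual case safety report (ICSR) carries demographics, a list of drug
entries with reporter-assigned roles, and a list of adverse events coded as
MedDRA Preferred Terms. Two table dialects are supported:

- **JADER dialect** — CP932-encoded CSV tables (`demo`, `drug`, `reac`,
  `hist`), case key `識別番号`. JADER has a single "suspect" role (被疑薬),
  which we map to `primary_suspect` so the suspect-restricted sensitivity
  analysis means the same thing in both dialects. Events can be read from
  REAC or HIST (config `analysis.event_source`).
- **FAERS dialect** — `$`-delimited ASCII tables (`DEMO`, `DRUG`, `REAC`,
  `THER`, `OUTC`). Duplicate submissions are resolved before merging by
  keeping the highest `caseversion` per `caseid` (ties: larger `primaryid`;
  missing version counts as 0). Children attach by `primaryid`, so rows
  belonging to superseded versions are dropped as orphans with a logged
  count. Therapy dates come from THER via `dsg_drug_seq`; FAERS stores one
  `event_dt` per case, which is attached to every reaction of that case.

Drug identification is exact matching after normalization (uppercase, trim,
collapse whitespace) against an explicit synonym lexicon — no fuzzy matching.
The default lexicon covers pemafibrate, fenofibrate (including "FENOFIBRIC
ACID" and "CHOLINE FENOFIBRATE"), and bezafibrate, with Japanese generic
names for JADER.

The counting unit is the **drug–event pair**: a report with *k* drug entries
and *m* events contributes *k·m* pairs (repeated listings of the same drug
are kept as distinct pairs; a config switch collapses them). Agent-level
pair counts are not mutually exclusive across drugs, so the pipeline also
reports the number of distinct ICSRs behind each cell.

The default target event set is the 14 PTs under the high-level term
"Cholecystitis and cholelithiasis" (HLT 10008616). PT membership is pure
configuration — the package does not traverse a MedDRA distribution — and
the shipped list must be confirmed against a licensed MedDRA version.

## Disproportionality metrics

From the pair universe and a target drug set / event set we build the 2×2
table (n11, n12, n21, n22) and compute:

- **ROR** = (n11·n22)/(n12·n21), 95% CI `exp(ln ROR ± z·√(1/n11 + 1/n12 +
  1/n21 + 1/n22))`, plus a two-sided Fisher exact p (point-probability
  method). The log-symmetric construction forces √(lower·upper) = estimate,
  which is also how published point estimates can be cross-checked against
  their printed bounds.
- **PRR** = [n11/(n11+n12)] / [n21/(n21+n22)], Wald CI on the log scale,
  with a Yates-continuity-corrected χ² (the MHRA convention; a flag disables
  the correction).
- **BCPNN IC** = log2((n11+0.5)/(E+0.5)) with E = n1+·n+1/n++; the 95%
  credibility interval comes from the exact posterior Gamma(n11+0.5,
  rate E+0.5) of the reporting-rate ratio λ. The classical 1998 moment
  approximation is available as `variant="moment"`.
- **GPS / EBGM** — see below.

Zero-cell tables yield an "undefined" marker (NaN estimate, auxiliary
statistics retained) rather than a silent Haldane–Anscombe correction; a
`continuity` flag enables the +0.5 correction. Since the signal rules
require n11 ≥ 3, zero-cell tables are never signals either way.

**Signal rules** (flags evaluated only on defined metrics): ROR — n11 ≥ 3
and ROR025 > 1; PRR — n11 ≥ 3, PRR025 > 2 (strict) and χ² > 4 (strict);
IC — IC025 > 0 (strict); EBGM — EBGM05 ≥ 2.0 (inclusive). No multiplicity
correction is applied: these are fixed per-metric thresholds.

### Gamma–Poisson Shrinker

Cell counts are modelled as n ~ Poisson(λE) with the DuMouchel mixture prior
λ ~ w·Gamma(a1,b1) + (1−w)·Gamma(a2,b2) (rate parameterisation), fitted by
marginal maximum likelihood over every drug×event cell of the universe
(marginally a two-component negative-binomial mixture). Expected counts are
computed under independence within each sex×age stratum and pooled,
E = Σ_s n_d+(s)·n_+e(s)/n_++(s); cases with unknown sex or age form explicit
"unknown" strata so no pair is lost from the margins. The cell posterior is
again a two-component gamma mixture; EBGM = 2^{E[log2 λ | n]} evaluated with
digamma (posterior-mean form via `point="mean"`), and EBGM05/EBGM95 are the
5%/95% posterior percentiles found by root-finding on the mixture CDF
(90% interval; ROR/PRR/IC use 95%).

Numerical choices: optimization runs on (logit w, log a1, log b1, log a2,
log b2) with L-BFGS-B from the standard initialization (1/3, 0.2, 0.1, 2, 4)
plus 4 seeded random restarts, tolerance 1e-8, and box bounds |logit w| ≤ 7,
|log a|, |log b| ≤ 8. The bounds matter: on a cell universe that is close to
pure Poisson (as a clean synthetic null is), the unconstrained likelihood is
maximized by a degenerate point-mass prior with a, b → ∞ jointly; the box
keeps the prior proper while leaving realistic fits interior. A consequence
worth knowing: when the whole universe is consistent with λ = 1, weak cells
are shrunk hard toward 1 — that is empirical Bayes working as intended, not
a defect.

EBGM is computed for the JADER dialect by default (sex×age-stratified
expected counts). For FAERS it is skipped, matching the practice of not
computing EBGM without stratification; forcing it computes an unstratified
EBGM with a warning.

## Stratified and sensitivity analyses

The sensitivity analysis restricts pairs to primary-suspect listings and
recomputes everything. Stratified analysis re-derives pairs within each
stratum and recomputes ROR/PRR/IC and flags per level:

- sex: male / female;
- age: ≥60 vs 20–50, resolved on banded decade labels ("20s"–"50s" →
  20–50; "60s" and above → ≥60; other bands excluded);
- BMI: ≥25 vs <25, with BMI = mid(weight band) / (mid(height band)/100)²
  using band midpoints, because JADER records anthropometry in 10-cm/10-kg
  bands (half-open [low, low+10); e.g. heights [160,170) and weights
  [60,70) give BMI 23.9 → "<25").

Reports missing the stratum variable are excluded from that stratum, never
imputed. FAERS carries no height, so BMI strata are empty there.

## Time-to-onset (TTO)

TTO = (onset − therapy start in calendar days) + 1, so a same-day onset
counts as one day and log-likelihoods are always defined. Only records with
complete dates on both ends qualify; year-month dates are excluded (counted
by reason), never imputed to a day. Month-only and invalid calendar days
(e.g. Feb 30) both degrade to incomplete. When one case has several
qualifying events for a drug, each contributes a record; an
`earliest_only` switch keeps the first.

The Weibull law f(t) = (β/α)(t/α)^{β−1} exp(−(t/α)^β) is fitted by maximum
likelihood via the profile equation in β (monotone one-dimensional
root-find, Brent to 1e-12 after normalising t by its maximum for overflow
safety) with α̂ = (mean t^β̂)^{1/β̂} in closed form. Shape interpretation:
β > 1 increasing hazard ("wear-out"), β ≈ 1 constant ("random"), β < 1
decreasing ("early failure"), decided on the bootstrap CI (lower > 1 →
wear-out; upper < 1 → early failure; else random).

Confidence intervals use B = 2000 seeded bootstrap resamples, refitted with
a vectorised bisection solver; degenerate resamples (all values identical)
are redrawn (> 10% failures aborts). The default interval is the **basic**
(reversed-percentile) bootstrap: at SRS-typical sample sizes (n ≈ 17) the
shape MLE is biased upward by ~10–15%, the raw percentile interval inherits
that bias and loses coverage on the low side (~0.82 measured at n = 17,
true β = 1.59), while the basic interval restores ~0.91. `percentile` and
`bca` are available as options. Quartiles use linear interpolation between
order statistics (numpy's default, "type 7"). The bootstrap median CI and
the IQR are reported separately — they are different quantities even when
they happen to look alike in small samples.

## Synthetic SRS generator

The generator exists so every stage — parsing, deduplication, merging, pair
expansion, metrics, stratification, TTO — can be validated end-to-end with
known ground truth, without multi-GB database downloads. Per report:
demographics are drawn from configured marginals; each drug is exposed
independently with its exposure probability and receives a role from its
role distribution; each event occurs with odds = baseline_odds × Π θ(d,e)
over exposed drugs, converted via p = odds/(1+odds). θ acts on the odds
scale precisely so that the report-level 2×2 odds ratio equals θ exactly
(absent a second associated drug for the same event, which
`true_ror` refuses to answer for). The pair-level table approximates this
estimand under rare exposure; the recovery checks therefore use the
report-level table (`table_unit="icsr"`), which the pipeline exposes as a
config switch.

Onsets for (drug, event) combinations with a configured TTO law fall
round(Weibull(α, β)) days (half-up, floored at 0) after that drug's therapy
start — the +1 rule then guarantees TTO ≥ 1. Other realized events get an
arbitrary in-window date. Each date loses its day component with the
configured missingness probability; FAERS cases are emitted twice with an
incremented case version (children under both `primaryid`s) with the
duplication probability, isolating the dedup rule.

Default study conditions (chosen once; all overridable): 50 000 reports;
pemafibrate/fenofibrate/bezafibrate at exposure 0.020/0.015/0.008 plus
eight common background drugs (aggregate ≈1 drug entry per report); three
biliary target PTs at baseline odds 0.004/0.002/0.0015 plus six background
events including one high-frequency term so most reports are non-empty;
sex ratio 0.55 male; JADER-like banded age/height/weight distributions with
explicit unknown mass; date-component missingness 0.2 per date (reproducing
the ≈60% complete-TTO availability seen in practice); FAERS duplication
0.05; default association θ = 3.74 on pemafibrate–biliary PTs with
per-PT Weibull TTO laws (α=486, β=2.05 for cholelithiasis; α=448, β=1.29
for the cholecystitis terms).

**What passing synthetic tests shows — and does not.** The generator
reproduces the structural features the pipeline logic depends on
(multi-drug/multi-event reports, role codes, banded demographics, partial
dates, duplicate versions, a tunable odds-scale association, Weibull
onsets). It deliberately omits features of real SRS data: reporting-rate
dynamics (Weber effect, notoriety bias), correlated co-prescription,
event-term misclassification, true-duplicate reports with differing
content, and between-cell heterogeneity of reporting ratios beyond the
configured θ. Passing tests therefore validate the computations and
counting rules, not the epidemiology of any real database.

## Validation summary

The test suite and `scripts/acceptance.py` recompute, from scratch:
geometric-mean reproduction of published fibrate–biliary ROR/PRR point
estimates from their printed 95% bounds (a construction check, exact up to
printed rounding); Fisher exact p against full hypergeometric enumeration
on 500 random tables with n++ ≤ 200; GPS posterior percentiles against
10⁶-draw Monte Carlo on the λ scale (within 0.01); 95% ROR CI coverage of
θ = 4 across 100 seeded 50 000-report replicates (≥ 90 required); all four
signal flags firing at θ = 8 and none at θ = 1; Weibull recovery of
(α = 470, β = 1.59) within 3% from 10 000 draws; and bootstrap shape-CI
coverage within [0.88, 0.99] over 500 replicates at n = 17. Problem sizes
were chosen to make each check statistically decisive at desk scale.

## Known limitations

- Real JADER/FAERS extracts vary in column naming across vintages; the
  readers accept the standard names plus ASCII aliases but do not attempt
  schema inference.
- No censoring-aware survival modelling: the Weibull fit uses observed
  onsets only, as is conventional for SRS TTO analysis.
- No FDR/multiplicity layer, no EBGM "squashing" for very large databases,
  and no covariate-adjusted disproportionality regression.
- The moment-variant BCPNN interval is a normal approximation retained for
  comparison; the gamma-posterior variant is the default and the tested one.
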