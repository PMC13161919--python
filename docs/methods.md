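# Methods

## Data model and ingestion

The unit of analysis is the deduplicated safety report.  Input follows the
public FAERS ASCII dialect: `$`-delimited text with a header row, UTF-8
with replacement of undecodable bytes, one file per table (DEMO, DRUG,
REAC, plus optional OUTC, RPSR, THER, INDI).  DEMO, DRUG and REAC are
required; a DEMO row is kept only if at least one drug row and one reaction
preferred term join to it on `primaryid` (dropped rows are counted in the
log).  Receipt dates must be 8-digit `YYYYMMDD` values with a valid
month/day; anything else becomes 0 ("missing"), so in deduplication any
dated version beats an undated one and the selection rule — keep the
maximum `(fda_dt, primaryid)` per `caseid` — is a total order.  That makes
deduplication idempotent and independent of row order, which the tests
check by permutation.

Ages are converted to years from the unit code (`YR`, `DEC` ×10, `MON`
÷12, `WK` ÷52, `DY` ÷365, `HR` ÷8766) and binned to {<18, 18–64, 65–85,
>85, unknown}.  Drug names are standardized by exact, case-insensitive
lookup in a user-supplied synonym table (no live RxNorm access); unmapped
names are **retained** under their lowercased raw string rather than
dropped, because dropping them would deflate the non-event cells of every
contingency table.  The target event is defined by a configurable
preferred-term list matched case-insensitively against each report's
reactions; broader SMQ-style lists are supplied the same way.

A report can carry several outcome codes.  Demographic summaries assign
each report its single most serious outcome (death > life-threatening >
hospitalization > disability > congenital anomaly > other serious) so that
category counts partition the cohort.

## Contingency tables

A report contributes to a drug's exposure margin iff it has at least one
row for that drug whose role code passes the filter (default {PS, SS}:
suspect drugs only, configurable to all roles), and contributes exactly
once however many rows repeat the drug.  Counting is report-level, not
drug–event-row-level, so the four cells partition the cohort and the event
margin a+c is identical across drugs.  The same report may count toward
several different drugs.

## Signal statistics

*ROR and PRR.*  Woolf (log-scale Wald) interval for the ROR with z = 1.96.
χ² is Yates-continuity-corrected by default (plain Pearson selectable); it
is computed on the raw cells.  Zero-cell policy: a = 0 pairs are skipped
with an explicit reason (they cannot reach the report-count threshold
anyway); a zero in b, c or d triggers the Haldane–Anscombe +0.5 on all four
cells for the two ratio statistics only, logged.  Not-computable statistics
propagate as NaN and fail their signal criterion; they are never silently 0
or 1.

*BCPNN.*  The information component uses the conjugate-Beta closed form
with hyperparameters γ₁₁ = 1, α = β = 2, α₁ = β₁ = 1 and the
independence-tuned joint prior weight γ = (N+2)²/((a+b+1)(a+c+1)).  The
reported IC is the plug-in posterior estimate, which is exactly 0 on a
symmetric independence table.  For the lower bound IC025 = E(IC) − 2√V(IC),
two variance dialects are implemented.  The default computes the exact
posterior moments of log p under the model's independent Beta posteriors
(digamma means, trigamma variances, three terms); it tracks a 100,000-draw
Monte-Carlo posterior 2.5th percentile to better than 0.1 bits across the
spontaneous-reporting regime (all cells ≥ 5, d dominant), which we verified
directly.  The `bate1998` dialect is the original delta-method variance; it
is noticeably anti-conservative for a ≲ 10 (up to ~0.26 bits) and is kept
for comparability.  The Monte-Carlo oracle draws the model's own three
Beta posteriors independently; a joint four-cell Dirichlet would impose a
joint–margin correlation the BCPNN model deliberately lacks and disagrees
with any E − 2√V bound by construction.

*MGPS.*  The relative reporting rate λ = a/E with E = (a+b)(a+c)/N is
modeled with DuMouchel's two-component gamma prior
w·Gamma(α₁,β₁) + (1−w)·Gamma(α₂,β₂); the marginal of a is the matching
negative-binomial mixture.  The five hyperparameters are fitted once per
screen by maximizing the total marginal log-likelihood over **all**
drug–event pairs (including a = 0 pairs, which inform the null component) —
shrinkage requires the shared prior.  The search runs in unconstrained
(log, logit) space with L-BFGS-B and finite-difference gradients from the
conventional start point (0.2, 0.1, 2.0, 4.0, 1/3) plus five
deterministically jittered restarts (fixed seed, N(0, 0.5) jitter);
objective tolerance 10⁻⁶.  Parameters are boxed to e^±15: outside that box
the negative-binomial log-pmf loses all precision to `gammaln` cancellation
and the optimizer can chase numerically fake likelihood gains — the box is
a numerical guard, not a prior belief.  The returned fit is never worse
than the start point.  The posterior per pair is the mixture
Q·Gamma(α₁+a, β₁+E) + (1−Q)·Gamma(α₂+a, β₂+E) with Q the (log-sum-exp
stabilized) posterior component weight; EBGM = exp(E[ln λ]) via the digamma
closed form, and EB05 solves mixture-CDF = 0.05 by bracketed Brent root
finding (bracket grown from [10⁻¹², max(10·EBGM, 10⁻⁶)], CDF tolerance
well below 10⁻⁸).

*Signal rule.*  Positive iff all six conditions hold: a ≥ 3, ROR CI lower
bound > 1, PRR ≥ 2, χ² ≥ 4, IC025 > 0, EB05 > 2.  The rule is read
conjunctively across all four algorithm families; thresholds are a config
object so alternates can be screened.

## Synthetic cohort generator

The generator emulates the features of a spontaneous-reporting cohort the
pipeline must handle: verbatim drug synonyms needing normalization,
multi-drug and multi-reaction reports, categorical demographics, duplicate
case versions, and — centrally — known drug–event effect sizes.  Each
report draws its drug set independently per catalog entry; reports with no
drug are redrawn, so realized exposure shares exceed nominal use
probabilities by the factor 1/P(≥1 drug) (reported by the
`single_signal_config` helper's docstring and accounted for in study
design).  The target event occurs with odds
(p₀/(1−p₀))·Πθ over implanted drugs present, so with a **single** implanted
drug the implanted θ is exactly the ROR estimand.  With several signals
implanted at once the background event rate is contaminated and every
measured ROR is attenuated below its θ — the default study-shaped catalog
deliberately exhibits this, as real databases do, while effect-recovery
studies implant one signal per cohort.

Default demographic shares mimic the published ED cohort (49.4% aged
18–64, 52.0% consumer reporters, 35.6% other-serious outcomes, a
US-dominated country mix, reporting peak in 2015); the baseline event
probability defaults to 0.025, giving a few-percent event margin at desk
scale.  Duplicates: a configurable fraction of cases gains one or two
extra versions with strictly later receipt dates (70%) or the same date
and a higher primaryid (30%), together with a manifest naming the version
the dedup rule must keep; output rows are shuffled.  One global seed
drives named substreams (stage-name CRC), so adding a stage never shifts
another stage's draws, and equal configs give byte-identical quarter
files.

What the generator does **not** model: calendar-time reporting dynamics
(Weber effect, stimulated reporting), drug co-prescription correlation,
indication bias, free-text misspellings beyond synonym lists, and
within-case field conflicts between versions.  Passing tests therefore
demonstrate correctness of the screening machinery and its operating
characteristics under clean assumptions, not robustness to real FAERS
messiness.

## Study problem sizes

Chosen as the package's own desk-scale designs:

- Null operating characteristics: 5 independent cohorts × 100 null drugs
  at n = 20,000, baseline event probability 0.05 so per-drug a-cells (~30)
  sit in the asymptotic regime the Woolf interval assumes; 500
  drug-replicates give a ±1% binomial SE on 95% coverage.
- Effect recovery: θ = 4 at n = 200,000 with p₀ = 0.01, judged within ±3
  Woolf standard errors.
- Hyperparameter recovery: 50,000 (a, E) pairs, E log-uniform on
  [0.1, 100], 15% relative tolerance.
- Headline statin studies (acceptance script): n = 200,000 per replicate
  with margins sized so the realized a-cells (~450 and ~230) match the
  information content implied by the published intervals — the recovered
  CI bounds then estimate the published bounds rather than those of a
  larger study; reported values average 8 independent replicates to reduce
  Monte-Carlo error of the mean to ~2–4%.
- The power-monotonicity grid uses 12 replicates per cell with a
  one-replicate slack allowance for sampling noise.

## Known limitations

- Term standardization is exact-match lookup; fuzzy matching and live
  dictionary access are out of scope.
- No stratified (age/sex/year) tables, no Mantel–Haenszel-pooled MGPS, no
  multiplicity adjustment of the signal rule — the screen reports
  unstratified statistics only.
- The country-percentage denominator is configurable (total vs
  known-country) because published country tables conventionally use the
  known-country denominator while other categories use the total; both are
  available per category.
- The BCPNN IC025 is a posterior-moment bound, not a credible-interval
  endpoint; agreement with the simulated percentile degrades below the
  all-cells ≥ 5 regime.
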