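# Methods

## The dating problem

Gestational age (GA) at birth is carried in integer days throughout;
"weeks" always means completed weeks, `days // 7`. Three kinds of source
can date a pregnancy:

* **LMP dating.** GA at birth = birth date − first day of the last
  menstrual period, an exact calendar day count. An LMP after the birth
  date is an invalid interval (a real data error, handled by dropping the
  LMP estimate for that record and logging it).
* **Ultrasound dating.** GA at birth = (birth date − exam date) + the
  clinician's GA estimate at the exam, in days. Raw biometry (crown–rump
  length etc.) is out of scope; the clinician-reported GA is the input.
* **Capurro neonatal exam.** The recorded GA-at-birth value is used
  verbatim.

Ultrasound exams are grouped by GA at the exam into three windows with
completed-week semantics: 7–20 weeks is 7 w 0 d through 20 w 6 d, i.e.
[49, 146] days; 21–28 weeks is [147, 202]; 29+ weeks is ≥ 203. Exams
before 49 days fall outside every window and are never used. Whether
"7–20 weeks" should truncate at 20 w 0 d instead is a genuine ambiguity of
the completed-week idiom; the inclusive reading was adopted because it is
the standard clinical convention, and the window bounds are module
constants so a sensitivity analysis only has to change one table. Within
a window the exam with the smallest GA at exam wins; ties are broken by
input record order so selection is deterministic.

Maturity cut-offs follow the WHO completed-week convention: preterm
< 259 days (< 37 w), post-term ≥ 294 days (≥ 42 w).

## Birthweight-for-GA screen

The plausibility screen computes `z = (weight − μ_{sex,week}) /
σ_{sex,week}` against a sex × completed-week growth reference covering
weeks 22–44. Two closely related rules coexist in practice: the *category*
boundaries are strict (low if z < −3, high if z > +3), while the analysis
*exclusion* rule is inclusive (|z| ≥ 3). The inclusive rule is the
default because it is the one that governs outlier-excluded analyses; a
`strict` flag (CLI `--outlier-strict`) keeps boundary values instead.
GA weeks outside the table are clamped to the nearest row with a logged
warning — how sub-22-week or post-44-week births were historically scored
is not recoverable, and clamping is the least-surprising total behaviour.

The bundled reference is a **synthetic stand-in**, not a published
standard: a per-sex logistic median curve
`μ(w) = L / (1 + e^{−k (w − w₀)})` with L = 3900 g (male) / 3750 g
(female), k = 0.22, w₀ = 31, and σ(w) = 0.12 · μ(w) (a fixed coefficient
of variation). It gives ≈470 g at 22 w and ≈3430 g at 40 w for males —
plausible for a liveborn intrauterine curve — and is strictly increasing,
which is all the screen's correctness depends on. Any table in the
documented CSV schema (`sex,week,mean_g,sd_g`) can be supplied instead,
and real analyses should supply one.

## Hierarchical assignment

Default priority: US 7–20 w → US 21–28 w → US 29+ w → LMP. The Capurro
exam is excluded from the default priority because its agreement with
early ultrasound on prematurity is poor; it can be appended for
sensitivity analyses. For each candidate source the Z-score is evaluated
*under that candidate's GA* — a birthweight can be implausible under one
dating and plausible under another, which is precisely the misdating
signal — and the outlier rule is re-checked at every fall-through step
rather than excluding the newborn outright when its top source fails.
Per-step re-checking is what makes fall-through entrance counts at the
lower criteria possible at all. A record whose every source is missing,
invalid or an outlier is *unclassified*: a reported outcome, not an
error. By default the LMP step accepts any reported LMP; a flag restricts
it to dates the woman reported as certain.

## Agreement battery

All comparisons are pairwise-complete (records having both the reference
7–20-week estimate and the comparator's) and are run twice: on all pairs,
and excluding pairs where either estimate flags the birthweight as an
outlier.

* **Cohen's kappa** (unweighted, marginal-product chance agreement) per
  dichotomy, banded with the Landis–Koch intervals: ≤0 poor, (0, 0.20]
  slight, (0.20, 0.40] fair, (0.40, 0.60] moderate, (0.60, 0.80]
  substantial, (0.80, 1] almost perfect. Degenerate single-cell marginals
  (chance agreement 1) raise an explicit undefined-kappa signal.
* **Diagnostic metrics** treat the reference as truth: sens = tp/(tp+fn),
  spec = tn/(tn+fp), ppv = tp/(tp+fp), npv = tn/(tn+fn). A zero
  denominator yields a not-defined marker (`None`, rendered "—"), never a
  silent 0; a zero numerator over a positive denominator is a true 0.00.
* **Rate chi-square** compares the two methods' positive rates as an
  unpaired 2×2 Pearson test without continuity correction (1 df). This
  mirrors the conventional presentation but ignores the pairing; a
  McNemar variant on the paired table is provided (`use_mcnemar=True`)
  for methodological honesty. A zero marginal raises a degenerate-table
  signal rather than returning a NaN statistic.
* **GA differences** are comparator − reference in days (positive = the
  comparator dates the pregnancy further along), categorised into
  <−14 / −14…−8 / ±7 / +8…+14 / >+14 days — the thresholds at which a
  clinician would redate against a first- or second-trimester scan. The
  stratified table reports n, mean (SD, ddof = 1) and band percentages
  per stratum of a maternal covariate, LMP certainty, or the derived
  infant stratifiers (birthweight group; reference-GA group), with a
  strata × band chi-square across strata (computed only when at least
  two populated strata and two non-empty bands remain).
* **Percentages** are rendered to one decimal with half-up rounding; the
  per-week distribution table pools ≤29 and ≥43 completed weeks, carries
  exact-proportion cumulative percents ending at 100.0, and reports the
  preterm subtotal (< 37 w).

## Synthetic cohort generator

The generator's job is to reproduce the *structure* of the measurement
problem — not to forge any particular study's tables (those are
unidentifiable from printed marginals and chasing them would be
circular). Defaults live in `src/gestage/data/default_config.yaml`.

* **True GA** at birth: a preterm/term/postterm mixture (12.5% / 85.5% /
  2.0%) of truncated normals — preterm N(247, 16²) on [168, 258], term
  N(276, 8²) on [259, 293], postterm N(297, 3²) on [294, 308] days. The
  true LMP date is drawn uniformly over a year; birth = LMP + GA.
* **LMP report** (available 97.4%; certain 76.9% of those): certain dates
  get a small symmetric error (SD 3 d); uncertain dates a wider one (SD
  7 d) plus, with probability 0.25, a whole-calendar-month slip, 80% of
  the time toward a *later* reported date — recalling the first month the
  period failed to occur — which underestimates GA and inflates the
  apparent preterm rate. Slips use the slipped month's real length
  (28–31 d). Reported LMPs are capped so the implied GA stays ≥ 140 d.
* **Ultrasound** (window availability 78.6% / 59.8% / 61.7%): the exam is
  scheduled uniformly inside the window, truncated below the birth date;
  the clinician GA is the true GA at exam plus Gaussian error with
  window SDs 4 / 8 / 14 days — early scans are accurate, third-trimester
  scans are not. Window membership downstream is judged from the
  *reported* GA, so boundary exams can migrate windows, as in real data.
* **Capurro** (available 87.5%): `GA_cap = GA + 0.4 · (273 − GA) + ε`,
  ε ~ N(0, 6²) — a pull of extreme GAs roughly half-way toward a 39-week
  target. The 0.4 coefficient is set so the exam's operating behaviour
  matches the published pattern for this instrument (prematurity
  sensitivity near 0.6 at specificity near 0.97, GA overestimated by
  more than two weeks in a sizeable fraction of preterm births and
  underestimated by weeks in post-term ones).
* **Birth weight** is drawn from the same growth reference used for
  scoring (mean + Gaussian with the reference SD, multiplier
  configurable), making the outlier machinery self-consistent: in the
  noiseless limit nothing is flagged, and at multiplier 1 the flag rate
  approaches the two-sided 3-SD normal tail (~0.27%). Gross transcription
  errors (probability 0.01) replace the weight with a uniform draw on
  [250, 6000] g.
* **Determinism**: every record's draws come from
  `SeedSequence((seed, record_index))`, so records are reproducible
  independently of cohort size or insertion order.

What the generator does **not** emulate: correlated missingness
(availability is independent of covariates and of true GA except through
window feasibility), digit-preference in reported dates, multiple
gestation, pregnancy loss, and any covariate→error association (strata
differ only by sampling noise). Passing tests therefore demonstrate the
statistical machinery, not epidemiological findings about any real
population.

## Numerical and interface choices

* All GA arithmetic is integer days; no fractional weeks exist anywhere.
* Dates are ISO-8601 only; day/month-ambiguous input is refused.
* The cohort CSV carries a schema-version header line; malformed rows are
  skipped with a logged row number and reason, never silently dropped or
  fatal.
* Report files carry a provenance comment (config hash + seed); the run
  manifest (config, hashes, counts, versions) is sufficient to reproduce
  a bundle byte-for-byte.
* Problem sizes used by the test suite and the acceptance script — 600
  records for noiseless-limit checks, 1,483 (the emulated study size) for
  directional checks, 5,000 for error-SD recovery, 1,000 random tables
  for oracle equivalence — were chosen so Monte-Carlo error is comfortably
  inside each check's tolerance (±15% for SD recovery, binomial 3-σ for
  rates).

## Known limitations

* The bundled growth curve is synthetic; absolute Z-scores from it are
  not clinically meaningful, only their internal consistency is.
* The unpaired chi-square on paired data overstates p-values; use the
  McNemar variant when the pairing matters.
* Kappa confidence intervals, weighted kappa and LMS (skewness-adjusted)
  Z-scores are out of scope.
* Simulator error magnitudes for LMP recall are order-of-magnitude
  choices exposed in the config file; nothing in the package claims they
  equal any particular population's error distribution.
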