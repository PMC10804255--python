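# Methods

## Model and procedure

The quantity at the core of the package is a conditional probability. For a
*code pair* — a suicide-attempt coded patient-day together with the
immediately (temporally) preceding suicide-attempt coded day in the same
record — the positive predictive value (PPV) is the probability that the
second code marks an attempt event distinct from the one indexed by the
first. With k of n pairs in a stratum labeled distinct,

    PPV = k / n,    95% CI = PPV ± z · sqrt(PPV (1 − PPV) / n),  z = 1.96.

Three design commitments follow the way predictive-modelling pipelines
consume these codes rather than textbook inference practice, and are
deliberate:

* **Pairs are treated as independent observations.** No within-patient
  clustering correction is applied, because downstream risk models treat
  each code occurrence independently. Cluster-robust or exact-binomial
  intervals are intentionally not the default.
* **The Wald interval is not clipped to [0, 1].** Small strata with PPV near
  1 produce upper bounds above 1; these are reported as-is (clipping is a
  display choice that hides the approximation's behaviour). `n = 0` is an
  undefined estimate, signalled as NaN — never as 0. Boundary cases
  (k = 0 or k = n) are likewise reported without continuity correction.
* **Display rounding is half-up** at 2 decimals (1 decimal for percentage
  shares), matching clinical-reporting convention; all computation is done
  at full precision.

An *interval floor* d restricts a stratum to pairs at least d days apart.
Because leaked codes cluster near their source event, PPV is non-decreasing
in d in expectation, and the floor curve (PPV vs d) crosses any benchmark
attainable for the stratum. Rule derivation finds, for each of the four
setting-pair strata (nonED/nonED, ED/nonED, nonED/ED, ED/ED), the two
method-concordance strata, the pooled second-code-in-ED stratum and all
pairs, the **smallest** d whose PPV reaches the benchmark (default 0.90).
The smallest crossing is used even if the curve later dips below the
benchmark — sampling noise at large d thins the strata quickly — and a
`strict` mode requiring every later populated floor to qualify is available.
The deployable rule takes its ED floor from the pooled second-code-in-ED
stratum and (optionally) a global floor from the all-pairs stratum.

### Rule application

Applying a rule to an unlabeled stream labels each patient-day: distinct
when it is an ED day at least `ed_floor_days` after the immediately
preceding coded day, or any day at least `global_floor_days` after it (when
that floor is armed); otherwise leaked. The interval is measured to the
immediately preceding coded day — not to the last accepted event — because
that is how the pairs behind the derivation were built; a
`since_last_event` mode exists for pipelines that prefer episode anchoring
but is non-default. The first coded day of a record has no preceding code,
so its treatment is explicit configuration: `first_code_is_event` (default;
risk models need an index attempt) or `first_code_ignored`.

## Case definition and character counting

Codes are normalized (uppercased, periods removed) before matching, and all
character positions count in the normalized string. For the ICD-10-CM
poisoning/toxic-effect families (T36–T65) the intentional-self-harm intent
character `2` sits in the 6th normalized position, except for stems with no
agent subdivision (T36.9, T37.9, T39.9, T41.4, T42.7, T43.9, T45.9, T47.9,
T49.9; T51.9, T52.9, T53.9, T54.9, T56.9, T57.9, T58.0, T58.1, T58.9,
T59.9, T60.9, T61.0, T61.1, T61.9, T62.9, T63.9, T64.0, T64.8, T65.9),
where it sits in the 5th. This period-free convention reproduces standard
ICD-10-CM structure (T42.72XA: 5th character `2`, placeholder `X` 6th) and
makes the exception list coherent; codes too short to carry the intent
character do not match. The code→method mapping is not part of the
validated definition and is shipped as an editable CSV
(`sadedup/data/method_map.csv`); unmapped matched codes fall back to
`other`, which by construction includes unspecified-means codes (T14.91\*).
ICD-10's matched window X71–X83 contains no hanging code (X70 is outside
the validated set), so hanging appears only via ICD-9 E953\*.

## Day-level aggregation choices

Same-day encounters collapse to one patient-day: a day with any ED
encounter is an ED day (the ED presentation is the clinically salient one,
and this errs toward applying the stricter ED evidence), methods and
settings are unions, and a pair is "same method" when the two days' method
sets intersect (one shared specific method is stronger evidence of a shared
event than disjoint sets). In the 6×6 method cross-table a multi-method day
is reduced to its highest-priority category (poisoning, cutting/piercing,
hanging/strangulation/suffocation, jumping, firearm, `other` last) — a
deterministic tie-break. Intervals are whole calendar days from timezone-free
date subtraction. The contiguous-inpatient sensitivity filter removes
inpatient/ICU-only days whose previous calendar day carried an inpatient or
ICU code, judged against the unfiltered input so that only the first day of
a coded admission run survives.

## Synthetic cohort generator

Real chart-reviewed cohorts cannot be shared, so `sadedup.synth` generates
labeled cohorts reproducing the leakage *structure* the derivation depends
on. Per patient: 1 + geometric number of attempt events
(P(another) = 0.35, capped at 8), separated by lognormal gaps (median
≈ 40 days, σ = 1.1, minimum 2). Each event emits a cascade: an index
presentation (ED with probability 0.85, otherwise
inpatient/outpatient/other), an admission with probability 0.40 (length
≈ 1 + Poisson(2.5) days, ICU start for 30% of admissions, daily coding with
probability 0.9), a short-lag ED re-presentation for the same event with
probability 0.18, and Poisson(0.5) follow-up codes in mostly
outpatient/other settings (ED with probability only 0.03). Every leaked
code falls within the leakage horizon H = 28 days of the event's first
code. Codes are drawn from per-(version, method) pools that all pass the
case definition, with a 12% ICD-9 mix, 15% unspecified-means miscoding and
a 25% chance of the `D` encounter extension on ICD-10 follow-ups.

Under these defaults a 2000-patient cohort yields ≈82% nonindependent
pairs, a 1-day median intercode interval, a nonED/nonED-dominated setting
mix, and a derived ED floor of 4–5 days with PPV ≥ 0.9 — the regime the
rule was designed for. The defaults are the study conditions of the test
suite and are not tuned per test.

What the generator does **not** emulate: care sought outside the observed
system (truncated cascades), coding-practice drift over calendar time
(ICD-9/ICD-10 mix is i.i.d. per code rather than era-based), long-horizon
leaked codes beyond H (real records contain anniversary/late follow-up
coding, which is why observed all-pairs floors can be far larger than any
simulated one), and narrative-note content. Passing tests therefore show
the pipeline recovers known structure from data shaped like real cascades —
not that the specific floors derived from any health system transfer to
another.

## Numerical and problem-size choices

Floor curves are computed by sorted-array counting (exact, no binning);
ties in floor selection cannot arise since floors are integers scanned in
order. Test and acceptance cohorts use 2000 patients (≈12k encounters,
≈7.5k narrow-frame pairs), enough for floor estimates stable to ±1 day
across seeds while the whole suite runs in seconds. Empty strata report
n = 0 with undefined (NaN) estimates and an absent floor, with a warning
rather than an error.

## Known limitations

* The derived floors are health-system specific; the 5-day ED default in
  `RuleSpec.default()` and the 53-day global floor in
  `RuleSpec.permissive()` are sensible starting points, not universal
  constants — re-derive them on local labeled data where possible.
* Day-level logic cannot separate two true attempts on the same calendar
  day, or on consecutive days below any floor.
* The reader ingests delimited encounter exports only (no FHIR/OMOP); the
  setting mapping is string-based and must cover local vocabulary.
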