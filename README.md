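# sa-dedup

Deduplicate recurrent suicide-attempt ICD codes in longitudinal EHR data.

## The problem

Suicide-attempt outcomes in EHR-based risk prediction models are defined by
ICD diagnostic codes (ICD-9: E95\*, 965\*, 967\*, 969\*, 881\*; ICD-10-CM:
X71\*–X83\*, T14.91\*, and the T36\*–T65\* poisoning/toxic-effect families
with intentional-self-harm intent character `2`). A single attempt, however,
typically spawns a *cascade* of coded encounters — an emergency department
(ED) visit, an inpatient admission coded daily, outpatient follow-ups — so a
patient's record contains many recurrent codes that re-document one event.
Treating each code as a new attempt leaks the outcome into the predictor set
("data leakage") and inflates model performance; dropping all but the first
code discards prior attempts, the strongest known risk factor.

`sa-dedup` implements the full derivation pipeline for an automated
deduplication rule, and applies it:

1. **Case definition** (`sadedup.casedef`) — match ICD-9/ICD-10-CM codes,
   classify the attempt method (poisoning, cutting/piercing,
   hanging/strangulation/suffocation, jumping, firearm, other), and flag
   7th-character-`D` subsequent-encounter codes.
2. **Pairing** (`sadedup.events`) — collapse same-day encounters to
   patient-days and pair each coded day with the immediately preceding coded
   day; apply sampling frames (narrow: a pair 1–90 days apart; broad: ≥ 1 day)
   and sensitivity filters (contiguous-inpatient exclusion, ICD-9 exclusion).
3. **Estimation** (`sadedup.stats`) — for any stratum of labeled pairs, the
   positive predictive value that the second code marks a distinct event,

   PPV = k/n, 95% CI = PPV ± 1.96·√(PPV(1−PPV)/n)

   (unclipped Wald interval; pairs treated as independent), by clinical
   setting, method concordance and 7-day intercode-interval bin, plus
   *interval-floor* curves: PPV over pairs at least d days apart.
4. **Rule** (`sadedup.rule.IntervalFloorRule`, `sadedup.dedup`) — a
   scikit-learn style estimator that *fits* the smallest floor reaching a PPV
   benchmark (default 0.90) per stratum and *predicts* distinct/leaked status
   for unlabeled code streams. The headline rule: **an ED-documented
   suicide-attempt code at least 5 days after the preceding code is a new
   event**; a permissive preset adds a 53-day all-pairs floor for non-ED codes.
5. **Synthetic cohorts** (`sadedup.synth`) — a generator of labeled encounter
   tables with the observed leakage structure (≈82% nonindependent adjacent
   pairs, ~1-day median intercode interval), for end-to-end testing without
   access to protected clinical data.

## Worked example

```python
from sadedup import SimConfig, simulate_cohort, label_pairs, IntervalFloorRule
from sadedup.events import events_from_frame, aggregate_days, build_pairs, filter_to_frame
from sadedup.stats import ppv_by_setting

encounters, truth = simulate_cohort(SimConfig(n_patients=2000, seed=7))
days = aggregate_days(events_from_frame(encounters))
pairs = label_pairs(filter_to_frame(build_pairs(days), "narrow"), truth)
print(f"{len(pairs)} code pairs; "
      f"{100 * (1 - pairs['distinct_label'].astype(bool).mean()):.1f}% nonindependent")

print(ppv_by_setting(pairs)[["stratum", "n_pairs", "n_distinct", "ppv",
                             "ci_low", "ci_high"]].round(2).to_string(index=False))

rule = IntervalFloorRule(benchmark=0.90).fit(pairs)
print(f"derived ED floor: {rule.ed_floor_days_} days")
events = rule.annotate(days)
print(f"{int(events['is_distinct_event'].sum())} distinct events "
      f"over {len(events)} coded patient-days")
```

prints

```
7641 code pairs; 82.3% nonindependent
    stratum  n_pairs  n_distinct  ppv  ci_low  ci_high
nonED_nonED     3854         140 0.04    0.03     0.04
   ED_nonED     1995          89 0.04    0.04     0.05
   nonED_ED     1006         756 0.75    0.72     0.78
      ED_ED      786         368 0.47    0.43     0.50
    overall     7641        1353 0.18    0.17     0.19
derived ED floor: 4 days
3159 distinct events over 9647 coded patient-days
```

Most adjacent code pairs are nonindependent; a second code in a non-ED
setting almost never marks a new attempt (PPV ≤ 0.04), a second code in the
ED often does, and once an ED code falls at least `ed_floor_days_` after the
preceding code the PPV clears the 0.90 benchmark — only those days (and each
record's index day) are counted as events.

The same workflow is available from the shell:

```bash
sa-dedup simulate --seed 7 --n-patients 2000 --out cohort.csv --truth truth.csv
sa-dedup derive   --input cohort.csv --truth truth.csv --outdir derived/
sa-dedup apply    --input cohort.csv --rule derived/rule.json --outdir applied/
sa-dedup report   --events applied/events.csv --out report.json
```

`derive` writes the PPV tables (by setting, method, interval bin), the
interval-floor curves, the per-stratum floors, `rule.json` and a provenance
record; `apply` writes per-day distinct/leaked labels with event indices.

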