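# Methods

This note documents the models, rules, and numerical choices behind
`afcds`: what each component assumes, which parameters matter, what the
synthetic county does and does not emulate, and where the design was
genuinely open.

## 1. Coded-EHR data model

The unit of data is the coded patient record: demographics (birth date,
two-valued administrative sex, clinic listing), dated ICD-10 diagnoses, and
ATC-coded prescription intervals. Conventions:

* **Dates.** ISO-8601 in files, `datetime.date` in memory. Prescription
  intervals are closed on both ends: active on *d* means
  start ≤ *d* ≤ end; an open (ongoing) prescription has an empty
  `end_date` field and covers every date from its start.
* **Codes.** ICD-10 comparison is dot- and case-insensitive (`I48.1` ≡
  `i481`); matching is by configurable prefix, so `I48` covers the whole
  AF/flutter block. ATC matching is likewise by prefix, allowing class
  codes.
* **Loading.** Malformed rows abort a strict load, or are collected and
  reported together in lenient mode. Rows are never silently dropped:
  silently losing an untreated patient would inflate the adherence
  denominator's complement and bias the endpoint.

## 2. Risk engine

CHA₂DS₂-VASc is computed from the factor set evidenced by diagnoses with
onset on or before the assessment date, the age in completed years at that
date, and sex. The eligibility (guideline-indication) rule is AF/flutter
present **and** non-sex score ≥ 1; a woman whose single point is her sex is
deliberately not flagged, matching guideline practice of not treating
female sex as a sufficient indication.

Code lists are configuration, not algorithm. The shipped defaults:

| factor | ICD-10 prefixes |
|---|---|
| AF / flutter | I48 |
| congestive heart failure | I50 |
| hypertension | I10–I13, I15 |
| diabetes | E10–E14 |
| prior stroke / TIA / thromboembolism | I63, I64, G45, I74 |
| vascular disease | I21, I25.2, I70, I73 |

OAC set: B01AA03 (warfarin), B01AF02 (apixaban), B01AE07 (dabigatran),
B01AF01 (rivaroxaban). The thromboembolic outcome set reuses
I63/I64/G45/I74; bleeding defaults to the intracranial and
gastrointestinal haemorrhage blocks (I60–I62, K92.0–K92.2, D62). Chronic
kidney disease is a descriptive covariate only — it is not a score
component. The displayed annual stroke risk is a pure table lookup
(score → percent) shipped as data, validated to be non-decreasing, and
never used in any analysis.

## 3. CDS alert lifecycle

An alert fires at a chart login iff (a) an AF/flutter code predates the
login, (b) the eligibility rule holds, and (c) no configured OAC is active
on the login date. Evaluation is a pure function of (record, date, code
map) — hence idempotent, and trivially "no alert for treated patients".

Decision capture enforces the form's invariants at construction: refrain
requires one of three prespecified reasons (patient preference,
contraindication, other); "other" requires non-empty free text (a
mandatory field); prescribe requires an agent and appends an open-ended
prescription, which suppresses all subsequent alerts. Postpone leaves the
patient alertable at every later login — no snooze window is applied; a
suppression period would be a one-line change but there is no basis for
choosing its length. The generated note is a deterministic template
(date, score, decision, reason), enabling byte-identical regression tests.

Accounting: the first-alert series bins each alerted patient once, at their
earliest alert month, so the series sums to the number of distinct alerted
patients. The deviation summary partitions unique refusing patients by
their **most recent** recorded reason — a patient who first refuses for
contraindication and later for "other" counts once, under "other". Latest
reason was chosen over first/any because the most recent decision is the
clinically operative one.

## 4. Synthetic county

The generator emulates a county of 43 primary-care clinics with ~444,000
inhabitants and ~14,000 AF patients, of whom ~95% carry a treatment
indication.

* **Clinic sizes**: log-normal by moment matching (mean 10,300, SD 4,400),
  truncated below at 1,000 and rescaled to sum to the configured county
  total (444,347 by default). Rescaling keeps the county-wide AF count
  binomially tight; without it, clinic-size sampling noise alone gives the
  total a ~6.5% SD.
* **AF cohort mix**: age bands 15% / 27% / 58% (<65, 65–74, ≥75), 43%
  female. Risk-factor prevalences are specified **per age band** and
  chosen so that the mixture reproduces the county marginals
  (hypertension 0.77, CHF 0.35, diabetes 0.23, vascular 0.33, prior
  stroke/TIA/TE 0.18) while patients under 65 are healthy enough that
  ~5% of the cohort has no indication. Factors are sampled independently
  given the age band; only marginals are targeted — the true comorbidity
  joint distribution (e.g. hypertension–diabetes correlation) is not
  emulated, a noted limitation. `marginal_report` audits realized vs
  target marginals from the coded records alone.
* **Between-clinic adherence heterogeneity**: clinic propensities
  p_j ~ Beta(α, β) with mean 0.70 and pairwise ICC ρ = 1/(α+β+1) = 0.01 —
  the standard exchangeable-clusters (beta-binomial) model. Each eligible
  patient is treated at baseline with probability p_j; treated patients
  receive an open-ended prescription for a random one of the four agents.
* **New AF entrants** appear at 4.32 per 1,000 at-risk person-years
  (~1,860/year county-wide), with a lighter comorbidity mix (their own
  band-specific prevalence table, targeting hypertension 0.69, CHF 0.17,
  diabetes 0.18, vascular 0.19, prior stroke 0.14, ~92% with indication).
  Their onset is strictly after the baseline census, so they enter
  denominators only from diagnosis.

### Follow-up behaviour (calibrated defaults)

Encounters are Poisson at 4 visits/patient-year (configurable; primary-care
contact rates for elderly AF patients are plausibly 3–6/year). At each
encounter of an untreated eligible patient:

* control arm: background initiation with probability 0.021;
* intervention arm: the CDS is evaluated; on an alert the physician
  prescribes with combined probability 1−(1−0.021)(1−0.015) (background
  plus alert response), refrains with probability 0.095 (reason split
  0.25/0.32/0.43 over preference/contraindication/other), else postpones.

Treated patients discontinue at 0.015/year. Newly diagnosed patients are
initiated at the diagnosis visit with probability 0.70 in both arms.
Thromboembolic hazards are 0.044/yr (treated) and 0.072/yr (untreated);
bleeding 0.020/yr among treated; both discretized monthly
(1−exp(−h/12)), at most one event of each type per patient, and written
back into the record as coded diagnoses (so a simulated stroke raises the
patient's subsequent score).

These defaults were calibrated jointly so the simulated county reproduces
the observed county-wide trajectories this tool produced in practice:
control adherence drifting 70% → ~71.2%, the intervention arm adding
~+1.6 pp beyond that (WLS effect ≈ 0.015–0.016), ~49 and ~47
thromboembolic events per 1,000 AF patients, ~12–16 bleeds per 1,000, and
~660 unique patients with a recorded deviation reason (~43% "other"). One
observed feature is deliberately not reproduced: the arms' *different*
bleeding rates (12 vs 16 per 1,000) — the simulator applies one bleeding
hazard to all treated patients, so both arms land near 13–14; reproducing
an arm difference would require an arm-specific hazard with no mechanistic
justification.

**Closure.** By default one randomly chosen control clinic closes at month
6; its patients (including entrants diagnosed there) are reassigned to the
remaining clinics with probability proportional to list size, across both
arms. A reassigned patient follows the behaviour of the arm they sit in at
each encounter; censuses count them at their new clinic, and the closed
clinic ends with denominator 0 and is excluded from the regression — the
analyzed set is therefore 42 clinics under their original assignments.

**Determinism.** All randomness flows from one seed through named
substreams (`county`, `encounters`, `events`), derived from the seed via
`SeedSequence` spawn keys built from the stream name's bytes — stable
across processes and platforms. Identical (config, seed) gives
byte-identical registries and event logs.

What the synthetic county does **not** emulate: mortality, migration other
than the closure, within-year treatment switching between agents, any
causal effect of treatment on stroke beyond the configured hazard
difference, correlated comorbidities, seasonal encounter patterns, and
physician-level (as opposed to clinic-level) behaviour variation. Passing
tests therefore demonstrate correctness of the machinery and
recoverability of configured parameters — not transportability of the
calibrated effect to other settings.

## 5. Trial design

* **Stratification**: four strata from crossing a median split on list
  size with a median split on baseline adherence. A clinic exactly at a
  median goes to the lower stratum (deterministic tie-break).
* **Randomization**: within each stratum a seeded uniform balanced split.
  Odd strata each leave one clinic over; the leftovers are assigned from a
  random *balanced* arm pattern rather than independent coin flips, so the
  county's total split is always as even as possible (22/21 for 43
  clinics).
* **Sample size**: the two-proportion formula with rounded quantiles
  (1.96, 0.84) by default; exact quantiles (±0.0004 precision) give a
  slightly larger n and are available via `z_mode="exact"`. For
  0.70 vs 0.75 at α=0.05, power 0.80 the rounded mode gives 1,247/arm
  (2,494 total), the exact mode 2,496. The ICC enters only through the
  separately reported design-effect inflation 1+(m−1)ρ — the base figure
  is the unadjusted formula, which is what the printed 2,494 corresponds
  to; conflating the two would misstate both.
* **Power by simulation** distributes the computed n over 40 equal
  clusters per arm, draws beta-binomial trials at the spec's proportions
  and ICC, and runs the primary analysis on each replicate. 40 clusters
  keeps the t-test's residual df high enough (~77) that the finite-cluster
  df penalty does not depress power relative to the normal-theory formula
  being verified; with the county's own 43 clusters the same simulation
  runs ~2 pp lower. A `true_effect` override supports type-I-error runs
  (zero effect at the computed n).

## 6. Trial analysis

* **Census**: denominator = patients with AF on or before the census date
  and non-sex score ≥ 1; numerator = the subset with an active OAC. Empty
  clinics are carried as 0/0 and excluded from regression.
* **Primary analysis**: WLS of follow-up proportion on {1, arm, baseline
  proportion}, weights = follow-up eligible denominators ("cluster size"
  is ambiguous between baseline and follow-up; follow-up is the analyzed
  outcome's sample size, and a `weights="baseline"` option preserves the
  alternative). Inference is classical normal-theory WLS via statsmodels
  (t-based, df = k−3). A constant baseline column (degenerate but legal)
  is dropped rather than crashing on collinearity.
* **Arm-level adherence** is reported three ways — pooled Σnum/Σden,
  unweighted cluster mean, and denominator-weighted cluster mean — because
  printed arm percentages in cluster trials often match none of them
  exactly; the report labels which is which instead of silently choosing.
* **ICC**: Shrout–Fleiss one-way random-effects ICC(1,1) with the standard
  unbalanced-design n₀ = (N − Σn_j²/N)/(k−1). For binary data the
  patient-level ANOVA is computed exactly from clinic numerator/denominator
  pairs without expanding rows (SSW = Σ n_j p_j(1−p_j)). Negative
  estimates are reported as computed, not truncated at zero.
* **Event comparisons**: Pearson chi-squared on the 2×2 table without
  continuity correction (the uncorrected statistic is the default in the
  major statistics packages; the corrected variant is a flag), rates per
  1,000 with normal-approximation binomial CIs. Degenerate tables (no
  events, or all events) are reported with χ²=0, p=1.
* **Quartile subgroups**: the primary analysis re-run within the first and
  fourth quartiles of baseline adherence (25th/75th percentile
  boundaries); a subgroup with fewer than two clinics in either arm is
  flagged inestimable rather than fitted.
* **Safety extractions** at 3/6/9/12 months: among patients initiated on
  an OAC after study commencement (first qualifying start strictly after
  the study start), the proportion with a bleeding event on or before the
  extraction date, compared between arms; the per-1,000-AF-patients
  variant of the same numerators is reported alongside, because the two
  denominators answer different questions (risk among the newly treated
  vs population burden) and both are in circulation.
* **Multiplicity**: no adjustment is applied anywhere; secondary p-values
  are unadjusted by construction.

An XLSX importer (`read_cluster_table_xlsx`) accepts cluster-level
workbooks (clinic, arm, baseline and follow-up numerators/denominators) so
the identical analysis path can run on externally published cluster tables.

## 7. Problem sizes in tests and the acceptance script

The statistical calibration checks (type-I error over 1,000 null trials,
ICC recovery over 500 replicates, effect recovery over 500 trials, power
over 2,000 replicates) run on the cluster-level beta-binomial trial
generator — the exact data model the primary analysis consumes — which
makes each check a matter of seconds. Alert-lifecycle invariants run on a
full 12-month patient-level simulation of a 10-clinic county. The
acceptance script simulates eight full-scale (43-clinic, ~14,000-patient)
county trials end to end and averages their estimates; a single replicate's
effect estimate has SD ≈ 0.004, so the 8-replicate mean pins the recovered
effect to ≈ ±0.003.

## 8. Known limitations

* Factor marginals, not joint distributions, are matched; real comorbidity
  clustering would raise score variance slightly.
* The eligibility denominator uses the package's single census definition
  throughout; published trial tables of this design sometimes mix
  denominators across time points, and no reconciliation is attempted.
* The simulator's bleeding model cannot produce arm-different bleeding
  rates (single hazard among treated).
* Real EHR session semantics ("login") are reduced to encounter records;
  alert fatigue, UI behaviour, and physician identity are out of scope.
* ICC(1,1) is the one-way variant; two-way or consistency variants would
  differ for the same data.
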