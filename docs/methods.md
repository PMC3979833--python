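# Methods

This note documents the models and procedures `dilipipe` implements, the
choices made where the design was genuinely open, and what the synthetic
cohort does and does not emulate.

## Reference limits

Each analyte's upper limit of normal (ULN) is the arithmetic mean of the
cohort's week-0 values after symmetric trimming: `floor(n·f/2)`
observations removed per tail at trim fraction `f` (default 0.05). "Exclude
the extreme 5%" is ambiguous between two-sided and top-only trimming; we
default to the symmetric reading, which is standard trimmed-mean practice
for reference intervals, and expose `one_sided=True` (top `floor(n·f)`
removed) as the alternative. Only ALT is sex-stratified, because only ALT
has a sex-specific published limit; other analytes pool sexes. Each stratum
requires ≥ 20 baselines. Floor-based trim counts make the limit invariant
to input order always, and to whole-sample replication whenever the floored
tail count scales consistently (it always does at `f = 0.05` for strata of
the sizes this pipeline targets). The packaged published limits (ALT 33/29,
AST 41, ALP 128, TBIL 1.0, DBIL 0.3) are used when raw baselines are
unavailable; they are not recomputable from any data shipped here.

## Adjudication

**Branch choice is per analyte.** ALT's reference is its ULN or the
patient's baseline ALT (whichever rule the baseline status selects), and
ALP's is chosen independently from baseline ALP. The alternative — one
branch for both analytes once *either* baseline is elevated — would grade
a normal-baseline analyte against an unrelated reference; the per-analyte
reading is the conservative interpretation of "changes relative to their
respective baseline value".

**Rule order.** The three case rules are tested in the fixed order ALT,
ALP, combination; the first satisfied rule is recorded as the qualifying
criterion. Thresholds are inclusive (ALT exactly 5× qualifies).

**R-value always uses ULN normalisation**, including for baseline-elevated
patients: R describes the biochemical signature (transaminase- vs
phosphatase-dominant) of the injury, not its treatment-emergence.
Boundaries: R = 2 is cholestatic, R = 5 hepatocellular.

**Severity bands are contiguous half-open intervals.** The printed band
edges (1.25–2.5, 2.6–5, 5.1–10, >10; and 2.6–3.5, 3.6–5, >5 on the
baseline-relative scale) contain gaps at 2.5/2.6 etc.; we implement
[·, 2.5), [2.5, 5), [5, 10), [10, ∞) and [·, 2.5), [2.5, 3.5), [3.5, 5),
[5, ∞), a gap-free total function deviating ≤ 0.1× from any printed edge.
The driving fold is the larger of the ALT and ALP folds, each against its
own branch reference. A case whose driving fold is below 1.25 (possible
when the ALP rule fired at 2× but the grading scale is baseline-relative)
clamps to grade 1; a case is never grade 0. Clinical escalation is
monotone: TBIL ≥ 2×ULN ⇒ grade ≥ 2; additionally any of {INR ≥ 1.5,
ascites, encephalopathy, other organ failure} ⇒ grade ≥ 3; death or
transplantation due to DILI ⇒ grade 4. The grade-3 qualifiers "duration
< 26 weeks" and "absence of cirrhosis" are recorded as flags but not
enforced as necessary conditions — the grading text does not state them as
such.

**Missing data.** A visit missing both ALT and ALP contributes nothing. If
ALT or ALP is missing at the qualifying visit, the grade is computed from
the available fold and the pattern is marked `unclassifiable` (excluded
from pattern tables, counted separately). Duplicate (patient, week) visit
rows are a validation error, so no same-week repeat panel lookup exists.
Patients without a week-0 panel cannot be adjudicated; in batch mode such
errors are collected per patient rather than aborting the cohort.

**Censoring.** Default analysis cutoff 24 weeks (completion of anti-TB
therapy), configurable to 48. Non-cases are censored at
min(last follow-up, cutoff); patients lost to follow-up are censored at
their last observed visit — the monitoring design gives no information
between visits, and no imputation is attempted.

## Cohort statistics

Odds ratios use OR = ad/bc with the Woolf log-normal interval; a zero cell
triggers the Haldane–Anscombe +0.5 on every cell (method labelled
accordingly). With both case cells zero the OR is reported as an error, not
a number. P-values: Pearson chi-square without continuity correction, or
Fisher's exact test when any expected cell is < 5; Bonferroni adjustment
`min(1, k·p)` across a declared family of k comparisons. Percents are
rounded to one decimal and ratios to two, matching the reporting convention
of the tables the pipeline reproduces. (The Woolf interval reproduces the
published upper CI bounds exactly at two decimals; published lower bounds
differ by ±0.01–0.03, so the exact CI procedure used upstream is unknown
and only point estimates and upper bounds are targeted.)

Survival estimation uses lifelines: Nelson–Aalen with d/n increments (no
tie smoothing), Kaplan–Meier for the survival complement. The Cox workflow
fits one single-covariate model per declared variable (Efron approximation
for the tied onset weeks an interval visit schedule produces), flags
p < 0.1 (default) for entry, then removes the largest p ≥ 0.05 (default)
one at a time with refitting until all retained variables pass or one
remains. The removal threshold is a design choice (only the entry threshold
is specified by the workflow we reproduce) and is configurable. Constant
covariates are excluded as uninformative; exactly collinear covariates are
dropped deterministically, later-declared first; non-converging univariate
fits are excluded with a note.

## Synthetic cohort generator

The generator emulates the four-arm cohort's *structure*: arm sizes
(273/495/83/209), per-arm event probabilities (0.088/0.242/0.108/0.029),
onset medians (4/1/2/6 weeks), per-arm pattern mixtures, the pooled grade
mixture (53.5/32.7/11.3/2.5%), baseline covariate medians/IQRs per arm
(normal or log-normal families, clipped to plausible ranges — the source
tables give only medians and IQRs, so the family is a modelling choice),
sex/HBsAg/HCV prevalences, HAART regimen mixes, and a 6% dropout rate.

**Constraint-built trajectories.** For each planted case the generator
samples ALT/ALP/TBIL folds uniformly from the interior of the feasible box
for the assigned (pattern, grade) cell — every boundary (case rule,
R-value cut, band edge, escalation threshold) is approached no closer than
a fixed margin (≥ 2% of the local band width; e.g. ALP folds for a grade-1
case are drawn from [2.05, 2.45] against the rule's [2, 2.5)). Pre-onset
and non-case panels wander multiplicatively around baseline but are capped
at 2.6×/1.8×/1.8× of the ALT/ALP/TBIL references, ≥ 7% below every rule
threshold. Adjudication outcomes are therefore decided with margin at
every visit, and planted-truth recovery is exact rather than
probabilistic — which is what the recovery tests assert.

**Feasibility.** Under the ULN grading scale, grade 1 forces the ALP-rule
geometry (ALP fold in [2, 2.5), ALT fold < 2.5), which pins R < 1.25:
grade-1 hepatocellular and grade-1 mixed cells are impossible. Pattern and
grade are therefore sampled jointly from the product of the configured
mixtures conditioned on feasible cells; a configuration whose entire joint
mass is infeasible raises an error naming the cells. Grades 2–4 are planted
via band folds alone (the hepatocellular grade-2 cell uses the
ALT + bilirubin combination rule, whose TBIL ≥ 2 escalation lands exactly
at grade 2); clinical-flag escalation paths are exercised by unit tests
rather than by the generator.

**Planted cases are built on the baseline-normal branch** (baseline ALT/ALP
clipped to 0.92×ULN) so case folds and the R-value share the ULN reference
and the fold constraints stay exactly solvable. Baseline-elevated branches
are exercised by non-case trajectories and by direct adjudication tests.
Real cohorts, of course, contain baseline-elevated *cases*; passing
recovery tests demonstrate correctness of the decision logic, not
distributional realism of that subgroup.

**Onset weeks** follow a truncated geometric distribution over the
monitoring grid {1, 2, 4, 8, 12, 24}, the simplest one-parameter family
matching a target median on a discrete grid. For an on-grid target the
parameter is solved (Brent) so the CDF brackets 0.5 with balanced margins,
making the sample median stable. A between-visit target (week 6, the
midpoint of weeks 4 and 8) is representable only as CDF(4) = 0.5 — no
distribution on the grid has an almost-sure sample median of 6 — so the
sample median is bracketed by the neighbouring visit weeks instead; this is
a property of interval-scheduled monitoring, not of the generator.

**Dropout** truncates the visit series at a uniformly drawn grid week. A
planted case whose dropout precedes its onset is recorded in the truth
table as a non-event with a `truncated` flag: it is a *designed*
non-detection and counts toward specificity. This deflates realized
incidence below the nominal probability by under half a percentage point at
the default 6% dropout, well inside the binomial tolerance the calibration
tests use.

**Covariate effects** (`covariate_effects`) perturb the per-arm event
probability through a logistic link on standardized covariates — a
discrete-time approximation to proportional hazards on a coarse visit grid.
The Cox log-HR estimand is attenuated relative to the logistic coefficient
by a factor of roughly (1 − p̄); the parameter-recovery test therefore runs
at event probability 0.05 and effect +0.4 per SD (20 replicates of 3,000
patients), where the attenuation (≈ 0.02) is well below one standard error
(≈ 0.08) and 2-SE coverage is essentially nominal.

## Numerical and reporting conventions

CSV round-trips are exact: floats are written with `repr` precision and
re-parsed bit-identically. Validation reports *all* violations, not the
first. Generation is deterministic given (config, seed); a config digest is
stamped into the cohort provenance. Monte-Carlo checks in the test suite
use fixed literal seeds; the acceptance script derives all sub-seeds from
its `--seed` via `SeedSequence.spawn`. Simulation sizes in tests (e.g.
n = 2000 for hazard-ratio recovery, 500 × n = 200 for screen calibration,
10,000 for incidence convergence) are chosen as the smallest that give the
asserted tolerances comfortable binomial/normal coverage.

## Known limitations

- No causality assessment (RUCAM), re-challenge modelling, or
  hepatitis-flare differential; elevated panels are attributed to treatment
  by design.
- The generator assigns onset independently of covariates unless
  `covariate_effects` is set, simulates no virologic/immunologic
  trajectories, and draws covariates independently within arm (no
  correlation structure).
- Severity escalation flags are patient-level constants, not time-varying
  clinical states.
- The Cox stage assumes proportional hazards and uses complete-case
  handling of missing covariates; no imputation, competing risks, or
  time-varying covariates.
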