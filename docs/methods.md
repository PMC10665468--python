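# Methods

This note documents the models implemented by `malnut`, the design choices
made where the published descriptions were ambiguous, what the synthetic
cohort generator does and does not emulate, and known limitations.

## Scope and intent

The package targets retrospective research on orthopedic-surgery cohorts
where only routinely-collected variables exist: age, sex, weight, height,
ASA physical status, and a routine lab panel (albumin, prealbumin, CRP,
differential counts, hemoglobin, red-cell indices).  It computes eight
screening scores and one probable-diagnosis classifier, all threshold-based.
It does **not** implement interview-based screening questionnaires
(MST, NRS-2002, MUST, MNA-SF, PG-SGA SF), canonical GLIM criteria that need
weight-loss history, food intake or muscle mass, severity grading, or any
outcome modelling; and it makes no treatment recommendations.

## Units and missingness

All values are stored in one canonical unit per analyte: albumin g/L,
prealbumin mg/L, CRP mg/L, cell counts cells/µL, hemoglobin g/L, MCV fL,
MCH pg, MCHC g/dL, weight kg, height cm.  The published formulas mix
dialects (GNRI takes albumin in g/L while INA/LxA/PMA/PMAC take g/dL), so
each scoring function converts internally from canonical storage to the
unit its formula expects.  Ingestion converts declared source units by exact
fixed factors; the supported dialects are enumerated in
`malnut.core_model.UNIT_FACTORS` and a round-trip property test holds each
conversion to 1e-12 relative error.

Missing measurements are represented as `None`, never as sentinel numbers.
Each score checks its own requirement list and returns a not-applicable
result with a reason string naming the limitation; a ragged cohort is scored
row by row and never aborts the batch.

## The scores

### BWd — body weight difference

`value = ABW − IBW` (kg).  A loss greater than 10 % of IBW codes 1 (risk of
undernutrition), a gain greater than 10 % codes 2 (risk of overnutrition),
anything within the band — including a deviation of exactly 10 % — codes 0.
The source table's coding column swaps the "loss"/"gain" parentheticals
between codes 1 and 2; we follow the semantics (loss → undernutrition),
which matches the equations column.  Ideal body weight is not part of the
published material; we default to the Lorenz formula
(men: H−100−(H−150)/4; women: H−100−(H−150)/2.5, H in cm) because the
original GNRI cohort used it, with Devine
(50 kg / 45.5 kg + 2.3 kg per inch over 5 ft) selectable via config.  A
property test keeps the two within a 15 % envelope over 150–190 cm.

### GNRI — geriatric nutritional risk index

`value = 1.489·ALB(g/L) + 41.7·min(ABW/IBW, 1)`.  The weight ratio is
capped at 1 by default (being above ideal weight does not offset
hypoalbuminemia, as in the original index); the cap is config-removable.
Risk bands: major < 82, moderate [82, 92), low [92, 98], no risk > 98 —
the published moderate band stops at 91.9 and resumes at 92; we close the
gap with a half-open interval so classification is total.  The index was
developed in geriatric patients, so by default the pipeline gates it to the
senior age class (≥ 70 years) and reports younger patients as
not-applicable; `gnri_senior_only: false` computes it anyway for
retrospective use.

### INA, LxA, PMA

INA classifies the albumin × lymphocyte quadrants at 3.5 g/dL and
1 500 cells/µL; both boundaries are inclusive on the no-risk side.  LxA is
the product LYMC(/µL)·ALB(g/dL), banded poor ≤ 4 515 < middle ≤ 7 920 <
good.  PMA is CRP(mg/L)/ALB(g/dL), banded at 0.4 / 1.2 / 2.0 with
left-closed upper bands.

### PMAC and IDM — cohort-relative scores

PMAC is `(NLR + CRP(mg/L)) / (ALB(g/dL) + PALB(mg/L))`.  IDM is the Ganzoni
total-body iron deficit `ABW·(IHB − AHB)·2.4 + 500 mg`.  The printed
Ganzoni form writes hemoglobin in g/L, but the classical 2.4 factor assumes
the difference in g/dL (it is 0.24 for g/L); we convert the difference to
g/dL before multiplying, which keeps the +500 mg depot term and the usual
order-10³ mg repletion magnitudes coherent.  Ideal hemoglobin is not
defined by the published material; we default to the standard Ganzoni
target of 15 g/dL for men and 14 g/dL for women, configurable per cohort
(`ihb_policy`).  A patient whose actual hemoglobin exceeds the ideal is
outside the score's domain (not applicable), not clamped to zero.

Neither score has published cutoffs; codes 0–3 are the cohort's own
quartiles: < 25th percentile → 0, [25th, 50th) → 1, [50th, 75th) → 2,
≥ 75th → 3.  Percentiles are estimated by linear interpolation over the
non-missing values (numpy's default, R type 7).  Consequences of that
single deterministic choice: ties share a code, an all-equal cohort
degenerates to everyone at code 3 (each value is ≥ its own 75th
percentile), and a cohort with fewer than 4 codable values cannot define
quartiles — coding is then refused with an explicit reason while the
continuous value is preserved (`extra["uncoded_value"]` and the CSV value
column) so cohorts can be pooled and recoded.  Percentiles are whole-cohort;
no subgroup (e.g. per-sex) standardization is attempted.

### VBD — vitamin-B deficit indicator

The published rule is symbolic ("MCV↑ AND MCH↑ OR MCHC↓") with two possible
precedences.  The score targets macrocytic hyperchromic anemia, so
macrocytosis is treated as necessary: code 1 iff MCV > 100 fL **and**
(MCH > 34 pg **or** MCHC < 32 g/dL).  The alternative reading
`(MCV↑ ∧ MCH↑) ∨ MCHC↓` is available behind
`vbd_macrocytosis_required: false`, and all three reference limits are
config-exposed since the publication gives only arrows.

### NLR grading

NLR = NEUTC/LYMC, graded normal < 2 ≤ low < 4 ≤ mild < 6 ≤ moderate < 8 ≤
severe.

### GLIM from routine data

Phenotypic criterion: BMI < 20 kg/m² below 70 years, < 22 kg/m² at ≥ 70.
Etiologic criteria: disease burden ASAPS ≥ 2; inflammation CRP > 5 mg/L
(strict) or NLR ≥ 6 (inclusive) — the asymmetry of the inequalities is
deliberate fidelity to the published note.  Codes: 3 when disease burden
and at least one inflammatory marker are present, 2 with disease burden but
quiet markers, 1 with nothing elevated.  Two decisions where the published
rows are ambiguous:

* With discordant inflammatory markers both the with- and
  without-inflammation rows are literally satisfiable (the without-row uses
  an OR of quiet markers).  We give precedence to DRM **with** inflammation:
  one elevated marker is the clinically dominant etiology.
* Low BMI + no disease burden + elevated inflammation matches no published
  row.  Rather than inventing a class, the patient is reported
  not-applicable with reason "unclassifiable combination"; the exhaustive
  truth-table test pins this to exactly the three such boolean patterns.

A BMI at or above the cutoff means no phenotypic criterion and hence no
diagnosis: not-applicable, not "code 0".

### Age and BMI categories

Younger adult < 40 ≤ adult < 70 ≤ senior (70 is senior: the explicit
inequality in the source is ≥ 70).  BMI categories are age-adjusted; below
70 years the usual bands apply (< 18.5 underweight, [18.5, 25) normal,
[25, 30) overweight, then obesity I/II/III at 30/35/40).  Senior bands are
shifted (underweight < 25, normal 25–35, then 35–40 / 40–45 / 45–50 / > 50)
and published with 0.1-wide gaps ("25.0–35.0" then "35.1–40.0"); we close
them as upper-closed intervals ((35, 40] overweight, etc.) so that every
positive BMI classifies deterministically — a partition property test
covers both band systems.

## Pipeline behavior

`score_cohort` derives BMI, IBW, NLR and age class per patient, computes
the selected scores honoring each score's applicability rules, finalizes
the cohort-relative codes, and attaches a summary table (per score: counts
and proportions per code over applicable patients, plus counts per
not-applicable reason; counts conserve cohort size).  Single-patient
results from `score_patient` carry a provisional code of −1 for PMAC/IDM
until cohort coding runs.  Scoring is fully deterministic: identical input
and config produce byte-identical output CSVs.

The CSV dialect is fixed (comma, header, `.` decimal, UTF-8, `\n` line
endings — no locale inference) for the same reason.  Malformed numeric
cells become missing values with a logged warning naming row and column;
duplicate patient ids and absent mapped columns are hard errors.  Floating
values are written with `repr`, i.e. shortest round-tripping decimal.

## Synthetic cohorts

`generate_cohort(n, seed, mix)` draws patients from plausible clinical
distributions — albumin ~ N(42, 3) g/L truncated at 30, CRP ~ LogNormal(ln 2,
0.5) mg/L, lymphocytes ~ N(2200, 400) /µL truncated at 800, neutrophils ~
N(4500, 900), hemoglobin ~ N(145, 10) g/L, MCV ~ N(90, 4) fL, MCH ~ N(30,
1.5) pg, MCHC ~ N(34, 1) g/dL, prealbumin ~ N(250, 40) mg/L, BMI ~ N(26, 3),
age ~ N(68, 12) clipped to [18, 95], heights N(175, 7)/N(162, 6) cm by sex —
and then applies per-phenotype overrides that push the relevant analytes
decisively across the classifier thresholds:

* *undernourished_inflamed*: BMI drawn at least 1 kg/m² below the GLIM
  cutoff, ASAPS ∈ {3, 4}, CRP > 10 mg/L → forces GLIM code 3;
* *undernourished_clean*: low BMI, ASAPS 1, CRP < 2, NLR < 2 → GLIM code 1;
* *overnourished*: ABW ≥ 1.16 × IBW → BWd code 2;
* *b_deficient*: MCV > 102 fL and MCH > 35 pg → VBD code 1;
* *iron_deficient*: hemoglobin ≥ 21 g/L below the ideal → IDM applicable;
* *healthy*: BMI kept ≥ 23 (above both GLIM cutoffs), ASAPS ∈ {1, 2} →
  GLIM not applicable, VBD expected 0.

The default case mix (55 % healthy, 10 % undernourished-inflamed, 5 %
undernourished-clean, 15 % overnourished, 5 % B-deficient, 10 %
iron-deficient) is a plausible elective-orthopedic composition chosen once
and deliberately weighted toward the phenotypes the tools exist to find.
These distributions are **test fixtures with clinically sensible
magnitudes, not a model of any real population**: marginals are independent
given the phenotype, there is no correlation structure between analytes, no
assay noise or batch effects, and no informative missingness
(`inject_missingness` blanks fields independently at a fixed rate).
Passing the recovery tests therefore demonstrates that the classifiers
implement their thresholds and coding correctly — not that the scores are
valid in any real cohort.  The overrides leave a ≥ 1-threshold-unit margin,
so forced codes are recovered deterministically up to rounding of the
stored values (records are rounded to realistic lab precision); the
recovery tests allow 1 % boundary grazes at n = 500.

## Numerical choices

* All band edges follow the conventions stated above; every one is
  recovered from the implemented classifiers by black-box bisection to
  1e-9 in the test suite, against the single threshold registry
  (`malnut.screening_scores.THRESHOLDS`) that documentation and tests share.
* Percentile estimator: linear interpolation (inclusive), minimum cohort
  size 4, ties share codes.
* Unit conversions are single multiplications by exact decimal factors.
* Test problem sizes: property tests run a few hundred examples each;
  partition checks use 10⁵ random inputs per score; phenotype-recovery runs
  n = 500 per phenotype; the whole suite completes in well under a minute.

## Known limitations

* The scores are screening surrogates; none is validated here against
  outcomes, and the package makes no claim about their prognostic value.
* The GLIM operationalization cannot see weight-loss history, food intake
  or muscle mass; true malnutrition with preserved BMI is invisible to it.
* Cohort-relative PMAC/IDM codes are not comparable across cohorts; pooling
  before coding is the intended workaround.
* All inputs are assumed assay-harmonized; no cross-assay calibration is
  attempted.
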