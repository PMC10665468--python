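# malnut

Batch scoring of malnutrition risk and probable malnutrition diagnosis from
**routinely-collected orthopedic-surgery data**.

Retrospective orthopedic databases (hip, knee, spine surgery) rarely contain
the interview and body-composition measurements that canonical malnutrition
screening and diagnosis require.  What they do contain are demographics,
weight and height, and routine labs: albumin, prealbumin, C-reactive
protein, differential blood counts, red-cell indices, and the ASA physical
status class.  `malnut` implements a toolkit of literature-based substitute
scores computable from exactly those variables, for researchers who want to
classify historical patients as at-risk or probably malnourished:

| Score | What it measures | Form |
|---|---|---|
| **BWd**  | deviation of actual from ideal body weight beyond the 10 %-of-IBW minimal clinically important difference | ABW − IBW (kg) |
| **GNRI** | geriatric nutritional risk index | 1.489·ALB(g/L) + 41.7·ABW/IBW |
| **INA**  | instant nutritional assessment (protein / energy / protein-energy risk) | ALB < 3.5 g/dL × LYMC < 1 500 /µL quadrants |
| **LxA**  | lymphocyte-albumin product | LYMC(/µL) · ALB(g/dL) |
| **PMA**  | protein malnutrition with acute inflammation | CRP(mg/L) / ALB(g/dL) |
| **PMAC** | protein malnutrition with acute and chronic inflammation | (NLR + CRP) / (ALB(g/dL) + PALB(mg/L)), coded by cohort quartiles |
| **IDM**  | total-body iron deficit (Ganzoni) | ABW · ΔHb(g/dL) · 2.4 + 500 mg, coded by cohort quartiles |
| **VBD**  | functional vitamin-B deficiency (macrocytic hyperchromic indices) | MCV↑ and (MCH↑ or MCHC↓) |
| **GLIM** | probable malnutrition diagnosis from routine data | low BMI (< 20, or < 22 at ≥ 70 y) + ASAPS ≥ 2 / CRP > 5 mg/L / NLR ≥ 6 |

Every score carries its published categorical coding, its applicability
rules (which inputs it needs, which patients it is defined for), and an
explicit reason string when it cannot be computed.  The GLIM classifier
distinguishes clean undernutrition (code 1), disease-related malnutrition
without inflammation (2), and with inflammation (3).  Units are handled by
an explicit conversion layer — source data may arrive in g/dL, 10⁹/L, etc.
and are converted once at ingestion.

Because no public reference dataset exists for these scores, the package
ships a seeded synthetic-cohort generator that plants nutritional
phenotypes (undernourished with/without inflammation, overnourished,
B-vitamin deficient, iron deficient, healthy) whose expected codes are
known by construction; the test suite recovers them after scoring.

## Worked example

```python
from malnut import PatientRecord, Sex, score_patient

rec = PatientRecord(patient_id="P001", age=78, sex=Sex.FEMALE, abw=48.0,
                    height=160.0, alb=29.0, palb=140.0, crp=22.0,
                    lymc=1200.0, neutc=8400.0, ahb=105.0, mcv=88.0,
                    mch=29.0, mchc=33.0, asaps=3)
for score, res in score_patient(rec).items():
    print(score.value, res.value, res.code, res.reason)
```

prints

```
GLIM  value=None        code=3   applicable=True
BWd   value=-8.0        code=1   applicable=True
GNRI  value=78.92385... code=3   applicable=True
INA   value=None        code=3   applicable=True
LxA   value=3480.0      code=2   applicable=True
PMA   value=7.58620...  code=3   applicable=True
PMAC  value=0.20293...  code=-1  applicable=True
IDM   value=903.2       code=-1  applicable=True
VBD   value=None        code=0   applicable=True
```

This 78-year-old woman is 8 kg below her Lorenz ideal weight — more than
10 % of it, so BWd flags risk of undernutrition (code 1).  Her GNRI of 78.9
(1.489 × 29 + 41.7 × 48/56) is below 82: major risk.  Albumin 2.9 g/dL and
lymphocytes 1 200/µL put INA in the protein-energy quadrant (code 3), the
LxA product 3 480 is in the poor band, and a CRP/albumin ratio of 7.6 is
high-risk PMA.  With BMI 18.75 < 22, ASAPS 3 and CRP 22 > 5 mg/L, GLIM
diagnoses disease-related malnutrition **with** inflammation (code 3).  Her
Ganzoni iron deficit is 48 × 3.5 × 2.4 + 500 = 903.2 mg.  PMAC and IDM show
code −1 here because their 0–3 codes are quartiles of the *cohort* being
scored: `score_cohort` (not the single-patient call) finalizes them.

The same pipeline runs from the shell:

```bash
malnut synth --n 500 --seed 42 --output cohort.csv   # synthetic cohort + truth labels
malnut score --input cohort.csv --output scored.csv  # per-patient values/codes/reasons
malnut summarize --input cohort.csv                  # per-score prevalence table
```

Column names, source units (e.g. albumin in g/dL), ideal-hemoglobin policy,
thresholds and flags are set in a YAML config passed with `--config`; see
`docs/methods.md`.

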