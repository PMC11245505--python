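# ulcerquant

Quantification of corneal ulcer lesions from slit-lamp region masks, and
machine-learning prognosis of corneal perforation and vision outcomes.

Corneal ulcers can progress to perforation and permanent visual impairment,
and judging that risk from a slit-lamp photograph is subjective. Given
per-eye region masks — the corneal disc (interior of the limbus), the
pupil, and up to five lesion types (corneal scar, descemetocele,
anterior-chamber abscess/hypopyon, fluorescein-stained ulcer under blue
light, and corneal neovascularization) — this package reduces each lesion
to a small set of ordinal clinical features, fuses them with clinical
covariates, and models binary outcomes at one and three months.

## What it computes

**Hierarchical lesion quantification.** For a lesion mask *L* and cornea
mask *C*, the area fraction *r* = |*L* ∩ *C*| / |*C*| is binned into a
quartile grade:

    grade(r) = 1 if 0.00 ≤ r ≤ 0.25,  2 if 0.25 < r ≤ 0.50,
               3 if 0.50 < r ≤ 0.75,  4 if 0.75 < r ≤ 1.00

(grade 0 encodes an absent lesion). Scar, blue-light ulcer and
neovascularization additionally carry a pupil-occlusion indicator
**1**[*L* ∩ *P* ≠ ∅] and a count of occupied corneal quadrants (image-frame
quadrants about the corneal centroid). The abscess is graded by the
fraction of the cornea's vertical extent its fluid level spans (a hypopyon
is a horizontal layer, so depth — not area — tracks severity); the plain
area grade is available as an option.

**Segmentation evaluation.** Per-class pixel accuracy, IoU
(TP/(TP+FP+FN)) and Dice (2TP/(2TP+FP+FN)) over the four-class label map
{background, cornea, pupil, lesion}, plus global accuracy and unweighted
four-class macro means (mIoU, mDice). Dice and IoU are linked by
Dice = 2J/(1+J).

**Prognosis modeling.** Per-patient features (worst-lesion fusion across a
patient's images, one-hot etiology, age, sex, BCVA) are screened with
L1-penalized logistic regression (penalty chosen by 5-fold cross-validated
deviance), then an XGBoost or LightGBM classifier is fit with shallow trees
and early stopping. Evaluation reports accuracy, AUC with a stratified
percentile-bootstrap 95% CI, sensitivity/specificity, PPV/NPV,
precision/recall and F1; stratified k-fold cross-validation re-runs the
screening inside every fold.

**Synthetic data.** Generators produce eyes with analytically known
grades/occlusion/quadrants (lesion blobs grown to an exact pixel budget)
and cohorts with planted sparse logistic effects, so the whole pipeline is
testable without patient data.

## Worked example

```python
import ulcerquant as uq

spec = uq.EyeSpec(
    size=128,
    lesions={
        "scar": uq.LesionRequest(0.30, quadrants=(0, 1), pupil_overlap=False),
        "abscess": uq.LesionRequest(0.20),
        "blue_ulcer": uq.LesionRequest(0.55, quadrants=(0, 1, 2), pupil_overlap=True),
    },
    seed=11, eye_id="demo",
)
eye, truth = uq.generate_eye(spec)
for tag, f in uq.quantify_eye(eye).lesions.items():
    print(f"{tag:20s} grade={f.grade} occludes={f.occludes_pupil} quadrants={f.quadrants}")
```

prints

```
scar                 grade=2 occludes=0 quadrants=2
descemetocele        grade=0 occludes=None quadrants=None
abscess              grade=1 occludes=None quadrants=None
blue_ulcer           grade=3 occludes=1 quadrants=3
neovascularization   grade=0 occludes=0 quadrants=0
```

The scar covers 30% of the cornea (grade 2, second quartile) across two
quadrants without touching the pupil; the blue-light ulcer covers 55%
(grade 3) of the cornea over three quadrants and occludes the pupil; the
hypopyon spans 20% of the cornea's vertical extent (grade 1). `None` marks
features the policy does not define for a lesion type.

Continuing with a synthetic cohort whose outcomes follow a planted sparse
logistic model (log-odds +1 per scar grade, +1 per blue-light ulcer grade,
−1 per logMAR unit of BCVA):

```python
cohort = uq.generate_cohort(uq.planted_cohort_spec(n=500, seed=11))
train, val = uq.split_cohort(cohort, "perforation_1m", ratio=0.8, seed=11)
selected = uq.lasso_screen(train, "perforation_1m", seed=11)
model = uq.fit_prognostic_model(train, "perforation_1m", selected, algorithm="xgb", seed=11)
report = uq.evaluate(model, val, "perforation_1m", seed=11)
```

Screening keeps `['scar_grade', 'abscess_grade', 'blue_ulcer_grade',
'blue_ulcer_quadrants', 'sex', 'bcva']` — all three planted features plus a
few correlated passengers — and the held-out panel reads accuracy 0.80,
AUC 0.86 (95% CI 0.78–0.93), sensitivity 0.85, specificity 0.75, F1 0.80:
the model recovers the planted signal well above chance on the 100
validation patients.

## Command line

```
ulcerquant simulate-eyes   --n-eyes 50 --out-dir data --seed 1
ulcerquant simulate-cohort --n 240 --out-dir data --seed 1
ulcerquant quantify        --masks-dir data/masks --eyes data/eyes.csv --out features.csv
ulcerquant segscore        --pred-dir pred/ --truth-dir truth/ --out seg.csv
ulcerquant train|evaluate|crossval --cohort data/cohort.csv --task perforation_1m ...
ulcerquant run             --config pipeline.yaml
```

`run` executes quantify → fuse → screen → fit → evaluate end to end into a
run directory stamped with the config hash and seeds; re-running the same
config reproduces every report byte for byte.

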