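# wbrtplan

Automatic treatment planning for tangential-field whole-breast radiotherapy
(WBRT) with electronic tissue compensation, exercised end to end on
procedurally generated thorax phantoms.

Post-lumpectomy WBRT is delivered through two nearly parallel-opposed
tangential photon fields whose per-beamlet fluence maps compensate for the
varying breast thickness.  Painting those fluence maps by hand takes an
experienced planner anywhere from half an hour to several hours per patient.
This package implements — and lets you study, on synthetic but
anatomy-driven cohorts — a three-stage automation of that workflow:

1. **Energy selection.** Digitally reconstructed radiographs (DRRs) are
   ray-cast for both beams; the gray-level histogram of the irradiated area,
   pooled over both beams, is projected onto the first two principal
   components of the training cohort, and a linear discriminant recommends
   single energy (SE, 6 MV) or mixed energy (ME, 6 + 15 MV).
2. **Fluence estimation.** A 150-tree random forest maps per-beamlet anatomy
   features x = (gray level, penetration depth through breast and lung,
   radiological path, field-edge/axis geometry) to the fluence intensity
   Φ(x) a trained planner would have painted, learned from teacher plans.
   For ME plans the total fluence is split into 6 and 15 MV components by a
   learned monotone low-energy fraction f_low(d) of the beamlet penetration
   depth d.
3. **Fine-tuning.** Dose anchor points on the transverse isocenter plane are
   repositioned so both beams' penetration depths balance (centrality
   correction), then the fluence is iteratively rescaled,
   Φ ← Φ · (D_target/D_anchor)^0.5 on a Gaussian neighborhood of each
   anchor's beamlet, until every anchor dose is within 1% of the 5000 cGy
   prescription (200 cGy x 25 fractions).

Everything needed to train and validate the workflow without patient data is
included: a phantom generator (separation-driven breast anatomy with lung
and heart), a linear divergent pencil-beam dose engine with analytic
percentage depth dose PDD(d) = N(1 − e^{−kd})e^{−μd}, DVH/endpoint
evaluation, and the one-sided Wilcoxon signed-rank comparison protocol at
the Bonferroni-adjusted level α/8 = 0.006.  See `docs/methods.md` for the
model details, parameter defaults and known limitations.

## Worked example

```python
import wbrtplan as w
from wbrtplan.pipeline import PlanConfig, fit_models, prepare_case, run_autoplan

# fit the three models on a 10-phantom training cohort with teacher plans
train = w.generate_cohort(10, se_fraction=0.5, seed=7)
cases = [prepare_case(p, label, with_teacher=True) for p, label in train]
models = fit_models(cases, seed=7)

# auto-plan a new patient
spec = w.PhantomSpec(breast_separation=17.0, breast_extent_ap=5.7,
                     breast_extent_si=12.2, seed=42)
phantom = w.generate_phantom(spec)
plan = run_autoplan(phantom, models, PlanConfig())
```

This prints (via the fields of `plan`):

```
energy choice : SE (PC1 = -0.012)
fine-tuning   : converged=True after 6 iterations (18 anchors)
target V95    : 95.8 %
target V100   : 74.2 %
target V105   : 7.7 %
hot spot      : 76.0 cc above 105% Rx
plan maximum  : 123.8 % of Rx
```

Reading the numbers: the 17 cm-separation phantom falls on the single-energy
side of the PCA boundary (PC1 < 0); six multiplicative sweeps bring all 18
anchor doses within 1% of prescription; 95.8% of the breast target receives
at least 95% of the prescribed 50 Gy, and the volume above the 105% hot-spot
threshold (76 cc) is in the range a human-quality tangential plan shows.
The plan maximum sits in thin near-skin tissue — high because the toy dose
engine has no lateral scatter to blur grazing-ray peaks.

The same workflow is scriptable from the shell (`wbrtplan phantom generate`,
`wbrtplan energy fit|predict`, `wbrtplan fluence fit|predict|split`,
`wbrtplan finetune`, `wbrtplan autoplan`, `wbrtplan experiment`; see
`wbrtplan --help`).

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the package's main experiment from scratch: it generates a
training cohort, builds the teacher plans and fits all three models, then
auto-plans a held-out cohort and prints the paired endpoint comparison
(auto vs teacher plans), the energy-selection confusion counts and the
fine-tuning convergence summary, writing the results file to `--out`.
All randomness derives from `--seed`.
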