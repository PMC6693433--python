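"""End-to-end orchestration: beam setup -> DRR -> energy selection -> RF
fluence (+ ME split) -> anchor fine-tuning -> dose -> metrics, plus the
train/validate experiment harness."""
from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from . import dose as dose_mod
from . import drr as drr_mod
from . import energy as energy_mod
from . import evaluate as eval_mod
from . import finetune as ft
from . import fluence as fl
from . import phantom as ph
from .geometry import BeamPair, tangential_beam_setup


@dataclass
class Models:
    """The three fitted components the auto-planner consumes."""

    energy: energy_mod.EnergyModel
    fluence: fl.FluenceModel
    split: fl.SplitModel | None = None


@dataclass
class PlanConfig:
    prescription: float = 5000.0       # cGy (200 x 25)
    fractions: int = 25
    energy_override: str = "auto"      # {"auto", "SE", "ME"}
    tune: ft.TuneConfig = field(default_factory=ft.TuneConfig)
    engine: dose_mod.EngineConfig = field(default_factory=dose_mod.EngineConfig)
    seed: int = 0

    def __post_init__(self):
        if self.prescription <= 0:
            raise ValueError("prescription must be positive")
        if self.energy_override not in ("auto", "SE", "ME"):
            raise ValueError("energy_override must be auto/SE/ME")


def _config_hash(config: PlanConfig, models: Models, phantom) -> str:
    payload = {
        "prescription": config.prescription,
        "fractions": config.fractions,
        "energy_override": config.energy_override,
        "tune": {k: v for k, v in asdict(config.tune).items()},
        "engine": {e: (p.mu, p.k, p.calibration)
                   for e, p in config.engine.energies.items()},
        "seed": config.seed,
        "spec": asdict(phantom.spec) if phantom.spec else None,
        "energy_model_mean": np.round(models.energy.mean, 12).tolist(),
        "fluence_schema": models.fluence.schema_version,
    }
    return hashlib.sha256(
        json.dumps(payload, sort_keys=True, default=str).encode()).hexdigest()


@dataclass
class Plan:
    phantom_id: str
    beams: BeamPair
    energy_choice: str                       # "SE" or "ME"
    classifier_scores: energy_mod.EnergyFeature
    fluences: dict                           # beam -> {energy -> FluenceMap}
    dose: dose_mod.DoseGrid                  # normalized plan dose
    metrics: eval_mod.PlanMetrics
    tune_report: ft.TuneReport
    anchors: list
    provenance: dict

    @property
    def converged(self) -> bool:
        return self.tune_report.converged


def run_autoplan(phantom, models: Models, config: PlanConfig | None = None,
                 beams: BeamPair | None = None) -> Plan:
    """Run the full automatic planning workflow on one phantom.

    Deterministic given the phantom, fitted models and config.  Non-convergent
    tuning yields a flagged Plan, not an abort; any stage error raises with a
    stage-tagged message.
    """
    config = config or PlanConfig()
    timings = {}

    def stage(name):
        timings[name] = time.perf_counter()

    try:
        stage("beams")
        if beams is None:
            beams = tangential_beam_setup(phantom)
        fans = dose_mod.build_fans(phantom, beams, config.engine)

        stage("drr")
        drr_m, drr_l = drr_mod.render_drr_pair(phantom, beams, fans)
        hist = drr_mod.gray_histogram(drr_m, drr_l)
        scores = energy_mod.project(models.energy, hist)

        stage("energy")
        predicted = energy_mod.classify_energy(models.energy, scores)
        choice = predicted if config.energy_override == "auto" \
            else config.energy_override
        energies = ("6MV",) if choice == "SE" else ("6MV", "15MV")
        beams = BeamPair(
            medial=_with_energies(beams.medial, energies),
            lateral=_with_energies(beams.lateral, energies))

        stage("fluence")
        drrs = {"medial": drr_m, "lateral": drr_l}
        totals = {b.name: fl.predict_fluence(models.fluence, phantom, b,
                                             drrs[b.name], fans[b.name])
                  for b in beams}

        stage("finetune")
        anchors = ft.select_anchor_points(phantom, beams, config.tune, fans)
        anchors = ft.centrality_correction(phantom, beams, anchors, fans)
        split_fraction = None
        if choice == "ME":
            if models.split is None:
                raise ValueError("ME plan requested but no split model fitted")
            split_fraction = models.split
        tuned, report = ft.tune_fluence(
            phantom, beams, totals, anchors, config.tune,
            engine_config=config.engine, fans=fans,
            split_fraction=split_fraction, fractions=config.fractions)

        stage("split")
        fluences = {}
        for b in beams:
            if choice == "ME":
                depth = fans[b.name].total_path("breast_target")
                low, high = fl.split_fluence(models.split, tuned[b.name], depth)
                fluences[b.name] = {"6MV": low, "15MV": high}
            else:
                fluences[b.name] = {"6MV": tuned[b.name]}

        stage("dose")
        raw = dose_mod.compute_dose(phantom, list(beams), fluences,
                                    config=config.engine,
                                    fractions=config.fractions, fans=fans)
        dose_grid = dose_mod.normalize_to_anchors(
            raw, config.prescription,
            anchor_positions=np.array([a.position for a in anchors]))

        stage("metrics")
        metrics = eval_mod.plan_metrics(dose_grid, phantom, config.prescription)
    except Exception as err:
        done = list(timings)
        raise RuntimeError(f"autoplan failed in stage {done[-1]!r}: {err}") \
            from err

    now = time.perf_counter()
    order = list(timings)
    stage_s = {name: round((timings[order[i + 1]] if i + 1 < len(order)
                            else now) - timings[name], 4)
               for i, name in enumerate(order)}
    provenance = {
        "config_hash": _config_hash(config, models, phantom),
        "energy_predicted": predicted,
        "energy_override": config.energy_override,
        "schema_version": models.fluence.schema_version,
        "seed": config.seed,
        "stage_seconds": stage_s,
    }
    return Plan(
        phantom_id=f"spec{phantom.spec.seed}" if phantom.spec else "anon",
        beams=beams, energy_choice=choice, classifier_scores=scores,
        fluences=fluences, dose=dose_grid, metrics=metrics,
        tune_report=report, anchors=anchors, provenance=provenance)


def _with_energies(beam, energies):
    from dataclasses import replace
    return replace(beam, energies=tuple(energies))


# --------------------------------------------------------------------------
# experiment harness
# --------------------------------------------------------------------------

@dataclass
class ExperimentReport:
    comparison: eval_mod.ComparisonReport
    energy_confusion: pd.DataFrame      # labels x predictions counts
    energy_accuracy: float
    n_train: int
    n_test: int
    plans: list
    teacher_metrics: list
    smoke_mode: bool = False


@dataclass
class TrainedCase:
    phantom: ph.Phantom
    label: ph.CohortLabel
    beams: BeamPair
    fans: dict
    drrs: tuple
    histogram: drr_mod.HistogramFeature
    teacher: ph.TeacherPlan | None = None


def prepare_case(phantom, label, engine_config=None, with_teacher=False,
                 teacher_tune: ft.TuneConfig | None = None) -> TrainedCase:
    """Beam setup, fans, DRRs (+ optionally the teacher plan) for one case."""
    engine_config = engine_config or dose_mod.EngineConfig()
    energies = ("6MV",) if label.energy_class == "SE" else ("6MV", "15MV")
    beams = tangential_beam_setup(phantom, energies=energies)
    fans = dose_mod.build_fans(phantom, beams, engine_config)
    drrs = drr_mod.render_drr_pair(phantom, beams, fans)
    hist = drr_mod.gray_histogram(*drrs)
    teacher = None
    if with_teacher:
        teacher = ph.teacher_plan(phantom, beams, engine_config=engine_config,
                                  tune_config=teacher_tune, energies=energies,
                                  fans=fans)
    return TrainedCase(phantom=phantom, label=label, beams=beams, fans=fans,
                       drrs=drrs, histogram=hist, teacher=teacher)


def fit_models(train_cases: list[TrainedCase], n_trees: int = 150,
               seed: int = 0) -> Models:
    """Fit energy, fluence and (when ME cases exist) split models."""
    emodel = energy_mod.fit_energy_model(
        [c.histogram for c in train_cases],
        [c.label for c in train_cases])
    rf_cases, split_cases = [], []
    for c in train_cases:
        if c.teacher is None:
            continue
        drrs = {d.beam_name: d for d in c.drrs}
        for b in c.beams:
            X, (rows, cols) = fl.extract_feature_grid(
                c.phantom, b, drrs[b.name], c.fans[b.name])
            y = c.teacher.total_fluence[b.name].values[rows, cols]
            rf_cases.append((X, y))
            if "15MV" in c.teacher.energies:
                depth = c.fans[b.name].total_path("breast_target")[rows, cols]
                low = c.teacher.fluences[b.name]["6MV"].values[rows, cols]
                tot = c.teacher.total_fluence[b.name].values[rows, cols]
                split_cases.append((depth, low, tot))
    fmodel = fl.fit_fluence_model(rf_cases, n_trees=n_trees, seed=seed)
    smodel = fl.fit_energy_split(split_cases) if split_cases else None
    return Models(energy=emodel, fluence=fmodel, split=smodel)


def run_experiment(train_cohort, test_cohort, config: PlanConfig | None = None,
                   n_trees: int = 150, allow_overlap: bool = False
                   ) -> ExperimentReport:
    """Fit all models on the training cohort, auto-plan the test cohort and
    compare auto vs teacher plans endpoint-wise.

    Cohorts are lists of (Phantom, CohortLabel).  Auto-plans use the teacher's
    energy class (the override protocol that removes the effect of energy
    choice from the plan-quality comparison); classifier predictions are
    reported separately as confusion counts.  ``allow_overlap`` enables the
    flagged train==test smoke mode.
    """
    config = config or PlanConfig()
    train_ids = {id(p) for p, _ in train_cohort}
    overlap = any(id(p) in train_ids for p, _ in test_cohort)
    if overlap and not allow_overlap:
        raise ValueError("train and test cohorts overlap")

    train_cases = [prepare_case(p, lbl, config.engine, with_teacher=True)
                   for p, lbl in train_cohort]
    models = fit_models(train_cases, n_trees=n_trees, seed=config.seed)

    plans, teacher_metrics, records = [], [], []
    for p, lbl in test_cohort:
        case = prepare_case(p, lbl, config.engine, with_teacher=True)
        pred = energy_mod.classify_energy(models.energy, case.histogram)
        cfg = PlanConfig(prescription=config.prescription,
                         fractions=config.fractions,
                         energy_override=lbl.energy_class,
                         tune=config.tune, engine=config.engine,
                         seed=config.seed)
        plan = run_autoplan(p, models, cfg, beams=case.beams)
        tdose = dose_mod.normalize_to_anchors(
            case.teacher.dose, config.prescription,
            anchor_positions=np.array([a.position
                                       for a in case.teacher.anchors]))
        teacher_metrics.append(
            eval_mod.plan_metrics(tdose, p, config.prescription))
        plans.append(plan)
        records.append((lbl.energy_class, pred))

    comparison = eval_mod.compare_cohorts(
        [pl.metrics for pl in plans], teacher_metrics)
    labels = [r[0] for r in records]
    preds = [r[1] for r in records]
    confusion = pd.crosstab(pd.Series(labels, name="label"),
                            pd.Series(preds, name="predicted"),
                            dropna=False)
    accuracy = float(np.mean([l == p for l, p in records]))
    return ExperimentReport(
        comparison=comparison, energy_confusion=confusion,
        energy_accuracy=accuracy, n_train=len(train_cohort),
        n_test=len(test_cohort), plans=plans,
        teacher_metrics=teacher_metrics, smoke_mode=overlap)
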