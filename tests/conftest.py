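"""Shared fixtures: analytic slab setups and the (expensive) synthetic
cohorts reused across the unit and acceptance tests."""
from __future__ import annotations

import numpy as np
import pytest

import wbrtplan as w
from wbrtplan import dose as dose_mod
from wbrtplan import drr as drr_mod
from wbrtplan import finetune as ft
from wbrtplan import fluence as fl
from wbrtplan import pipeline as pl
from wbrtplan.geometry import Beam, BeamPair, Raster

SEED = 1234


# --------------------------------------------------------------------------
# analytic slab fixtures
# --------------------------------------------------------------------------

def opposed_slab_beams(half_u: float = 40.0, half_v: float = 40.0,
                       px: float = 2.5,
                       energies: tuple = ("6MV",)) -> BeamPair:
    """Parallel-opposed lateral beams (gantry 270/90) with an open square
    aperture, traversing a slab whose normal is the x axis."""
    n = 2 * int(round(half_u / px)) + 1
    raster = Raster(-px * (n // 2), -px * (n // 2), px, n, n)
    ap = np.ones((n, n), bool)
    iso = np.zeros(3)
    return BeamPair(
        medial=Beam("medial", 270.0, iso, raster, ap.copy(), energies=energies),
        lateral=Beam("lateral", 90.0, iso, raster, ap.copy(), energies=energies))


@pytest.fixture(scope="session")
def slab10():
    """10 cm homogeneous water slab."""
    return w.make_slab_phantom(thickness_cm=10.0, density=1.0)


@pytest.fixture(scope="session")
def slab_beams():
    return opposed_slab_beams()


# --------------------------------------------------------------------------
# cohorts (session-scoped: built once, shared by unit + acceptance tests)
# --------------------------------------------------------------------------

@pytest.fixture(scope="session")
def rf_train_cases():
    """10 training phantoms (5 SE / 5 ME) with converged teacher plans."""
    cohort = w.generate_cohort(10, 0.5, seed=101)
    return [pl.prepare_case(p, lbl, with_teacher=True) for p, lbl in cohort]


@pytest.fixture(scope="session")
def trained_models(rf_train_cases):
    return pl.fit_models(rf_train_cases, seed=SEED)


@pytest.fixture(scope="session")
def heldout_cases():
    """10 held-out phantoms; the first 3 carry teacher plans (used for the
    fluence-recovery comparison), the rest are tuned-from-RF only."""
    cohort = w.generate_cohort(10, 0.5, seed=202)
    return [pl.prepare_case(p, lbl, with_teacher=(k < 3))
            for k, (p, lbl) in enumerate(cohort)]


@pytest.fixture(scope="session")
def me_teacher_cases(rf_train_cases):
    """10 mixed-energy teacher plans (5 from training + 5 extra)."""
    extra = w.generate_cohort(5, 0.0, seed=505)
    cases = [c for c in rf_train_cases if c.label.energy_class == "ME"]
    cases += [pl.prepare_case(p, lbl, with_teacher=True) for p, lbl in extra]
    return cases


@pytest.fixture(scope="session")
def energy_cohorts():
    """(train, test) lists of (HistogramFeature, CohortLabel), 20 each."""
    def histogrammed(cohort):
        out = []
        for p, lbl in cohort:
            beams = w.tangential_beam_setup(p)
            fans = dose_mod.build_fans(p, beams)
            hist = drr_mod.gray_histogram(*drr_mod.render_drr_pair(p, beams,
                                                                   fans))
            out.append((hist, lbl))
        return out
    return (histogrammed(w.generate_cohort(20, 0.5, seed=303)),
            histogrammed(w.generate_cohort(20, 0.5, seed=404)))


@pytest.fixture(scope="session")
def tuned_heldout(heldout_cases, trained_models):
    """RF-predicted fluence, then fine-tuning, on the 10 held-out phantoms.

    Each record carries the plan dose before and after tuning (both
    anchor-normalized), the tuning report and the endpoint metrics.
    """
    rx = 5000.0
    records = []
    for case in heldout_cases:
        p = case.phantom
        drrs = {d.beam_name: d for d in case.drrs}
        totals = {b.name: fl.predict_fluence(trained_models.fluence, p, b,
                                             drrs[b.name], case.fans[b.name])
                  for b in case.beams}
        cfg = ft.TuneConfig()
        anchors = ft.select_anchor_points(p, case.beams, cfg, case.fans)
        anchors = ft.centrality_correction(p, case.beams, anchors, case.fans)
        is_me = case.label.energy_class == "ME"
        split = trained_models.split if is_me else None

        def plan_dose(total_maps):
            fluences = {}
            for b in case.beams:
                if is_me:
                    depth = case.fans[b.name].total_path("breast_target")
                    low, high = fl.split_fluence(trained_models.split,
                                                 total_maps[b.name], depth)
                    fluences[b.name] = {"6MV": low, "15MV": high}
                else:
                    fluences[b.name] = {"6MV": total_maps[b.name]}
            raw = dose_mod.compute_dose(p, list(case.beams), fluences,
                                        fans=case.fans)
            norm = dose_mod.normalize_to_anchors(
                raw, rx, anchor_positions=np.array([a.position
                                                    for a in anchors]))
            return raw, norm

        raw_before, dose_before = plan_dose(totals)
        tuned, report = ft.tune_fluence(p, case.beams, totals, anchors, cfg,
                                        fans=case.fans, split_fraction=split)
        raw_after, dose_after = plan_dose(tuned)

        def v105cc(grid):
            return float((grid.dose >= 1.05 * rx).sum()) * p.voxel_volume_cc

        records.append({
            "case": case,
            "dose_before": dose_before,
            "dose_after": dose_after,
            "report": report,
            "metrics_before": w.plan_metrics(dose_before, p, rx),
            "metrics_after": w.plan_metrics(dose_after, p, rx),
            # hot-spot control is judged on the raw dose the tuner acts on:
            # anchor-mean renormalization of the *untuned* plan would mask
            # the tuner's actual effect on the hot spot
            "v105cc_raw_before": v105cc(raw_before),
            "v105cc_raw_after": v105cc(raw_after),
            "pred_fluence": totals,
        })
    return records
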