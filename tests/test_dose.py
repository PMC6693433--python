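"""Dose engine: PDD model, closed-form oracles, linearity, symmetry."""
import numpy as np
import pytest

import wbrtplan as w
from wbrtplan.dose import (DEFAULT_ENERGIES, EngineConfig, EnergyParams,
                           SSD_REF_MM, beamlet_dose, compute_dose,
                           normalize_to_anchors, pdd)
from wbrtplan.geometry import FluenceMap

from conftest import opposed_slab_beams


def _uniform_fluence(beam, value=1.0):
    return FluenceMap(np.full(beam.raster.shape, value), beam.raster.pixel_size,
                      (beam.raster.u0, beam.raster.v0), beam.name)


class TestPdd:
    @pytest.mark.parametrize("energy", ["6MV", "15MV"])
    def test_surface_and_peak(self, energy):
        assert pdd(energy, 0.0) == 0.0
        assert pdd(energy, DEFAULT_ENERGIES[energy].d_max_cm) == \
            pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("energy", ["6MV", "15MV"])
    def test_bounded_unit_interval(self, energy):
        d = np.linspace(0, 40, 500)
        vals = pdd(energy, d)
        assert np.all((vals >= 0) & (vals <= 1.0 + 1e-12))

    def test_harder_beam_penetrates_deeper(self):
        # closed-form evaluation at 15 cm with the default parameters
        assert pdd("6MV", 15.0) < pdd("15MV", 15.0)

    def test_negative_depth_rejected(self):
        with pytest.raises(ValueError):
            pdd("6MV", -0.1)

    def test_parameter_invariants(self):
        with pytest.raises(ValueError):
            EnergyParams(mu=0.05, k=0.04)
        assert DEFAULT_ENERGIES["15MV"].mu < DEFAULT_ENERGIES["6MV"].mu


class TestBeamletDose:
    def test_zero_weight_zero_dose(self, slab10, slab_beams):
        d = beamlet_dose(slab10, slab_beams.medial, (16, 16), "6MV", 0.0)
        assert not d.dose.any()

    def test_linear_in_weight(self, slab10, slab_beams):
        cfg = EngineConfig(lateral_sigma_mm=0.0)
        center = ((slab_beams.medial.raster.nv - 1) // 2,) * 2
        d1 = beamlet_dose(slab10, slab_beams.medial, center, "6MV", 1.0,
                          config=cfg)
        d2 = beamlet_dose(slab10, slab_beams.medial, center, "6MV", 2.0,
                          config=cfg)
        assert np.allclose(d2.dose, 2.0 * d1.dose, rtol=0, atol=0)

    def test_negative_weight_rejected(self, slab10, slab_beams):
        with pytest.raises(ValueError):
            beamlet_dose(slab10, slab_beams.medial, (16, 16), "6MV", -1.0)

    @staticmethod
    def _aligned_setup(t_step_mm):
        """Slab + beam whose raster pixels are centered on the slab's
        (half-offset) voxel columns, so one beamlet's cone contains one voxel
        column for its whole length."""
        slab = w.make_slab_phantom(thickness_cm=20.0, density=1.0,
                                   lateral_mm=80.0, si_mm=80.0)
        px, n = 2.5, 16
        raster = w.Raster(-px * (n / 2 - 0.5), -px * (n / 2 - 0.5), px, n, n)
        beam = w.Beam("medial", 270.0, np.zeros(3), raster,
                      np.ones((n, n), bool))
        cfg = EngineConfig(lateral_sigma_mm=0.0, t_step_mm=t_step_mm)
        pixel = (n // 2, n // 2)  # centered at u = v = +1.25 mm
        grid = beamlet_dose(slab, beam, pixel, "6MV", 1.0, config=cfg)
        iy = int(round((1.25 - slab.origin[1]) / slab.voxel_size))
        iz = int(round((1.25 - slab.origin[2]) / slab.voxel_size))
        return slab, beam, cfg, grid, iy, iz

    @staticmethod
    def _closed_form(slab, beam, cfg, xs, iy_c=1.25, iz_c=1.25):
        p = cfg.energies["6MV"]
        pts = np.column_stack([xs, np.full_like(xs, iy_c),
                               np.full_like(xs, iz_c)])
        q = pts - beam.source
        r = np.linalg.norm(q, axis=1)
        t_entry = (-100.0 - beam.source[0]) / (q[:, 0] / r)
        depth_cm = (r - t_entry) / 10.0
        return p.calibration * pdd(p, np.maximum(depth_cm, 0.0)) \
            * ((SSD_REF_MM + 10.0 * p.d_max_cm) / r) ** 2

    def test_central_beamlet_matches_closed_form(self):
        """Water slab, single beamlet, no lateral kernel: dose along the
        beamlet equals calibration * PDD(d) * inverse-square to < 1e-3."""
        slab, beam, cfg, grid, iy, iz = self._aligned_setup(t_step_mm=1.0)
        nx = slab.density.shape[0]
        xs = slab.origin[0] + slab.voxel_size * np.arange(nx)
        sel = (xs > -80.0) & (xs < 95.0)  # depths ~2..19.5 cm
        expect = self._closed_form(slab, beam, cfg, xs[sel])
        got = grid.dose[sel, iy, iz]
        assert np.max(np.abs(got / expect - 1.0)) < 1e-3

    def test_depth_dose_ratio_oracle(self):
        """Dose ratio between 5 and 10 cm depth matches the closed-form
        PDD x inverse-square ratio within 1%."""
        slab, beam, cfg, grid, iy, iz = self._aligned_setup(t_step_mm=2.0)
        xs = np.array([-100.0 + 50.0, -100.0 + 100.0])  # 5 and 10 cm
        ix = np.round((xs - slab.origin[0]) / slab.voxel_size).astype(int)
        got = grid.dose[ix, iy, iz]
        expect = self._closed_form(slab, beam, cfg,
                                   slab.origin[0] + slab.voxel_size * ix)
        assert got[0] / got[1] == pytest.approx(expect[0] / expect[1],
                                                rel=0.01)


class TestComputeDose:
    def test_zero_fluence_zero_dose(self, slab10, slab_beams):
        fl = {b.name: {"6MV": _uniform_fluence(b, 0.0)} for b in slab_beams}
        grid = compute_dose(slab10, list(slab_beams), fl)
        assert not grid.dose.any()

    def test_superposition_linearity(self, slab10, slab_beams):
        rng = np.random.default_rng(7)
        cfg = EngineConfig()
        fans = w.build_fans(slab10, slab_beams, cfg)

        def random_fluences():
            return {b.name: {"6MV": FluenceMap(
                rng.uniform(0, 2, b.raster.shape), b.raster.pixel_size,
                (b.raster.u0, b.raster.v0), b.name)} for b in slab_beams}

        f1, f2 = random_fluences(), random_fluences()
        fsum = {n: {"6MV": FluenceMap(
            f1[n]["6MV"].values + f2[n]["6MV"].values,
            f1[n]["6MV"].pixel_size, f1[n]["6MV"].origin, n)} for n in f1}
        d1 = compute_dose(slab10, list(slab_beams), f1, config=cfg, fans=fans)
        d2 = compute_dose(slab10, list(slab_beams), f2, config=cfg, fans=fans)
        ds = compute_dose(slab10, list(slab_beams), fsum, config=cfg,
                          fans=fans)
        assert np.allclose(d1.dose + d2.dose, ds.dose, rtol=1e-12, atol=1e-9)

    def test_opposed_beams_midplane_symmetry(self, slab10, slab_beams):
        fl = {b.name: {"6MV": _uniform_fluence(b)} for b in slab_beams}
        grid = compute_dose(slab10, list(slab_beams), fl)
        iy = slab10.density.shape[1] // 2
        iz = slab10.density.shape[2] // 2
        profile = grid.dose[:, iy, iz]
        inside = slab10.masks["body"][:, iy, iz]
        p = profile[inside]
        asym = np.abs(p - p[::-1]) / p.max()
        assert asym.max() < 0.01

    def test_fluence_shape_mismatch_rejected(self, slab10, slab_beams):
        bad = FluenceMap(np.ones((3, 3)), 2.5, (0, 0), "medial")
        with pytest.raises(ValueError, match="does not match"):
            compute_dose(slab10, list(slab_beams), {"medial": {"6MV": bad}})

    def test_normalization_idempotent(self, slab10, slab_beams):
        fl = {b.name: {"6MV": _uniform_fluence(b)} for b in slab_beams}
        grid = compute_dose(slab10, list(slab_beams), fl)
        n1 = normalize_to_anchors(grid, 5000.0,
                                  target_mask=slab10.masks["breast_target"])
        n2 = normalize_to_anchors(n1, 5000.0,
                                  target_mask=slab10.masks["breast_target"])
        assert np.allclose(n1.dose, n2.dose, rtol=1e-12)
        assert np.median(n1.dose[slab10.masks["breast_target"]]) == \
            pytest.approx(5000.0, rel=1e-12)
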