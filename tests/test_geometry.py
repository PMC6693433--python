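"""Beam geometry, ray tracing and fluence serialization."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import wbrtplan as w
from wbrtplan.geometry import Beam, BeamPair, FluenceMap, Raster, trace_ray

from conftest import opposed_slab_beams


@pytest.fixture(scope="module")
def phantom18():
    spec = w.PhantomSpec(breast_separation=18, breast_extent_ap=6.2,
                         breast_extent_si=12.8, seed=3)
    return w.generate_phantom(spec)


@pytest.fixture(scope="module")
def beams18(phantom18):
    return w.tangential_beam_setup(phantom18)


def _chord_length(phantom, source, direction):
    """Independent slab-method oracle for the in-grid chord length."""
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    lo = phantom.origin - 0.5 * phantom.voxel_size
    hi = phantom.origin + (np.array(phantom.density.shape) - 0.5) \
        * phantom.voxel_size
    t0, t1 = -np.inf, np.inf
    for ax in range(3):
        if d[ax] == 0:
            if not (lo[ax] <= source[ax] <= hi[ax]):
                return 0.0
            continue
        with np.errstate(over="ignore"):  # near-subnormal direction components
            ta = (lo[ax] - source[ax]) / d[ax]
            tb = (hi[ax] - source[ax]) / d[ax]
        t0, t1 = max(t0, min(ta, tb)), min(t1, max(ta, tb))
    return max(0.0, t1 - max(t0, 0.0))


class TestTraceRay:
    def test_water_slab_radiological_path(self, slab10):
        path = trace_ray(slab10, [-300.0, 0.0, 0.0], [1.0, 0.0, 0.0])
        assert path.radiological_cm == pytest.approx(10.0, abs=1e-9)

    def test_quarter_density_slab(self):
        slab = w.make_slab_phantom(thickness_cm=10.0, density=0.25)
        path = trace_ray(slab, [-300.0, 0.0, 0.0], [1.0, 0.0, 0.0])
        assert path.radiological_cm == pytest.approx(2.5, abs=1e-9)

    def test_two_layer_linearity(self):
        # 2 cm at density 1.0 + 3 cm at 0.25 -> 2.75 cm water-equivalent
        slab = w.make_slab_phantom(thickness_cm=5.0, density=1.0)
        x = slab.origin[0] + slab.voxel_size * np.arange(slab.density.shape[0])
        layer = (x[:, None, None] >= -5.0) & slab.masks["body"]
        slab.density[np.broadcast_to(layer, slab.density.shape)] = 0.25
        path = trace_ray(slab, [-300.0, 0.0, 0.0], [1.0, 0.0, 0.0])
        assert path.radiological_cm == pytest.approx(2.0 + 0.75, abs=1e-9)

    def test_miss_returns_empty_path(self, slab10):
        path = trace_ray(slab10, [-300.0, 500.0, 0.0], [1.0, 0.0, 0.0])
        assert path.entry is None and path.lengths.size == 0
        assert path.radiological_cm == 0.0

    def test_zero_direction_rejected(self, slab10):
        with pytest.raises(ValueError):
            trace_ray(slab10, [0, 0, 0], [0, 0, 0])

    def test_voxel_lengths_sum_to_chord(self, phantom18):
        rng = np.random.default_rng(0)
        for _ in range(200):
            src = rng.uniform(-400, 400, size=3)
            tgt = rng.uniform(-50, 50, size=3)
            d = tgt - src
            path = trace_ray(phantom18, src, d)
            chord = _chord_length(phantom18, src, d)
            assert path.total_length == pytest.approx(chord, rel=1e-6,
                                                      abs=1e-6)

    @settings(deadline=None, max_examples=30)
    @given(sy=st.floats(-200, 200), sz=st.floats(-200, 200),
           dy=st.floats(-0.5, 0.5), dz=st.floats(-0.5, 0.5))
    def test_chord_property_slab(self, slab10, sy, sz, dy, dz):
        src = np.array([-400.0, sy, sz])
        d = np.array([1.0, dy, dz])
        path = trace_ray(slab10, src, d)
        assert path.total_length == pytest.approx(
            _chord_length(slab10, src, d), rel=1e-6, abs=1e-6)

    def test_structure_path_equals_radiological_at_unit_density(self, slab10):
        path = trace_ray(slab10, [-300.0, 0.0, 0.0], [1.0, 0.2, 0.1])
        assert path.structure_paths["body"] / 10.0 == pytest.approx(
            path.radiological_cm, rel=1e-9)


class TestBeams:
    def test_beamlet_central_axis(self, slab_beams):
        beam = slab_beams.medial
        center = ((beam.raster.nv - 1) // 2, (beam.raster.nu - 1) // 2)
        src, d = beam.beamlet_ray(center)
        expect = (beam.isocenter - beam.source)
        expect /= np.linalg.norm(expect)
        assert np.allclose(d, expect, atol=1e-12)

    def test_beamlet_offset_crosses_iso_plane(self, slab_beams):
        beam = slab_beams.medial
        i = (beam.raster.nv - 1) // 2
        j = (beam.raster.nu - 1) // 2 + 10  # +25 mm in u
        src, d = beam.beamlet_ray((i, j))
        t = beam.sad / np.dot(d, beam.axes[2])
        hit = src + t * d
        assert np.linalg.norm(hit - beam.isocenter) == pytest.approx(25.0,
                                                                     abs=1e-9)

    def test_adjacent_beamlet_divergence(self, slab_beams):
        beam = slab_beams.medial
        c = ((beam.raster.nv - 1) // 2, (beam.raster.nu - 1) // 2)
        _, d0 = beam.beamlet_ray(c)
        _, d1 = beam.beamlet_ray((c[0], c[1] + 1))
        angle = np.arccos(np.clip(np.dot(d0, d1), -1, 1))
        assert angle == pytest.approx(beam.raster.pixel_size / beam.sad,
                                      rel=1e-3)

    def test_pixel_outside_grid_rejected(self, slab_beams):
        with pytest.raises(IndexError):
            slab_beams.medial.beamlet_ray((-1, 0))

    def test_left_phantom_gantry_ranges(self, beams18):
        assert 270.0 < beams18.medial.gantry_deg < 360.0
        assert 90.0 < beams18.lateral.gantry_deg < 180.0

    def test_mirrored_phantom_mirrored_gantry(self, phantom18, beams18):
        mirrored = w.Phantom(
            density=phantom18.density[::-1].copy(),
            masks={k: v[::-1].copy() for k, v in phantom18.masks.items()},
            origin=phantom18.origin, voxel_size=phantom18.voxel_size)
        bm = w.tangential_beam_setup(mirrored)
        assert abs(bm.medial.gantry_deg
                   - (360.0 - beams18.medial.gantry_deg)) <= 1.0

    def test_aperture_covers_target_projection(self, phantom18, beams18):
        idx = np.argwhere(phantom18.masks["breast_target"])
        pts = phantom18.origin + idx * phantom18.voxel_size
        for beam in beams18:
            u, v, _, _ = beam.project(pts)
            i, j = beam.raster.index_of(u, v)
            assert beam.raster.contains(i, j).all()
            assert beam.aperture[i, j].all()

    def test_near_opposed_invariant_enforced(self, slab_beams):
        bad = Beam("lateral", 200.0, slab_beams.medial.isocenter,
                   slab_beams.lateral.raster, slab_beams.lateral.aperture)
        with pytest.raises(ValueError, match="parallel-opposed"):
            BeamPair(medial=slab_beams.medial, lateral=bad)

    def test_empty_target_rejected(self, slab10):
        empty = w.Phantom(density=slab10.density,
                          masks={**slab10.masks,
                                 "breast_target": np.zeros_like(
                                     slab10.masks["body"])},
                          origin=slab10.origin, voxel_size=slab10.voxel_size)
        with pytest.raises(ValueError, match="breast_target"):
            w.tangential_beam_setup(empty)


class TestFluenceAscii:
    def test_bit_exact_round_trip(self, tmp_path):
        rng = np.random.default_rng(5)
        values = np.abs(rng.normal(size=(7, 5))) * rng.choice(
            [1e-12, 1.0, 1e7], size=(7, 5))
        fmap = FluenceMap(values, 2.5, (-5.0, -7.5), "medial")
        path = tmp_path / "f.txt"
        w.write_fluence_ascii(fmap, path)
        back = w.read_fluence_ascii(path)
        assert np.array_equal(back.values, fmap.values)
        assert back.pixel_size == fmap.pixel_size
        assert back.origin == fmap.origin
        assert back.beam_name == "medial"

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError):
            FluenceMap(np.array([[-1.0]]), 2.5, (0.0, 0.0), "medial")
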