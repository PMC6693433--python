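"""Tangential beam geometry, beam's-eye-view rasters and voxel ray tracing.

Coordinate convention (used package-wide): patient coordinates in mm,
right-handed, axes = (x: right->left, y: anterior->posterior,
z: inferior->superior).  Voxel indices are 0-based and a voxel's position is
its center.  Gantry angles follow the IEC 61217 scale: at 0 deg the source is
anterior of the patient and the beam points posteriorly; at 90 deg the source
is at the patient's left.  The source rotates in the transverse plane at a
fixed source-axis distance (SAD, default 1000 mm).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy import ndimage

MAX_FIELD_MM = 400.0  # jaw limit: maximum aperture extent in either BEV axis


# --------------------------------------------------------------------------
# rasters and fluence maps
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Raster:
    """Regular 2-D pixel grid on the isocenter plane (BEV coordinates).

    ``values[i, j]`` lives at BEV coordinates ``u = u0 + j*pixel_size``,
    ``v = v0 + i*pixel_size`` (u spans the in-plane transverse axis, v the
    superior-inferior axis).
    """

    u0: float
    v0: float
    pixel_size: float
    nu: int
    nv: int

    @property
    def shape(self) -> tuple[int, int]:
        return (self.nv, self.nu)

    def u_coords(self) -> np.ndarray:
        return self.u0 + self.pixel_size * np.arange(self.nu)

    def v_coords(self) -> np.ndarray:
        return self.v0 + self.pixel_size * np.arange(self.nv)

    def index_of(self, u, v):
        """Nearest pixel (i, j) for BEV coordinates; may fall outside grid."""
        j = np.rint((np.asarray(u) - self.u0) / self.pixel_size).astype(int)
        i = np.rint((np.asarray(v) - self.v0) / self.pixel_size).astype(int)
        return i, j

    def frac_index_of(self, u, v):
        j = (np.asarray(u) - self.u0) / self.pixel_size
        i = (np.asarray(v) - self.v0) / self.pixel_size
        return i, j

    def contains(self, i, j):
        return (i >= 0) & (i < self.nv) & (j >= 0) & (j < self.nu)


@dataclass
class FluenceMap:
    """2-D grid of nonnegative beamlet weights in the BEV at isocenter."""

    values: np.ndarray          # (nv, nu), unitless relative weights
    pixel_size: float           # mm at isocenter
    origin: tuple[float, float]  # (u0, v0) mm relative to the central axis
    beam_name: str

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fluence values must be finite")
        if np.any(self.values < 0):
            raise ValueError("fluence values must be nonnegative")

    @property
    def raster(self) -> Raster:
        return Raster(self.origin[0], self.origin[1], self.pixel_size,
                      self.values.shape[1], self.values.shape[0])

    def copy(self) -> "FluenceMap":
        return FluenceMap(self.values.copy(), self.pixel_size,
                          tuple(self.origin), self.beam_name)


# --------------------------------------------------------------------------
# beams
# --------------------------------------------------------------------------

@dataclass
class Beam:
    """One tangential treatment beam (medial or lateral)."""

    name: str                      # {"medial", "lateral"}
    gantry_deg: float              # IEC 61217
    isocenter: np.ndarray          # (3,) mm
    raster: Raster                 # fluence/DRR pixel grid at isocenter
    aperture: np.ndarray           # (nv, nu) bool, True inside the open field
    sad: float = 1000.0            # mm
    energies: tuple[str, ...] = ("6MV",)

    def __post_init__(self):
        self.isocenter = np.asarray(self.isocenter, dtype=float)
        self.aperture = np.asarray(self.aperture, dtype=bool)
        if self.aperture.shape != self.raster.shape:
            raise ValueError("aperture shape must match raster")
        if not self.aperture.any():
            raise ValueError("aperture must be nonempty")

    # -- geometry -----------------------------------------------------------
    @property
    def source(self) -> np.ndarray:
        g = np.deg2rad(self.gantry_deg)
        return self.isocenter + self.sad * np.array(
            [np.sin(g), -np.cos(g), 0.0])

    @property
    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(e_u, e_v, d_hat): BEV in-plane axis, SI axis, beam direction."""
        g = np.deg2rad(self.gantry_deg)
        d_hat = np.array([-np.sin(g), np.cos(g), 0.0])
        e_v = np.array([0.0, 0.0, 1.0])
        e_u = np.cross(e_v, d_hat)
        return e_u, e_v, d_hat

    def project(self, points: np.ndarray):
        """Divergent projection of points onto the isocenter plane.

        Returns (u, v, w, r): BEV coordinates in mm, depth-axis distance w
        (along the beam axis, from the source) and euclidean source distance r.
        """
        e_u, e_v, d_hat = self.axes
        q = np.atleast_2d(points) - self.source
        w = q @ d_hat
        u = self.sad * (q @ e_u) / w
        v = self.sad * (q @ e_v) / w
        r = np.linalg.norm(q, axis=-1)
        return u, v, w, r

    def beamlet_ray(self, pixel: tuple[int, int]):
        """(source, unit direction) of the ray through a pixel center.

        ``pixel`` is (i, j) into the raster; the ray passes through the pixel
        center on the isocenter plane, divergence set by the SAD point source.
        """
        i, j = pixel
        if not (0 <= i < self.raster.nv and 0 <= j < self.raster.nu):
            raise IndexError(f"pixel {pixel} outside fluence grid")
        e_u, e_v, _ = self.axes
        u = self.raster.u0 + j * self.raster.pixel_size
        v = self.raster.v0 + i * self.raster.pixel_size
        target = self.isocenter + u * e_u + v * e_v
        direction = target - self.source
        return self.source, direction / np.linalg.norm(direction)


@dataclass
class BeamPair:
    """Medial/lateral near-parallel-opposed tangential fields."""

    medial: Beam
    lateral: Beam

    def __post_init__(self):
        diff = abs(self.medial.gantry_deg - self.lateral.gantry_deg) % 360.0
        diff = min(diff, 360.0 - diff)
        if not (160.0 <= diff <= 200.0):
            raise ValueError(
                f"tangential beams must be near parallel-opposed "
                f"(gantry difference {diff:.1f} deg)")
        if not np.allclose(self.medial.isocenter, self.lateral.isocenter):
            raise ValueError("beams must share the isocenter")

    def __iter__(self):
        return iter((self.medial, self.lateral))


# --------------------------------------------------------------------------
# ray tracing
# --------------------------------------------------------------------------

@dataclass
class RayPath:
    """Exact voxel traversal of one ray through the phantom grid."""

    entry: np.ndarray | None            # mm, None when the ray misses the grid
    exit: np.ndarray | None
    voxels: np.ndarray                  # (n, 3) int indices
    lengths: np.ndarray                 # (n,) mm intersection lengths
    structure_paths: dict[str, float]   # geometric path per structure, mm
    radiological_cm: float              # water-equivalent path, cm

    @property
    def total_length(self) -> float:
        return float(self.lengths.sum())


def _grid_bounds(phantom):
    lo = phantom.origin - 0.5 * phantom.voxel_size
    hi = phantom.origin + (np.array(phantom.density.shape) - 0.5) * phantom.voxel_size
    return lo, hi


def trace_ray(phantom, source, direction) -> RayPath:
    """Siddon-style exact traversal: per-voxel intersection lengths of a ray.

    The per-voxel lengths sum to the in-grid chord length (relative tolerance
    ~1e-6 comes only from floating-point plane intersections).  A ray that
    misses the grid returns an empty path, not an error.
    """
    source = np.asarray(source, dtype=float)
    direction = np.asarray(direction, dtype=float)
    norm = np.linalg.norm(direction)
    if norm == 0:
        raise ValueError("ray direction must be nonzero")
    d = direction / norm

    lo, hi = _grid_bounds(phantom)
    t0, t1 = -np.inf, np.inf
    for ax in range(3):
        if d[ax] == 0.0:
            if not (lo[ax] <= source[ax] <= hi[ax]):
                return _empty_path(phantom)
        else:
            with np.errstate(over="ignore"):  # near-zero direction component
                ta = (lo[ax] - source[ax]) / d[ax]
                tb = (hi[ax] - source[ax]) / d[ax]
            t0 = max(t0, min(ta, tb))
            t1 = min(t1, max(ta, tb))
    if not (t1 > t0):
        return _empty_path(phantom)
    t0 = max(t0, 0.0)
    if t1 <= t0:
        return _empty_path(phantom)

    ts = [np.array([t0, t1])]
    for ax in range(3):
        if d[ax] != 0.0:
            n_planes = phantom.density.shape[ax] + 1
            planes = lo[ax] + phantom.voxel_size * np.arange(n_planes)
            tp = (planes - source[ax]) / d[ax]
            ts.append(tp[(tp > t0) & (tp < t1)])
    ts = np.unique(np.concatenate(ts))
    mids = source[None, :] + 0.5 * (ts[:-1] + ts[1:])[:, None] * d[None, :]
    idx = np.floor((mids - lo[None, :]) / phantom.voxel_size).astype(int)
    shape = np.array(phantom.density.shape)
    np.clip(idx, 0, shape - 1, out=idx)
    lengths = np.diff(ts)
    keep = lengths > 0
    idx, lengths = idx[keep], lengths[keep]

    dens = phantom.density[idx[:, 0], idx[:, 1], idx[:, 2]]
    structure_paths = {
        name: float((lengths * mask[idx[:, 0], idx[:, 1], idx[:, 2]]).sum())
        for name, mask in phantom.masks.items()
    }
    return RayPath(
        entry=source + t0 * d,
        exit=source + t1 * d,
        voxels=idx,
        lengths=lengths,
        structure_paths=structure_paths,
        radiological_cm=float((lengths * dens).sum()) / 10.0,
    )


def _empty_path(phantom) -> RayPath:
    return RayPath(None, None, np.empty((0, 3), int), np.empty(0),
                   {name: 0.0 for name in phantom.masks}, 0.0)


# --------------------------------------------------------------------------
# tangential beam setup
# --------------------------------------------------------------------------

def _mask_points(phantom, name, step=1):
    idx = np.argwhere(phantom.masks[name])[::step]
    return phantom.origin + idx * phantom.voxel_size


def _disk(radius_px: int) -> np.ndarray:
    if radius_px < 1:
        return np.ones((1, 1), bool)
    r = radius_px
    y, x = np.ogrid[-r:r + 1, -r:r + 1]
    return (x * x + y * y) <= r * r


def _build_aperture(u_t, v_t, u_b, margin, flash, px):
    """Aperture raster from target / body BEV projections.

    Aperture = target projection, hole-filled, dilated by ``margin`` and
    extended by ``flash`` past the skin on the open-air side (the u-side where
    the body projection ends closest to the target projection).
    """
    m_px = max(1, int(round(margin / px)))
    f_px = max(1, int(round(flash / px)))
    pad = (m_px + f_px + 2) * px
    u0 = np.floor((u_t.min() - pad) / px) * px
    v0 = np.floor((v_t.min() - pad) / px) * px
    nu = int(np.ceil((u_t.max() + pad - u0) / px)) + 1
    nv = int(np.ceil((v_t.max() + pad - v0) / px)) + 1
    raster = Raster(u0, v0, px, nu, nv)

    occ = np.zeros((nv, nu), bool)
    i, j = raster.index_of(u_t, v_t)
    occ[i, j] = True
    occ = ndimage.binary_fill_holes(occ)
    ap = ndimage.binary_dilation(occ, structure=_disk(m_px))

    # skin (open-air) side: smaller gap between body and target extent in u
    gap_hi = u_b.max() - u_t.max()
    gap_lo = u_t.min() - u_b.min()
    hi_side = gap_hi < gap_lo
    for _ in range(f_px):
        if hi_side:
            ap[:, 1:] |= ap[:, :-1]
        else:
            ap[:, :-1] |= ap[:, 1:]
    return raster, ap


def _aperture_for_angle(phantom, gantry, iso, pts_t, pts_b, margin, flash, px,
                        sad=1000.0):
    probe = Beam("probe", gantry, iso,
                 Raster(0.0, 0.0, px, 1, 1), np.ones((1, 1), bool), sad=sad)
    u_t, v_t, _, _ = probe.project(pts_t)
    u_b, _, _, _ = probe.project(pts_b)
    raster, ap = _build_aperture(u_t, v_t, u_b, margin, flash, px)
    return probe, raster, ap


def _infield_count(probe, raster, ap, pts):
    u, v, _, _ = probe.project(pts)
    i, j = raster.index_of(u, v)
    ok = raster.contains(i, j)
    return int(ap[i[ok], j[ok]].sum())


def tangential_beam_setup(phantom, skin_flash: float = 20.0,
                          margin: float = 7.0, pixel_size: float = 2.5,
                          angle_step: float = 1.0,
                          energies: tuple[str, ...] = ("6MV",)) -> BeamPair:
    """Construct the medial/lateral tangential pair for a breast phantom.

    The gantry angle of the (parallel-opposed) pair is found by a 1-D search
    minimizing the ipsilateral-lung volume projecting inside the open fields,
    with a small penalty on in-field body volume to break ties toward the most
    grazing geometry.  The aperture is the target projection dilated by
    ``margin`` and extended ``skin_flash`` past the skin surface on the
    open-air side; the isocenter sits at the target centroid.
    """
    target = phantom.masks["breast_target"]
    if not target.any():
        raise ValueError("phantom has an empty breast_target")
    idx = np.argwhere(target)
    iso = phantom.origin + idx.mean(axis=0) * phantom.voxel_size

    step = max(1, int(round(8.0 / phantom.voxel_size)))  # ~8 mm subsampling
    pts_t = _mask_points(phantom, "breast_target", step)
    pts_b = _mask_points(phantom, "body", step)
    pts_l = _mask_points(phantom, "ipsilateral_lung", step)

    left = iso[0] >= 0.0  # grid is built symmetric about the midline x = 0
    if left:
        candidates = np.arange(271.0, 360.0, angle_step)
    else:
        candidates = np.arange(1.0, 90.0, angle_step)

    def pair_cost(g_med):
        cost = 0.0
        for g in (g_med, (g_med + 180.0) % 360.0):
            probe, raster, ap = _aperture_for_angle(
                phantom, g, iso, pts_t, pts_b, margin, skin_flash, pixel_size)
            cost += _infield_count(probe, raster, ap, pts_l)
            cost += 1e-3 * _infield_count(probe, raster, ap, pts_b)
        return cost

    def argmin(cands):
        best = None
        for g in cands:
            c = pair_cost(g)
            if best is None or c < best[0] - 1e-12:
                best = (c, g)
        return best[1]

    # coarse scan, then refine around the coarse optimum
    coarse = max(3.0 * angle_step, angle_step)
    g0 = argmin(candidates[::max(1, int(round(coarse / angle_step)))])
    g_med = argmin(candidates[np.abs(candidates - g0) <= coarse + 1e-9])
    g_lat = (g_med + 180.0) % 360.0

    pts_t_full = _mask_points(phantom, "breast_target", 1)
    pts_b_full = _mask_points(phantom, "body", 2)
    beams = {}
    for name, g in (("medial", g_med), ("lateral", g_lat)):
        probe, raster, ap = _aperture_for_angle(
            phantom, g, iso, pts_t_full, pts_b_full, margin, skin_flash,
            pixel_size)
        rows = np.any(ap, axis=1)
        cols = np.any(ap, axis=0)
        if (rows.sum() * pixel_size > MAX_FIELD_MM
                or cols.sum() * pixel_size > MAX_FIELD_MM):
            raise ValueError("target projection exceeds the maximum field "
                             f"size ({MAX_FIELD_MM:.0f} mm)")
        beams[name] = Beam(name, g, iso, raster, ap, energies=tuple(energies))
    return BeamPair(medial=beams["medial"], lateral=beams["lateral"])


# --------------------------------------------------------------------------
# fluence map ASCII serialization (bit-exact round trip)
# --------------------------------------------------------------------------

def write_fluence_ascii(fmap: FluenceMap, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"beam={fmap.beam_name}\n")
        fh.write(f"pixel_size_mm={fmap.pixel_size!r}\n")
        fh.write(f"origin_mm={fmap.origin[0]!r} {fmap.origin[1]!r}\n")
        fh.write(f"rows={fmap.values.shape[0]}\n")
        fh.write(f"cols={fmap.values.shape[1]}\n")
        for row in fmap.values:
            fh.write(" ".join(repr(float(x)) for x in row) + "\n")


def read_fluence_ascii(path) -> FluenceMap:
    with open(path) as fh:
        header = {}
        for _ in range(5):
            key, val = fh.readline().strip().split("=", 1)
            header[key] = val
        rows = int(header["rows"])
        cols = int(header["cols"])
        values = np.array(
            [[float(x) for x in fh.readline().split()] for _ in range(rows)])
    if values.shape != (rows, cols):
        raise ValueError("fluence matrix does not match declared shape")
    u0, v0 = (float(x) for x in header["origin_mm"].split())
    return FluenceMap(values, float(header["pixel_size_mm"]), (u0, v0),
                      header["beam"])
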