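"""Self-contained beamlet dose engine.

A divergent pencil model standing in for a TPS dose algorithm: absolute dose
is strictly linear in fluence, with an analytic energy-specific percentage
depth dose (PDD) and inverse-square falloff,

    dose(voxel) = weight * calibration * PDD_E(d_rad) * ((SSD_ref + d_max)/r)^2

where ``d_rad`` is the water-equivalent (radiological) depth of the voxel
along the ray from the source and ``r`` the source-voxel distance.  The PDD
uses the buildup-attenuation form

    PDD(d) = N * (1 - exp(-k d)) * exp(-mu d),   N chosen so max(PDD) = 1,

whose maximum sits at d_max = ln((k + mu)/mu) / k.  The method this engine
serves only requires a dose operator that is monotone and linear in fluence;
no attempt is made to match any commercial algorithm numerically.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .geometry import FluenceMap

SSD_REF_MM = 900.0  # reference source-surface distance (90 cm)


@dataclass(frozen=True)
class EnergyParams:
    """Analytic beam model for one nominal energy."""

    mu: float            # attenuation, cm^-1
    k: float             # buildup, cm^-1
    calibration: float = 200.0  # cGy per weight-unit at d_max, SSD 90 cm

    def __post_init__(self):
        if not (self.mu > 0 and self.k > self.mu):
            raise ValueError("require k > mu > 0")

    @property
    def d_max_cm(self) -> float:
        return float(np.log((self.k + self.mu) / self.mu) / self.k)

    @property
    def _norm(self) -> float:
        d = self.d_max_cm
        return float(1.0 / ((1.0 - np.exp(-self.k * d)) * np.exp(-self.mu * d)))


#: default beam models: the 15MV beam is harder (smaller mu, deeper d_max)
DEFAULT_ENERGIES: dict[str, EnergyParams] = {
    "6MV": EnergyParams(mu=0.050, k=2.0),
    "15MV": EnergyParams(mu=0.035, k=1.2),
}


def pdd(energy: str | EnergyParams, depth_cm) -> np.ndarray | float:
    """Relative depth dose in [0, 1] at water-equivalent depth (cm)."""
    p = DEFAULT_ENERGIES[energy] if isinstance(energy, str) else energy
    d = np.asarray(depth_cm, dtype=float)
    if np.any(d < 0):
        raise ValueError("depth must be nonnegative")
    out = p._norm * (1.0 - np.exp(-p.k * d)) * np.exp(-p.mu * d)
    return out if out.ndim else float(out)


@dataclass
class EngineConfig:
    """All tunable dose-engine parameters in one block."""

    energies: dict[str, EnergyParams] = field(
        default_factory=lambda: dict(DEFAULT_ENERGIES))
    t_step_mm: float = 2.0          # fan sampling step along rays
    lateral_sigma_mm: float = 3.0   # Gaussian beamlet spread; 0 disables
    fan_pad_px: int = 3             # raster padding of the depth fan


@dataclass
class DoseGrid:
    """Absolute dose per voxel (cGy) on the phantom grid."""

    dose: np.ndarray
    origin: np.ndarray
    voxel_size: float

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)

    def at(self, points: np.ndarray) -> np.ndarray:
        """Dose at arbitrary points (nearest voxel)."""
        idx = np.rint((np.atleast_2d(points) - self.origin)
                      / self.voxel_size).astype(int)
        idx = np.clip(idx, 0, np.array(self.dose.shape) - 1)
        return self.dose[idx[:, 0], idx[:, 1], idx[:, 2]]


# --------------------------------------------------------------------------
# depth fan: beam-aligned cumulative path sampling
# --------------------------------------------------------------------------

class DepthFan:
    """Beam-aligned sampling of cumulative (radiological and per-structure)
    path length.

    A fan of rays is cast through every (padded) raster pixel; density and
    selected structure masks are sampled along each ray at ``t_step`` and
    accumulated, giving water-equivalent depth / geometric structure path as a
    function of (pixel, distance from source).  All per-point queries are then
    trilinear interpolations into these fan volumes, which makes DRR
    rendering, feature extraction, anchor bookkeeping and dose computation
    share one geometry code path.
    """

    def __init__(self, phantom, beam, t_step: float = 2.0, pad_px: int = 3,
                 structures: tuple[str, ...] = ("breast_target",
                                                "ipsilateral_lung")):
        self.phantom = phantom
        self.beam = beam
        self.t_step = float(t_step)
        self.pad = int(pad_px)
        r = beam.raster
        self.fan_raster = type(r)(
            r.u0 - self.pad * r.pixel_size, r.v0 - self.pad * r.pixel_size,
            r.pixel_size, r.nu + 2 * self.pad, r.nv + 2 * self.pad)

        source = beam.source
        corners = phantom.origin[None, :] + (
            np.array(np.meshgrid([0, 1], [0, 1], [0, 1])).reshape(3, -1).T
            * (np.array(phantom.density.shape) - 1) * phantom.voxel_size)
        dists = np.linalg.norm(corners - source, axis=1)
        self.t0 = max(float(dists.min()) - 2 * t_step, 1.0)
        t1 = float(dists.max()) + 2 * t_step
        self.nt = int(np.ceil((t1 - self.t0) / t_step)) + 1

        e_u, e_v, _ = beam.axes
        uu = self.fan_raster.u_coords()
        vv = self.fan_raster.v_coords()
        U, V = np.meshgrid(uu, vv)  # (nv, nu)
        targets = (beam.isocenter[None, :]
                   + U.reshape(-1, 1) * e_u[None, :]
                   + V.reshape(-1, 1) * e_v[None, :])
        dirs = targets - source
        dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)

        ts = self.t0 + t_step * np.arange(self.nt)
        pos = (source[None, None, :]
               + dirs[:, None, :] * ts[None, :, None])  # (npix, nt, 3)
        coords = ((pos - phantom.origin[None, None, :])
                  / phantom.voxel_size)
        coords = coords.reshape(-1, 3).T

        def _cum(volume):
            samp = ndimage.map_coordinates(
                volume, coords, order=1, mode="constant", cval=0.0,
                prefilter=False).reshape(-1, self.nt)
            cum = np.cumsum(samp, axis=1) - 0.5 * samp
            cum *= t_step / 10.0  # mm * rel.density -> cm
            return cum.reshape(self.fan_raster.nv, self.fan_raster.nu, self.nt)

        self.depth = _cum(np.ascontiguousarray(phantom.density, dtype=np.float32))
        self.structure_depth = {
            name: _cum(phantom.masks[name].astype(np.float32))
            for name in structures if name in phantom.masks
        }

    # -- queries ------------------------------------------------------------
    def fan_coords(self, points: np.ndarray):
        """Fractional fan indices (fi, fj, ft) and source distance r."""
        u, v, _, r = self.beam.project(points)
        fi, fj = self.fan_raster.frac_index_of(u, v)
        ft = (r - self.t0) / self.t_step
        return fi, fj, ft, r

    def _interp(self, volume, fi, fj, ft):
        return ndimage.map_coordinates(
            volume, np.vstack([fi, fj, ft]), order=1, mode="nearest",
            prefilter=False)

    def depth_at(self, points: np.ndarray, structure: str | None = None):
        """Water-equivalent depth (cm) — or geometric structure path (cm) —
        from the skin surface to each point along its ray from the source."""
        fi, fj, ft, _ = self.fan_coords(np.atleast_2d(points))
        vol = self.depth if structure is None else self.structure_depth[structure]
        return self._interp(vol, fi, fj, ft)

    def total_path(self, structure: str | None = None) -> np.ndarray:
        """Full in-grid path (cm) per raster pixel (fan cropped to the beam
        raster).  ``structure=None`` gives the radiological path."""
        vol = self.depth if structure is None else self.structure_depth[structure]
        p = self.pad
        return vol[p:p + self.beam.raster.nv, p:p + self.beam.raster.nu, -1].copy()

    def entry_t(self, points: np.ndarray, eps_cm: float = 1e-3) -> np.ndarray:
        """Source distance (mm) of the skin entry of the rays through points."""
        pts = np.atleast_2d(points)
        fi, fj, ft, _ = self.fan_coords(pts)
        ts = np.arange(self.nt, dtype=float)
        n = len(pts)
        FI = np.repeat(fi, self.nt)
        FJ = np.repeat(fj, self.nt)
        FT = np.tile(ts, n)
        prof = self._interp(self.depth, FI, FJ, FT).reshape(n, self.nt)
        first = np.argmax(prof > eps_cm, axis=1)
        none = ~(prof > eps_cm).any(axis=1)
        t = self.t0 + self.t_step * np.maximum(first - 0.5, 0.0)
        t[none] = np.nan
        return t

    def reference_point_t(self, depth_fraction: float = 0.4) -> np.ndarray:
        """Per raster pixel: source distance (mm) where the cumulative
        radiological depth reaches ``depth_fraction`` of the pixel's total."""
        p = self.pad
        vol = self.depth[p:p + self.beam.raster.nv,
                         p:p + self.beam.raster.nu, :]
        goal = depth_fraction * vol[:, :, -1][:, :, None]
        reached = vol >= goal
        first = np.argmax(reached, axis=2)
        return self.t0 + self.t_step * first


def build_fans(phantom, beams, config: EngineConfig | None = None
               ) -> dict[str, DepthFan]:
    config = config or EngineConfig()
    return {b.name: DepthFan(phantom, b, t_step=config.t_step_mm,
                             pad_px=config.fan_pad_px) for b in beams}


# --------------------------------------------------------------------------
# dose computation
# --------------------------------------------------------------------------

def _voxel_centers(phantom) -> np.ndarray:
    shape = phantom.density.shape
    ax = [phantom.origin[i] + phantom.voxel_size * np.arange(shape[i])
          for i in range(3)]
    X, Y, Z = np.meshgrid(*ax, indexing="ij")
    return np.stack([X.ravel(), Y.ravel(), Z.ravel()], axis=1)


def _smoothed(values, sigma_mm, pixel_size):
    if not sigma_mm:
        return values
    return ndimage.gaussian_filter(values, sigma=sigma_mm / pixel_size)


def beamlet_dose(phantom, beam, pixel, energy: str, weight: float,
                 config: EngineConfig | None = None, fan: DepthFan | None = None,
                 fractions: int = 1) -> DoseGrid:
    """Dose contribution of a single beamlet (one fluence pixel).

    A pixel outside the aperture contributes zero (not an error).  The
    contribution is strictly linear in ``weight``.
    """
    if weight < 0:
        raise ValueError("beamlet weight must be nonnegative")
    i, j = pixel
    values = np.zeros(beam.raster.shape)
    if beam.aperture[i, j]:
        values[i, j] = weight
    fmap = FluenceMap(values, beam.raster.pixel_size,
                      (beam.raster.u0, beam.raster.v0), beam.name)
    return compute_dose(phantom, [beam], {beam.name: {energy: fmap}},
                        config=config, fans={beam.name: fan} if fan else None,
                        fractions=fractions)


def compute_dose(phantom, beams, fluences, *, config: EngineConfig | None = None,
                 fractions: int = 25, fans: dict[str, DepthFan] | None = None,
                 mask_aperture: bool = True) -> DoseGrid:
    """Superpose beamlet dose over all beams, energies and pixels.

    ``fluences`` maps beam name -> {energy -> FluenceMap}; fluence grids must
    match the beam rasters.  The result is the *raw* linear superposition (in
    cGy for ``fractions`` fractions); plan normalization to prescription is a
    separate explicit step (:func:`normalize_to_anchors`).
    """
    config = config or EngineConfig()
    dose = np.zeros(phantom.density.shape, dtype=float).ravel()
    points = _voxel_centers(phantom)

    for beam in beams:
        beam_fl = fluences.get(beam.name, {})
        if not beam_fl:
            continue
        fan = (fans or {}).get(beam.name) or DepthFan(
            phantom, beam, t_step=config.t_step_mm, pad_px=config.fan_pad_px)
        fi, fj, ft, r = fan.fan_coords(points)
        fr = fan.fan_raster
        inside = ((fi >= 0) & (fi <= fr.nv - 1) & (fj >= 0) & (fj <= fr.nu - 1)
                  & (ft >= 0) & (ft <= fan.nt - 1))
        depth = fan._interp(fan.depth, fi[inside], fj[inside], ft[inside])
        # nearest-pixel beamlet lookup into the (unpadded) fluence raster
        ii = np.rint(fi[inside]).astype(int) - fan.pad
        jj = np.rint(fj[inside]).astype(int) - fan.pad
        on_raster = ((ii >= 0) & (ii < beam.raster.nv)
                     & (jj >= 0) & (jj < beam.raster.nu))
        ii, jj = np.clip(ii, 0, beam.raster.nv - 1), np.clip(jj, 0, beam.raster.nu - 1)
        r_in = r[inside]
        for energy, fmap in beam_fl.items():
            if fmap.values.shape != beam.raster.shape:
                raise ValueError(
                    f"fluence shape {fmap.values.shape} does not match beam "
                    f"raster {beam.raster.shape}")
            p = config.energies[energy]
            values = fmap.values
            if mask_aperture:
                values = values * beam.aperture
            values = _smoothed(values, config.lateral_sigma_mm,
                               fmap.pixel_size)
            w = np.where(on_raster, values[ii, jj], 0.0)
            if not w.any():
                continue
            r_ref = SSD_REF_MM + 10.0 * p.d_max_cm
            contrib = (fractions * p.calibration * w
                       * pdd(p, depth) * (r_ref / r_in) ** 2)
            dose[inside] += contrib

    return DoseGrid(dose.reshape(phantom.density.shape), phantom.origin,
                    phantom.voxel_size)


def normalize_to_anchors(dose_grid: DoseGrid, rx_cgy: float,
                         anchor_positions: np.ndarray | None = None,
                         target_mask: np.ndarray | None = None) -> DoseGrid:
    """Scale a plan so the mean anchor dose (or, absent anchors, the target
    median dose) equals the prescription.  Idempotent."""
    if anchor_positions is not None and len(anchor_positions):
        ref = float(np.mean(dose_grid.at(np.asarray(anchor_positions))))
    elif target_mask is not None and target_mask.any():
        ref = float(np.median(dose_grid.dose[target_mask]))
    else:
        raise ValueError("need anchor positions or a target mask")
    if ref <= 0:
        raise ValueError("reference dose is zero; cannot normalize")
    return DoseGrid(dose_grid.dose * (rx_cgy / ref), dose_grid.origin,
                    dose_grid.voxel_size)
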