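"""Anchor-point fluence fine-tuning.

Dose anchor points are laid out on the transverse plane through the isocenter
("iso-plane"), pushed inside the target by a surface clearance, then moved by
the *centrality correction* along the line joining their two beam entry
points to the position balancing the medial and lateral penetration depths.
Fluence is then iteratively rescaled — a multiplicative update of a Gaussian
neighborhood of each anchor's beamlet by (target/dose)^relaxation, followed by
3x3 mean smoothing and clipping — until every anchor dose sits within
tolerance of its target.  The update only ever touches fluence, never beam
geometry, which is what makes interactive re-tuning with adjusted per-anchor
targets cheap.

The dose seen by an anchor under the engine's nearest-pixel beamlet model
depends only on its associated pixel in each beam, so the inner loop uses
precomputed per-anchor dose coefficients and costs O(n_pixels) per iteration.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .dose import DepthFan, EngineConfig, SSD_REF_MM, build_fans, pdd


def masked_mean3(values: np.ndarray, aperture: np.ndarray) -> np.ndarray:
    """3x3 mean smoothing restricted to the aperture domain.

    A plain moving average mixes in the zeros outside the open field and
    erodes the aperture border a little further on every iteration; weighting
    by the aperture keeps edge beamlets at their local mean instead.
    """
    num = ndimage.uniform_filter(values * aperture, size=3)
    den = ndimage.uniform_filter(aperture.astype(float), size=3)
    out = np.zeros_like(values)
    np.divide(num, den, out=out, where=den > 1e-12)
    out[~aperture] = 0.0
    return out


@dataclass
class TuneConfig:
    target_dose: float = 5000.0     # cGy prescription (200 x 25)
    tolerance: float = 0.01         # relative anchor-dose tolerance
    max_iter: int = 20
    relaxation: float = 0.5         # exponent in (0, 1]
    sigma_mm: float = 7.5           # Gaussian update neighborhood
    spacing_mm: float = 10.0        # anchor lattice spacing on the iso-plane
    clearance_mm: float = 5.0       # minimum in-plane distance to the target edge
    smooth: bool = True             # 3x3 mean smoothing after each update
    factor_cap: float = 4.0         # per-iteration update factor clip
    plane_offsets_mm: tuple = (0.0,)  # transverse planes relative to isocenter

    def __post_init__(self):
        if self.tolerance <= 0:
            raise ValueError("tolerance must be positive")
        if not (0.0 < self.relaxation <= 1.0):
            raise ValueError("relaxation must be in (0, 1]")


@dataclass
class AnchorPoint:
    position: np.ndarray            # (3,) mm, inside breast_target
    depth_medial: float             # cm, water-equivalent
    depth_lateral: float
    pixels: dict                    # beam name -> (i, j) associated beamlet
    current_dose: float = float("nan")
    target: float | None = None     # per-anchor dose target; None = Rx

    @property
    def depth_imbalance(self) -> float:
        return abs(self.depth_medial - self.depth_lateral)


@dataclass
class TuneReport:
    deviations: list                # max relative anchor deviation per state
    converged: bool
    iterations: int
    zero_dose_anchors: int = 0


# --------------------------------------------------------------------------
# anchor selection
# --------------------------------------------------------------------------

def _make_anchor(position, beams, fans) -> AnchorPoint:
    pos = np.asarray(position, dtype=float)
    depths, pixels = {}, {}
    for b in beams:
        depths[b.name] = float(fans[b.name].depth_at(pos[None, :])[0])
        u, v, _, _ = b.project(pos[None, :])
        i, j = b.raster.index_of(u[0], v[0])
        pixels[b.name] = (int(np.clip(i, 0, b.raster.nv - 1)),
                          int(np.clip(j, 0, b.raster.nu - 1)))
    return AnchorPoint(position=pos, depth_medial=depths["medial"],
                       depth_lateral=depths["lateral"], pixels=pixels)


def select_anchor_points(phantom, beams, config: TuneConfig | None = None,
                         fans: dict | None = None) -> list[AnchorPoint]:
    """Regular anchor lattice on the iso-plane(s), clear of the target edge.

    Raises if fewer than 3 anchors fit at the stated clearance.
    """
    config = config or TuneConfig()
    fans = fans or build_fans(phantom, beams)
    target = phantom.masks["breast_target"]
    vox = phantom.voxel_size
    iso = beams.medial.isocenter
    step = max(1, int(round(config.spacing_mm / vox)))

    positions = []
    for off in config.plane_offsets_mm:
        k = int(round((iso[2] + off - phantom.origin[2]) / vox))
        if not (0 <= k < target.shape[2]) or not target[:, :, k].any():
            continue
        sl = target[:, :, k]
        edt = ndimage.distance_transform_edt(sl, sampling=vox)
        i0 = (sl.shape[0] % step) // 2
        j0 = (sl.shape[1] % step) // 2
        lattice = np.zeros_like(sl)
        lattice[i0::step, j0::step] = True
        ii, jj = np.nonzero(lattice & (edt >= config.clearance_mm))
        for i, j in zip(ii, jj):
            positions.append(phantom.origin + vox * np.array([i, j, k]))
    if len(positions) < 3:
        raise ValueError(
            "target too small for at least 3 anchors at "
            f"{config.clearance_mm} mm clearance")
    return [_make_anchor(p, beams, fans) for p in positions]


def centrality_correction(phantom, beams, anchors, fans: dict | None = None,
                          step_mm: float = 1.0,
                          dedupe: bool = True) -> list[AnchorPoint]:
    """Balance per-beam penetration depths for every anchor.

    Each anchor is moved along the segment joining its medial and lateral
    skin-entry points (which lies in the iso-plane, since the beams are
    coplanar) to the in-target position minimizing |depth_medial -
    depth_lateral|; the original position is always a candidate, so the
    imbalance never increases.
    """
    fans = fans or build_fans(phantom, beams)
    fan_m, fan_l = fans["medial"], fans["lateral"]
    target = phantom.masks["breast_target"]
    out = []
    for a in anchors:
        pos = a.position
        entries = []
        for b, fan in ((beams.medial, fan_m), (beams.lateral, fan_l)):
            src = b.source
            d = pos - src
            d = d / np.linalg.norm(d)
            t = float(fan.entry_t(pos[None, :])[0])
            entries.append(None if np.isnan(t) else src + t * d)
        if entries[0] is None or entries[1] is None:
            out.append(a)
            continue
        e_m, e_l = entries
        n = max(2, int(np.ceil(np.linalg.norm(e_l - e_m) / step_mm)) + 1)
        cand = e_m[None, :] + np.linspace(0, 1, n)[:, None] * (e_l - e_m)[None, :]
        cand = np.vstack([cand, pos[None, :]])
        idx = np.rint((cand - phantom.origin) / phantom.voxel_size).astype(int)
        inside = np.all((idx >= 0) & (idx < np.array(target.shape)), axis=1)
        inside &= target[np.clip(idx[:, 0], 0, target.shape[0] - 1),
                         np.clip(idx[:, 1], 0, target.shape[1] - 1),
                         np.clip(idx[:, 2], 0, target.shape[2] - 1)]
        inside[-1] = True               # original anchor always admissible
        cand = cand[inside]
        dm = fan_m.depth_at(cand)
        dl = fan_l.depth_at(cand)
        imb = np.abs(dm - dl)
        disp = np.linalg.norm(cand - pos, axis=1)
        best = np.lexsort((disp, np.round(imb, 9)))[0]
        new = _make_anchor(cand[best], beams, fans)
        new.target = a.target
        out.append(new)
    if dedupe:
        # anchors from the same chord collapse onto the same beamlet-pixel
        # pair; keep the best-balanced representative of each pair so no two
        # anchors pull one beamlet toward conflicting doses
        best_by_pix: dict = {}
        for a in out:
            key = (a.pixels["medial"], a.pixels["lateral"], a.target)
            cur = best_by_pix.get(key)
            if cur is None or a.depth_imbalance < cur.depth_imbalance:
                best_by_pix[key] = a
        out = list(best_by_pix.values())
    return out


# --------------------------------------------------------------------------
# iterative fluence rescaling
# --------------------------------------------------------------------------

def anchor_dose_coefficients(anchors, beams, fans, engine_config=None,
                             fractions: int = 25, split_fraction=None
                             ) -> np.ndarray:
    """kappa[j, b]: plan dose (cGy) at anchor j per unit fluence in its
    associated pixel of beam b, summed over the beam's energies."""
    engine_config = engine_config or EngineConfig()
    kappa = np.zeros((len(anchors), 2))
    pos = np.array([a.position for a in anchors])
    for bi, b in enumerate(beams):
        fan = fans[b.name]
        depth = fan.depth_at(pos)
        r = np.linalg.norm(pos - b.source[None, :], axis=1)
        if split_fraction is not None and "15MV" in b.energies:
            db = fan.total_path("breast_target")
            dpix = np.array([db[a.pixels[b.name]] for a in anchors])
            f_low = np.asarray(split_fraction(dpix), dtype=float)
            shares = {"6MV": f_low, "15MV": 1.0 - f_low}
        else:
            shares = {e: np.ones(len(anchors)) for e in b.energies}
        for e in b.energies:
            p = engine_config.energies[e]
            r_ref = SSD_REF_MM + 10.0 * p.d_max_cm
            kappa[:, bi] += (shares[e] * fractions * p.calibration
                             * pdd(p, depth) * (r_ref / r) ** 2)
    return kappa


def tune_fluence(phantom, beams, fluences, anchors,
                 config: TuneConfig | None = None, *,
                 engine_config: EngineConfig | None = None,
                 fans: dict | None = None, split_fraction=None,
                 fractions: int = 25):
    """Iteratively rescale per-beam (total) fluence so anchor doses hit their
    targets.  Returns (tuned fluences, TuneReport); the input maps are not
    mutated.  An anchor receiving zero dose is flagged, capped, and makes the
    plan non-convergent rather than raising.
    """
    if not anchors:
        raise ValueError("anchors must be nonempty")
    config = config or TuneConfig()
    engine_config = engine_config or EngineConfig()
    fans = fans or build_fans(phantom, beams, engine_config)

    kappa = anchor_dose_coefficients(anchors, beams, fans, engine_config,
                                     fractions, split_fraction)
    targets = np.array([a.target if a.target is not None else
                        config.target_dose for a in anchors])
    beam_list = list(beams)
    pix = {b.name: (np.array([a.pixels[b.name][0] for a in anchors]),
                    np.array([a.pixels[b.name][1] for a in anchors]))
           for b in beam_list}
    F = {b.name: fluences[b.name].copy() for b in beam_list}

    def anchor_doses():
        d = np.zeros(len(anchors))
        for bi, b in enumerate(beam_list):
            i, j = pix[b.name]
            d += F[b.name].values[i, j] * kappa[:, bi]
        return d

    doses = anchor_doses()
    dev = float(np.max(np.abs(doses - targets) / targets))
    report = TuneReport(deviations=[dev], converged=dev <= config.tolerance,
                        iterations=0)
    if report.converged:
        for a, d in zip(anchors, doses):
            a.current_dose = float(d)
        return F, report

    sigma_px = config.sigma_mm / beam_list[0].raster.pixel_size
    cap = config.factor_cap
    for it in range(1, config.max_iter + 1):
        # global output rescale first (exact under the linear dose operator):
        # local Gaussian updates then only correct the per-anchor residuals,
        # so rows far from any anchor keep a consistent scale
        mean_dose = float(doses.mean())
        if mean_dose > 0:
            g = float(targets.mean()) / mean_dose
            for b in beam_list:
                F[b.name].values *= g
            doses *= g
        zero = doses <= 0
        report.zero_dose_anchors = int(zero.sum())
        with np.errstate(divide="ignore"):
            factors = np.where(zero, cap, targets / np.maximum(doses, 1e-300))
        factors = np.clip(factors, 1.0 / cap, cap) ** config.relaxation
        logf = np.log(factors)
        for b in beam_list:
            shape = b.raster.shape
            A = np.zeros(shape)
            W = np.zeros(shape)
            i, j = pix[b.name]
            np.add.at(A, (i, j), logf)
            np.add.at(W, (i, j), 1.0)
            if sigma_px > 0:
                scale = 2.0 * np.pi * sigma_px ** 2  # peak-1 Gaussian kernels
                A = ndimage.gaussian_filter(A, sigma_px) * scale
                W = ndimage.gaussian_filter(W, sigma_px) * scale
            mult = np.exp(A / np.maximum(W, 1.0))
            if config.smooth:
                # smooth the update, not the accumulated fluence: repeated
                # smoothing of the map itself diffuses the compensator
                # profile in rows no anchor pushes back on
                mult = masked_mean3(mult, b.aperture) + ~b.aperture
            vals = F[b.name].values * mult
            vals *= b.aperture
            np.clip(vals, 0.0, None, out=vals)
            F[b.name].values = vals
        doses = anchor_doses()
        dev = float(np.max(np.abs(doses - targets) / targets))
        report.deviations.append(dev)
        report.iterations = it
        if dev <= config.tolerance:
            break
    report.converged = dev <= config.tolerance and not report.zero_dose_anchors
    for a, d in zip(anchors, doses):
        a.current_dose = float(d)
    return F, report
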