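"""Procedural thorax/breast phantoms and teacher plans.

The generator emulates a WBRT planning CT with RTOG-style contours: an
elliptical-cylinder chest, a breast modelled as a half-ellipsoid fused to the
antero-lateral chest wall, an ipsilateral lung and (always left-sided) heart.
Breast size is driven by the *separation* — the chest-wall chord between the
medial and lateral field entry points — which is the anatomical quantity that
drives both the DRR-histogram energy signal and the fluence magnitude.

Teacher ("clinical") plans stand in for manually painted fluence plans: the
ECOMP-style initial fluence is fine-tuned to convergence by this package's own
anchor-point tuner.  That circularity is deliberate: the downstream random
forest is validated as *mimicking its training policy on unseen anatomy*.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from . import dose as dose_mod
from . import finetune as ft
from . import fluence as fl
from .geometry import BeamPair

#: separation (cm) at and above which the generator labels a phantom ME
SEPARATION_THRESHOLD_CM = 21.0

#: uniform separation ranges (cm) the cohort generator draws from; the 1 cm
#: gap between classes keeps the toy energy-selection task learnable
SE_SEPARATION_RANGE = (14.0, 20.0)
ME_SEPARATION_RANGE = (21.0, 27.0)

DEFAULT_DENSITIES = {"body": 1.00, "breast": 0.95, "lung": 0.25, "heart": 1.00}

#: evaluation target = breast tissue cropped this far from the skin surface
SKIN_CROP_MM = 5.0
CHEST_WALL_MM = 18.0


@dataclass(frozen=True)
class PhantomSpec:
    """Anatomical parameters of one synthetic patient."""

    breast_separation: float           # cm, chest-wall chord medial->lateral
    breast_extent_ap: float            # cm, anterior protrusion of the breast
    breast_extent_si: float            # cm, superior-inferior extent
    laterality: str = "left"           # {"left", "right"}
    voxel_size: float = 2.5            # mm, isotropic
    densities: dict = field(default_factory=lambda: dict(DEFAULT_DENSITIES))
    seed: int = 0

    def __post_init__(self):
        if not (12.0 <= self.breast_separation <= 30.0):
            raise ValueError("breast_separation must be within [12, 30] cm")
        if self.breast_extent_ap <= 0 or self.breast_extent_si <= 0:
            raise ValueError("breast extents must be positive "
                             "(degenerate target)")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if self.laterality not in ("left", "right"):
            raise ValueError("laterality must be 'left' or 'right'")
        if any(v <= 0 for v in self.densities.values()):
            raise ValueError("densities must be positive")


@dataclass(frozen=True)
class CohortLabel:
    """Generator-side energy-class label (SE = 6MV, ME = 6/15MV)."""

    energy_class: str

    def __post_init__(self):
        if self.energy_class not in ("SE", "ME"):
            raise ValueError("energy_class must be 'SE' or 'ME'")


@dataclass
class Phantom:
    """Voxelized patient stand-in: density grid plus named structure masks."""

    density: np.ndarray                 # relative electron density
    masks: dict[str, np.ndarray]        # breast_target/ipsilateral_lung/heart/body
    origin: np.ndarray                  # mm, center of voxel (0,0,0)
    voxel_size: float                   # mm, isotropic
    spec: PhantomSpec | None = None

    def __post_init__(self):
        self.origin = np.asarray(self.origin, dtype=float)

    @property
    def voxel_volume_cc(self) -> float:
        return (self.voxel_size / 10.0) ** 3

    def structure_volume_cc(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.voxel_volume_cc


def _centered_axis(half_extent: float, vox: float) -> np.ndarray:
    n = 2 * int(np.ceil(half_extent / vox)) + 1  # odd count, symmetric about 0
    return (np.arange(n) - (n - 1) / 2) * vox


def generate_phantom(spec: PhantomSpec) -> Phantom:
    """Deterministically build a phantom from its spec (seed fixes jitter)."""
    rng = np.random.default_rng(spec.seed)
    vox = spec.voxel_size
    lam = 1.0 if spec.laterality == "left" else -1.0

    # chest ellipse with mild per-patient jitter
    a_b = 130.0 * (1.0 + 0.05 * np.clip(rng.normal(), -2, 2))
    b_b = 90.0 * (1.0 + 0.05 * np.clip(rng.normal(), -2, 2))
    theta = np.deg2rad(25.0 + rng.uniform(-5.0, 5.0))

    s = 10.0 * spec.breast_separation      # mm
    ap = 10.0 * spec.breast_extent_ap
    si = 10.0 * spec.breast_extent_si

    p0 = np.array([lam * a_b * np.sin(theta), -b_b * np.cos(theta)])
    nrm = np.array([lam * np.sin(theta) / a_b, -np.cos(theta) / b_b])
    nrm /= np.linalg.norm(nrm)
    tng = np.array([lam * a_b * np.cos(theta), b_b * np.sin(theta)])
    tng /= np.linalg.norm(tng)            # points medial -> lateral

    bx = abs(tng[0]) * s / 2 + abs(nrm[0]) * ap
    by = abs(tng[1]) * s / 2 + abs(nrm[1]) * ap
    half_x = max(a_b, abs(p0[0]) + bx) + 15.0
    y_min = min(-b_b, p0[1] - by) - 15.0
    y_max = b_b + 15.0
    half_z = si / 2 + 40.0

    xs = _centered_axis(half_x, vox)
    ys = y_min + vox * np.arange(int(np.ceil((y_max - y_min) / vox)) + 1)
    zs = _centered_axis(half_z, vox)

    X, Y = np.meshgrid(xs, ys, indexing="ij")
    in_chest = (X / a_b) ** 2 + (Y / b_b) ** 2 <= 1.0

    c1 = (X - p0[0]) * tng[0] + (Y - p0[1]) * tng[1]
    c2 = (X - p0[0]) * nrm[0] + (Y - p0[1]) * nrm[1]
    q2 = (c1 / (s / 2)) ** 2 + (c2 / ap) ** 2
    z_term = (zs / (si / 2)) ** 2
    breast3d = ((q2[:, :, None] + z_term[None, None, :] <= 1.0)
                & (c2 >= 0.0)[:, :, None])
    if not breast3d.any():
        raise ValueError("breast geometry degenerate at this voxel size")
    if breast3d[0].any() or breast3d[-1].any() or breast3d[:, 0].any() \
            or breast3d[:, -1].any() or breast3d[..., 0].any() \
            or breast3d[..., -1].any():
        raise ValueError("breast would be truncated outside the grid")

    body = in_chest[:, :, None] | breast3d
    body = np.broadcast_to(body, (len(xs), len(ys), len(zs))).copy()
    breast_region = breast3d & ~in_chest[:, :, None]

    dist_to_air = ndimage.distance_transform_edt(body, sampling=vox)
    target = breast_region & (dist_to_air >= SKIN_CROP_MM)
    if not target.any():
        raise ValueError("breast target vanished after skin crop "
                         "(degenerate target)")

    # ipsilateral lung: shrunk ellipse, guaranteed chest-wall clearance
    lscale = 1.0 + 0.05 * np.clip(rng.normal(), -2, 2)
    lx, ly = lam * 0.38 * a_b, -0.05 * b_b
    in_lung2d = (((X - lx) / (0.42 * a_b * lscale)) ** 2
                 + ((Y - ly) / (0.60 * b_b * lscale)) ** 2) <= 1.0
    z_lung = (zs >= -si / 2 - 30.0) & (zs <= si / 2 + 30.0)
    lung = (in_lung2d[:, :, None] & z_lung[None, None, :]
            & (dist_to_air >= CHEST_WALL_MM))

    # heart: always left-sided, tucked against the antero-medial chest wall
    hr = 45.0 * (1.0 + 0.03 * np.clip(rng.normal(), -2, 2))
    hc = np.array([30.0, -(b_b - 50.0), -si / 4])
    d2 = ((X[:, :, None] - hc[0]) ** 2 + (Y[:, :, None] - hc[1]) ** 2
          + (zs[None, None, :] - hc[2]) ** 2)
    heart = (d2 <= hr ** 2) & (dist_to_air >= 8.0) & body
    lung &= ~heart

    dens = spec.densities
    density = np.zeros(body.shape, dtype=np.float32)
    density[body] = dens.get("body", 1.0)
    density[breast_region] = dens.get("breast", 0.95)
    density[lung] = dens.get("lung", 0.25)
    density[heart] = dens.get("heart", 1.0)

    return Phantom(
        density=density,
        masks={"body": body, "breast_target": target,
               "ipsilateral_lung": lung, "heart": heart},
        origin=np.array([xs[0], ys[0], zs[0]]),
        voxel_size=vox,
        spec=spec,
    )


def label_for(spec: PhantomSpec) -> CohortLabel:
    """SE/ME label from the generator's separation threshold."""
    return CohortLabel("ME" if spec.breast_separation
                       >= SEPARATION_THRESHOLD_CM else "SE")


def draw_spec(rng: np.random.Generator, energy_class: str,
              voxel_size: float = 2.5) -> PhantomSpec:
    """Draw one phantom spec for the given class.

    Breast extents follow the separation allometrically (larger breasts
    protrude proportionally more) with 6% relative jitter.
    """
    lo, hi = (SE_SEPARATION_RANGE if energy_class == "SE"
              else ME_SEPARATION_RANGE)
    sep = rng.uniform(lo, hi)
    ap = max(3.0, (0.42 * sep - 1.4) * (1 + 0.06 * np.clip(rng.normal(), -2, 2)))
    si = max(6.0, (0.60 * sep + 2.0) * (1 + 0.06 * np.clip(rng.normal(), -2, 2)))
    return PhantomSpec(
        breast_separation=sep, breast_extent_ap=ap, breast_extent_si=si,
        laterality="left" if rng.random() < 0.5 else "right",
        voxel_size=voxel_size,
        seed=int(rng.integers(2 ** 31)),
    )


def generate_cohort(n: int, se_fraction: float, seed: int,
                    voxel_size: float = 2.5
                    ) -> list[tuple[Phantom, CohortLabel]]:
    """Generate a labelled cohort; reproducible under ``seed``."""
    if n < 2:
        raise ValueError("cohort needs at least 2 phantoms")
    rng = np.random.default_rng(seed)
    n_se = int(round(n * se_fraction))
    classes = ["SE"] * n_se + ["ME"] * (n - n_se)
    rng.shuffle(classes)
    out = []
    for cls in classes:
        spec = draw_spec(rng, cls, voxel_size=voxel_size)
        out.append((generate_phantom(spec), label_for(spec)))
    return out


# --------------------------------------------------------------------------
# teacher plans
# --------------------------------------------------------------------------

@dataclass
class TeacherPlan:
    """An emulated 'clinical' plan: tuned fluence + dose, used as RF labels."""

    fluences: dict                      # beam -> {energy -> FluenceMap}
    total_fluence: dict                 # beam -> FluenceMap (energy sum)
    dose: dose_mod.DoseGrid             # raw (unnormalized) plan dose
    anchors: list
    report: "ft.TuneReport"
    energies: tuple[str, ...]
    converged: bool


def teacher_plan(phantom: Phantom, beams: BeamPair,
                 engine_config: dose_mod.EngineConfig | None = None,
                 tune_config: "ft.TuneConfig | None" = None,
                 energies: tuple[str, ...] = ("6MV",),
                 fans: dict | None = None,
                 compute_final_dose: bool = True) -> TeacherPlan:
    """ECOMP initial fluence tuned to convergence (tol 1%, up to 50 iters).

    Non-convergence is propagated as a flagged plan, not an error.
    """
    engine_config = engine_config or dose_mod.EngineConfig()
    tune_config = tune_config or ft.TuneConfig(tolerance=0.01, max_iter=50)
    fans = fans or dose_mod.build_fans(phantom, beams, engine_config)

    split_init = fl.logistic_low_fraction if "15MV" in energies else None
    init = {b.name: fl.ecomp_initial_fluence(phantom, b, fans[b.name],
                                             energy=energies[0],
                                             config=engine_config,
                                             split_fraction=split_init)
            for b in beams}
    anchors = ft.select_anchor_points(phantom, beams, tune_config, fans)
    anchors = ft.centrality_correction(phantom, beams, anchors, fans)

    split_fraction = fl.logistic_low_fraction if "15MV" in energies else None
    tuned, report = ft.tune_fluence(
        phantom, beams, init, anchors, tune_config,
        engine_config=engine_config, fans=fans,
        split_fraction=split_fraction)

    fluences = {}
    for b in beams:
        total = tuned[b.name]
        if "15MV" in energies:
            depth = fans[b.name].total_path("breast_target")
            frac = fl.logistic_low_fraction(depth)
            low = total.copy()
            low.values = total.values * frac
            high = total.copy()
            high.values = total.values - low.values
            fluences[b.name] = {"6MV": low, "15MV": high}
        else:
            fluences[b.name] = {"6MV": total}

    dose_grid = None
    if compute_final_dose:
        dose_grid = dose_mod.compute_dose(
            phantom, list(beams), fluences, config=engine_config, fans=fans)
    return TeacherPlan(fluences=fluences, total_fluence=tuned, dose=dose_grid,
                       anchors=anchors, report=report,
                       energies=tuple(energies), converged=report.converged)


# --------------------------------------------------------------------------
# analytic fixtures
# --------------------------------------------------------------------------

def make_slab_phantom(thickness_cm: float = 10.0, density: float = 1.0,
                      lateral_mm: float = 120.0, si_mm: float = 120.0,
                      voxel_size: float = 2.5,
                      target_inset_mm: float = 15.0) -> Phantom:
    """Synthetic homogeneous slab (normal along x) for analytic oracles.

    Opposed beams at gantry 90/270 traverse the slab thickness; the
    breast_target is a centered box inset from every face.
    """
    t = 10.0 * thickness_cm

    def axis(half):
        # half-voxel-offset symmetric axis: voxel faces land exactly on the
        # stated slab boundaries, so analytic path lengths are exact
        n = int(round(2 * half / voxel_size))
        return (np.arange(n) + 0.5) * voxel_size - half

    xs = axis(t / 2 + 20.0)
    ys = axis(lateral_mm / 2 + 10.0)
    zs = axis(si_mm / 2 + 10.0)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    # strict bounds: voxel centers span exactly the requested extents
    body = (np.abs(X) < t / 2) & (np.abs(Y) < lateral_mm / 2) \
        & (np.abs(Z) < si_mm / 2)
    inset = target_inset_mm
    target = (np.abs(X) < t / 2 - inset) & (np.abs(Y) < lateral_mm / 2 - inset) \
        & (np.abs(Z) < si_mm / 2 - inset)
    dens = np.where(body, float(density), 0.0).astype(np.float32)
    empty = np.zeros_like(body)
    return Phantom(density=dens,
                   masks={"body": body, "breast_target": target,
                          "ipsilateral_lung": empty, "heart": empty},
                   origin=np.array([xs[0], ys[0], zs[0]]),
                   voxel_size=voxel_size)
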