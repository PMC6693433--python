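"""Anatomy-driven fluence estimation.

Three pieces live here:

* :func:`ecomp_initial_fluence` — the irregular-surface-compensator baseline:
  per-beamlet fluence chosen so each beam alone delivers a uniform dose on the
  40%-depth surface (the starting point human planners iterate from);
* the per-pixel random-forest fluence model mapping beamlet anatomy features
  to teacher fluence intensity (150 trees, pooled pixels across cases);
* the mixed-energy split: a monotone non-increasing low-energy fraction as a
  function of beamlet penetration depth through the breast, learned from ME
  teacher plans (whose generator-side convention is a logistic in depth).

Feature schema: the three anatomy features named in the field's practice
(gray level, breast penetration depth, lung penetration depth) plus four
geometric extensions that make the task learnable at toy scale; the schema is
versioned and a model refuses to predict across schema versions.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.ensemble import RandomForestRegressor
from sklearn.isotonic import IsotonicRegression

from .dose import DepthFan, EngineConfig, SSD_REF_MM, pdd
from .geometry import FluenceMap

SCHEMA_VERSION = "1"
FEATURE_NAMES = (
    "drr_gray",            # [0,1], joint-scale DRR gray level
    "depth_breast_cm",     # geometric beamlet path through the breast target
    "depth_lung_cm",       # geometric beamlet path through ipsilateral lung
    "radiological_total_cm",
    "dist_to_field_edge_mm",   # signed; positive inside the aperture
    "dist_to_central_axis_mm",
    "off_axis_si_mm",
)


# --------------------------------------------------------------------------
# ECOMP baseline
# --------------------------------------------------------------------------

def ecomp_initial_fluence(phantom, beam, fan: DepthFan | None = None,
                          energy: str = "6MV",
                          config: EngineConfig | None = None,
                          depth_fraction: float = 0.4,
                          target_dose_per_beam: float = 100.0,
                          split_fraction=None) -> FluenceMap:
    """Compensator-style initial fluence: uniform dose at the 40%-depth plane.

    Each in-aperture beamlet weight is the inverse of its PDD x inverse-square
    factor at the fractional radiological depth, scaled so that dose there is
    ``target_dose_per_beam`` cGy per fraction (half a 200 cGy fraction per
    beam).  Flash pixels (no tissue) inherit the nearest valid value along
    their row; weights are capped at 3x the median to avoid grazing-ray
    blowups.  For mixed-energy beams, pass the depth->low-energy-fraction
    rule as ``split_fraction`` so the compensation accounts for the actual
    energy mix of each beamlet.
    """
    config = config or EngineConfig()
    fan = fan or DepthFan(phantom, beam, t_step=config.t_step_mm,
                          pad_px=config.fan_pad_px)
    total = fan.total_path()                       # cm
    t_ref = fan.reference_point_t(depth_fraction)  # mm from source
    d_ref = depth_fraction * total

    if split_fraction is not None and "15MV" in beam.energies:
        f_low = np.asarray(split_fraction(fan.total_path("breast_target")))
        shares = {"6MV": f_low, "15MV": 1.0 - f_low}
    else:
        shares = {energy: 1.0}
    dose_per_unit = np.zeros(beam.raster.shape)
    for e, share in shares.items():
        p = config.energies[e]
        r_ref = SSD_REF_MM + 10.0 * p.d_max_cm
        dose_per_unit += share * p.calibration * pdd(p, d_ref) \
            * (r_ref / t_ref) ** 2

    valid = beam.aperture & (total > 1.0)
    w = np.zeros(beam.raster.shape)
    with np.errstate(divide="ignore", invalid="ignore"):
        raw = target_dose_per_beam / dose_per_unit
    w[valid] = raw[valid]
    med = float(np.median(w[valid])) if valid.any() else 0.0
    np.clip(w, 0.0, 3.0 * med if med > 0 else None, out=w)

    # fill flash / shallow pixels with the nearest valid in-aperture value
    missing = beam.aperture & ~valid
    if missing.any() and valid.any():
        _, (ii, jj) = ndimage.distance_transform_edt(
            ~valid, return_indices=True)
        w[missing] = w[ii[missing], jj[missing]]
    w[~beam.aperture] = 0.0
    return FluenceMap(w, beam.raster.pixel_size,
                      (beam.raster.u0, beam.raster.v0), beam.name)


# --------------------------------------------------------------------------
# beamlet anatomy features
# --------------------------------------------------------------------------

def extract_feature_grid(phantom, beam, drr, fan: DepthFan | None = None):
    """Features for every in-aperture pixel of a beam.

    Returns ``(X, (rows, cols))`` with ``X`` of shape (n_pixels, 7) following
    :data:`FEATURE_NAMES` and the pixel indices the rows correspond to.
    """
    fan = fan or DepthFan(phantom, beam)
    ap = beam.aperture
    rows, cols = np.nonzero(ap)

    signed_edge = ndimage.distance_transform_edt(
        ap, sampling=beam.raster.pixel_size)
    signed_edge = signed_edge - ndimage.distance_transform_edt(
        ~ap, sampling=beam.raster.pixel_size)

    u = beam.raster.u_coords()[cols]
    v = beam.raster.v_coords()[rows]
    X = np.column_stack([
        drr.values[rows, cols],
        fan.total_path("breast_target")[rows, cols],
        fan.total_path("ipsilateral_lung")[rows, cols],
        fan.total_path()[rows, cols],
        signed_edge[rows, cols],
        np.hypot(u, v),
        v,
    ])
    return X, (rows, cols)


def extract_features(phantom, beam, drr, pixel, fan: DepthFan | None = None
                     ) -> np.ndarray:
    """Feature vector of a single in-aperture pixel (i, j)."""
    i, j = pixel
    if not beam.aperture[i, j]:
        raise ValueError(f"pixel {pixel} outside the aperture")
    X, (rows, cols) = extract_feature_grid(phantom, beam, drr, fan)
    (k,) = np.nonzero((rows == i) & (cols == j))
    return X[int(k[0])]


# --------------------------------------------------------------------------
# random-forest fluence model
# --------------------------------------------------------------------------

@dataclass
class FluenceModel:
    """150-tree regression forest over the versioned feature schema."""

    forest: RandomForestRegressor
    schema_version: str
    feature_names: tuple[str, ...]
    oob_score: float | None
    n_trees: int


def fit_fluence_model(training_cases, n_trees: int = 150, seed: int = 0,
                      max_train_pixels: int = 60000) -> FluenceModel:
    """Fit the forest on pooled per-pixel (features, teacher fluence) pairs.

    ``training_cases`` is a list of ``(X, y)`` arrays (one per beam per plan).
    Pixels are pooled across cases with no per-case weighting (cases with
    larger apertures contribute more pixels); if the pool exceeds
    ``max_train_pixels`` it is subsampled uniformly, which preserves the
    proportional contribution.  Hyperparameters beyond the tree count are
    library-typical regression defaults, pinned for reproducibility
    (unlimited depth, one-third of features per split, bootstrap on).
    """
    if not training_cases:
        raise ValueError("empty training set")
    X = np.concatenate([np.asarray(x) for x, _ in training_cases])
    y = np.concatenate([np.asarray(t).ravel() for _, t in training_cases])
    if X.shape[1] != len(FEATURE_NAMES):
        raise ValueError("feature matrix does not match the schema")
    rng = np.random.default_rng(seed)
    if len(X) > max_train_pixels:
        keep = rng.choice(len(X), size=max_train_pixels, replace=False)
        X, y = X[keep], y[keep]
    forest = RandomForestRegressor(
        n_estimators=n_trees, max_features=1.0 / 3.0, bootstrap=True,
        oob_score=True, random_state=int(rng.integers(2 ** 31)), n_jobs=1)
    forest.fit(X, y)
    return FluenceModel(forest=forest, schema_version=SCHEMA_VERSION,
                        feature_names=FEATURE_NAMES,
                        oob_score=float(forest.oob_score_), n_trees=n_trees)


def predict_fluence(model: FluenceModel, phantom, beam, drr,
                    fan: DepthFan | None = None, smooth: bool = True
                    ) -> FluenceMap:
    """Predicted fluence map: RF per pixel, 0 outside the aperture, optional
    3x3 mean post-smoothing (on by default), clipped nonnegative."""
    if model.schema_version != SCHEMA_VERSION:
        raise ValueError(
            f"model schema {model.schema_version!r} does not match "
            f"runtime schema {SCHEMA_VERSION!r}")
    X, (rows, cols) = extract_feature_grid(phantom, beam, drr, fan)
    values = np.zeros(beam.raster.shape)
    if len(X):
        values[rows, cols] = model.forest.predict(X)
    if smooth:
        from .finetune import masked_mean3
        values = masked_mean3(values, beam.aperture)
    values *= beam.aperture
    np.clip(values, 0.0, None, out=values)
    return FluenceMap(values, beam.raster.pixel_size,
                      (beam.raster.u0, beam.raster.v0), beam.name)


# --------------------------------------------------------------------------
# mixed-energy split
# --------------------------------------------------------------------------

def logistic_low_fraction(depth_cm, d0: float = 11.0, w: float = 2.0):
    """Generator-side teacher convention: low-energy (6MV) fraction as a
    logistic in beamlet breast penetration depth."""
    return 1.0 / (1.0 + np.exp((np.asarray(depth_cm, dtype=float) - d0) / w))


@dataclass
class SplitModel:
    """Monotone non-increasing low-energy fraction vs depth (binned means,
    isotonic projection, linear interpolation, flat extrapolation)."""

    bin_centers_cm: np.ndarray
    low_fraction: np.ndarray

    def __call__(self, depth_cm) -> np.ndarray:
        d = np.asarray(depth_cm, dtype=float)
        # np.interp needs ascending x; curve is non-increasing in depth
        out = np.interp(d, self.bin_centers_cm, self.low_fraction)
        return np.clip(out, 0.0, 1.0)


def fit_energy_split(me_cases, bin_width_cm: float = 0.5,
                     min_total: float = 1e-6) -> SplitModel:
    """Learn the depth->low-fraction curve from ME teacher plans.

    ``me_cases`` is a list of ``(depth_cm, low_values, total_values)`` array
    triples (one per beam per ME plan); pixels with negligible total fluence
    are ignored.
    """
    if not me_cases:
        raise ValueError("need at least one ME training case")
    depth = np.concatenate([np.asarray(d).ravel() for d, _, _ in me_cases])
    low = np.concatenate([np.asarray(l).ravel() for _, l, _ in me_cases])
    total = np.concatenate([np.asarray(t).ravel() for _, _, t in me_cases])
    ok = total > min_total
    if not ok.any():
        raise ValueError("no pixels with fluence to learn the split from")
    depth, frac = depth[ok], low[ok] / total[ok]

    bins = np.floor(depth / bin_width_cm).astype(int)
    centers, means = [], []
    for b in np.unique(bins):
        sel = bins == b
        centers.append((b + 0.5) * bin_width_cm)
        means.append(float(frac[sel].mean()))
    centers = np.asarray(centers)
    means = np.asarray(means)
    iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
    mono = iso.fit_transform(centers, means)
    return SplitModel(bin_centers_cm=centers, low_fraction=mono)


def split_fluence(split_model: SplitModel, fluence: FluenceMap,
                  depth_breast_cm: np.ndarray
                  ) -> tuple[FluenceMap, FluenceMap]:
    """Split a total map into (6MV, 15MV) components.

    Conservation is exact by construction: high = total - low, pixelwise.
    """
    frac = split_model(depth_breast_cm)
    low = fluence.copy()
    low.values = fluence.values * frac
    high = fluence.copy()
    high.values = fluence.values - low.values
    return low, high
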