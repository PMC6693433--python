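"""PCA energy selection: single (6MV) vs mixed (6/15MV) beam energy.

Cohort DRR-histograms are mean-centered and decomposed by exact SVD (no
stochastic solver, so fits are bit-deterministic); each case is represented by
its first two principal-component scores, and a linear discriminant between
the two class clouds recommends the energy.  The PC1 sign is oriented so the
single-energy class mean has PC1 < 0, matching the convention in which PC1 = 0
itself is already a good classifier; :func:`boundary_angle_deg` reports how
close the fitted boundary lands to that degenerate vertical line.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .drr import HistogramFeature


@dataclass(frozen=True)
class EnergyFeature:
    pc1: float
    pc2: float


@dataclass
class EnergyModel:
    mean: np.ndarray              # (n_bins,) training mean histogram
    axes: np.ndarray              # (2, n_bins) orthonormal principal axes
    boundary_normal: np.ndarray   # (2,) in PC space
    boundary_offset: float        # score = normal . pc + offset; > 0 -> ME
    training_scores: np.ndarray   # (n, 2)
    training_labels: list[str]

    def __post_init__(self):
        g = self.axes @ self.axes.T
        if not np.allclose(g, np.eye(2), atol=1e-9):
            raise ValueError("principal axes must be orthonormal")
        if np.linalg.norm(self.boundary_normal) == 0:
            raise ValueError("boundary normal must be nonzero")


def _as_matrix(features) -> np.ndarray:
    rows = [f.counts if isinstance(f, HistogramFeature) else np.asarray(f)
            for f in features]
    return np.asarray(rows, dtype=float)


def fit_energy_model(features, labels) -> EnergyModel:
    """PCA + 2-D Fisher discriminant between the SE and ME class clouds."""
    X = _as_matrix(features)
    labels = list(labels)
    y = np.array([lbl if isinstance(lbl, str) else lbl.energy_class
                  for lbl in labels])
    if len(X) < 4:
        raise ValueError("need at least 4 training cases")
    if len(set(y)) < 2:
        raise ValueError("training set must contain both SE and ME cases")

    mean = X.mean(axis=0)
    Xc = X - mean
    # exact thin SVD; right singular vectors are the principal axes
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    axes = vt[:2].copy()
    scores = Xc @ axes.T

    se, me = scores[y == "SE"], scores[y == "ME"]
    if se[:, 0].mean() >= 0:            # orient PC1: SE class mean < 0
        axes[0] *= -1.0
        scores[:, 0] *= -1.0
        se, me = scores[y == "SE"], scores[y == "ME"]
    if axes[1][np.argmax(np.abs(axes[1]))] < 0:   # deterministic PC2 sign
        axes[1] *= -1.0
        scores[:, 1] *= -1.0
        se, me = scores[y == "SE"], scores[y == "ME"]

    # Fisher LDA in the 2-D score space (pooled within-class covariance)
    sw = np.cov(se.T, bias=False) * (len(se) - 1) \
        + np.cov(me.T, bias=False) * (len(me) - 1)
    sw /= max(len(scores) - 2, 1)
    sw += 1e-9 * np.trace(sw) * np.eye(2)
    normal = np.linalg.solve(sw, me.mean(axis=0) - se.mean(axis=0))
    scale = np.linalg.norm(normal)
    normal = normal / scale
    offset = -float(normal @ (me.mean(axis=0) + se.mean(axis=0)) / 2)

    return EnergyModel(mean=mean, axes=axes, boundary_normal=normal,
                       boundary_offset=offset, training_scores=scores,
                       training_labels=list(y))


def project(model: EnergyModel, feature) -> EnergyFeature:
    """PC scores of a (query) histogram: pc_i = (h - mean) . axis_i."""
    h = feature.counts if isinstance(feature, HistogramFeature) \
        else np.asarray(feature, dtype=float)
    if h.shape != model.mean.shape:
        raise ValueError(f"histogram dimension {h.shape} does not match "
                         f"model {model.mean.shape}")
    pc = model.axes @ (h - model.mean)
    return EnergyFeature(pc1=float(pc[0]), pc2=float(pc[1]))


def classify_energy(model: EnergyModel, feature) -> str:
    """SE/ME recommendation; exact boundary points resolve to SE (the
    simpler, single-energy plan)."""
    if isinstance(feature, EnergyFeature):
        pc = np.array([feature.pc1, feature.pc2])
    else:
        f = project(model, feature)
        pc = np.array([f.pc1, f.pc2])
    score = float(model.boundary_normal @ pc + model.boundary_offset)
    return "ME" if score > 0 else "SE"


def boundary_angle_deg(model: EnergyModel) -> float:
    """Angle (deg) between the fitted boundary and the PC1 = 0 line; 0 means
    the discriminant reduces to the pure PC1-sign rule."""
    n = model.boundary_normal / np.linalg.norm(model.boundary_normal)
    return float(np.degrees(np.arccos(np.clip(abs(n[0]), 0.0, 1.0))))
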