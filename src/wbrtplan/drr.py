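"""Digitally reconstructed radiographs and their gray-level histogram feature.

Gray level is defined as the per-beamlet radiological (water-equivalent) path,
min-max normalized to [0, 1] *jointly over the in-aperture pixels of both
beams* so the medial and lateral images share one scale.  This monotone
thickness encoding is all the energy classifier needs; no attempt is made at
radiographic realism (beam hardening, scatter, detector response).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dose import DepthFan


@dataclass
class DRRImage:
    """Projection image on the beam's fluence raster; values in [0, 1]."""

    values: np.ndarray       # (nv, nu) gray level, 0 outside the aperture
    raw_cm: np.ndarray       # unnormalized radiological path, cm
    aperture: np.ndarray
    beam_name: str


def _normalize(raw, aperture, scale):
    """Min-max normalization; a constant image maps to 0.5 by convention."""
    lo, hi = scale
    values = np.zeros_like(raw)
    if hi - lo < 1e-12:
        values[aperture] = 0.5
    else:
        values[aperture] = np.clip((raw[aperture] - lo) / (hi - lo), 0.0, 1.0)
    return values


def render_drr(phantom, beam, fan: DepthFan | None = None,
               scale: tuple[float, float] | None = None) -> DRRImage:
    """Render one beam's DRR; ``scale`` overrides the min-max range (used to
    put both beams of a patient on a joint scale)."""
    if not beam.aperture.any():
        raise ValueError("beam aperture is empty")
    fan = fan or DepthFan(phantom, beam)
    raw = fan.total_path()
    if scale is None:
        inap = raw[beam.aperture]
        scale = (float(inap.min()), float(inap.max()))
    return DRRImage(values=_normalize(raw, beam.aperture, scale),
                    raw_cm=raw, aperture=beam.aperture, beam_name=beam.name)


def render_drr_pair(phantom, beams, fans: dict | None = None
                    ) -> tuple[DRRImage, DRRImage]:
    """Render both beams' DRRs on a joint per-patient min-max scale."""
    fans = fans or {}
    raws = {}
    for b in beams:
        fan = fans.get(b.name) or DepthFan(phantom, b)
        raws[b.name] = (b, fan.total_path())
    pooled = np.concatenate([raw[b.aperture] for b, raw in raws.values()])
    scale = (float(pooled.min()), float(pooled.max()))
    return tuple(
        DRRImage(values=_normalize(raw, b.aperture, scale), raw_cm=raw,
                 aperture=b.aperture, beam_name=b.name)
        for b, raw in raws.values())


def export_drr(drr: DRRImage, png_path=None, ascii_path=None) -> None:
    """Write a DRR as 16-bit grayscale PNG and/or a whitespace ASCII matrix
    of the [0, 1] gray levels."""
    if png_path is not None:
        from PIL import Image
        arr = np.round(drr.values * 65535.0).astype(np.uint16)
        Image.fromarray(arr, mode="I;16").save(png_path)
    if ascii_path is not None:
        np.savetxt(ascii_path, drr.values, fmt="%.6f")


@dataclass
class HistogramFeature:
    """Normalized gray-level histogram pooled over both beams' apertures."""

    bin_edges: np.ndarray    # (n_bins + 1,) over [0, 1]
    counts: np.ndarray       # (n_bins,) frequencies summing to 1

    def __post_init__(self):
        if abs(self.counts.sum() - 1.0) > 1e-9:
            raise ValueError("histogram counts must sum to 1")
        if np.any(self.counts < 0):
            raise ValueError("histogram counts must be nonnegative")


def gray_histogram(drr_medial: DRRImage, drr_lateral: DRRImage,
                   apertures: tuple[np.ndarray, np.ndarray] | None = None,
                   n_bins: int = 64) -> HistogramFeature:
    """Histogram of gray levels inside the irradiated area, beams pooled
    (summed) then normalized to unit mass."""
    aps = apertures or (drr_medial.aperture, drr_lateral.aperture)
    pooled = np.concatenate([drr_medial.values[aps[0]],
                             drr_lateral.values[aps[1]]])
    if pooled.size == 0:
        raise ValueError("no in-aperture pixels to histogram")
    counts, edges = np.histogram(pooled, bins=n_bins, range=(0.0, 1.0))
    counts = counts.astype(float)
    counts /= counts.sum()
    return HistogramFeature(bin_edges=edges, counts=counts)
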