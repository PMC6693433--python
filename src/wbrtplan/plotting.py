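"""Small plotting helpers (DVH curves, tuning convergence)."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .evaluate import dvh


def plot_dvh(dose_grid, phantom, rx: float, structures=None, ax=None):
    """Cumulative DVH curves for the named structures (dose axis in % Rx)."""
    structures = structures or ("breast_target", "ipsilateral_lung", "heart")
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for name in structures:
        if not phantom.masks[name].any():
            continue
        curve = dvh(dose_grid, phantom.masks[name])
        ax.plot(100.0 * curve["dose_cgy"] / rx, curve["volume_pct"],
                label=name.replace("_", " "))
    ax.set_xlabel("dose (% of prescription)")
    ax.set_ylabel("volume (%)")
    ax.set_xlim(0, 120)
    ax.legend()
    return ax


def plot_tuning(report, ax=None):
    """Max relative anchor deviation per fine-tuning iteration."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.semilogy(range(len(report.deviations)), report.deviations,
                marker="o")
    ax.set_xlabel("iteration")
    ax.set_ylabel("max |anchor dose - target| / target")
    return ax
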