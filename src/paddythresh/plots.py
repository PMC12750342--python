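"""Diagnostic plots: SSD curve and four-quadrant scatter."""

from __future__ import annotations

import numpy as np

from .core import RICE_COLUMNS, SOIL_TOTAL_COLUMNS, Dataset
from .ssd import LogisticSSDFit, logistic_curve


def plot_ssd_curve(fit: LogisticSSDFit, x, y, ax=None):
    """Empirical (x, y) points with the fitted S-curve, x log-scaled."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(x, dtype=float)
    grid = np.geomspace(x.min() / 2, x.max() * 2, 200)
    ax.semilogx(x, y, "o", ms=4, label="empirical")
    ax.semilogx(grid, logistic_curve(grid, fit.a, fit.b, fit.x0), "-",
                label=f"logistic fit (a={fit.a:.1f}, b={fit.b:.2f}, x0={fit.x0:.1f})")
    ax.set_xlabel("1/BCF")
    ax.set_ylabel("cumulative probability (%)")
    title = " ".join(filter(None, [fit.element, fit.ph_bin]))
    if title:
        ax.set_title(title)
    ax.legend()
    return ax


def plot_quadrants(dataset: Dataset, element: str, soil_threshold: float,
                   grain_limit: float, ax=None):
    """ln-ratio scatter with quadrant boundaries at zero."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    frame = dataset.frame if isinstance(dataset, Dataset) else dataset
    x = np.log(frame[RICE_COLUMNS[element]].to_numpy(float) / grain_limit)
    y = np.log(frame[SOIL_TOTAL_COLUMNS[element]].to_numpy(float) / soil_threshold)
    ax.scatter(x, y, s=12)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    ax.set_xlabel(f"ln(grain {element} / limit)")
    ax.set_ylabel(f"ln(soil {element} / threshold)")
    return ax
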