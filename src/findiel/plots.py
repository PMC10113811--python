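"""Diagnostic plots for the standard data products.

Requires matplotlib (the ``plot`` extra).  These are quick-look displays —
the presence matrix by day-of-year and hour, per-regime noise distributions,
and the residual ACF — not publication figures.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_presence_matrix(grid: np.ndarray, ax=None):
    """Day-of-year x hour-of-day presence counts as an image."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    im = ax.imshow(grid.T, aspect="auto", origin="lower", interpolation="nearest", cmap="viridis")
    ax.set_xlabel("day of year")
    ax.set_ylabel("hour of day (UTC)")
    ax.figure.colorbar(im, ax=ax, label="years with presence")
    return ax


def plot_regime_noise(hourly: pd.DataFrame, level_col: str = "noise_p20_db", ax=None):
    """Per-regime distribution of hourly percentile noise levels: jittered
    points, mean bar, and a smoothed density outline per regime."""
    import matplotlib.pyplot as plt
    from scipy.stats import gaussian_kde

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    regimes = [r for r in ("dawn", "day", "dusk", "night") if r in set(hourly["regime"])]
    rng = np.random.default_rng(0)
    for i, regime in enumerate(regimes):
        vals = hourly.loc[hourly["regime"] == regime, level_col].dropna().to_numpy()
        if len(vals) == 0:
            continue
        ax.plot(i + rng.uniform(-0.15, 0.15, len(vals)), vals, ".", alpha=0.3, ms=3)
        ax.hlines(vals.mean(), i - 0.3, i + 0.3, color="k")
        if len(vals) > 5 and np.std(vals) > 0:
            kde = gaussian_kde(vals)
            grid = np.linspace(vals.min(), vals.max(), 100)
            dens = kde(grid)
            dens = 0.3 * dens / dens.max()
            ax.plot(i + dens, grid, color="C0", lw=1)
            ax.plot(i - dens, grid, color="C0", lw=1)
    ax.set_xticks(range(len(regimes)), regimes)
    ax.set_ylabel(f"{level_col} (dB)")
    return ax


def plot_acf(values: np.ndarray, ax=None):
    """Residual autocorrelation by lag with the large-sample +-2/sqrt(n) band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    lags = np.arange(len(values))
    ax.stem(lags, values)
    ax.axhline(0, color="k", lw=0.5)
    ax.set_xlabel("lag (hours)")
    ax.set_ylabel("autocorrelation")
    return ax
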