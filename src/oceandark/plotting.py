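"""Simple plot helpers for trend and photic-change rasters.

Colour convention: red where K_d(490) increases (the ocean darkens), blue
where it decreases, white where no significant change.
"""

from __future__ import annotations

import numpy as np


def plot_trend_map(results, ax=None):
    """Classification map (red/white/blue) from fitted trend results."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import BoundaryNorm, ListedColormap

    if ax is None:
        _, ax = plt.subplots()
    cmap = ListedColormap(["0.6", "#2166ac", "white", "#b2182b"])
    norm = BoundaryNorm([-9.5, -1.5, -0.5, 0.5, 1.5], cmap.N)
    grid = results.grid
    extent = [grid.lon_min, grid.lon_max, grid.lat_min, grid.lat_max]
    im = ax.imshow(results.classification, cmap=cmap, norm=norm, extent=extent,
                   origin="upper", interpolation="nearest")
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_title("K$_d$(490) trend classification")
    return im


def plot_delta_histogram(hist, ax=None):
    """Bar chart of area per 10 m photic-depth change increment."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for direction, color in (("reduction", "#b2182b"), ("increase", "#2166ac")):
        sub = hist[hist["direction"] == direction]
        sign = -1.0 if direction == "increase" else 1.0
        ax.bar(sign * (sub["bin_low_m"] + sub["bin_high_m"]) / 2.0,
               sub["area_km2"], width=0.9 * np.diff(
                   np.array([sub["bin_low_m"], sub["bin_high_m"]]), axis=0).ravel(),
               color=color, label=direction)
    ax.set_xlabel("photic-depth reduction (m)")
    ax.set_ylabel("area (km$^2$)")
    ax.legend()
    return ax
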