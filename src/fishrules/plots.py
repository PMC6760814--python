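"""Matplotlib renderings of the analysis products (maps, weights, series)."""

from __future__ import annotations

import numpy as np

from .maps_scores import PairLogitMap, RegionMap

__all__ = [
    "plot_pair_logit_map",
    "plot_region_map",
    "plot_weight_map",
    "plot_count_series",
]

_REGION_COLORS = ["0.55", "#f2a0c0", "#f5a142", "#7a4fa3"]  # align/anti/attr/rep


def _grid_extent(x, y):
    dx = (x[1] - x[0]) / 2 if len(x) > 1 else 0.5
    dy = (y[1] - y[0]) / 2 if len(y) > 1 else 0.5
    return [x[0] - dx, x[-1] + dx, y[0] - dy, y[-1] + dy]


def plot_pair_logit_map(pmap: PairLogitMap, speed_index: int = 0, ax=None):
    """Theta-averaged pair logit over neighbour position, red = turn right."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    z = pmap.z[speed_index].mean(axis=-1)
    lim = np.abs(z).max() or 1.0
    im = ax.imshow(
        z.T, origin="lower", extent=_grid_extent(pmap.x, pmap.y),
        cmap="RdBu_r", vmin=-lim, vmax=lim,
    )
    ax.set_xlabel("neighbour x (BL)")
    ax.set_ylabel("neighbour y (BL)")
    ax.set_title(
        f"pair logit, v_n = {pmap.neighbour_speeds[speed_index]:g} BL/s"
    )
    plt.colorbar(im, ax=ax, label="logit z (theta-averaged)")
    return ax


def plot_region_map(rmap: RegionMap, speed_index: int = 0, ax=None):
    """Alignment / anti-alignment / attraction / repulsion classification."""
    import matplotlib.pyplot as plt
    from matplotlib.colors import ListedColormap

    if ax is None:
        _, ax = plt.subplots()
    ax.imshow(
        rmap.region[speed_index].T, origin="lower",
        extent=_grid_extent(rmap.x, rmap.y),
        cmap=ListedColormap(_REGION_COLORS), vmin=-0.5, vmax=3.5,
    )
    ax.set_xlabel("neighbour x (BL)")
    ax.set_ylabel("neighbour y (BL)")
    ax.set_title("interaction regions")
    return ax


def plot_weight_map(w: np.ndarray, x, y, speed_index: int = 0, ax=None):
    """log of the aggregation weight W over neighbour position."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(
        np.log(w[speed_index]).T, origin="lower", extent=_grid_extent(x, y),
        cmap="viridis",
    )
    ax.set_xlabel("neighbour x (BL)")
    ax.set_ylabel("neighbour y (BL)")
    ax.set_title("log aggregation weight")
    plt.colorbar(im, ax=ax, label="log W")
    return ax


def plot_count_series(series: dict, fps: float = 32.0, ax=None):
    """N_total and N_important over time for one focal individual."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    t = series["frames"] / fps
    ax.plot(t, series["n_total"], label="N_total", color="tab:blue")
    ax.plot(t, series["n_important"], label="N_important", color="tab:red")
    ax.set_xlabel("time (s)")
    ax.set_ylabel("neighbours")
    ax.legend()
    return ax
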