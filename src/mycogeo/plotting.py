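"""Quick-look maps: occurrence surfaces and single-sample predictions."""

from __future__ import annotations

from .geometry import SpatialGrid
from .prediction import OriginPrediction
from .smoothing import OccurrenceAtlas

__all__ = ["plot_surface", "plot_prediction"]


def _scatter_grid(ax, grid: SpatialGrid, values, **kw):
    sc = ax.scatter(grid.lons, grid.lats, c=values, s=8, marker="s", **kw)
    ax.set_xlabel("longitude")
    ax.set_ylabel("latitude")
    ax.set_aspect(1.3)  # rough lat/lon aspect at mid-latitudes
    return sc


def plot_surface(atlas: OccurrenceAtlas, taxon_id: str, ax=None):
    """Map one taxon's smoothed occurrence-probability surface."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    j = atlas.taxon_ids.index(taxon_id)
    s = atlas.surfaces[j]
    sc = _scatter_grid(ax, atlas.grid, s.probs, cmap="viridis", vmin=0, vmax=1)
    ax.figure.colorbar(sc, ax=ax, label="occurrence probability")
    title = f"{taxon_id}"
    if s.rho == s.rho:  # not NaN
        title += f"  (rho = {s.rho:.0f} km)"
    ax.set_title(title)
    return ax


def plot_prediction(prediction: OriginPrediction, grid: SpatialGrid, ax=None,
                    true_origin=None):
    """Map a query's predictive pmf, point estimate and nested regions."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 5))
    sc = _scatter_grid(ax, grid, prediction.pmf, cmap="magma")
    ax.figure.colorbar(sc, ax=ax, label="predictive probability")
    for level in sorted(prediction.regions, reverse=True):
        cells = prediction.regions[level]
        if cells.size:
            ax.scatter(
                grid.lons[cells], grid.lats[cells], s=8, marker="s",
                facecolors="none", label=f"{level:.0%} region", alpha=0.6,
                edgecolors="cyan" if level < 0.9 else "white", linewidths=0.4,
            )
    ax.plot(prediction.s_hat.lon, prediction.s_hat.lat, "r*", ms=14,
            label="predicted origin")
    if true_origin is not None:
        ax.plot(true_origin.lon, true_origin.lat, "g^", ms=10, label="true origin")
    ax.legend(loc="lower left", fontsize=8)
    ax.set_title(f"query {prediction.query_id}")
    return ax
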