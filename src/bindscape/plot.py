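"""Map export: equirectangular heat maps of landscapes and probabilities.

Renders the unrolled 2D map (longitude on x, latitude on y) with optional
pocket-mask outline and binding-pathway overlay.  Display only — every
quantitative statement in the pipeline comes from the grid arrays, never from
these images.
"""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .landscape import GridMap

__all__ = ["plot_map"]


def plot_map(
    grid: GridMap,
    quantity: str = "dG",
    surface=None,
    mask=None,
    pathway=None,
    path=None,
    title: str | None = None,
):
    """Render one grid quantity (or a smoothed surface) as a heat map.

    Parameters
    ----------
    quantity : "dG" or "count", ignored when ``surface`` is given.
    surface : optional smoothed-surface callable (e.g. from ``tps_smooth``),
        evaluated on a dense raster.
    mask : optional PocketMask; cap masks draw their boundary circle.
    pathway : optional BindingPathway; key points are connected in time order.
    path : output PNG path; when None the figure is returned unsaved.
    """
    fig, ax = plt.subplots(figsize=(10, 5))
    extent = (-180, 180, -90, 90)
    if surface is not None:
        lons = np.linspace(-180, 180, 360)
        lats = np.linspace(-90, 90, 180)
        LO, LA = np.meshgrid(lons, lats)
        Z = surface(np.column_stack([LO.ravel(), LA.ravel()])).reshape(LA.shape)
        im = ax.imshow(Z, origin="lower", extent=extent, aspect="auto",
                       cmap="rainbow")
    elif quantity == "dG":
        im = ax.imshow(grid.dG, origin="lower", extent=extent, aspect="auto",
                       cmap="rainbow")
    else:
        im = ax.imshow(grid.counts, origin="lower", extent=extent,
                       aspect="auto", cmap="rainbow")
    fig.colorbar(
        im, ax=ax,
        label="ΔG (kcal/mol)" if (surface is not None or quantity == "dG")
        else "binding number (num./grid)",
    )
    if mask is not None and getattr(mask, "center", None) is not None:
        theta = np.linspace(0, 2 * np.pi, 181)
        # small-circle outline of the cap, drawn in plate-carree coordinates
        from .geometry import GeoPosition, geo_to_unit, _unit_to_geo

        c = geo_to_unit(mask.center)
        north = np.array([0.0, 0.0, 1.0])
        t1 = np.cross(north, c)
        if np.linalg.norm(t1) < 1e-9:
            t1 = np.array([1.0, 0.0, 0.0])
        t1 /= np.linalg.norm(t1)
        t2 = np.cross(c, t1)
        r = np.radians(mask.radius_deg)
        ring = (
            np.cos(r) * c[None, :]
            + np.sin(r) * (np.cos(theta)[:, None] * t1 + np.sin(theta)[:, None] * t2)
        )
        geos = [_unit_to_geo(v) for v in ring]
        lons = np.array([g.lon for g in geos])
        lats = np.array([g.lat for g in geos])
        jumps = np.abs(np.diff(lons)) > 180
        lons[1:][jumps] = np.nan  # break the line at the dateline
        ax.plot(lons, lats, "r-", lw=1.5)
    if pathway is not None:
        lons = [kp.geo.lon for kp in pathway.key_points]
        lats = [kp.geo.lat for kp in pathway.key_points]
        ax.plot(lons, lats, "k.-", lw=1.2, ms=8)
        for kp in pathway.key_points:
            ax.annotate(f"{kp.time:g}", (kp.geo.lon, kp.geo.lat), fontsize=7)
    ax.set_xlabel("longitude (°)")
    ax.set_ylabel("latitude (°)")
    if title:
        ax.set_title(title)
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
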