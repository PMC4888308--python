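"""Topographic scalp maps of ERD/ERS values.

Electrode positions on the unit sphere are projected to 2-D with an
azimuthal equidistant projection from the vertex; values are interpolated
with inverse-distance weighting (power 2) on great-circle distances, so
the interpolant is exact at electrode sites. Grid points outside the
convex hull of the electrodes are masked. Color limits are symmetric
about zero with maximum ERD in red and maximum ERS in blue.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import Delaunay

from .errors import ConfigurationError
from .montage import positions_for


@dataclasses.dataclass
class TopographicFrame:
    grid: np.ndarray          # (res, res), NaN outside the hull
    extent: tuple             # (xmin, xmax, ymin, ymax) for imshow
    electrode_xy: np.ndarray  # (n, 2) projected positions
    values: np.ndarray
    labels: list[str]
    clim: tuple[float, float]


def project_azimuthal(pos: np.ndarray) -> np.ndarray:
    """Azimuthal equidistant projection from the vertex (0, 0, 1)."""
    rho = np.arccos(np.clip(pos[:, 2], -1.0, 1.0))
    r_xy = np.hypot(pos[:, 0], pos[:, 1])
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.where(r_xy > 1e-12, rho / r_xy, 0.0)
    return np.column_stack([pos[:, 0] * scale, pos[:, 1] * scale])


def topomap(values, labels: list[str], grid_res: int = 67,
            idw_power: float = 2.0,
            positions: dict | None = None) -> TopographicFrame:
    """Interpolate per-channel values over the scalp.

    ``positions`` supplies unit-sphere coordinates for labels missing
    from the built-in montage; an unknown label raises an error naming it.
    """
    values = np.asarray(values, dtype=float)
    if len(values) != len(labels):
        raise ConfigurationError("one value per electrode required")
    if len(labels) < 4:
        raise ConfigurationError("topographic interpolation needs ≥ 4 electrodes")
    pos = positions_for(list(labels), positions)
    xy = project_azimuthal(pos)

    lim = float(np.abs(xy).max()) * 1.02
    axis = np.linspace(-lim, lim, grid_res)
    gx, gy = np.meshgrid(axis, axis)
    rho = np.hypot(gx, gy)
    # back-project the grid to the sphere for great-circle distances
    with np.errstate(invalid="ignore", divide="ignore"):
        ux = np.where(rho > 1e-12, gx / rho, 0.0)
        uy = np.where(rho > 1e-12, gy / rho, 0.0)
    sphere = np.stack([np.sin(rho) * ux, np.sin(rho) * uy, np.cos(rho)], axis=-1)
    dots = np.clip(sphere @ pos.T, -1.0, 1.0)        # (res, res, n)
    dist = np.arccos(dots)
    with np.errstate(divide="ignore"):
        w = dist ** (-idw_power)
    grid = np.empty(gx.shape)
    exact = dist < 1e-9
    any_exact = exact.any(axis=-1)
    w_safe = np.where(np.isfinite(w), w, 0.0)
    grid = (w_safe @ values) / w_safe.sum(axis=-1)
    if any_exact.any():
        nearest = np.argmax(exact, axis=-1)
        grid[any_exact] = values[nearest[any_exact]]

    hull = Delaunay(xy)
    inside = hull.find_simplex(np.column_stack([gx.ravel(), gy.ravel()])) >= 0
    grid[~inside.reshape(gx.shape)] = np.nan

    vmax = float(np.nanmax(np.abs(values))) or 1.0
    return TopographicFrame(grid=grid, extent=(-lim, lim, -lim, lim),
                            electrode_xy=xy, values=values,
                            labels=list(labels), clim=(-vmax, vmax))


def render_band_figure(maps, band: str, path, clim: float | None = None):
    """4 types × 3 windows panel figure for one band's grand-average maps.

    Maximum ERD is red, maximum ERS blue; the shared color limit is the
    grand max |index| over the band unless ``clim`` is given.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    band_maps = sorted((m for m in maps if m.band == band), key=lambda m: m.ptype)
    if not band_maps:
        raise ConfigurationError(f"no maps for band {band!r}")
    if clim is None:
        clim = max(float(np.nanmax(np.abs(m.values))) for m in band_maps) or 1.0
    n_int = band_maps[0].values.shape[1]
    fig, axes = plt.subplots(len(band_maps), n_int,
                             figsize=(3 * n_int, 2.6 * len(band_maps)),
                             squeeze=False)
    windows = ["−3…−2 s", "−2…−1 s", "−1…0 s"]
    im = None
    for r, m in enumerate(band_maps):
        for c in range(n_int):
            frame = topomap(m.values[:, c], m.channels)
            ax = axes[r][c]
            im = ax.imshow(frame.grid, origin="lower", extent=frame.extent,
                           cmap="RdBu_r", vmin=-clim, vmax=clim)
            ax.scatter(*frame.electrode_xy.T, s=4, c="k")
            ax.set_axis_off()
            if r == 0:
                ax.set_title(windows[c] if c < 3 else f"window {c}", fontsize=9)
        axes[r][0].text(-0.15, 0.5, f"Type {m.ptype}", rotation=90,
                        transform=axes[r][0].transAxes, va="center", fontsize=9)
    fig.suptitle(f"{band} ERD/ERS (%), max |{clim:.1f}|")
    fig.colorbar(im, ax=[a for row in axes for a in row], shrink=0.6,
                 label="ERD (+) / ERS (−) %")
    fig.savefig(path, dpi=110)
    plt.close(fig)
    return path
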