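"""Minimal matplotlib helpers for grid-lattice results."""

from __future__ import annotations

import numpy as np

from .lattice import GridLattice


def plot_unit_values(lattice: GridLattice, values: np.ndarray,
                     mask: np.ndarray | None = None, ax=None,
                     title: str | None = None):
    """Raster map of per-unit values; hotspot cells are outlined.

    Only regular grids are drawn; polygon lattices fall back to a centroid
    scatter.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    values = np.asarray(values, dtype=float)
    if lattice.is_regular:
        nrows, ncols = lattice.shape
        im = ax.imshow(values.reshape(nrows, ncols), origin="upper",
                       interpolation="nearest")
        ax.figure.colorbar(im, ax=ax, shrink=0.8)
        if mask is not None and mask.any():
            m = np.asarray(mask, dtype=bool).reshape(nrows, ncols)
            ax.contour(m.astype(float), levels=[0.5], colors="red",
                       linewidths=1.2)
    else:
        sc = ax.scatter(lattice.centroids[:, 0], lattice.centroids[:, 1],
                        c=values, s=25)
        ax.figure.colorbar(sc, ax=ax, shrink=0.8)
        if mask is not None and mask.any():
            hot = lattice.centroids[np.asarray(mask, dtype=bool)]
            ax.scatter(hot[:, 0], hot[:, 1], facecolors="none",
                       edgecolors="red", s=60)
    if title:
        ax.set_title(title)
    return ax
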