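"""Sliding-window spatial maps of node metrics.

Node metrics (normalized clustering, max-normalized degree, ...) are
averaged in sliding windows (default 20 × 20 μm, 5 μm stride) over the
(x, y) positions of the ROIs, planes collapsed, producing a heat map of
where in the brain a metric concentrates.  Window origins sit on an
absolute stride grid (anchored at multiples of the stride), so shifting
every coordinate by one stride shifts the map by exactly one cell.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class SpatialMap:
    """Window-averaged node-metric values on a regular stride grid.

    ``values[iy, ix]`` is the mean metric over ROIs whose centers fall in
    the window with lower corner ``(x0 + ix·stride, y0 + iy·stride)``
    (lower edges inclusive, upper edges exclusive); empty windows are
    masked NaN with count 0.
    """

    values: np.ndarray
    counts: np.ndarray
    x0: float
    y0: float
    window_size: float
    stride: float
    metric: str = ""

    @property
    def mask(self) -> np.ndarray:
        """True where the cell is undefined (no ROI in the window)."""
        return self.counts == 0

    def cell_origin(self, ix: int, iy: int) -> tuple[float, float]:
        return self.x0 + ix * self.stride, self.y0 + iy * self.stride

    def to_frame(self) -> pd.DataFrame:
        ny, nx = self.values.shape
        iy, ix = np.meshgrid(np.arange(ny), np.arange(nx), indexing="ij")
        return pd.DataFrame({
            "x_origin": self.x0 + ix.ravel() * self.stride,
            "y_origin": self.y0 + iy.ravel() * self.stride,
            "value": self.values.ravel(),
            "n_rois": self.counts.ravel(),
            "metric": self.metric,
        })


def node_metric_map(
    coords: pd.DataFrame | np.ndarray,
    values,
    window_size: float = 20.0,
    stride: float = 5.0,
    metric: str = "",
) -> SpatialMap:
    """Average a per-node metric in sliding windows over ROI positions.

    ``coords`` is either the dataset's coordinate table (columns
    ``x_um, y_um``) or an (n, 2) array of x, y positions; ``values`` is
    one number per ROI.  Every defined cell equals the exact mean over
    the ROIs inside its window.
    """
    if window_size <= 0 or stride <= 0:
        raise ValueError("window_size and stride must be > 0")
    if isinstance(coords, pd.DataFrame):
        xy = coords[["x_um", "y_um"]].to_numpy(float)
    else:
        xy = np.asarray(coords, float)
    values = np.asarray(values, float)
    if xy.shape[0] != values.shape[0]:
        raise ValueError(
            f"{xy.shape[0]} coordinates but {values.shape[0]} metric values")
    x, y = xy[:, 0], xy[:, 1]

    # origins on the absolute stride grid: every window whose [o, o+window)
    # span can contain a point
    def origins(lo: float, hi: float) -> np.ndarray:
        first = np.floor((lo - window_size) / stride) + 1
        # smallest origin with o + window_size > lo, i.e. o > lo - window
        o = np.arange(first, np.floor(hi / stride) + 1) * stride
        return o[(o + window_size > lo) & (o <= hi)]

    ox = origins(x.min(), x.max())
    oy = origins(y.min(), y.max())
    vals = np.full((oy.size, ox.size), np.nan)
    counts = np.zeros((oy.size, ox.size), dtype=int)
    for iy, oyv in enumerate(oy):
        in_y = (y >= oyv) & (y < oyv + window_size)
        for ix, oxv in enumerate(ox):
            member = in_y & (x >= oxv) & (x < oxv + window_size)
            c = int(member.sum())
            counts[iy, ix] = c
            if c:
                vals[iy, ix] = values[member].mean()
    return SpatialMap(
        values=vals, counts=counts,
        x0=float(ox[0]) if ox.size else 0.0,
        y0=float(oy[0]) if oy.size else 0.0,
        window_size=window_size, stride=stride, metric=metric,
    )


def normalize_degree_map(degrees) -> np.ndarray:
    """Degrees scaled to the network's maximum: k_i / max(k), in (0, 1]
    for the maximal node.  Raises if every degree is zero."""
    k = np.asarray(degrees, float)
    kmax = k.max()
    if kmax <= 0:
        raise ValueError("cannot normalize: all degrees are zero")
    return k / kmax
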