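"""Mosaic layouts, snapshot capture, and bilinear demosaicking.

A snapshot multispectral sensor samples one band per pixel according to a
small i x j mosaic of band indices tiled periodically across the sensor.
The spatial design question is which arrangement of the chosen bands in
the mosaic best preserves the downstream merit; layouts are enumerated as
all assignments of bands to cells in which every band appears at least
once (the surjective members of the Cartesian product), and the raw
mosaicked image is reconstructed per band by bilinear interpolation on
that band's knot pixels.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, List, Optional, Tuple, Union

import numpy as np
from scipy.interpolate import griddata

from .filters import FilterSet, featurize
from .hypercube import Hypercube

__all__ = [
    "MosaicLayout",
    "RawMosaic",
    "mosaic_dims",
    "surjection_count",
    "enumerate_layouts",
    "mosaic_image",
    "demosaic",
]

# full enumeration is used only while the unfiltered Cartesian product
# stays below this size; beyond it layouts are rejection-sampled
_ENUMERATION_LIMIT = 2_000_000

DEFAULT_LAYOUT_CAP = 10_000


class LayoutError(ValueError):
    """Infeasible or non-surjective mosaic layout."""


@dataclass(frozen=True)
class MosaicLayout:
    """An i x j grid of band indices, tiled periodically from pixel (0,0)."""

    cells: np.ndarray  # shape (i, j), int band indices
    n_bands: int

    def __post_init__(self):
        cells = np.asarray(self.cells, dtype=int)
        if cells.ndim != 2:
            raise LayoutError("cells must be a 2D grid")
        if cells.min() < 0 or cells.max() >= self.n_bands:
            raise LayoutError("cell band index out of range")
        if self.n_bands > 1 and len(np.unique(cells)) != self.n_bands:
            raise LayoutError("every band must appear at least once in the mosaic")
        object.__setattr__(self, "cells", cells)

    @property
    def dims(self) -> Tuple[int, int]:
        return self.cells.shape

    def band_map(self, shape: Tuple[int, int]) -> np.ndarray:
        """Per-pixel band index for an image of the given spatial shape."""
        i, j = self.dims
        rr = np.arange(shape[0]) % i
        cc = np.arange(shape[1]) % j
        return self.cells[np.ix_(rr, cc)]

    def to_json(self) -> str:
        import json

        return json.dumps(
            {"dims": list(self.dims), "cells": self.cells.ravel().tolist(),
             "n_bands": self.n_bands}
        )

    @classmethod
    def from_json(cls, text: str) -> "MosaicLayout":
        import json

        d = json.loads(text)
        cells = np.array(d["cells"], dtype=int).reshape(d["dims"])
        return cls(cells, d["n_bands"])


@dataclass(frozen=True)
class RawMosaic:
    """The scalar-per-pixel snapshot measurement and its provenance."""

    values: np.ndarray
    layout: MosaicLayout

    def __post_init__(self):
        if self.values.ndim != 2:
            raise ValueError("raw mosaic must be 2D")

    @property
    def shape(self) -> Tuple[int, int]:
        return self.values.shape


def mosaic_dims(n_bands: int) -> Tuple[int, int]:
    """Smallest square mosaic accommodating ``n_bands`` (2x2 up to 4, 3x3 up to 9)."""
    if n_bands < 1:
        raise ValueError("need at least one band")
    s = math.isqrt(n_bands - 1) + 1
    return (s, s)


def surjection_count(n_bands: int, n_cells: int) -> int:
    """Number of onto assignments of ``n_bands`` to ``n_cells`` cells
    (inclusion-exclusion)."""
    return sum(
        (-1) ** k * math.comb(n_bands, k) * (n_bands - k) ** n_cells
        for k in range(n_bands + 1)
    )


def enumerate_layouts(
    fs: Union[FilterSet, int],
    dims: Optional[Tuple[int, int]] = None,
    cap: Optional[int] = DEFAULT_LAYOUT_CAP,
    rng_seed: int = 0,
) -> List[MosaicLayout]:
    """All surjective band-to-cell assignments, lexicographic in row-major cells.

    When the surjective family exceeds ``cap`` a seeded uniform subsample of
    ``cap`` layouts is returned (order preserved where enumerable); pass
    ``cap=None`` to force full enumeration.
    """
    n = len(fs) if isinstance(fs, FilterSet) else int(fs)
    if dims is None:
        dims = mosaic_dims(n)
    i, j = dims
    m = i * j
    if m < n:
        raise LayoutError(f"{i}x{j} mosaic cannot hold {n} distinct bands")
    total = n**m
    rng = np.random.default_rng(rng_seed)

    if total <= _ENUMERATION_LIMIT:
        layouts = [
            t for t in itertools.product(range(n), repeat=m)
            if len(set(t)) == n
        ]
        if cap is not None and len(layouts) > cap:
            keep = np.sort(rng.choice(len(layouts), size=cap, replace=False))
            layouts = [layouts[k] for k in keep]
    else:
        if cap is None:
            raise LayoutError(
                f"{n} bands on {i}x{j}: {total} assignments is too large to "
                "enumerate exhaustively; provide a cap"
            )
        seen = set()
        while len(seen) < min(cap, surjection_count(n, m)):
            t = tuple(rng.integers(0, n, size=m).tolist())
            if len(set(t)) == n:
                seen.add(t)
        layouts = sorted(seen)

    return [MosaicLayout(np.array(t, dtype=int).reshape(i, j), n) for t in layouts]


def mosaic_image(cube: Hypercube, layout: MosaicLayout, fs: FilterSet) -> RawMosaic:
    """Simulate the snapshot capture: each pixel measures its assigned band."""
    if layout.n_bands != len(fs):
        raise LayoutError("layout and FilterSet band counts differ")
    features = featurize(cube, fs)  # rows x cols x n
    bmap = layout.band_map(cube.labels.shape)
    raw = np.take_along_axis(features, bmap[:, :, None], axis=2)[:, :, 0]
    return RawMosaic(values=raw, layout=layout)


def _demosaic_band(raw: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """Reconstruct one band image from its knot pixels.

    When the knots form a complete product lattice (one mosaic cell per
    band, the common case) separable bilinear interpolation with constant
    edge extension is used; otherwise piecewise-linear interpolation on
    the scattered knots with nearest-knot fill outside their hull.
    """
    rows, cols = raw.shape
    knot_r = np.unique(np.nonzero(mask.any(axis=1))[0])
    knot_c = np.unique(np.nonzero(mask.any(axis=0))[0])
    if mask.sum() == len(knot_r) * len(knot_c) and mask[np.ix_(knot_r, knot_c)].all():
        vals = raw[np.ix_(knot_r, knot_c)]
        # interpolate along columns, then rows; np.interp extends constantly
        tmp = np.empty((len(knot_r), cols))
        cgrid = np.arange(cols)
        for a in range(len(knot_r)):
            tmp[a] = np.interp(cgrid, knot_c, vals[a])
        out = np.empty((rows, cols))
        rgrid = np.arange(rows)
        for b in range(cols):
            out[:, b] = np.interp(rgrid, knot_r, tmp[:, b])
        return out
    pts = np.argwhere(mask)
    vals = raw[mask]
    grid_r, grid_c = np.mgrid[0:rows, 0:cols]
    out = griddata(pts, vals, (grid_r, grid_c), method="linear")
    holes = np.isnan(out)
    if holes.any():
        out[holes] = griddata(pts, vals, (grid_r[holes], grid_c[holes]),
                              method="nearest")
    return out


def demosaic(raw: RawMosaic, layout: Optional[MosaicLayout] = None,
             fs: Optional[FilterSet] = None) -> np.ndarray:
    """Reconstruct the per-band image stack from a raw snapshot.

    Returns a rows x cols x n_bands stack; knot pixels are preserved
    exactly and each band is filled by bilinear interpolation on its knot
    lattice.
    """
    layout = layout if layout is not None else raw.layout
    if fs is not None and len(fs) != layout.n_bands:
        raise LayoutError("layout and FilterSet band counts differ")
    bmap = layout.band_map(raw.shape)
    n = layout.n_bands
    stack = np.empty(raw.shape + (n,))
    for b in range(n):
        mask = bmap == b
        if not mask.any():
            raise LayoutError(f"band {b} has no knot pixels in the tiled layout")
        stack[:, :, b] = _demosaic_band(raw.values, mask)
    return stack
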