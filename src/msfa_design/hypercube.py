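"""Synthetic spatial phantoms for snapshot-mosaic simulation.

Two idealized scene layouts are provided: an esophageal phantom of
concentric circles (neoplasia within Barrett's segment within squamous
background) and a colon phantom of two circular lesions (polyp and
postresection site) on normal mucosa with small specular-glare discs.
Label maps are populated with spectra drawn from a labeled pool in
correlated square blocks, emulating the spatial coherence of tissue, and
an evaluation border is cropped after demosaicking so that edge
interpolation artifacts do not enter the merit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np

from .synthetic_spectra import LabeledSpectraDataset, WavelengthGrid

__all__ = [
    "LabelMap",
    "Hypercube",
    "GeometryError",
    "PopulationError",
    "build_esophageal_labels",
    "build_colon_labels",
    "populate_hypercube",
    "crop_border",
    "save_hypercube",
    "load_hypercube",
]

ESOPHAGEAL_FRACTIONS = {"neoplasia": 236 / 715, "NDBE": 320 / 715, "squamous": 159 / 715}

DEFAULT_CROP_MARGIN = 5


class GeometryError(ValueError):
    """Invalid phantom geometry (radii or margins out of range)."""


class PopulationError(ValueError):
    """Spectra pool does not cover the label map's classes."""


@dataclass(frozen=True)
class LabelMap:
    """2D grid of class indices with the class-name registry."""

    labels: np.ndarray
    class_names: Tuple[str, ...]

    def __post_init__(self):
        lab = np.asarray(self.labels, dtype=int)
        if lab.ndim != 2 or min(lab.shape) < 1:
            raise ValueError("label map must be a non-empty 2D grid")
        if lab.min() < 0 or lab.max() >= len(self.class_names):
            raise ValueError("label index outside the class registry")
        object.__setattr__(self, "labels", lab)
        object.__setattr__(self, "class_names", tuple(self.class_names))

    @property
    def shape(self) -> Tuple[int, int]:
        return self.labels.shape

    def class_counts(self) -> Dict[str, int]:
        return {
            name: int(np.sum(self.labels == i))
            for i, name in enumerate(self.class_names)
        }

    def label_names(self) -> np.ndarray:
        """Per-pixel class-name array (object dtype)."""
        return np.asarray(self.class_names, dtype=object)[self.labels]


@dataclass
class Hypercube:
    """A reflectance stack (rows x cols x wavelengths) with ground truth."""

    stack: np.ndarray
    grid: WavelengthGrid
    labels: LabelMap
    truth_concentrations: Dict[str, np.ndarray] = field(default_factory=dict)
    block_size: int = 1
    seed: Optional[int] = None

    def __post_init__(self):
        if self.stack.ndim != 3:
            raise ValueError("stack must be rows x cols x wavelengths")
        if self.stack.shape[:2] != self.labels.shape:
            raise ValueError("stack spatial dims must match the label map")
        if self.stack.shape[2] != len(self.grid):
            raise ValueError("stack spectral dim must match the grid")
        if np.any(self.stack < 0):
            raise ValueError("reflectance must be non-negative")

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.stack.shape


def _disc_mask(shape: Tuple[int, int], center: Tuple[float, float], radius: float) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2


def _radius_for_fraction(shape: Tuple[int, int], center, fraction: float) -> int:
    """Integer radius whose disc pixel fraction best matches ``fraction``."""
    total = shape[0] * shape[1]
    best_r, best_err = 1, np.inf
    for r in range(1, min(shape) // 2):
        err = abs(_disc_mask(shape, center, r).sum() / total - fraction)
        if err < best_err:
            best_r, best_err = r, err
    return best_r


def build_esophageal_labels(
    shape: Tuple[int, int] = (80, 80),
    radii: Optional[Tuple[float, float]] = None,
    class_fractions: Optional[Dict[str, float]] = None,
) -> LabelMap:
    """Concentric-circle esophageal phantom.

    Center disc = neoplasia, annulus = NDBE, background = squamous.  When
    ``radii`` is omitted the two radii are solved so the class pixel
    fractions best approximate the cohort's class proportions.
    """
    center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    if radii is None:
        fr = class_fractions or ESOPHAGEAL_FRACTIONS
        r_inner = _radius_for_fraction(shape, center, fr["neoplasia"])
        r_outer = _radius_for_fraction(shape, center, fr["neoplasia"] + fr["NDBE"])
        radii = (r_inner, r_outer)
    r_inner, r_outer = radii
    if not (0 < r_inner < r_outer < min(shape) / 2):
        raise GeometryError(
            f"radii must satisfy 0 < r_inner < r_outer < {min(shape) / 2:g}; "
            f"got {radii}"
        )
    class_names = ("squamous", "NDBE", "neoplasia")
    lab = np.zeros(shape, dtype=int)
    lab[_disc_mask(shape, center, r_outer)] = 1
    lab[_disc_mask(shape, center, r_inner)] = 2
    return LabelMap(lab, class_names)


def build_colon_labels(
    shape: Tuple[int, int] = (96, 96),
    polyp: Optional[Tuple[Tuple[float, float], float]] = None,
    postresection: Optional[Tuple[Tuple[float, float], float]] = None,
    specular_radius: float = 3.0,
    n_specular: int = 2,
) -> LabelMap:
    """Two-lesion colon phantom with specular glare.

    Polyp and postresection discs sit on a normal-mucosa background;
    small specular discs overlap the lesions (specular overwrites).
    Lesion geometry defaults scale with the phantom so the 96x96
    classification and 196x196 unmixing variants share one layout.
    """
    m = min(shape)
    if polyp is None:
        polyp = ((0.30 * shape[0], 0.32 * shape[1]), 0.17 * m)
    if postresection is None:
        postresection = ((0.66 * shape[0], 0.64 * shape[1]), 0.24 * m)
    for (ctr, rad), name in ((polyp, "polyp"), (postresection, "postresection")):
        if rad <= 0:
            raise GeometryError(f"{name} disc is degenerate (radius {rad:g})")
        if not (rad <= ctr[0] <= shape[0] - 1 - rad and rad <= ctr[1] <= shape[1] - 1 - rad):
            raise GeometryError(f"{name} disc extends outside the phantom bounds")
    class_names = ("normal", "polyp", "postresection", "specular")
    lab = np.zeros(shape, dtype=int)
    lab[_disc_mask(shape, *polyp)] = 1
    lab[_disc_mask(shape, *postresection)] = 2
    if specular_radius > 0 and n_specular > 0:
        # glare spots centered inside each lesion, offset toward the lesion rim
        hosts = [polyp, postresection][:n_specular]
        for (ctr, rad) in hosts:
            spot = (ctr[0] - 0.4 * rad, ctr[1] + 0.3 * rad)
            lab[_disc_mask(shape, spot, specular_radius)] = 3
    return LabelMap(lab, class_names)


def populate_hypercube(
    labels: LabelMap,
    pool: LabeledSpectraDataset,
    block_size: int = 2,
    rng_seed: int = 0,
) -> Hypercube:
    """Fill a label map with spectra drawn from ``pool`` in coherent blocks.

    For every block_size x block_size tile and every class present in it,
    one spectrum of that class is drawn uniformly at random (with
    replacement across tiles) and assigned to all pixels of that class in
    the tile.  Per-pixel truth concentration maps are copied from the
    spectra's generation records when available.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    pool_by_class: Dict[str, List[int]] = {}
    for i, s in enumerate(pool.spectra):
        pool_by_class.setdefault(s.class_label, []).append(i)
    present = {labels.class_names[i] for i in np.unique(labels.labels)}
    missing = present - set(pool_by_class)
    if missing:
        raise PopulationError(f"pool is missing classes: {sorted(missing)}")

    rng = np.random.default_rng(rng_seed)
    rows, cols = labels.shape
    n_wl = len(pool.grid)
    stack = np.zeros((rows, cols, n_wl))
    truth: Dict[str, np.ndarray] = {}
    have_truth = all(
        s.true_concentrations is not None for s in pool.spectra
    )
    if have_truth:
        truth = {"Hb": np.zeros((rows, cols)), "HbO2": np.zeros((rows, cols))}

    for r0 in range(0, rows, block_size):
        for c0 in range(0, cols, block_size):
            tile = labels.labels[r0 : r0 + block_size, c0 : c0 + block_size]
            for lab_idx in np.unique(tile):
                name = labels.class_names[lab_idx]
                pick = pool.spectra[rng.choice(pool_by_class[name])]
                mask = tile == lab_idx
                rr, cc = np.nonzero(mask)
                stack[r0 + rr, c0 + cc, :] = pick.reflectance
                if have_truth:
                    truth["Hb"][r0 + rr, c0 + cc] = pick.true_concentrations["Hb"]
                    truth["HbO2"][r0 + rr, c0 + cc] = pick.true_concentrations["HbO2"]

    return Hypercube(
        stack=stack,
        grid=pool.grid,
        labels=labels,
        truth_concentrations=truth,
        block_size=block_size,
        seed=rng_seed,
    )


def crop_border(x, margin: int = DEFAULT_CROP_MARGIN):
    """Remove ``margin`` pixels from all four sides.

    Accepts a Hypercube, LabelMap, or a bare 2D/3D array and returns the
    same kind.  The default margin of 5 px strips the demosaicking edge
    artifacts before evaluation.
    """
    if margin < 0:
        raise GeometryError("margin must be >= 0")
    if margin == 0:
        return x
    sl = slice(margin, -margin)
    if isinstance(x, Hypercube):
        if 2 * margin >= min(x.labels.shape):
            raise GeometryError("margin too large for the spatial shape")
        return Hypercube(
            stack=x.stack[sl, sl, :],
            grid=x.grid,
            labels=crop_border(x.labels, margin),
            truth_concentrations={k: v[sl, sl] for k, v in x.truth_concentrations.items()},
            block_size=x.block_size,
            seed=x.seed,
        )
    if isinstance(x, LabelMap):
        if 2 * margin >= min(x.shape):
            raise GeometryError("margin too large for the spatial shape")
        return LabelMap(x.labels[sl, sl], x.class_names)
    arr = np.asarray(x)
    if arr.ndim not in (2, 3):
        raise TypeError("expected Hypercube, LabelMap, or 2D/3D array")
    if 2 * margin >= min(arr.shape[:2]):
        raise GeometryError("margin too large for the spatial shape")
    return arr[sl, sl]


def save_hypercube(cube: Hypercube, path) -> None:
    """Write a hypercube to HDF5 (reflectance, grid, labels, truth maps)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.create_dataset("reflectance", data=cube.stack)
        f.create_dataset("wavelength_nm", data=cube.grid.values)
        f.create_dataset("labels", data=cube.labels.labels)
        f.attrs["class_names"] = list(cube.labels.class_names)
        f.attrs["block_size"] = cube.block_size
        if cube.seed is not None:
            f.attrs["seed"] = cube.seed
        for k, v in cube.truth_concentrations.items():
            f.create_dataset(f"truth/c{k}", data=v)


def load_hypercube(path) -> Hypercube:
    import h5py

    with h5py.File(path, "r") as f:
        labels = LabelMap(f["labels"][()], tuple(f.attrs["class_names"]))
        truth = {}
        if "truth" in f:
            truth = {k[1:]: f["truth"][k][()] for k in f["truth"]}
        return Hypercube(
            stack=f["reflectance"][()],
            grid=WavelengthGrid(f["wavelength_nm"][()]),
            labels=labels,
            truth_concentrations=truth,
            block_size=int(f.attrs["block_size"]),
            seed=int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
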