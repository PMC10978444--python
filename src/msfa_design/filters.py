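"""Spectral band filters: transmission profiles and band measurements.

A band is an idealized passband with a center wavelength and a bandwidth
given as full-width at half-maximum (FWHM).  The default profile is a
Gaussian with unit peak (a boxcar is available); the band measurement is
the transmission-weighted mean reflectance, which keeps a constant
spectrum invariant across bandwidths so measurements are comparable when
the optimizer varies the FWHM.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, List, Sequence, Tuple, Union

import numpy as np

from .synthetic_spectra import (
    LabeledSpectraDataset,
    Spectrum,
    WavelengthGrid,
    default_grid,
)
from .hypercube import Hypercube

__all__ = [
    "FilterBand",
    "FilterSet",
    "BandGrid",
    "transmission_profile",
    "apply_band",
    "featurize",
    "hyperspectral_filterset",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


class AlignmentError(ValueError):
    """Spectrum and filter profile are not on the same grid."""


class ConfigurationError(ValueError):
    pass


@dataclass(frozen=True, order=True)
class FilterBand:
    """One passband: center wavelength and FWHM bandwidth, both in nm."""

    center: float
    fwhm: float

    def __post_init__(self):
        if self.fwhm <= 0:
            raise ValueError("fwhm must be positive")


@dataclass(frozen=True)
class FilterSet:
    """An ordered set of bands, canonically sorted by (center, fwhm)."""

    bands: Tuple[FilterBand, ...]

    def __init__(self, bands: Iterable[FilterBand]):
        bands = tuple(sorted(bands))
        if not bands:
            raise ConfigurationError("a FilterSet needs at least one band")
        object.__setattr__(self, "bands", bands)

    def __len__(self) -> int:
        return len(self.bands)

    def __iter__(self):
        return iter(self.bands)

    def __getitem__(self, i) -> FilterBand:
        return self.bands[i]

    def describe(self) -> str:
        """Human-readable 'center (FWHM)' rendering, e.g. '475 (24)'."""
        return ", ".join(f"{b.center:g} ({b.fwhm:g})" for b in self.bands)

    def to_json(self) -> str:
        return json.dumps(
            [{"center_nm": b.center, "fwhm_nm": b.fwhm} for b in self.bands]
        )

    @classmethod
    def from_json(cls, text: str) -> "FilterSet":
        return cls(FilterBand(d["center_nm"], d["fwhm_nm"]) for d in json.loads(text))


@dataclass(frozen=True)
class BandGrid:
    """Allowed center/FWHM values the optimizer may place bands on."""

    centers: Tuple[float, ...] = tuple(range(450, 701))
    fwhms: Tuple[float, ...] = tuple(range(10, 31, 2))

    def __post_init__(self):
        for name, vals in (("centers", self.centers), ("fwhms", self.fwhms)):
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            if sorted(set(vals)) != list(vals):
                raise ValueError(f"{name} must be sorted and unique")

    def contains(self, band: FilterBand) -> bool:
        return band.center in self.centers and band.fwhm in self.fwhms


def sam_band_grid() -> BandGrid:
    """Band grid with the 470 nm lower center bound used for SAM designs."""
    return BandGrid(centers=tuple(range(470, 701)))


def transmission_profile(
    band: FilterBand,
    grid: WavelengthGrid,
    shape: str = "gaussian",
) -> np.ndarray:
    """Per-wavelength transmission in [0, 1] with T(center)=1 and
    T(center +/- fwhm/2)=0.5 (Gaussian) or a boxcar spanning the FWHM."""
    lam = grid.values
    if shape == "gaussian":
        sigma = band.fwhm * _FWHM_TO_SIGMA
        return np.exp(-0.5 * ((lam - band.center) / sigma) ** 2)
    if shape == "boxcar":
        return (np.abs(lam - band.center) <= band.fwhm / 2).astype(float)
    raise ConfigurationError(f"unknown profile shape {shape!r}")


def _weights(fs: FilterSet, grid: WavelengthGrid, shape: str) -> np.ndarray:
    """(n_bands, n_wavelengths) matrix of area-normalized transmissions."""
    w = np.stack([transmission_profile(b, grid, shape) for b in fs])
    return w / w.sum(axis=1, keepdims=True)


def apply_band(
    spectrum: Spectrum, band: FilterBand, shape: str = "gaussian"
) -> float:
    """Transmission-weighted mean reflectance through one band."""
    t = transmission_profile(band, spectrum.grid, shape)
    return float(np.dot(spectrum.reflectance, t) / t.sum())


def featurize(
    x: Union[Spectrum, LabeledSpectraDataset, Hypercube, np.ndarray],
    fs: FilterSet,
    grid: WavelengthGrid = None,
    shape: str = "gaussian",
):
    """Reduce spectra to band measurements.

    - Spectrum -> 1D vector of n band values
    - LabeledSpectraDataset -> (n_spectra, n_bands) array (labels unchanged
      in the dataset; pair with ``merit_classify.FeatureTable.from_dataset``)
    - Hypercube -> rows x cols x n_bands stack
    - bare (..., n_wavelengths) array with ``grid`` -> (..., n_bands)
    """
    if len(fs) == 0:
        raise ConfigurationError("empty FilterSet")
    if isinstance(x, Spectrum):
        return _weights(fs, x.grid, shape) @ x.reflectance
    if isinstance(x, LabeledSpectraDataset):
        return x.reflectance_matrix() @ _weights(fs, x.grid, shape).T
    if isinstance(x, Hypercube):
        return x.stack @ _weights(fs, x.grid, shape).T
    arr = np.asarray(x, dtype=float)
    if grid is None:
        raise AlignmentError("bare arrays require an explicit wavelength grid")
    if arr.shape[-1] != len(grid):
        raise AlignmentError("last axis must match the wavelength grid")
    return arr @ _weights(fs, grid, shape).T


def hyperspectral_filterset(
    grid: WavelengthGrid = None, fwhm: float = 1.0
) -> FilterSet:
    """The full-sampling baseline: one band per grid wavelength.

    Emulates a hyperspectral system with the given FWHM (1-30 nm allowed).
    """
    if grid is None:
        grid = default_grid()
    if not (1.0 <= fwhm <= 30.0):
        raise ConfigurationError("hyperspectral fwhm must be within 1-30 nm")
    return FilterSet(FilterBand(float(c), float(fwhm)) for c in grid.values)
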