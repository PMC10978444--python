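"""Least-squares chromophore unmixing and the band-reduction error merit.

Measured reflectance is modelled as a linear mixture of deoxyhemoglobin,
oxyhemoglobin, water and scattering bases plus a constant offset; the
fitted hemoglobin concentrations yield oxygen saturation

    sO2 = c_HbO2 / (c_Hb + c_HbO2)

and relative blood volume v_blood = c_Hb + c_HbO2.  The merit of a
reduced band set is the normalized root-mean-square error (NRMSE) between
the hemoglobin concentrations fitted from the full spectra and from the
band measurements,

    NRMSE = sqrt( (1/p) sum_p [ (cHb* - cHb**)^2 + (cHbO2* - cHbO2**)^2 ] )
            / ( mean(cHb*) * mean(cHbO2*) ).

The placement of the radical is a documented convention (root of the
per-pixel mean squared error, then normalized); ``radical="global"``
selects the alternative reading with the root over the entire normalized
sum.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple, Union

import numpy as np
from scipy.optimize import nnls

from .filters import FilterSet, featurize
from .hypercube import Hypercube
from .synthetic_spectra import CHROMOPHORES, ReferenceSpectra, WavelengthGrid

__all__ = [
    "Concentrations",
    "UnmixingResult",
    "fit_concentrations",
    "nrmse",
    "oxygen_saturation",
    "blood_volume",
    "unmix_cube",
    "reduced_basis",
]

COMPONENTS = CHROMOPHORES + ("offset",)


class ConditioningError(ValueError):
    """The unmixing basis is rank deficient."""


class NormalizationError(ValueError):
    """NRMSE normalization requires non-zero mean hemoglobin concentrations."""


@dataclass(frozen=True)
class Concentrations:
    """Fitted mixture coefficients for one measurement."""

    Hb: float
    HbO2: float
    H2O: float
    scattering: float
    offset: float
    residual: float = 0.0

    def as_array(self) -> np.ndarray:
        return np.array([self.Hb, self.HbO2, self.H2O, self.scattering, self.offset])


@dataclass
class UnmixingResult:
    """Per-pixel unmixing maps and the band-reduction error."""

    concentrations: Dict[str, np.ndarray]
    so2: np.ndarray
    vblood: np.ndarray
    r2: np.ndarray
    nrmse: Optional[float] = None
    negative_fraction: float = 0.0  # fraction of pixels with a negative Hb/HbO2 fit


def _check_basis(basis: np.ndarray, names) -> None:
    if np.linalg.matrix_rank(basis) < basis.shape[1]:
        # name the most collinear column pair for the error message
        norms = np.linalg.norm(basis, axis=0)
        norms[norms == 0] = 1.0
        g = np.abs((basis / norms).T @ (basis / norms))
        np.fill_diagonal(g, 0.0)
        a, b = np.unravel_index(np.argmax(g), g.shape)
        raise ConditioningError(
            f"unmixing basis is rank deficient; most collinear pair: "
            f"{names[a]!r} and {names[b]!r}"
        )


def fit_concentrations(
    measurement: np.ndarray,
    basis: np.ndarray,
    nonnegative: bool = False,
) -> Concentrations:
    """Ordinary least squares fit of the 5-component mixture model.

    ``basis`` is the (n_measurements, 5) design matrix with columns
    [R_Hb, R_HbO2, R_H2O, R_scattering, 1], reduced through the same bands
    as the measurement when a filter set is in play.  Unconstrained by
    default; ``nonnegative=True`` switches to NNLS.
    """
    y = np.asarray(measurement, dtype=float)
    basis = np.asarray(basis, dtype=float)
    if basis.ndim != 2 or basis.shape[1] != len(COMPONENTS):
        raise ValueError("basis must have 5 columns (4 chromophores + offset)")
    if len(y) < basis.shape[1]:
        raise ValueError(
            f"need >= {basis.shape[1]} measurements to fit {basis.shape[1]} components"
        )
    _check_basis(basis, COMPONENTS)
    if nonnegative:
        coef, rnorm = nnls(basis, y)
        resid = rnorm**2
    else:
        coef, res, _, _ = np.linalg.lstsq(basis, y, rcond=None)
        resid = float(res[0]) if res.size else float(np.sum((basis @ coef - y) ** 2))
    return Concentrations(*coef, residual=float(resid))


def reduced_basis(refs: ReferenceSpectra, fs: Optional[FilterSet]) -> np.ndarray:
    """The design matrix as seen through a filter set (or the full grid)."""
    full = refs.basis_matrix(with_offset=True)
    if fs is None:
        return full
    return featurize(full.T, fs, grid=refs.grid).T


def nrmse(
    full: Dict[str, np.ndarray],
    reduced: Dict[str, np.ndarray],
    radical: str = "per_pixel_mean",
) -> float:
    """Hemoglobin NRMSE between full-spectrum and band-reduced fits.

    ``full`` and ``reduced`` map 'Hb' and 'HbO2' to equally-shaped
    concentration arrays; normalization uses the means of the
    full-spectrum fit.
    """
    c_hb_f = np.asarray(full["Hb"], dtype=float).ravel()
    c_ox_f = np.asarray(full["HbO2"], dtype=float).ravel()
    c_hb_r = np.asarray(reduced["Hb"], dtype=float).ravel()
    c_ox_r = np.asarray(reduced["HbO2"], dtype=float).ravel()
    if not (c_hb_f.shape == c_ox_f.shape == c_hb_r.shape == c_ox_r.shape):
        raise ValueError("full/reduced concentration maps must share one shape")
    p = c_hb_f.size
    if p < 1:
        raise ValueError("need at least one pixel")
    mean_hb = c_hb_f.mean()
    mean_ox = c_ox_f.mean()
    if mean_hb <= 0 or mean_ox <= 0:
        raise NormalizationError(
            "NRMSE normalization requires positive mean Hb and HbO2 concentrations"
        )
    sq = (c_hb_f - c_hb_r) ** 2 + (c_ox_f - c_ox_r) ** 2
    if radical == "per_pixel_mean":
        return float(np.sqrt(sq.mean()) / (mean_hb * mean_ox))
    if radical == "global":
        return float(np.sqrt(sq.sum() / (p * mean_hb * mean_ox)))
    raise ValueError(f"unknown radical convention {radical!r}")


def oxygen_saturation(c: Union[Concentrations, Tuple[float, float]]) -> float:
    """sO2 = c_HbO2 / (c_Hb + c_HbO2); NaN when total hemoglobin is zero."""
    hb, ox = (c.Hb, c.HbO2) if isinstance(c, Concentrations) else c
    total = hb + ox
    if total == 0:
        return float("nan")
    return ox / total


def blood_volume(c: Union[Concentrations, Tuple[float, float]]) -> float:
    """v_blood = c_Hb + c_HbO2."""
    hb, ox = (c.Hb, c.HbO2) if isinstance(c, Concentrations) else c
    return hb + ox


def _fit_stack(Y: np.ndarray, basis: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Least-squares fit of every row of Y (n_pixels, n_meas); returns
    (coefficients (n_pixels, 5), r2 per pixel).

    With fewer measurements than components (band counts below 5) the fit
    is underdetermined and the minimum-norm solution is used.
    """
    if basis.shape[0] >= basis.shape[1]:
        _check_basis(basis, COMPONENTS)
    coef, _, _, _ = np.linalg.lstsq(basis, Y.T, rcond=None)
    coef = coef.T
    fitted = coef @ basis.T
    ss_res = np.sum((Y - fitted) ** 2, axis=1)
    ss_tot = np.sum((Y - Y.mean(axis=1, keepdims=True)) ** 2, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 1.0)
    return coef, r2


def unmix_cube(
    recon: Union[Hypercube, np.ndarray],
    refs: ReferenceSpectra,
    fs: Optional[FilterSet] = None,
    full_reference: Optional[Dict[str, np.ndarray]] = None,
) -> UnmixingResult:
    """Per-pixel unmixing of a full cube or a demosaicked band stack.

    ``recon`` is either a Hypercube (full spectra; pass ``fs=None``) or a
    rows x cols x n_bands stack reconstructed through ``fs``.  When
    ``full_reference`` (the full-spectrum fit of the same scene) is given,
    the hemoglobin NRMSE against it is reported.  Negative fitted
    hemoglobin concentrations are reported, not clipped; their prevalence
    is flagged in ``negative_fraction``.
    """
    if isinstance(recon, Hypercube):
        data = recon.stack
        basis = reduced_basis(refs, None)
        if fs is not None:
            data = featurize(recon, fs)
            basis = reduced_basis(refs, fs)
    else:
        data = np.asarray(recon, dtype=float)
        basis = reduced_basis(refs, fs)
    rows, cols, n_meas = data.shape
    if n_meas != basis.shape[0]:
        raise ValueError("measurement depth does not match the reduced basis")
    coef, r2 = _fit_stack(data.reshape(-1, n_meas), basis)
    maps = {
        name: coef[:, i].reshape(rows, cols) for i, name in enumerate(COMPONENTS)
    }
    hb, ox = maps["Hb"], maps["HbO2"]
    total = hb + ox
    with np.errstate(divide="ignore", invalid="ignore"):
        so2 = np.where(total != 0, ox / total, np.nan)
    err = None
    if full_reference is not None:
        err = nrmse(full_reference, {"Hb": hb, "HbO2": ox})
    return UnmixingResult(
        concentrations=maps,
        so2=so2,
        vblood=total,
        r2=r2.reshape(rows, cols),
        nrmse=err,
        negative_fraction=float(np.mean((hb < 0) | (ox < 0))),
    )
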