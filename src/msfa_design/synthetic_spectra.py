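"""Labeled reflectance spectra with the structure of clinical GI datasets.

Tissue reflectance in the visible range is dominated by hemoglobin
absorption (oxy and deoxy), a weak water contribution and a smoothly
decreasing scattering background.  Spectra are generated by a linear
forward model

    R(lambda) = c_Hb * R_Hb + c_HbO2 * R_HbO2 + c_H2O * R_H2O
                + c_scattering * R_scattering + offset + noise

with per-class concentration ranges, so that classes differ in blood
volume and oxygenation the way dysplastic/neoplastic tissue differs from
healthy mucosa.  Each spectrum carries its tissue class, a patient id and
(for synthetic spectra) the true concentrations used to generate it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from importlib import resources
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "WavelengthGrid",
    "ReferenceSpectra",
    "Spectrum",
    "LabeledSpectraDataset",
    "ClassConcentrationModel",
    "DatasetSpec",
    "default_grid",
    "load_chromophore_references",
    "generate_endmember",
    "generate_dataset",
    "resample_to_grid",
    "split_train_test",
    "esophageal_dataset_spec",
    "colon_dataset_spec",
    "save_dataset",
    "load_dataset",
]

CHROMOPHORES = ("Hb", "HbO2", "H2O", "scattering")

_DATA_FILES = {
    "Hb": "synthetic_hb_extinction.csv",
    "HbO2": "synthetic_hbo2_extinction.csv",
    "H2O": "synthetic_water_absorption.csv",
}


class CoverageError(ValueError):
    """Requested wavelengths fall outside the packaged table coverage."""


class ExtrapolationError(ValueError):
    """Resampling target extends beyond the source wavelength span."""


class ConfigurationError(ValueError):
    """Invalid generation request."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Strictly increasing wavelength sampling points in nm."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("wavelength grid must be a 1D array of >= 2 points")
        if not np.all(np.diff(v) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)

    def __eq__(self, other) -> bool:
        return isinstance(other, WavelengthGrid) and np.array_equal(
            self.values, other.values
        )

    def __hash__(self):
        return hash(self.values.tobytes())

    @property
    def span(self) -> Tuple[float, float]:
        return float(self.values[0]), float(self.values[-1])


def default_grid(lo: float = 470.0, hi: float = 720.0, step: float = 1.0) -> WavelengthGrid:
    """The working grid: 470-720 nm inclusive at 1 nm resolution."""
    n = int(round((hi - lo) / step)) + 1
    return WavelengthGrid(lo + step * np.arange(n))


@dataclass(frozen=True)
class ReferenceSpectra:
    """Chromophore basis curves sampled on a common grid.

    Curves are dimensionless reflectance-basis values in [0, 1] (each
    absorbance-derived curve is scaled to unit maximum over the grid, the
    scattering basis is a power law of wavelength).
    """

    grid: WavelengthGrid
    curves: Dict[str, np.ndarray]

    def __post_init__(self):
        for name, c in self.curves.items():
            c = np.asarray(c, dtype=float)
            if c.shape != self.grid.values.shape:
                raise ValueError(f"curve {name!r} not on the common grid")
            if not np.all(np.isfinite(c)):
                raise ValueError(f"curve {name!r} contains non-finite values")
            self.curves[name] = c

    def basis_matrix(self, with_offset: bool = True) -> np.ndarray:
        """Column-stacked design matrix [R_Hb, R_HbO2, R_H2O, R_scat (, 1)]."""
        cols = [self.curves[name] for name in CHROMOPHORES]
        if with_offset:
            cols.append(np.ones(len(self.grid)))
        return np.column_stack(cols)


@dataclass(frozen=True)
class Spectrum:
    """A single labeled reflectance spectrum."""

    grid: WavelengthGrid
    reflectance: np.ndarray
    class_label: str
    patient_id: str
    spectrum_id: str = ""
    true_concentrations: Optional[Dict[str, float]] = None

    def __post_init__(self):
        r = np.asarray(self.reflectance, dtype=float)
        if r.shape != self.grid.values.shape:
            raise ValueError("reflectance length must equal grid length")
        if not np.all(np.isfinite(r)):
            raise ValueError("reflectance must be finite")
        if np.any(r < 0):
            raise ValueError("reflectance must be non-negative")
        object.__setattr__(self, "reflectance", r)


@dataclass
class LabeledSpectraDataset:
    """A collection of spectra sharing one grid, with class/patient registries."""

    spectra: List[Spectrum]
    class_names: List[str]
    generation_params: Dict = field(default_factory=dict)

    def __post_init__(self):
        if self.spectra:
            grid = self.spectra[0].grid
            for s in self.spectra:
                if s.grid != grid:
                    raise ValueError("all spectra must share one wavelength grid")
                if s.class_label not in self.class_names:
                    raise ValueError(f"unregistered class {s.class_label!r}")

    def __len__(self) -> int:
        return len(self.spectra)

    @property
    def grid(self) -> WavelengthGrid:
        return self.spectra[0].grid

    @property
    def patient_ids(self) -> List[str]:
        return sorted({s.patient_id for s in self.spectra})

    def by_class(self, label: str) -> List[Spectrum]:
        return [s for s in self.spectra if s.class_label == label]

    def class_counts(self) -> Dict[str, int]:
        return {c: len(self.by_class(c)) for c in self.class_names}

    def reflectance_matrix(self) -> np.ndarray:
        """(n_spectra, n_wavelengths) stack of reflectance rows."""
        return np.array([s.reflectance for s in self.spectra])

    def subset(self, indices: Sequence[int], params: Optional[Dict] = None) -> "LabeledSpectraDataset":
        return LabeledSpectraDataset(
            [self.spectra[i] for i in indices],
            list(self.class_names),
            params if params is not None else dict(self.generation_params),
        )


@dataclass(frozen=True)
class ClassConcentrationModel:
    """Uniform concentration ranges for one tissue class.

    Each range is an inclusive (lo, hi) pair of dimensionless
    concentrations; ``offset`` models baseline signal plus systematic
    noise, ``noise_sd`` the per-wavelength additive Gaussian noise.
    """

    c_hb: Tuple[float, float] = (0.0, 0.0)
    c_hbo2: Tuple[float, float] = (0.0, 0.0)
    c_h2o: Tuple[float, float] = (0.0, 0.0)
    c_scattering: Tuple[float, float] = (0.0, 0.0)
    offset: Tuple[float, float] = (0.0, 0.0)
    noise_sd: float = 0.0

    def __post_init__(self):
        for name in ("c_hb", "c_hbo2", "c_h2o", "c_scattering", "offset"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name}: range minimum exceeds maximum")
            if name != "offset" and lo < 0:
                raise ValueError(f"{name}: concentrations must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")

    def ranges(self) -> Dict[str, Tuple[float, float]]:
        return {
            "Hb": self.c_hb,
            "HbO2": self.c_hbo2,
            "H2O": self.c_h2o,
            "scattering": self.c_scattering,
        }


def _load_table(name: str) -> Tuple[np.ndarray, np.ndarray]:
    ref = resources.files("msfa_design").joinpath("data", _DATA_FILES[name])
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, comment="#")
    return df["wavelength_nm"].to_numpy(float), df["value"].to_numpy(float)


def load_chromophore_references(
    grid: Optional[WavelengthGrid] = None,
    scattering_power: float = 1.3,
) -> ReferenceSpectra:
    """Interpolate the packaged chromophore tables onto ``grid``.

    The absorbance-derived tables (Hb, HbO2, H2O) are monotone-cubic
    interpolated and scaled to unit maximum over the grid, keeping the
    forward model linear.  The scattering basis is generated analytically
    as (lambda / 500 nm) ** (-scattering_power).

    Raises
    ------
    CoverageError
        If the grid extends beyond the packaged table coverage.
    """
    if grid is None:
        grid = default_grid()
    curves: Dict[str, np.ndarray] = {}
    for name in ("Hb", "HbO2", "H2O"):
        wl, val = _load_table(name)
        lo, hi = grid.span
        if lo < wl[0] or hi > wl[-1]:
            raise CoverageError(
                f"grid {lo:g}-{hi:g} nm outside {name} table coverage "
                f"{wl[0]:g}-{wl[-1]:g} nm"
            )
        c = PchipInterpolator(wl, val)(grid.values)
        curves[name] = c / c.max()
    curves["scattering"] = (grid.values / 500.0) ** (-scattering_power)
    return ReferenceSpectra(grid=grid, curves=curves)


def generate_endmember(
    model: ClassConcentrationModel,
    class_label: str,
    patient_id: str,
    refs: ReferenceSpectra,
    rng: np.random.Generator | int,
    spectrum_id: str = "",
) -> Spectrum:
    """Draw one spectrum from the linear forward model.

    Concentrations are drawn uniformly from the class ranges, mixed with
    the reference curves, offset and Gaussian noise added, and negative
    values clipped to zero.  True concentrations are recorded.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    conc = {k: float(rng.uniform(lo, hi)) if hi > lo else float(lo)
            for k, (lo, hi) in model.ranges().items()}
    off_lo, off_hi = model.offset
    offset = float(rng.uniform(off_lo, off_hi)) if off_hi > off_lo else float(off_lo)
    r = sum(conc[k] * refs.curves[k] for k in CHROMOPHORES) + offset
    if model.noise_sd > 0:
        r = r + rng.normal(0.0, model.noise_sd, size=len(refs.grid))
    r = np.clip(r, 0.0, None)
    truth = dict(conc)
    truth["offset"] = offset
    return Spectrum(
        grid=refs.grid,
        reflectance=r,
        class_label=class_label,
        patient_id=patient_id,
        spectrum_id=spectrum_id,
        true_concentrations=truth,
    )


@dataclass(frozen=True)
class DatasetSpec:
    """Per-class counts and concentration models plus a patient roster."""

    class_counts: Dict[str, int]
    class_models: Dict[str, ClassConcentrationModel]
    n_patients: int = 10
    name: str = "synthetic"

    def __post_init__(self):
        if not self.class_counts:
            raise ConfigurationError("at least one class must be requested")
        for c, n in self.class_counts.items():
            if n < 1:
                raise ConfigurationError(f"class {c!r}: count must be >= 1")
            if c not in self.class_models:
                raise ConfigurationError(f"class {c!r}: missing concentration model")
        if self.n_patients < 1:
            raise ConfigurationError("need at least one patient")


def generate_dataset(
    spec: DatasetSpec,
    refs: Optional[ReferenceSpectra] = None,
    rng_seed: int = 0,
) -> LabeledSpectraDataset:
    """Generate a labeled dataset with exact per-class counts.

    Spectra of each class are assigned round-robin to the patient roster,
    mimicking the observational patient grouping of clinical cohorts.
    """
    if refs is None:
        refs = load_chromophore_references()
    rng = np.random.default_rng(rng_seed)
    patients = [f"P{i + 1:02d}" for i in range(spec.n_patients)]
    spectra: List[Spectrum] = []
    for label in spec.class_counts:
        model = spec.class_models[label]
        for i in range(spec.class_counts[label]):
            spectra.append(
                generate_endmember(
                    model,
                    label,
                    patients[i % spec.n_patients],
                    refs,
                    rng,
                    spectrum_id=f"{label}_{i:05d}",
                )
            )
    return LabeledSpectraDataset(
        spectra=spectra,
        class_names=list(spec.class_counts),
        generation_params={
            "spec_name": spec.name,
            "seed": rng_seed,
            "n_patients": spec.n_patients,
            "class_counts": dict(spec.class_counts),
            "noise_sd": {c: m.noise_sd for c, m in spec.class_models.items()},
        },
    )


def resample_to_grid(spectrum: Spectrum, target: WavelengthGrid) -> Spectrum:
    """Linearly interpolate a spectrum onto ``target``.

    Wavelengths outside the target span are dropped; the target must lie
    within the source span (no extrapolation).
    """
    s_lo, s_hi = spectrum.grid.span
    t_lo, t_hi = target.span
    if t_lo < s_lo or t_hi > s_hi:
        raise ExtrapolationError(
            f"target {t_lo:g}-{t_hi:g} nm extends beyond source span "
            f"{s_lo:g}-{s_hi:g} nm"
        )
    if target == spectrum.grid:
        return spectrum
    r = np.interp(target.values, spectrum.grid.values, spectrum.reflectance)
    return replace(spectrum, grid=target, reflectance=r)


def split_train_test(
    dataset: LabeledSpectraDataset, rng_seed: int = 0
) -> Tuple[LabeledSpectraDataset, LabeledSpectraDataset]:
    """Stratified random 4:1 train/test split.

    Per class, test receives floor(count / 5) spectra and train the rest;
    the split is a partition (disjoint, union = dataset).
    """
    if not dataset.spectra:
        raise ValueError("cannot split an empty dataset")
    rng = np.random.default_rng(rng_seed)
    train_idx: List[int] = []
    test_idx: List[int] = []
    for label in dataset.class_names:
        idx = [i for i, s in enumerate(dataset.spectra) if s.class_label == label]
        if len(idx) < 5:
            warnings.warn(
                f"class {label!r} has {len(idx)} < 5 members; "
                "test split may receive none",
                stacklevel=2,
            )
        n_test = len(idx) // 5
        perm = rng.permutation(len(idx))
        test_idx.extend(idx[p] for p in perm[:n_test])
        train_idx.extend(idx[p] for p in perm[n_test:])
    params = dict(dataset.generation_params)
    return (
        dataset.subset(sorted(train_idx), {**params, "split": "train"}),
        dataset.subset(sorted(test_idx), {**params, "split": "test"}),
    )


# ---------------------------------------------------------------------------
# Preset cohorts
#
# Class counts and patient numbers mirror the published clinical cohorts
# (715 esophageal spectra from 15 patients; 14,065 colon spectra from 7).
# Concentration ranges encode the physiology the classes differ by:
# neoplastic/polyp tissue carries more blood at lower oxygenation than
# healthy mucosa, postresection tissue is blood-rich (bleeding), and
# specular glare is a high-amplitude flat spectrum.
# ---------------------------------------------------------------------------

def esophageal_class_models() -> Dict[str, ClassConcentrationModel]:
    return {
        "squamous": ClassConcentrationModel(
            c_hb=(0.05, 0.15), c_hbo2=(0.20, 0.40), c_h2o=(0.05, 0.20),
            c_scattering=(0.55, 0.85), offset=(0.0, 0.05), noise_sd=0.01,
        ),
        "NDBE": ClassConcentrationModel(
            c_hb=(0.15, 0.30), c_hbo2=(0.30, 0.50), c_h2o=(0.10, 0.25),
            c_scattering=(0.40, 0.70), offset=(0.0, 0.05), noise_sd=0.01,
        ),
        "neoplasia": ClassConcentrationModel(
            c_hb=(0.35, 0.60), c_hbo2=(0.25, 0.45), c_h2o=(0.15, 0.30),
            c_scattering=(0.25, 0.55), offset=(0.0, 0.05), noise_sd=0.01,
        ),
    }


def colon_class_models() -> Dict[str, ClassConcentrationModel]:
    return {
        "normal": ClassConcentrationModel(
            c_hb=(0.05, 0.15), c_hbo2=(0.25, 0.45), c_h2o=(0.05, 0.20),
            c_scattering=(0.55, 0.85), offset=(0.0, 0.05), noise_sd=0.01,
        ),
        "polyp": ClassConcentrationModel(
            c_hb=(0.30, 0.50), c_hbo2=(0.30, 0.55), c_h2o=(0.10, 0.25),
            c_scattering=(0.30, 0.60), offset=(0.0, 0.05), noise_sd=0.01,
        ),
        "postresection": ClassConcentrationModel(
            c_hb=(0.55, 0.85), c_hbo2=(0.15, 0.35), c_h2o=(0.15, 0.35),
            c_scattering=(0.15, 0.40), offset=(0.0, 0.05), noise_sd=0.01,
        ),
        "specular": ClassConcentrationModel(
            offset=(2.5, 3.5), noise_sd=0.02,
        ),
    }


def esophageal_dataset_spec(scale: float = 1.0) -> DatasetSpec:
    """Cohort emulating the esophageal study: 159/320/236 spectra, 15 patients.

    ``scale`` < 1 shrinks every class count proportionally (minimum 5 per
    class) for quick runs.
    """
    counts = {"squamous": 159, "NDBE": 320, "neoplasia": 236}
    counts = {c: max(5, int(round(n * scale))) for c, n in counts.items()}
    return DatasetSpec(counts, esophageal_class_models(),
                       n_patients=15, name="esophageal")


def colon_dataset_spec(scale: float = 1.0) -> DatasetSpec:
    """Cohort emulating the colon study: 5269/1045/7745/6 spectra, 7 patients."""
    counts = {"normal": 5269, "polyp": 1045, "postresection": 7745, "specular": 6}
    counts = {c: max(5, int(round(n * scale))) for c, n in counts.items()}
    return DatasetSpec(counts, colon_class_models(),
                       n_patients=7, name="colon")


# ---------------------------------------------------------------------------
# CSV round trip: wide spectra table + metadata companion
# ---------------------------------------------------------------------------

def save_dataset(dataset: LabeledSpectraDataset, spectra_csv, metadata_csv) -> None:
    """Write the wide spectra table and the metadata companion CSV."""
    ids = [s.spectrum_id or f"s{i:05d}" for i, s in enumerate(dataset.spectra)]
    wide = pd.DataFrame(
        dataset.reflectance_matrix().T, columns=ids
    )
    wide.insert(0, "wavelength_nm", dataset.grid.values)
    wide.to_csv(spectra_csv, index=False)
    rows = []
    for sid, s in zip(ids, dataset.spectra):
        row = {"spectrum_id": sid, "class_label": s.class_label,
               "patient_id": s.patient_id}
        if s.true_concentrations:
            row.update({f"true_{k}": v for k, v in s.true_concentrations.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(metadata_csv, index=False)


def load_dataset(spectra_csv, metadata_csv) -> LabeledSpectraDataset:
    wide = pd.read_csv(spectra_csv)
    meta = pd.read_csv(metadata_csv).set_index("spectrum_id")
    grid = WavelengthGrid(wide["wavelength_nm"].to_numpy(float))
    spectra = []
    for sid in wide.columns[1:]:
        m = meta.loc[sid]
        truth = {k[len("true_"):]: float(m[k]) for k in meta.columns
                 if k.startswith("true_") and pd.notna(m[k])} or None
        spectra.append(Spectrum(
            grid=grid,
            reflectance=wide[sid].to_numpy(float),
            class_label=str(m["class_label"]),
            patient_id=str(m["patient_id"]),
            spectrum_id=str(sid),
            true_concentrations=truth,
        ))
    class_names = list(dict.fromkeys(s.class_label for s in spectra))
    return LabeledSpectraDataset(spectra, class_names)
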