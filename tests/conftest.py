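import numpy as np
import pytest

import msfa_design as m
from msfa_design.merit_classify import ClassifierSpec
from msfa_design.synthetic_spectra import (
    ClassConcentrationModel,
    DatasetSpec,
    LabeledSpectraDataset,
    Spectrum,
)


@pytest.fixture(scope="session")
def grid():
    return m.default_grid()


@pytest.fixture(scope="session")
def refs(grid):
    return m.load_chromophore_references(grid)


@pytest.fixture(scope="session")
def esophageal_dataset(refs):
    """Full-size esophageal-style cohort (715 spectra, 15 patients)."""
    return m.generate_dataset(m.esophageal_dataset_spec(), refs, rng_seed=11)


@pytest.fixture(scope="session")
def small_dataset(refs):
    """Small three-class cohort for fast classification tests."""
    spec = m.esophageal_dataset_spec(scale=0.15)
    return m.generate_dataset(spec, refs, rng_seed=7)


@pytest.fixture(scope="session")
def small_colon_dataset(refs):
    spec = m.colon_dataset_spec(scale=0.01)
    return m.generate_dataset(spec, refs, rng_seed=7)


@pytest.fixture
def fs3():
    return m.FilterSet(
        [m.FilterBand(500.0, 20.0), m.FilterBand(560.0, 20.0), m.FilterBand(620.0, 20.0)]
    )


def make_flat_class_dataset(grid, levels, n_per_class=20, n_patients=4, seed=0):
    """Classes that are constant spectra at different levels (separable)."""
    rng = np.random.default_rng(seed)
    spectra = []
    names = []
    for ci, (name, level) in enumerate(levels.items()):
        names.append(name)
        for i in range(n_per_class):
            r = np.full(len(grid), level) + rng.normal(0, 0.002, len(grid))
            spectra.append(
                Spectrum(
                    grid=grid,
                    reflectance=np.clip(r, 0, None),
                    class_label=name,
                    patient_id=f"P{i % n_patients:02d}",
                    spectrum_id=f"{name}_{i}",
                )
            )
    return LabeledSpectraDataset(spectra, names)


@pytest.fixture
def flat_dataset(grid):
    return make_flat_class_dataset(
        grid, {"low": 0.2, "mid": 0.5, "high": 0.9}, n_per_class=25
    )
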