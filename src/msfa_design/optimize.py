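"""Two-stage MSFA design search: spectral screening + descent, then an
exhaustive spatial layout search.

Stage 1 (spectral): candidate band sets are drawn uniformly at random from
the allowed grids (centers 450-700 nm step 1, FWHM 10-30 nm step 2), the
few best under the merit are kept, and each is refined by discrete
best-improvement hill climbing over single-band moves (center +/- 1 nm,
FWHM +/- 2 nm).  The parameter space is a discrete grid, so the
"descent" is a coordinate hill climb; agreement among the refined
candidates is logged as a convergence diagnostic.

Stage 2 (spatial): with the band set fixed, every surjective mosaic
layout is evaluated by simulating snapshot capture of a phantom
hypercube, demosaicking, cropping the evaluation border, and scoring the
merit, averaged over cross-validation folds (one phantom per fold).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .filters import BandGrid, FilterBand, FilterSet, hyperspectral_filterset, featurize
from .hypercube import (
    Hypercube,
    build_colon_labels,
    build_esophageal_labels,
    crop_border,
    populate_hypercube,
)
from .merit_classify import (
    ClassifierSpec,
    FeatureTable,
    class_mean_references,
    knn_classify,
    per_patient_ci,
    sam_classify,
    stratified_folds,
    svm_classify,
)
from .merit_unmix import nrmse, reduced_basis, unmix_cube, _fit_stack
from .mosaic import demosaic, enumerate_layouts, mosaic_dims, mosaic_image, MosaicLayout
from .synthetic_spectra import LabeledSpectraDataset, ReferenceSpectra

__all__ = [
    "OptimizationConfig",
    "OptimizationResult",
    "ClassificationMerit",
    "UnmixingMerit",
    "make_merit",
    "random_filterset",
    "screen_candidates",
    "refine_descent",
    "optimize_spectral",
    "optimize_spatial",
    "sweep_band_counts",
    "hyperspectral_baseline",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class OptimizationConfig:
    """Knobs of the two-stage search."""

    n_bands: int = 3
    band_grid: BandGrid = field(default_factory=BandGrid)
    n_screen: int = 10_000
    n_keep: int = 5
    folds: int = 5
    seed: int = 0
    max_iterations: int = 500
    layout_cap: Optional[int] = 10_000
    distinct_centers: bool = True
    phantom: str = "esophageal"  # esophageal | colon | colon_unmix
    block_size: Optional[int] = None  # default 2 (classification) / 8 (unmixing)
    crop_margin: int = 5

    def __post_init__(self):
        if self.n_keep > self.n_screen:
            raise ValueError("n_keep must be <= n_screen")
        i, j = mosaic_dims(self.n_bands)
        if not (1 <= self.n_bands <= i * j):
            raise ValueError("n_bands outside the feasible mosaic range")
        if self.folds < 2:
            raise ValueError("need at least two folds")


@dataclass
class OptimizationResult:
    filterset: FilterSet
    layout: Optional[MosaicLayout]
    spectral_merit: float
    spatial_merit: Optional[float] = None
    per_fold_spatial: Optional[List[float]] = None
    patient_ci: Optional[Tuple[float, float]] = None
    refined_candidates: Optional[List[Tuple[FilterSet, float]]] = None
    candidates_agree: Optional[bool] = None
    trace: List[Dict] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Merit functions
# ---------------------------------------------------------------------------

def _build_phantom(kind: str, pool: LabeledSpectraDataset, block_size: int,
                   rng_seed: int) -> Hypercube:
    if kind == "esophageal":
        labels = build_esophageal_labels((80, 80))
    elif kind == "colon":
        labels = build_colon_labels((96, 96))
    elif kind == "colon_unmix":
        labels = build_colon_labels((196, 196))
    else:
        raise ValueError(f"unknown phantom kind {kind!r}")
    # generic pools: map the phantom's canonical tissue roles onto the pool's
    # class list positionally (geometry, not naming, is what the phantom fixes)
    if not set(labels.class_names) <= set(pool.class_names):
        if len(pool.class_names) < len(labels.class_names):
            raise ValueError(
                f"pool has {len(pool.class_names)} classes; phantom {kind!r} "
                f"needs {len(labels.class_names)}"
            )
        from .hypercube import LabelMap

        labels = LabelMap(labels.labels,
                          tuple(pool.class_names[: len(labels.class_names)]))
    return populate_hypercube(labels, pool, block_size=block_size, rng_seed=rng_seed)


class ClassificationMerit:
    """Classification-accuracy merit over seeded stratified folds.

    The spectral merit of a band set is the mean held-out accuracy across
    folds (4:1 train/test per fold).  The spatial merit of a layout is the
    mean per-pixel accuracy of classifying a demosaicked, border-cropped
    phantom built from each fold's held-out spectra.
    """

    sense = "max"

    def __init__(
        self,
        dataset: LabeledSpectraDataset,
        spec: ClassifierSpec,
        folds: int = 5,
        seed: int = 0,
        phantom: str = "esophageal",
        block_size: int = 2,
        crop_margin: int = 5,
    ):
        self.dataset = dataset
        self.spec = spec
        self.phantom = phantom
        self.block_size = block_size
        self.crop_margin = crop_margin
        self.seed = seed
        labels = [s.class_label for s in dataset.spectra]
        self.folds = stratified_folds(labels, folds, rng_seed=seed)

    @property
    def n_folds(self) -> int:
        return len(self.folds)

    def _classify(self, train: FeatureTable, test: FeatureTable):
        if self.spec.kind == "knn":
            return knn_classify(train, test, k=self.spec.k)
        if self.spec.kind == "svm":
            return svm_classify(train, test, self.spec)
        return sam_classify(class_mean_references(train), test)

    def spectral(self, fs: FilterSet, fold: Optional[int] = None) -> float:
        table = FeatureTable.from_dataset(self.dataset, fs)
        fold_ids = range(self.n_folds) if fold is None else [fold]
        accs = [
            self._classify(table.subset(tr), table.subset(te)).accuracy
            for tr, te in (self.folds[f] for f in fold_ids)
        ]
        return float(np.mean(accs))

    def spatial(self, fs: FilterSet, layout: MosaicLayout, fold: int):
        """Per-fold spatial merit; returns (accuracy, per-pixel patient ids)."""
        tr, te = self.folds[fold]
        train_tab = FeatureTable.from_dataset(self.dataset, fs).subset(tr)
        pool = self.dataset.subset(te)
        cube = _build_phantom(self.phantom, pool, self.block_size,
                              rng_seed=(self.seed * 1000 + fold) % (2**31))
        raw = mosaic_image(cube, layout, fs)
        stack = crop_border(demosaic(raw, layout, fs), self.crop_margin)
        truth = crop_border(cube.labels, self.crop_margin)
        rows, cols, n = stack.shape
        test_tab = FeatureTable(
            X=stack.reshape(-1, n),
            labels=truth.label_names().ravel(),
            patients=np.array(["scene"] * rows * cols, dtype=object),
            class_names=cube.labels.class_names,
        )
        res = self._classify(train_tab, test_tab)
        return res.accuracy

    def spatial_mean(self, fs: FilterSet, layout: MosaicLayout) -> float:
        return float(np.mean([self.spatial(fs, layout, f) for f in range(self.n_folds)]))

    def patient_ci(self, fs: FilterSet, level: float = 0.95) -> Tuple[float, float]:
        """Per-patient CI of held-out spectral accuracy, pooled over folds."""
        table = FeatureTable.from_dataset(self.dataset, fs)
        correct: List[float] = []
        patients: List[str] = []
        for tr, te in self.folds:
            res = self._classify(table.subset(tr), table.subset(te))
            correct.extend((res.predicted == table.labels[te]).astype(float))
            patients.extend(table.patients[te])
        return per_patient_ci(correct, patients, level)


class UnmixingMerit:
    """Hemoglobin-unmixing NRMSE merit (lower is better).

    The spectral merit fits every spectrum in the dataset with the full
    grid and with the band-reduced basis and reports the NRMSE between
    the two hemoglobin fits (p = the full dataset).  The spatial merit
    demosaics a phantom per fold and compares the per-pixel fits against
    the full-spectrum fit of the same cropped scene.
    """

    sense = "min"

    def __init__(
        self,
        dataset: LabeledSpectraDataset,
        refs: ReferenceSpectra,
        folds: int = 5,
        seed: int = 0,
        phantom: str = "colon_unmix",
        block_size: int = 8,
        crop_margin: int = 5,
    ):
        self.dataset = dataset
        self.refs = refs
        self.phantom = phantom
        self.block_size = block_size
        self.crop_margin = crop_margin
        self.seed = seed
        self.n_folds = folds
        Y = dataset.reflectance_matrix()
        coef, _ = _fit_stack(Y, reduced_basis(refs, None))
        self._full_fit = {"Hb": coef[:, 0], "HbO2": coef[:, 1]}

    def spectral(self, fs: FilterSet, fold: Optional[int] = None) -> float:
        Y = featurize(self.dataset, fs)
        coef, _ = _fit_stack(Y, reduced_basis(self.refs, fs))
        return nrmse(self._full_fit, {"Hb": coef[:, 0], "HbO2": coef[:, 1]})

    def spatial(self, fs: FilterSet, layout: MosaicLayout, fold: int) -> float:
        cube = _build_phantom(self.phantom, self.dataset, self.block_size,
                              rng_seed=(self.seed * 1000 + fold) % (2**31))
        cropped_cube = crop_border(cube, self.crop_margin)
        full = unmix_cube(cropped_cube, self.refs)
        full_ref = {"Hb": full.concentrations["Hb"],
                    "HbO2": full.concentrations["HbO2"]}
        raw = mosaic_image(cube, layout, fs)
        stack = crop_border(demosaic(raw, layout, fs), self.crop_margin)
        res = unmix_cube(stack, self.refs, fs=fs, full_reference=full_ref)
        return res.nrmse

    def spatial_mean(self, fs: FilterSet, layout: MosaicLayout) -> float:
        return float(np.mean([self.spatial(fs, layout, f) for f in range(self.n_folds)]))

    def patient_ci(self, fs: FilterSet, level: float = 0.95) -> Tuple[float, float]:
        """Per-patient CI of the per-spectrum hemoglobin fit error."""
        Y = featurize(self.dataset, fs)
        coef, _ = _fit_stack(Y, reduced_basis(self.refs, fs))
        err = np.sqrt(
            (self._full_fit["Hb"] - coef[:, 0]) ** 2
            + (self._full_fit["HbO2"] - coef[:, 1]) ** 2
        )
        patients = [s.patient_id for s in self.dataset.spectra]
        return per_patient_ci(err, patients, level)


def make_merit(
    kind: str,
    dataset: LabeledSpectraDataset,
    refs: Optional[ReferenceSpectra] = None,
    cfg: Optional[OptimizationConfig] = None,
    classifier_spec: Optional[ClassifierSpec] = None,
):
    """Build the merit object for one of knn | svm | sam | unmix."""
    cfg = cfg or OptimizationConfig()
    if kind == "unmix":
        if refs is None:
            raise ValueError("unmixing merit needs the chromophore references")
        return UnmixingMerit(
            dataset, refs, folds=cfg.folds, seed=cfg.seed,
            phantom=cfg.phantom if cfg.phantom.endswith("unmix") else "colon_unmix",
            block_size=cfg.block_size or 8, crop_margin=cfg.crop_margin,
        )
    spec = classifier_spec or ClassifierSpec(kind=kind)
    return ClassificationMerit(
        dataset, spec, folds=cfg.folds, seed=cfg.seed, phantom=cfg.phantom,
        block_size=cfg.block_size or 2, crop_margin=cfg.crop_margin,
    )


# ---------------------------------------------------------------------------
# Stage 1: spectral search
# ---------------------------------------------------------------------------

def _canonical_key(fs: FilterSet) -> Tuple:
    return tuple((b.center, b.fwhm) for b in fs)


def random_filterset(
    band_grid: BandGrid, n_bands: int, rng: np.random.Generator,
    distinct_centers: bool = True,
) -> FilterSet:
    centers = rng.choice(band_grid.centers, size=n_bands,
                         replace=not distinct_centers)
    fwhms = rng.choice(band_grid.fwhms, size=n_bands, replace=True)
    return FilterSet(FilterBand(float(c), float(w)) for c, w in zip(centers, fwhms))


def _score(merit, fs: FilterSet, fold: Optional[int] = None) -> float:
    """Merit as a maximization score (errors are negated)."""
    v = merit.spectral(fs, fold=fold)
    return v if merit.sense == "max" else -v


def screen_candidates(
    cfg: OptimizationConfig,
    merit,
    rng_seed: Optional[int] = None,
    screen_fold: Optional[int] = 0,
) -> List[Tuple[FilterSet, float]]:
    """Random screening: draw ``n_screen`` candidate sets, keep the best
    ``n_keep`` (ties broken by canonical band ordering).

    ``screen_fold`` restricts screening to one fold for speed (None uses
    the full fold average); the kept candidates are always re-scored on
    the full fold average.
    """
    rng = np.random.default_rng(cfg.seed if rng_seed is None else rng_seed)
    scored: List[Tuple[float, Tuple, FilterSet]] = []
    seen = set()
    for _ in range(cfg.n_screen):
        fs = random_filterset(cfg.band_grid, cfg.n_bands, rng, cfg.distinct_centers)
        key = _canonical_key(fs)
        if key in seen:
            continue
        seen.add(key)
        try:
            s = _score(merit, fs, fold=screen_fold)
        except Exception as exc:  # pragma: no cover - defensive
            log.warning("candidate %s skipped: %s", fs.describe(), exc)
            continue
        scored.append((s, key, fs))
    scored.sort(key=lambda t: (-t[0], t[1]))
    kept = scored[: cfg.n_keep]
    return [(fs, _score(merit, fs)) for _, _, fs in kept]


def _neighbors(fs: FilterSet, band_grid: BandGrid, distinct_centers: bool
               ) -> List[FilterSet]:
    """Single-band moves: center to the adjacent grid value, FWHM likewise."""
    centers = list(band_grid.centers)
    fwhms = list(band_grid.fwhms)
    out = []
    bands = list(fs)
    for i, b in enumerate(bands):
        ci = centers.index(b.center)
        wi = fwhms.index(b.fwhm)
        moves = []
        if ci > 0:
            moves.append(FilterBand(centers[ci - 1], b.fwhm))
        if ci < len(centers) - 1:
            moves.append(FilterBand(centers[ci + 1], b.fwhm))
        if wi > 0:
            moves.append(FilterBand(b.center, fwhms[wi - 1]))
        if wi < len(fwhms) - 1:
            moves.append(FilterBand(b.center, fwhms[wi + 1]))
        for nb in moves:
            new = bands[:i] + [nb] + bands[i + 1 :]
            if distinct_centers and len({x.center for x in new}) < len(new):
                continue
            out.append(FilterSet(new))
    return out


def refine_descent(
    fs: FilterSet,
    merit,
    cfg: OptimizationConfig,
    trace: Optional[List[Dict]] = None,
) -> Tuple[FilterSet, float]:
    """Best-improvement hill climb on the discrete band grid.

    Returns a set whose merit is >= the input's; stops at a local optimum
    or after ``cfg.max_iterations`` sweeps.
    """
    best = fs
    best_score = _score(merit, fs)
    for it in range(cfg.max_iterations):
        moved = False
        candidates = _neighbors(best, cfg.band_grid, cfg.distinct_centers)
        scores = [(_score(merit, c), _canonical_key(c), c) for c in candidates]
        scores.sort(key=lambda t: (-t[0], t[1]))
        if scores and scores[0][0] > best_score:
            best_score, _, best = scores[0]
            moved = True
            if trace is not None:
                trace.append({"iteration": it, "filterset": best.describe(),
                              "score": best_score})
        if not moved:
            break
    value = best_score if merit.sense == "max" else -best_score
    return best, value


def optimize_spectral(cfg: OptimizationConfig, merit,
                      screen_fold: Optional[int] = 0) -> OptimizationResult:
    """Screen then refine; return the best refined set.

    All refined candidates are kept in the result; their agreement is the
    convergence diagnostic (disagreement suggests local maxima).
    """
    kept = screen_candidates(cfg, merit, screen_fold=screen_fold)
    trace: List[Dict] = []
    refined: List[Tuple[FilterSet, float]] = []
    for fs, _ in kept:
        refined.append(refine_descent(fs, merit, cfg, trace=trace))
    sense = 1 if merit.sense == "max" else -1
    refined.sort(key=lambda t: (-sense * t[1], _canonical_key(t[0])))
    best_fs, best_val = refined[0]
    agree = len({_canonical_key(f) for f, _ in refined}) == 1
    if not agree:
        log.info("refined candidates disagree; descent may have hit local maxima")
    return OptimizationResult(
        filterset=best_fs, layout=None, spectral_merit=best_val,
        refined_candidates=refined, candidates_agree=agree, trace=trace,
    )


# ---------------------------------------------------------------------------
# Stage 2: spatial search
# ---------------------------------------------------------------------------

def optimize_spatial(
    fs: FilterSet, cfg: OptimizationConfig, merit,
    dims: Optional[Tuple[int, int]] = None,
) -> Tuple[MosaicLayout, float, List[float]]:
    """Exhaustive (capped) layout search averaged over folds.

    Returns the best layout, its mean merit, and the per-fold merits of
    that layout.  Classification merits are maximized, unmixing NRMSE
    minimized; ties resolve to the earlier layout in enumeration order.
    """
    layouts = enumerate_layouts(fs, dims=dims, cap=cfg.layout_cap,
                                rng_seed=cfg.seed)
    sense = 1 if merit.sense == "max" else -1
    best = None
    for layout in layouts:
        per_fold = [merit.spatial(fs, layout, f) for f in range(merit.n_folds)]
        mean = float(np.mean(per_fold))
        if best is None or sense * mean > sense * best[1]:
            best = (layout, mean, per_fold)
    return best


def sweep_band_counts(
    cfg: OptimizationConfig,
    merit,
    n_range: Sequence[int] = range(3, 10),
    with_spatial: bool = True,
) -> pd.DataFrame:
    """Run both stages for every band count; one row per n."""
    rows = []
    for n in n_range:
        cfg_n = replace(cfg, n_bands=n)
        spec_res = optimize_spectral(cfg_n, merit)
        row = {
            "n_bands": n,
            "filterset": spec_res.filterset.describe(),
            "spectral_merit": spec_res.spectral_merit,
            "candidates_agree": spec_res.candidates_agree,
        }
        ci = merit.patient_ci(spec_res.filterset)
        row["patient_mean"], row["patient_ci95"] = ci
        if with_spatial:
            layout, mean, per_fold = optimize_spatial(spec_res.filterset, cfg_n, merit)
            row["layout"] = layout.cells.ravel().tolist()
            row["spatial_merit"] = mean
            for f, v in enumerate(per_fold):
                row[f"fold{f}"] = v
            if (merit.sense == "max" and mean > spec_res.spectral_merit) or (
                merit.sense == "min" and mean < spec_res.spectral_merit
            ):
                log.info("n=%d: spatial stage outperformed spectral stage", n)
        rows.append(row)
    return pd.DataFrame(rows)


def hyperspectral_baseline(
    dataset: LabeledSpectraDataset,
    spec: ClassifierSpec,
    fwhm: float = 1.0,
    folds: int = 5,
    seed: int = 0,
) -> float:
    """Full-sampling reference: one band per grid wavelength, fivefold
    classification accuracy; no spatial stage (a hyperspectral system has
    no mosaic)."""
    fs = hyperspectral_filterset(dataset.grid, fwhm)
    merit = ClassificationMerit(dataset, spec, folds=folds, seed=seed)
    return merit.spectral(fs)
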