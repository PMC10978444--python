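import itertools

import numpy as np
import pytest

import msfa_design as m
from msfa_design.filters import BandGrid, FilterBand, FilterSet
from msfa_design.merit_classify import ClassifierSpec
from msfa_design.optimize import (
    ClassificationMerit,
    OptimizationConfig,
    UnmixingMerit,
    random_filterset,
    refine_descent,
    screen_candidates,
    optimize_spectral,
    optimize_spatial,
    sweep_band_counts,
    hyperspectral_baseline,
)
from tests.conftest import make_flat_class_dataset


class StubMerit:
    """Deterministic analytic merit for exercising the search machinery."""

    sense = "max"

    def __init__(self, fn):
        self.fn = fn
        self.n_folds = 2

    def spectral(self, fs, fold=None):
        return self.fn(fs)


def brute_force_best(band_grid, n_bands, merit_fn):
    best = None
    for centers in itertools.combinations(band_grid.centers, n_bands):
        for fwhms in itertools.product(band_grid.fwhms, repeat=n_bands):
            fs = FilterSet(FilterBand(float(c), float(w))
                           for c, w in zip(centers, fwhms))
            s = merit_fn(fs)
            if best is None or s > best[0]:
                best = (s, fs)
    return best


class TestScreening:
    def test_returns_exactly_n_keep(self):
        merit = StubMerit(lambda fs: -abs(fs[0].center - 550))
        cfg = OptimizationConfig(n_bands=2, n_screen=100, n_keep=5, seed=0)
        kept = screen_candidates(cfg, merit)
        assert len(kept) == 5
        scores = [s for _, s in kept]
        assert scores == sorted(scores, reverse=True)

    def test_single_candidate_degenerate(self):
        merit = StubMerit(lambda fs: 1.0)
        cfg = OptimizationConfig(n_bands=3, n_screen=1, n_keep=1, seed=0)
        kept = screen_candidates(cfg, merit)
        assert len(kept) == 1

    def test_seed_determinism(self):
        merit = StubMerit(lambda fs: sum(b.center for b in fs))
        cfg = OptimizationConfig(n_bands=3, n_screen=50, n_keep=3, seed=7)
        a = screen_candidates(cfg, merit)
        b = screen_candidates(cfg, merit)
        assert [f.describe() for f, _ in a] == [f.describe() for f, _ in b]

    def test_distinct_centers_enforced(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            fs = random_filterset(BandGrid(), 5, rng, distinct_centers=True)
            assert len({b.center for b in fs}) == 5

    def test_grid_closure(self):
        merit = StubMerit(lambda fs: 0.0)
        cfg = OptimizationConfig(n_bands=4, n_screen=30, n_keep=5, seed=1)
        grid = cfg.band_grid
        for fs, _ in screen_candidates(cfg, merit):
            assert all(grid.contains(b) for b in fs)


class TestRefinement:
    def test_unimodal_merit_converges_to_peak(self):
        merit = StubMerit(lambda fs: -abs(fs[0].center - 600))
        cfg = OptimizationConfig(n_bands=1, n_screen=1, n_keep=1, seed=0)
        start = FilterSet([FilterBand(590.0, 20.0)])
        best, val = refine_descent(start, merit, cfg)
        assert best[0].center == 600.0
        assert val == 0.0

    def test_local_optimum_is_a_fixed_point(self):
        merit = StubMerit(lambda fs: -abs(fs[0].center - 600))
        cfg = OptimizationConfig(n_bands=1, n_screen=1, n_keep=1, seed=0)
        start = FilterSet([FilterBand(600.0, 20.0)])
        best, _ = refine_descent(start, merit, cfg)
        assert best == start

    def test_trace_is_monotone(self):
        merit = StubMerit(lambda fs: -abs(fs[0].center - 650) - 0.1 * abs(fs[0].fwhm - 30))
        cfg = OptimizationConfig(n_bands=1, n_screen=1, n_keep=1, seed=0)
        trace = []
        refine_descent(FilterSet([FilterBand(620.0, 10.0)]), merit, cfg, trace=trace)
        scores = [t["score"] for t in trace]
        assert scores == sorted(scores)
        assert len(scores) > 0

    def test_refined_never_worse_than_screened(self, small_dataset):
        merit = ClassificationMerit(small_dataset, ClassifierSpec("knn"), seed=0)
        cfg = OptimizationConfig(n_bands=3, n_screen=10, n_keep=3, seed=0,
                                 max_iterations=3)
        for fs, score in screen_candidates(cfg, merit):
            _, refined_score = refine_descent(fs, merit, cfg)
            assert refined_score >= score - 1e-12

    def test_remains_on_grid(self):
        merit = StubMerit(lambda fs: fs[0].center + fs[0].fwhm)
        cfg = OptimizationConfig(n_bands=1, n_screen=1, n_keep=1, seed=0)
        best, _ = refine_descent(FilterSet([FilterBand(695.0, 26.0)]), merit, cfg)
        assert best[0].center == 700.0 and best[0].fwhm == 30.0
        assert cfg.band_grid.contains(best[0])


class TestOptimizeSpectral:
    def test_tiny_grid_matches_exhaustive_search(self):
        """With the screen covering the whole (small) space the two-stage
        search must equal brute force."""
        grid = BandGrid(centers=(500.0, 560.0, 620.0), fwhms=(20.0,))
        fn = lambda fs: -(abs(fs[0].center - 500) + abs(fs[-1].center - 620))
        merit = StubMerit(fn)
        cfg = OptimizationConfig(n_bands=2, band_grid=grid, n_screen=200,
                                 n_keep=3, seed=0)
        res = optimize_spectral(cfg, merit)
        _, brute = brute_force_best(grid, 2, fn)
        assert res.filterset == brute
        assert res.spectral_merit == fn(brute)

    def test_end_to_end_seed_determinism(self, small_dataset):
        merit = ClassificationMerit(small_dataset, ClassifierSpec("knn"), seed=3)
        cfg = OptimizationConfig(n_bands=3, n_screen=15, n_keep=2, seed=3,
                                 max_iterations=2)
        a = optimize_spectral(cfg, merit)
        b = optimize_spectral(cfg, merit)
        assert a.filterset == b.filterset
        assert a.spectral_merit == b.spectral_merit

    def test_reports_all_refined_candidates(self, small_dataset):
        merit = ClassificationMerit(small_dataset, ClassifierSpec("knn"), seed=0)
        cfg = OptimizationConfig(n_bands=3, n_screen=8, n_keep=4, seed=0,
                                 max_iterations=1)
        res = optimize_spectral(cfg, merit)
        assert len(res.refined_candidates) == 4
        assert res.candidates_agree in (True, False)


class TestOptimizeSpatial:
    def test_single_band_is_trivial(self, flat_dataset):
        merit = ClassificationMerit(flat_dataset, ClassifierSpec("knn"),
                                    folds=2, seed=0)
        fs1 = FilterSet([FilterBand(550.0, 20.0)])
        cfg = OptimizationConfig(n_bands=1, n_screen=1, n_keep=1, seed=0, folds=2)
        layout, mean, per_fold = optimize_spatial(fs1, cfg, merit, dims=(1, 1))
        assert layout.cells.tolist() == [[0]]
        assert mean == pytest.approx(np.mean(per_fold))

    def test_reported_merit_is_fold_mean(self, small_dataset, fs3):
        merit = ClassificationMerit(small_dataset, ClassifierSpec("knn"),
                                    folds=2, seed=1)
        cfg = OptimizationConfig(n_bands=3, n_screen=1, n_keep=1, seed=1,
                                 folds=2, layout_cap=3)
        layout, mean, per_fold = optimize_spatial(fs3, cfg, merit)
        recomputed = [merit.spatial(fs3, layout, f) for f in range(2)]
        assert per_fold == recomputed
        assert mean == pytest.approx(np.mean(recomputed))


class TestSweepAndBaseline:
    def test_single_n_sweep_schema(self, small_dataset):
        merit = ClassificationMerit(small_dataset, ClassifierSpec("knn"), seed=0)
        cfg = OptimizationConfig(n_bands=3, n_screen=5, n_keep=1, seed=0,
                                 max_iterations=1)
        table = sweep_band_counts(cfg, merit, n_range=[3], with_spatial=False)
        assert len(table) == 1
        assert {"n_bands", "filterset", "spectral_merit",
                "patient_mean", "patient_ci95"} <= set(table.columns)

    def test_multi_n_rows(self, small_dataset):
        merit = ClassificationMerit(small_dataset, ClassifierSpec("knn"), seed=0)
        cfg = OptimizationConfig(n_bands=3, n_screen=3, n_keep=1, seed=0,
                                 max_iterations=0)
        table = sweep_band_counts(cfg, merit, n_range=[3, 4], with_spatial=False)
        assert list(table["n_bands"]) == [3, 4]

    def test_baseline_is_perfect_on_separable_classes(self, flat_dataset):
        acc = hyperspectral_baseline(flat_dataset, ClassifierSpec("knn"),
                                     fwhm=2.0, seed=0)
        assert acc == 1.0

    def test_baseline_not_worse_than_single_band(self, flat_dataset):
        """The 251-band feature superset cannot lose to one band on
        noiseless separable classes (kNN)."""
        merit = ClassificationMerit(flat_dataset, ClassifierSpec("knn"), seed=0)
        single = merit.spectral(FilterSet([FilterBand(550.0, 20.0)]))
        full = hyperspectral_baseline(flat_dataset, ClassifierSpec("knn"), seed=0)
        assert full >= single - 1e-12

    def test_baseline_is_scalar(self, flat_dataset):
        acc = hyperspectral_baseline(flat_dataset, ClassifierSpec("sam"), seed=0)
        assert isinstance(acc, float) and 0.0 <= acc <= 1.0


class TestConfigValidation:
    def test_n_keep_le_n_screen(self):
        with pytest.raises(ValueError):
            OptimizationConfig(n_screen=2, n_keep=5)

    def test_fold_minimum(self):
        with pytest.raises(ValueError):
            OptimizationConfig(folds=1)


def test_unmixing_merit_prefers_more_bands(small_colon_dataset, refs):
    um = UnmixingMerit(small_colon_dataset, refs, seed=0)
    fs3 = FilterSet([FilterBand(510.0, 10.0), FilterBand(558.0, 18.0),
                     FilterBand(618.0, 30.0)])
    fs9 = FilterSet([FilterBand(float(c), 20.0) for c in range(480, 705, 28)])
    assert um.spectral(fs9) < um.spectral(fs3)
    assert um.sense == "min"
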