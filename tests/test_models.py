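"""Surface-range envelopes, pseudo-absence sampling, the BIOCLIM
percentile score, and the five-learner contract."""

import numpy as np
import pytest

from ensemblesdm.geo import GridSpec, RasterLayer, RasterStack, point_to_cell
from ensemblesdm.models import (
    ALGORITHMS,
    ModelSpec,
    PseudoAbsenceScheme,
    bioclim_score,
    build_sre_envelope,
    default_model_specs,
    fit_suitability_model,
    sample_pseudo_absences,
)
from ensemblesdm.occurrences import CalibrationRegion, OccurrenceSet


class TestSreEnvelope:
    def test_zero_tail_uses_min_max(self, rng):
        X = rng.normal(size=(50, 3))
        env = build_sre_envelope(X, q=0.0)
        assert np.allclose(env.lower, X.min(axis=0))
        assert np.allclose(env.upper, X.max(axis=0))
        assert env.inside(X).all()

    def test_quantile_bounds_linear_interpolation(self):
        X = np.arange(1.0, 101.0)[:, None]
        env = build_sre_envelope(X, q=0.025)
        # order-statistic oracle: position 1 + 0.025 * 99 = 3.475
        assert env.lower[0] == pytest.approx(3.475)
        assert env.upper[0] == pytest.approx(97.525)

    def test_outside_on_any_single_layer_is_outside(self):
        X = np.tile(np.linspace(0, 1, 10)[:, None], (1, 3))
        env = build_sre_envelope(X, q=0.0)
        point = np.array([[0.5, 0.5, 2.0]])
        assert not env.inside(point)[0]

    def test_half_tail_rejected(self):
        with pytest.raises(ValueError):
            build_sre_envelope(np.zeros((5, 2)), q=0.5)


class TestPseudoAbsences:
    @pytest.fixture()
    def setting(self, tiny_world):
        scen, species, occ = tiny_world
        grid = scen.current.grid
        region = CalibrationRegion(grid, np.ones(grid.shape, dtype=bool), 1.0)
        return scen.current, region, occ

    def test_zero_n_gives_empty_draw(self, setting):
        stack, region, occ = setting
        lon, lat = sample_pseudo_absences(
            PseudoAbsenceScheme("random", 0), region, stack, occ
        )
        assert lon.size == 0

    def test_presence_cells_never_selected(self, setting):
        stack, region, occ = setting
        lon, lat = sample_pseudo_absences(
            PseudoAbsenceScheme("random", 200, seed=4), region, stack, occ
        )
        pres = set(zip(*point_to_cell(stack.grid, occ.lon, occ.lat)))
        drawn = set(zip(*point_to_cell(stack.grid, lon, lat)))
        assert pres.isdisjoint(drawn)
        assert len(drawn) == 200  # distinct cells

    def test_outside_sre_draws_fail_the_envelope(self, setting):
        stack, region, occ = setting
        scheme = PseudoAbsenceScheme("random_outside_sre", 100, sre_quantile=0.025, seed=4)
        lon, lat = sample_pseudo_absences(scheme, region, stack, occ)
        env = build_sre_envelope(stack.extract(occ.lon, occ.lat), 0.025)
        assert not env.inside(stack.extract(lon, lat)).any()

    def test_deficit_raises_with_count(self, setting):
        stack, region, occ = setting
        n_cells = stack.grid.n_rows * stack.grid.n_cols
        with pytest.raises(ValueError, match="deficit"):
            sample_pseudo_absences(
                PseudoAbsenceScheme("random", n_cells), region, stack, occ
            )

    def test_default_specs_pair_schemes_with_algorithms(self):
        specs = {s.algorithm: s.scheme for s in default_model_specs(224)}
        assert specs["maxent_like"].n == 1000 and specs["maxent_like"].mode == "random"
        assert specs["regression_splines"].n == 100
        assert specs["discriminant"].mode == "random_outside_sre"
        assert specs["bagged_trees"].n == 224  # matches the presence count
        assert specs["bagged_trees"].mode == "random_outside_sre"
        assert specs["bioclim_envelope"].n == 100


class TestBioclimScore:
    def test_midpoint_rank_percentile(self):
        train = np.arange(1.0, 10.0)[:, None]  # 1..9
        score = bioclim_score(train, np.array([[3.0]]))
        # p = rank 3 of 9 = 1/3 -> score = 1 - 2|1/3 - 1/2| = 2/3
        assert score[0] == pytest.approx(2.0 / 3.0)

    def test_zero_strictly_outside_observed_range(self):
        train = np.arange(1.0, 10.0)[:, None]
        assert bioclim_score(train, np.array([[0.5]]))[0] == 0.0
        assert bioclim_score(train, np.array([[9.5]]))[0] == 0.0

    def test_minimum_over_layers(self):
        train = np.column_stack([np.arange(1.0, 10.0), np.arange(1.0, 10.0)])
        point = np.array([[5.0, 3.0]])  # central on layer 1, off-center on layer 2
        both = bioclim_score(train, point)[0]
        only2 = bioclim_score(train[:, 1:], point[:, 1:])[0]
        assert both == pytest.approx(only2)

    def test_symmetric_maximum_near_center(self, rng):
        train = rng.normal(size=(200, 1))
        x = np.linspace(train.min(), train.max(), 101)[:, None]
        s = bioclim_score(train, x)
        center = np.median(train)
        # the empirical mode of the score profile sits near the median
        assert abs(x[np.argmax(s), 0] - center) < np.std(train) / 2


@pytest.fixture(scope="module")
def training(tiny_world):
    scen, species, occ = tiny_world
    stack = scen.current
    grid = stack.grid
    pres_env = stack.extract(occ.lon, occ.lat)
    rng = np.random.default_rng(0)
    bg_idx = rng.choice(grid.n_rows * grid.n_cols, 300, replace=False)
    r, c = np.unravel_index(bg_idx, grid.shape)
    bg_env = np.column_stack([lyr.values[r, c] for lyr in stack.layers])
    return pres_env, bg_env


class TestSuitabilityModels:
    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_presences_score_above_background(self, algorithm, training):
        pres_env, bg_env = training
        spec = ModelSpec(algorithm, PseudoAbsenceScheme("random", len(bg_env)))
        train_p, test_p = pres_env[::2], pres_env[1::2]
        model = fit_suitability_model(spec, train_p, bg_env, seed=3)
        s_pres = model.predict(test_p)
        s_bg = model.predict(bg_env)
        assert np.all((s_pres >= 0) & (s_pres <= 1))
        assert s_pres.mean() > s_bg.mean()

    @pytest.mark.parametrize("algorithm", ALGORITHMS)
    def test_refit_is_deterministic(self, algorithm, training):
        pres_env, bg_env = training
        spec = ModelSpec(algorithm, PseudoAbsenceScheme("random", len(bg_env)))
        m1 = fit_suitability_model(spec, pres_env, bg_env, seed=3)
        m2 = fit_suitability_model(spec, pres_env, bg_env, seed=3)
        X = np.vstack([pres_env, bg_env])
        assert np.array_equal(m1.predict(X), m2.predict(X))

    def test_constant_layers_give_constant_predictions(self):
        pres = np.full((20, 2), 1.0) + np.random.default_rng(0).normal(0, 1e-9, (20, 2))
        bg = np.full((20, 2), 1.0) + np.random.default_rng(1).normal(0, 1e-9, (20, 2))
        spec = ModelSpec("bagged_trees", PseudoAbsenceScheme("random", 20))
        model = fit_suitability_model(spec, pres, bg, seed=0)
        out = model.predict(np.full((5, 2), 1.0))
        assert np.allclose(out, out[0])

    def test_single_class_training_rejected(self):
        pres = np.random.default_rng(0).normal(size=(20, 2))
        spec = ModelSpec("maxent_like", PseudoAbsenceScheme("random", 0))
        with pytest.raises(ValueError):
            fit_suitability_model(spec, pres, np.empty((0, 2)), seed=0)
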