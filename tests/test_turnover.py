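"""Gradient-forest turnover functions, pruning and the raster transform."""

import numpy as np
import pytest

from landgen.genio import EnvTable, RasterStack
from landgen.turnover import (
    TurnoverModel,
    fit_gradient_forest,
    prune_variables,
    transform_env,
)

from oracles import greedy_prune


def _env(values):
    values = np.asarray(values, dtype=float)
    names = [f"v{i}" for i in range(values.shape[1])]
    return EnvTable(
        pops=np.array([f"P{i}" for i in range(values.shape[0])], dtype=object),
        variables=np.array(names, dtype=object),
        classes={n: "bioclim" for n in names},
        values=values,
    )


def _step_model(seed=1, c=0.45, n_trees=100):
    """Forests fitted to noiseless step functions of one predictor whose
    training values sit on a coarse replicated grid, so split thresholds
    are resolution-stable under bootstrap resampling."""
    rng = np.random.default_rng(seed)
    x = np.repeat(np.linspace(0, 1, 11), 3)[:, None]
    y = np.column_stack([
        (x[:, 0] > c).astype(float) * 0.6
        + 0.2
        + 0.001 * rng.standard_normal(len(x))
        for _ in range(8)
    ])
    return fit_gradient_forest(y, _env(x), n_trees=n_trees, seed=seed)


class TestFit:
    def test_step_function_concentrates_turnover(self):
        """>= 80 % of the cumulative rise sits within one bin of the step."""
        c = 0.45
        model = _step_model(c=c)
        p = model.predictors[0]
        edges, cum = model.bin_edges[p], model.cumulative[p]
        width = edges[1] - edges[0]
        lo = model.transform_values(p, np.array([c - width]))[0]
        hi = model.transform_values(p, np.array([c + width]))[0]
        assert (hi - lo) >= 0.8 * cum[-1]

    def test_irrelevant_predictor_low_importance(self):
        rng = np.random.default_rng(1)
        ratios = []
        for rep in range(5):
            x = np.column_stack([
                np.linspace(0, 1, 25), rng.standard_normal(25)
            ])
            y = np.column_stack([
                x[:, 0] * 0.5 + 0.02 * rng.standard_normal(25) for _ in range(6)
            ])
            m = fit_gradient_forest(y, _env(x), n_trees=60, seed=rep)
            imps = [m.importance[p] for p in m.predictors]
            ratios.append(imps[1] / max(imps[0], 1e-12))
        assert np.mean(ratios) < 0.05

    def test_deterministic_under_seed(self):
        m1 = _step_model(seed=7)
        m2 = _step_model(seed=7)
        p = m1.predictors[0]
        np.testing.assert_array_equal(m1.cumulative[p], m2.cumulative[p])
        assert m1.importance == m2.importance

    def test_no_predictable_locus_raises(self):
        rng = np.random.default_rng(3)
        y = np.full((20, 3), 0.5)          # constant loci carry no signal
        x = rng.standard_normal((20, 2))
        with pytest.raises(ValueError, match="turnover"):
            fit_gradient_forest(y, _env(x), n_trees=30, seed=1)

    def test_conservation_total_turnover_equals_importance(self):
        model = _step_model()
        for p in model.predictors:
            assert model.cumulative[p][-1] == pytest.approx(
                model.importance[p], rel=1e-9
            )


class TestPrune:
    def test_identical_variables_lower_importance_dropped(self):
        x = np.random.default_rng(1).standard_normal(20)
        env = _env(np.column_stack([x, x]))
        out = prune_variables(env, {"v0": 1.0, "v1": 0.5}, r_max=0.75)
        assert list(out.variables) == ["v0"]

    def test_uncorrelated_table_unchanged(self):
        rng = np.random.default_rng(2)
        env = _env(rng.standard_normal((50, 4)))
        out = prune_variables(env, {f"v{i}": 1.0 for i in range(4)}, 0.75)
        assert list(out.variables) == list(env.variables)

    def test_chain_matches_greedy_oracle(self):
        rng = np.random.default_rng(3)
        base = rng.standard_normal(40)
        vals = np.column_stack([
            base + 0.2 * rng.standard_normal(40),
            base + 0.2 * rng.standard_normal(40),
            base + 0.2 * rng.standard_normal(40),
            rng.standard_normal(40),
            rng.standard_normal(40),
        ])
        env = _env(vals)
        imp = {"v0": 5.0, "v1": 4.0, "v2": 3.0, "v3": 2.0, "v4": 1.0}
        out = prune_variables(env, imp, 0.75)
        expect = greedy_prune(vals, list(env.variables), imp, 0.75)
        assert list(out.variables) == expect


class TestTransform:
    def _stack(self, model, values):
        values = np.asarray(values, dtype=float)
        return RasterStack(
            names=model.predictors,
            data=values[None].repeat(len(model.predictors), axis=0),
            mask=np.zeros(values.shape, dtype=bool),
            xll=0, yll=0, cell=1.0,
        )

    def test_training_minimum_maps_to_zero(self):
        model = _step_model()
        p = model.predictors[0]
        lo = model.bin_edges[p][0]
        assert model.transform_values(p, np.array([lo]))[0] == 0.0

    def test_clamping_above_training_range(self):
        model = _step_model()
        p = model.predictors[0]
        hi = model.bin_edges[p][-1]
        at_max = model.transform_values(p, np.array([hi]))[0]
        beyond = model.transform_values(p, np.array([hi + 100]))[0]
        assert beyond == at_max == pytest.approx(model.importance[p], rel=1e-9)

    def test_monotone_in_raw_values(self):
        model = _step_model()
        p = model.predictors[0]
        v = np.linspace(-0.5, 1.5, 200)
        f = model.transform_values(p, v)
        assert np.all(np.diff(f) >= -1e-12)

    def test_transform_commutes_with_cropping(self):
        model = _step_model()
        grid = np.linspace(0, 1, 24).reshape(4, 6)
        full = transform_env(model, self._stack(model, grid))
        crop_then = transform_env(model, self._stack(model, grid[:2, :3]))
        np.testing.assert_allclose(
            full.data[:, :2, :3], crop_then.data, atol=1e-12
        )

    def test_missing_predictor_rejected(self):
        model = _step_model()
        stack = self._stack(model, np.zeros((2, 2)))
        stack.names = ["nope"]
        with pytest.raises(ValueError, match="nope"):
            transform_env(model, stack)

    def test_json_round_trip(self, tmp_path):
        model = _step_model()
        model.to_json(tmp_path / "m.json")
        back = TurnoverModel.from_json(tmp_path / "m.json")
        p = model.predictors[0]
        np.testing.assert_allclose(back.cumulative[p], model.cumulative[p])
        assert back.importance == model.importance
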