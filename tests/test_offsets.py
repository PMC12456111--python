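"""Offset surfaces against exhaustive oracles, and RONA closed forms."""

import numpy as np
import pandas as pd
import pytest

from landgen.genio import EnvTable, RasterStack
from landgen.gea import GeaResult  # noqa: F401  (duck-typed core view below)
from landgen.offsets import (
    forward_offsets,
    local_offset,
    offset_surface,
    reverse_offset,
    rgb_composite,
    rona,
)
from landgen.popstats import AlleleFreqTable
from landgen.spatial import haversine_km
from landgen.turnover import TurnoverModel

from oracles import forward_offset_brute, reverse_offset_brute


def _identity_model(names, lo=0.0, hi=1.0):
    """Turnover model whose F is the identity on [lo, hi] per predictor."""
    edges = np.linspace(lo, hi, 202)
    cum = edges - lo
    return TurnoverModel(
        predictors=list(names),
        bin_edges={n: edges.copy() for n in names},
        cumulative={n: cum.copy() for n in names},
        importance={n: hi - lo for n in names},
        locus_r2={}, n_trees=0, seed=0,
    )


def _stack(names, layers, epoch="current", cell=1.0):
    data = np.stack([np.asarray(l, dtype=float) for l in layers])
    return RasterStack(
        names=list(names), data=data,
        mask=np.zeros(data.shape[1:], dtype=bool),
        xll=100.0, yll=30.0, cell=cell, epoch=epoch,
    )


class TestLocalOffset:
    def test_future_equals_current_zero(self):
        rng = np.random.default_rng(1)
        g = rng.uniform(0, 1, (4, 5))
        model = _identity_model(["a"])
        cur = _stack(["a"], [g])
        fut = _stack(["a"], [g], epoch="SSP585_2041_2060")
        assert np.nanmax(local_offset(model, cur, fut)) == 0.0

    def test_single_predictor_absolute_difference(self):
        model = _identity_model(["a"])
        cur = _stack(["a"], [[[0.2, 0.4]]])
        fut = _stack(["a"], [[[0.5, 0.1]]], epoch="SSP126_2041_2060")
        off = local_offset(model, cur, fut)
        np.testing.assert_allclose(off, [[0.3, 0.3]], atol=1e-12)

    def test_predictor_order_invariance(self):
        rng = np.random.default_rng(2)
        names = ["a", "b", "c"]
        cur_layers = [rng.uniform(0, 1, (3, 3)) for _ in names]
        fut_layers = [rng.uniform(0, 1, (3, 3)) for _ in names]
        model = _identity_model(names)
        o1 = local_offset(
            model, _stack(names, cur_layers),
            _stack(names, fut_layers, "SSP126_2041_2060"),
        )
        order = [2, 0, 1]
        o2 = local_offset(
            model,
            _stack([names[i] for i in order], [cur_layers[i] for i in order]),
            _stack([names[i] for i in order], [fut_layers[i] for i in order],
                   "SSP126_2041_2060"),
        )
        np.testing.assert_allclose(o1, o2, atol=1e-12)


class TestForwardReverse:
    def _toy(self, seed=1):
        rng = np.random.default_rng(seed)
        names = ["a", "b"]
        cur = _stack(names, [rng.uniform(0, 1, (3, 3)) for _ in names])
        fut = _stack(
            names, [rng.uniform(0, 1, (3, 3)) for _ in names],
            epoch="SSP585_2061_2080",
        )
        return _identity_model(names), cur, fut

    def test_monotone_in_radius(self):
        model, cur, fut = self._toy()
        offs = forward_offsets(model, cur, fut,
                               (50.0, 100.0, 200.0, 500.0, np.inf))
        loc = local_offset(model, cur, fut)
        prev = loc
        for r in (50.0, 100.0, 200.0, 500.0, np.inf):
            assert np.all(offs[r] <= prev + 1e-12)
            prev = offs[r]

    def test_unlimited_radius_future_equals_current_zero(self):
        model, cur, _ = self._toy()
        same = _stack(cur.names, list(cur.data), epoch="SSP126_2061_2080")
        offs = forward_offsets(model, cur, same, (np.inf,))
        assert np.nanmax(offs[np.inf]) == 0.0

    def test_matches_brute_force_oracle(self):
        model, cur, fut = self._toy()
        lat, lon = cur.cell_centres()
        la, lo = lat.ravel(), lon.ravel()
        geo = haversine_km(la[:, None], lo[:, None], la[None, :], lo[None, :])
        comp_cur = np.stack(
            [model.transform_values(n, cur.layer(n)).ravel() for n in cur.names]
        ).T
        comp_fut = np.stack(
            [model.transform_values(n, fut.layer(n)).ravel() for n in fut.names]
        ).T
        for r in (150.0, 400.0, np.inf):
            got = forward_offsets(model, cur, fut, (r,))[r].ravel()
            expect = forward_offset_brute(comp_cur, comp_fut, geo, r)
            np.testing.assert_allclose(got, expect, atol=1e-12)
        got_rev = reverse_offset(model, cur, fut).ravel()
        np.testing.assert_allclose(
            got_rev, reverse_offset_brute(comp_cur, comp_fut), atol=1e-12
        )

    def test_reverse_zero_when_any_current_cell_matches(self):
        model, cur, fut = self._toy()
        fut.data[:, 1, 1] = cur.data[:, 0, 2]
        rev = reverse_offset(model, cur, fut)
        assert rev[1, 1] == pytest.approx(0.0, abs=1e-12)


class TestRgb:
    def test_all_zero_black(self):
        z = np.zeros((3, 3))
        with pytest.warns(UserWarning, match="constant"):
            rgb, meta = rgb_composite(z, z, z)
        assert rgb.sum() == 0

    def test_max_cell_saturates_red(self):
        rng = np.random.default_rng(1)
        loc = rng.uniform(0, 1, (4, 4))
        rgb, _ = rgb_composite(loc, loc * 0.5, loc * 0.2)
        i, j = np.unravel_index(np.argmax(loc), loc.shape)
        assert rgb[0, i, j] == 255

    def test_metadata_inverts_within_quantisation(self):
        rng = np.random.default_rng(2)
        grids = [rng.uniform(0, 2, (5, 5)) for _ in range(3)]
        rgb, meta = rgb_composite(*grids)
        for band, grid, bounds in zip(rgb, grids, meta["bounds"]):
            lo, hi = bounds["min"], bounds["max"]
            back = band / 255.0 * (hi - lo) + lo
            assert np.abs(back - grid).max() <= (hi - lo) / 255 / 2 + 1e-12


class _CoreView:
    def __init__(self, ids, var_map):
        self.core_ids = ids
        self.variables_of_core = var_map


def _freqs(p):
    p = np.asarray(p, dtype=float)
    return AlleleFreqTable(
        pops=np.array([f"P{i}" for i in range(p.shape[0])], dtype=object),
        locus_ids=[f"l{j}" for j in range(p.shape[1])],
        p=p, n=np.full(p.shape, 20.0),
    )


def _env1(x, name="v"):
    return EnvTable(
        pops=np.array([f"P{i}" for i in range(len(x))], dtype=object),
        variables=np.array([name], dtype=object),
        classes={name: "bioclim"},
        values=np.asarray(x, dtype=float)[:, None],
    )


class TestRona:
    def test_exact_linear_closed_form(self):
        """p = a*v + b and a uniform shift d give RONA = |a| * d."""
        n = 12
        v = np.linspace(0, 1, n)
        a, b, d = 0.4, 0.1, 0.25
        p = a * v + b
        core = _CoreView(["l0"], {"l0": ["v"]})
        table = rona(_freqs(p[:, None]), core, _env1(v), _env1(v + d))
        np.testing.assert_allclose(table.summary["rona"], abs(a) * d, atol=1e-10)

    def test_zero_shift_zero_rona(self):
        n = 10
        v = np.linspace(0, 1, n)
        p = 0.3 * v + 0.2
        core = _CoreView(["l0"], {"l0": ["v"]})
        table = rona(_freqs(p[:, None]), core, _env1(v), _env1(v))
        np.testing.assert_allclose(table.summary["rona"], 0.0, atol=1e-12)

    def test_doubling_shift_doubles_rona(self):
        n = 10
        v = np.linspace(0, 1, n)
        p = 0.5 * v + 0.1
        core = _CoreView(["l0"], {"l0": ["v"]})
        t1 = rona(_freqs(p[:, None]), core, _env1(v), _env1(v + 0.1))
        t2 = rona(_freqs(p[:, None]), core, _env1(v), _env1(v + 0.2))
        np.testing.assert_allclose(
            2 * t1.summary["rona"].to_numpy(), t2.summary["rona"].to_numpy(),
            atol=1e-10,
        )

    def test_nonsignificant_slope_dropped_with_warning(self):
        rng = np.random.default_rng(1)
        v = np.linspace(0, 1, 10)
        p = rng.uniform(0.4, 0.6, 10)      # no relationship
        core = _CoreView(["l0"], {"l0": ["v"]})
        with pytest.warns(UserWarning, match="no loci"):
            table = rona(_freqs(p[:, None]), core, _env1(v), _env1(v + 0.3))
        assert table.summary.empty


def test_offset_surface_invariant_chain(small_dataset):
    """local >= forward(radii...) >= forward(inf) and reverse >= 0 on a
    synthetic landscape with a fitted-model-free identity transform."""
    scape = small_dataset.landscape
    names = scape.current.names[:4]
    lo = float(min(scape.current.select(names).data.min(),
                   scape.futures["SSP585_2061_2080"].select(names).data.min()))
    hi = float(max(scape.current.select(names).data.max(),
                   scape.futures["SSP585_2061_2080"].select(names).data.max()))
    model = _identity_model(names, lo, hi)
    surf = offset_surface(
        model, scape.current.select(names),
        scape.futures["SSP585_2061_2080"].select(names),
        radii_km=(100.0, 500.0, np.inf),
    )
    valid = np.isfinite(surf.local)
    prev = surf.local
    for r in (100.0, 500.0, np.inf):
        assert np.all(surf.forward[r][valid] <= prev[valid] + 1e-9)
        prev = surf.forward[r]
    assert np.all(surf.reverse[valid] >= 0)
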