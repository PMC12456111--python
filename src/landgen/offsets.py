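"""Genomic-vulnerability surfaces: local, forward and reverse offsets,
RGB composites and the risk of non-adaptedness (RONA).

Offsets are Euclidean distances in turnover-transformed ("genetic
composition") space. The local offset compares each cell's current and
future compositions in place; the forward offset takes, per cell, the
minimum offset achievable by migrating to any cell within a great-circle
radius (50/100/200/500 km or unlimited); the reverse offset asks how close
a cell's future climate is to the composition of the best current cell
anywhere. RONA regresses each climate-associated locus's frequencies on its
driver variable and averages the absolute predicted frequency change,
weighted by regression R-squared.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import linregress

from .genio import EnvTable, RasterStack
from .gea import GeaResult
from .popstats import AlleleFreqTable
from .spatial import haversine_km
from .turnover import TurnoverModel, transform_env

logger = logging.getLogger("landgen")


def _compositions(
    model: TurnoverModel, stack: RasterStack, valid: np.ndarray | None = None
):
    """(valid_index, composition matrix) for the unmasked cells."""
    comp = transform_env(model, stack)
    if valid is None:
        valid = ~stack.mask
    mat = comp.data[:, valid].T        # (n_valid, P)
    return valid, mat


def _check_aligned(a: RasterStack, b: RasterStack) -> RasterStack:
    """Validate variables and return ``b`` on the grid of ``a``, bilinearly
    resampling a coarser future stack when needed."""
    from .genio import resample_bilinear

    if a.names != b.names:
        raise ValueError("epoch stacks expose different variables")
    return resample_bilinear(b, a)


def local_offset(
    model: TurnoverModel, current: RasterStack, future: RasterStack
) -> np.ndarray:
    """Per-cell Euclidean distance between current and future composition;
    masked cells are NaN."""
    future = _check_aligned(current, future)
    valid = ~(current.mask | future.mask)
    _, cur = _compositions(model, current, valid)
    _, fut = _compositions(model, future, valid)
    out = np.full(current.shape, np.nan)
    out[valid] = np.sqrt(((cur - fut) ** 2).sum(axis=1))
    return out


def forward_offsets(
    model: TurnoverModel,
    current: RasterStack,
    future: RasterStack,
    radii_km: tuple[float, ...] = (50.0, 100.0, 200.0, 500.0, float("inf")),
) -> dict[float, np.ndarray]:
    """Forward offset grids for each migration radius.

    Per cell i: min over cells j within the radius (j includes i) of the
    distance between current composition at i and future composition at j.
    """
    future = _check_aligned(current, future)
    valid = ~(current.mask | future.mask)
    _, cur = _compositions(model, current, valid)
    _, fut = _compositions(model, future, valid)
    lat, lon = current.cell_centres()
    la, lo = lat[valid], lon[valid]
    geo = haversine_km(la[:, None], lo[:, None], la[None, :], lo[None, :])
    comp_d = cdist(cur, fut)
    out: dict[float, np.ndarray] = {}
    for r in radii_km:
        if r <= 0:
            raise ValueError("migration radius must be positive")
        if not np.isinf(r) and r < current.cell * 111.32:
            # below the N-S cell spacing; self always remains reachable
            warnings.warn(
                f"radius {r} km may be below the cell spacing; forward offset "
                "reduces to the local offset where no neighbour is in range"
            )
        allowed = geo <= r if not np.isinf(r) else np.ones_like(geo, dtype=bool)
        np.fill_diagonal(allowed, True)
        masked = np.where(allowed, comp_d, np.inf)
        grid = np.full(current.shape, np.nan)
        grid[valid] = masked.min(axis=1)
        out[r] = grid
    return out


def forward_offset(
    model: TurnoverModel,
    current: RasterStack,
    future: RasterStack,
    radius_km: float,
) -> np.ndarray:
    return forward_offsets(model, current, future, (radius_km,))[radius_km]


def reverse_offset(
    model: TurnoverModel, current: RasterStack, future: RasterStack
) -> np.ndarray:
    """Per cell i: min over all cells j of the distance between future
    composition at i and current composition at j."""
    future = _check_aligned(current, future)
    valid = ~(current.mask | future.mask)
    _, cur = _compositions(model, current, valid)
    _, fut = _compositions(model, future, valid)
    d = cdist(fut, cur)
    out = np.full(current.shape, np.nan)
    out[valid] = d.min(axis=1)
    return out


@dataclass
class OffsetSurface:
    local: np.ndarray
    forward: dict[float, np.ndarray]
    reverse: np.ndarray
    epoch: str
    locus_set: str = "neutral"


def offset_surface(
    model: TurnoverModel,
    current: RasterStack,
    future: RasterStack,
    radii_km: tuple[float, ...] = (50.0, 100.0, 200.0, 500.0, float("inf")),
    locus_set: str = "neutral",
) -> OffsetSurface:
    return OffsetSurface(
        local=local_offset(model, current, future),
        forward=forward_offsets(model, current, future, radii_km),
        reverse=reverse_offset(model, current, future),
        epoch=future.epoch,
        locus_set=locus_set,
    )


# ---------------------------------------------------------------------------
# RGB composite
# ---------------------------------------------------------------------------


def rgb_composite(
    local: np.ndarray, forward: np.ndarray, reverse: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Min-max scale the three offset grids to [0, 255] (R = local,
    G = forward, B = reverse). Returns (3, nrows, ncols) uint8 plus the
    scaling bounds needed to invert the quantisation."""
    bands = []
    meta: dict = {"bands": ["local", "forward", "reverse"], "bounds": []}
    for name, grid in (("local", local), ("forward", forward), ("reverse", reverse)):
        valid = np.isfinite(grid)
        lo = float(np.nanmin(grid)) if valid.any() else 0.0
        hi = float(np.nanmax(grid)) if valid.any() else 0.0
        if hi == lo:
            warnings.warn(f"constant {name} band mapped to 0")
            scaled = np.zeros_like(grid)
        else:
            scaled = (grid - lo) / (hi - lo) * 255.0
        band = np.zeros(grid.shape, dtype=np.uint8)
        band[valid] = np.round(scaled[valid]).astype(np.uint8)
        bands.append(band)
        meta["bounds"].append({"band": name, "min": lo, "max": hi})
    return np.stack(bands), meta


# ---------------------------------------------------------------------------
# RONA
# ---------------------------------------------------------------------------


@dataclass
class RonaTable:
    summary: pd.DataFrame        # pop x variable weighted mean / SE / n_loci
    per_locus: pd.DataFrame      # pop, variable, locus, rona, r2


def rona(
    freqs: AlleleFreqTable,
    core: GeaResult,
    env_current: EnvTable,
    env_future: EnvTable,
    slope_p_max: float = 0.05,
    weight_by_r2: bool = True,
) -> RonaTable:
    """Risk of non-adaptedness per population and environmental variable.

    For each variable and each core locus associated with it, the locus's
    population frequencies are regressed on the current variable; fits with
    slope p < ``slope_p_max`` are kept. RONA(pop, v, locus) =
    |a * v_future(pop) + b - p_current(pop)|; the population value is the
    R-squared-weighted mean over kept loci with its weighted standard error.
    """
    if list(env_current.pops) != list(env_future.pops):
        raise ValueError("env tables are not row-aligned")
    id_to_col = {l: i for i, l in enumerate(freqs.locus_ids)}
    variables = sorted({v for vs in core.variables_of_core.values() for v in vs})
    sum_rows, locus_rows = [], []
    for var in variables:
        loci = [
            l for l in core.core_ids
            if var in core.variables_of_core.get(l, []) and l in id_to_col
        ]
        kept = []
        for l in loci:
            p_obs = freqs.p[:, id_to_col[l]]
            ok = np.isfinite(p_obs)
            if ok.sum() < 3:
                continue
            x = env_current.column(var)[ok]
            fit = linregress(x, p_obs[ok])
            if fit.pvalue >= slope_p_max:
                continue
            pred_fut = fit.slope * env_future.column(var) + fit.intercept
            vals = np.abs(pred_fut - freqs.p[:, id_to_col[l]])
            kept.append((l, vals, fit.rvalue**2))
        if not kept:
            warnings.warn(f"no loci with a significant fit for {var}; entry missing")
            continue
        w = np.array([r2 if weight_by_r2 else 1.0 for _, _, r2 in kept])
        w = w / w.sum()
        mat = np.vstack([vals for _, vals, _ in kept])        # (n_loci, n_pops)
        mean = np.einsum("l,lp->p", w, np.nan_to_num(mat))
        dev = (mat - mean[None, :]) ** 2
        se = np.sqrt(np.einsum("l,lp->p", w, np.nan_to_num(dev))) / np.sqrt(len(kept))
        for i, pop in enumerate(env_current.pops):
            sum_rows.append(
                {"pop": pop, "variable": var, "rona": mean[i], "se": se[i],
                 "n_loci": len(kept)}
            )
            for l, vals, r2 in kept:
                locus_rows.append(
                    {"pop": pop, "variable": var, "locus": l,
                     "rona": vals[i], "r2": r2}
                )
    return RonaTable(
        summary=pd.DataFrame(sum_rows), per_locus=pd.DataFrame(locus_rows)
    )
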