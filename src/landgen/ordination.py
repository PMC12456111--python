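"""Redundancy analysis, partial RDA and variance partitioning.

The response is a centred population x locus allele-frequency matrix; the
explained fraction reported everywhere is the Ezekiel-adjusted R-squared, so
small negative fractions are legitimate. Conditional ("pure") fractions are
differences of adjusted R-squared between nested models, the construction
behind the usual variance-partitioning tables; significance comes from free
permutation of the rows of the (conditioned) response.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

from .genio import EnvTable

logger = logging.getLogger("landgen")


def _center(m: np.ndarray) -> np.ndarray:
    return m - m.mean(axis=0, keepdims=True)


def _standardise(m: np.ndarray, drop_constant: bool = True) -> np.ndarray:
    m = np.asarray(m, dtype=float)
    sd = m.std(axis=0)
    if drop_constant and np.any(sd == 0):
        warnings.warn("dropping constant predictor column(s)")
        m = m[:, sd > 0]
        sd = sd[sd > 0]
    return (m - m.mean(axis=0)) / sd


def _prune_aliased(x: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Drop linearly dependent columns (QR with pivoting), warning on each."""
    if x.shape[1] == 0:
        return x
    _, r, piv = scipy.linalg.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    thresh = max(tol * diag.max(), 1e-8)
    rank = int((diag > thresh).sum()) if diag.max() > 0 else 0
    if rank < x.shape[1]:
        dropped = sorted(piv[rank:])
        warnings.warn(f"rank-deficient predictors; dropping columns {dropped}")
        return x[:, sorted(piv[:rank])]
    return x


def env_pca_distance(env: EnvTable, class_filter: str | None = None) -> np.ndarray:
    """Euclidean distances between populations on the first two principal
    components of the standardised environmental variables."""
    table = env.select_class(class_filter) if class_filter else env
    if table.values.shape[1] < 3:
        raise ValueError("need at least 3 variables for an environmental PCA")
    z = _standardise(table.values)
    u, s, _ = np.linalg.svd(_center(z), full_matrices=False)
    pcs = (u * s)[:, :2]
    diff = pcs[:, None, :] - pcs[None, :, :]
    return np.sqrt((diff**2).sum(axis=-1))


# ---------------------------------------------------------------------------
# RDA
# ---------------------------------------------------------------------------


@dataclass
class RdaResult:
    site_scores: np.ndarray        # (n, k) constrained-axis scores
    eigenvalues: np.ndarray        # (k,)
    snp_loadings: np.ndarray       # (L, k)
    r2: float                      # fraction of total variance (semipartial if Z)
    adj_r2: float
    p_value: float
    rank: int


def _fit_r2(y: np.ndarray, x: np.ndarray) -> tuple[np.ndarray, float, int]:
    """OLS fit of centred y on centred x; returns (fitted, R2, rank)."""
    if x.shape[1] == 0:
        return np.zeros_like(y), 0.0, 0
    b, *_ = np.linalg.lstsq(x, y, rcond=None)
    fitted = x @ b
    ss_tot = (y**2).sum()
    r2 = float((fitted**2).sum() / ss_tot) if ss_tot > 0 else 0.0
    return fitted, r2, x.shape[1]


def _adjust(r2: float, n: int, p: int) -> float:
    """Ezekiel's adjusted R-squared."""
    if n - p - 1 <= 0:
        return np.nan
    return 1 - (1 - r2) * (n - 1) / (n - p - 1)


def rda(
    y: np.ndarray,
    x: np.ndarray,
    z: np.ndarray | None = None,
    n_permutations: int = 999,
    seed: int = 0,
    standardise: bool = True,
) -> RdaResult:
    """(Partial) redundancy analysis of a multivariate response.

    With conditioning variables ``z``, both response and predictors are
    first residualised on ``z``; the reported adjusted R-squared is then the
    semipartial fraction adjR2(x+z) - adjR2(z). Significance is assessed by
    freely permuting the rows of the (residualised) response.
    """
    y = _center(np.asarray(y, dtype=float))
    x = _standardise(x) if standardise else _center(np.asarray(x, dtype=float))
    x = _prune_aliased(x)
    n = y.shape[0]
    if z is not None and z.size > 0:
        z = _standardise(z) if standardise else _center(np.asarray(z, dtype=float))
        z = _prune_aliased(z)
        _, r2_z, p_z = _fit_r2(y, z)
        xz = _prune_aliased(np.hstack([x, z]))
        _, r2_xz, p_xz = _fit_r2(y, xz)
        adj = _adjust(r2_xz, n, p_xz) - _adjust(r2_z, n, p_z)
        # residualise for axes + permutation test
        bz, *_ = np.linalg.lstsq(z, y, rcond=None)
        y_fit_z = z @ bz
        y_res = y - y_fit_z
        bx, *_ = np.linalg.lstsq(z, x, rcond=None)
        x_res = _prune_aliased(x - z @ bx)
        q_rank = z.shape[1]
        r2_report = max(r2_xz - r2_z, 0.0)
    else:
        z = None
        y_fit_z = np.zeros_like(y)
        y_res, x_res = y, x
        q_rank = 0
        _, r2_report, p_x = _fit_r2(y, x)
        adj = _adjust(r2_report, n, p_x)

    fitted, r2_partial, rank = _fit_r2(y_res, x_res)
    u, s, vt = np.linalg.svd(fitted, full_matrices=False)
    k = int((s > s.max() * 1e-9).sum()) if s.size and s.max() > 0 else 0
    site = (u * s)[:, :k]
    eig = (s[:k] ** 2) / max(n - 1, 1)
    loadings = vt[:k].T

    # Freedman-Lane permutation of the conditioned response with a pseudo-F
    m = max(x_res.shape[1], 1)
    df_res = max(n - 1 - m - q_rank, 1)

    def pseudo_f(y_in: np.ndarray) -> float:
        fit, _, _ = _fit_r2(y_in, x_res)
        ss_x = (fit**2).sum()
        ss_r = max((y_in**2).sum() - ss_x, 0.0)
        if ss_r == 0:
            return np.inf
        return (ss_x / m) / (ss_r / df_res)

    f_obs = pseudo_f(y_res)
    rng = np.random.default_rng(seed)
    n_ge = 0
    for _ in range(n_permutations):
        y_star = y_fit_z + y_res[rng.permutation(n)]
        if z is not None:
            bzs, *_ = np.linalg.lstsq(z, y_star, rcond=None)
            y_star = y_star - z @ bzs
        if pseudo_f(y_star) >= f_obs - 1e-12:
            n_ge += 1
    p_value = (1 + n_ge) / (n_permutations + 1)
    return RdaResult(
        site_scores=site, eigenvalues=eig, snp_loadings=loadings,
        r2=r2_report, adj_r2=adj, p_value=p_value, rank=rank,
    )


# ---------------------------------------------------------------------------
# Variance partitioning
# ---------------------------------------------------------------------------


@dataclass
class VariancePartition:
    """Adjusted-R2 fractions for the full model, each predictor set
    conditioned on the others, marginal fractions, and the confounded
    remainder."""

    table: pd.DataFrame

    def fraction(self, row: str) -> float:
        return float(self.table.loc[row, "adj_r2"])


def variance_partition(
    y: np.ndarray,
    sets: dict[str, np.ndarray],
    n_permutations: int = 999,
    seed: int = 0,
) -> VariancePartition:
    """Decompose response variance over named predictor sets.

    For each set S the conditional fraction is adjR2(all) - adjR2(all \\ S),
    tested by the partial RDA of S given the others; marginal fractions
    adjR2(S) are reported alongside. The confounded remainder is the full
    fraction minus the sum of conditionals.
    """
    if not sets or any(v.shape[1] == 0 for v in sets.values()):
        raise ValueError("every predictor set must be non-empty")
    names = list(sets)
    flat = {k: _standardise(v) for k, v in sets.items()}
    seen: dict[int, str] = {}
    for k, v in flat.items():
        for h in (hash(v[:, j].tobytes()) for j in range(v.shape[1])):
            if h in seen and seen[h] != k:
                warnings.warn(
                    f"predictor shared between sets {seen[h]!r} and {k!r}; "
                    "its variance lands in the confounded term"
                )
            seen[h] = k

    y = _center(np.asarray(y, dtype=float))
    n = y.shape[0]

    def adj_of(cols: list[str]) -> float:
        if not cols:
            return 0.0
        x = _prune_aliased(np.hstack([flat[c] for c in cols]))
        _, r2, p = _fit_r2(y, x)
        return _adjust(r2, n, p)

    full_fit = rda(
        y, np.hstack([flat[c] for c in names]), n_permutations=n_permutations,
        seed=seed, standardise=False,
    )
    adj_full = adj_of(names)
    rows = {"full": {"adj_r2": adj_full, "p": full_fit.p_value}}
    cond_sum = 0.0
    for i, name in enumerate(names):
        others = [c for c in names if c != name]
        cond = adj_full - adj_of(others)
        fit = rda(
            y, flat[name], np.hstack([flat[c] for c in others]),
            n_permutations=n_permutations, seed=seed + 1 + i, standardise=False,
        )
        rows[f"{name}|rest"] = {"adj_r2": cond, "p": fit.p_value}
        rows[f"{name} (marginal)"] = {"adj_r2": adj_of([name]), "p": np.nan}
        cond_sum += cond
    rows["confounded"] = {"adj_r2": adj_full - cond_sum, "p": np.nan}
    return VariancePartition(table=pd.DataFrame(rows).T)
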