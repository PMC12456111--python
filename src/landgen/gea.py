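"""Genotype-environment association: ridge LFMM, RDA loadings, intersection.

Both scans run on the population x locus allele-frequency matrix by default
(environment is per-population); the latent-factor model is the
deterministic ridge formulation solved by alternating a truncated SVD for
the factors with a ridge update for the per-locus environmental effects.
Final p-values come from the per-locus OLS refit on [environment, factors],
optionally recalibrated by the genomic inflation factor, with
Benjamini-Hochberg correction applied per environmental variable.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2, t as t_dist

from .genio import EnvTable
from .neutral_scan import _bh
from .ordination import rda
from .popstats import AlleleFreqTable

logger = logging.getLogger("landgen")


def imputed_freq_matrix(freqs: AlleleFreqTable) -> np.ndarray:
    """Population x locus frequencies with NaN cells replaced by the locus
    mean (loci entirely missing are dropped by the caller)."""
    p = freqs.p.copy()
    mean = np.nanmean(p, axis=0)
    nan = np.isnan(p)
    p[nan] = np.broadcast_to(mean, p.shape)[nan]
    return p


# ---------------------------------------------------------------------------
# Ridge LFMM
# ---------------------------------------------------------------------------


@dataclass
class LfmmResult:
    locus_ids: list[str]
    variables: list[str]
    effect: np.ndarray         # (L, V)
    z: np.ndarray
    p: np.ndarray
    q: np.ndarray
    gif: np.ndarray            # (V,)
    converged: np.ndarray      # (V,) bool

    def hits(self, alpha: float = 0.05) -> np.ndarray:
        """Loci with q < alpha for at least one variable."""
        with np.errstate(invalid="ignore"):
            return np.nanmin(self.q, axis=1) < alpha

    def hit_ids(self, alpha: float = 0.05) -> set[str]:
        return {l for l, h in zip(self.locus_ids, self.hits(alpha)) if h}

    def variables_of(self, locus_id: str, alpha: float = 0.05) -> list[str]:
        i = self.locus_ids.index(locus_id)
        return [v for j, v in enumerate(self.variables) if self.q[i, j] < alpha]


def _lfmm_one(
    y: np.ndarray, x: np.ndarray, k: int, lam: float, max_iter: int, tol: float
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Alternating ridge LFMM for one (centred) environmental vector.

    Returns (b, u_factors, converged): per-locus effects, the n x k latent
    factor scores and the convergence flag.
    """
    n, L = y.shape
    xtx = float(x @ x) + lam
    b = np.zeros(L)
    u_fac = np.zeros((n, 0))
    converged = k == 0
    last_rel = np.inf
    for _ in range(max_iter if k > 0 else 0):
        r = y - np.outer(x, b)
        u, s, vt = np.linalg.svd(r, full_matrices=False)
        u_fac = u[:, :k] * s[:k]
        latent = u_fac @ vt[:k]
        b_new = x @ (y - latent) / xtx
        denom = max(np.linalg.norm(b_new), 1e-12)
        last_rel = np.linalg.norm(b_new - b) / denom
        b = b_new
        if last_rel < tol:
            converged = True
            break
    if not converged and k > 0:
        warnings.warn(f"LFMM did not converge (last relative change {last_rel:.2e})")
    return b, u_fac, converged


def lfmm_scan(
    y: np.ndarray,
    env: EnvTable,
    k: int = 3,
    locus_ids: list[str] | None = None,
    lam: float = 1e-5,
    max_iter: int = 200,
    tol: float = 1e-5,
    calibrate: bool = True,
    alpha: float = 0.05,
) -> LfmmResult:
    """Univariate latent-factor scan, one run per environmental variable.

    After the alternating solve, z-scores come from the per-locus OLS refit
    of the response on [1, variable, factors]; with ``calibrate`` they are
    rescaled by the genomic inflation factor (median z^2 over the chi2_1
    median) before chi-squared p-values and per-variable BH correction.
    """
    y = np.asarray(y, dtype=float)
    n, L = y.shape
    if k >= min(n, L):
        raise ValueError("k must be smaller than both response dimensions")
    yc = y - y.mean(axis=0)
    locus_ids = locus_ids or [f"locus{i}" for i in range(L)]
    variables = list(env.variables)
    eff = np.empty((L, len(variables)))
    zmat = np.empty_like(eff)
    pmat = np.empty_like(eff)
    qmat = np.empty_like(eff)
    gifs = np.empty(len(variables))
    conv = np.empty(len(variables), dtype=bool)
    for j, var in enumerate(variables):
        xv = env.column(var).astype(float)
        xv = (xv - xv.mean()) / xv.std()
        b, u_fac, conv[j] = _lfmm_one(yc, xv, k, lam, max_iter, tol)
        design = np.column_stack([np.ones(n), xv, u_fac])
        coef, *_ = np.linalg.lstsq(design, yc, rcond=None)
        resid = yc - design @ coef
        df = n - design.shape[1]
        sigma2 = (resid**2).sum(axis=0) / max(df, 1)
        xtx_inv = np.linalg.pinv(design.T @ design)
        se = np.sqrt(np.maximum(sigma2 * xtx_inv[1, 1], 1e-300))
        zval = coef[1] / se
        if calibrate:
            gif = float(np.median(zval**2) / chi2.median(df=1))
            gif = max(gif, 1e-12)
            pv = chi2.sf(zval**2 / gif, df=1)
        else:
            gif = 1.0
            pv = 2 * t_dist.sf(np.abs(zval), df=max(df, 1))
        eff[:, j] = coef[1]
        zmat[:, j] = zval
        pmat[:, j] = pv
        qmat[:, j] = _bh(pv)
        gifs[j] = gif
    return LfmmResult(
        locus_ids=locus_ids, variables=variables, effect=eff, z=zmat,
        p=pmat, q=qmat, gif=gifs, converged=conv,
    )


# ---------------------------------------------------------------------------
# RDA loading scan
# ---------------------------------------------------------------------------


@dataclass
class RdaScanResult:
    locus_ids: list[str]
    loadings: np.ndarray       # (L, n_axes)
    flags: np.ndarray          # (L,) any-axis flag
    axis_flags: np.ndarray     # (L, n_axes)
    sd_cutoff: float

    def hit_ids(self) -> set[str]:
        return {l for l, f in zip(self.locus_ids, self.flags) if f}


def flag_outlier_scores(scores: np.ndarray, sd_cutoff: float) -> np.ndarray:
    """Tail rule for one axis: |score - mean| >= sd_cutoff * SD (ties at
    the boundary are flagged)."""
    if np.isinf(sd_cutoff):
        return np.zeros(len(scores), dtype=bool)
    mu, sd = scores.mean(), scores.std()
    if sd == 0:
        return np.zeros(len(scores), dtype=bool)
    return np.abs(scores - mu) >= sd_cutoff * sd


def rda_loading_scan(
    y: np.ndarray,
    env: EnvTable,
    sd_cutoff: float = 3.0,
    n_axes: int | None = None,
    locus_ids: list[str] | None = None,
    z: np.ndarray | None = None,
    n_permutations: int = 99,
    seed: int = 0,
) -> RdaScanResult:
    """Flag loci whose loadings sit in the tails of the constrained axes.

    With ``z`` (structure proxies, e.g. leading genetic PCs) the fit is a
    partial RDA, removing the neutral-structure signal that would otherwise
    inflate the axis-score spread.
    """
    fit = rda(y, env.values, z=z, n_permutations=n_permutations, seed=seed)
    avail = fit.snp_loadings.shape[1]
    want = min(3, avail) if n_axes is None else n_axes
    if want > avail:
        warnings.warn(f"requested {want} axes but only {avail} available")
        want = avail
    load = fit.snp_loadings[:, :want]
    axis_flags = np.column_stack(
        [flag_outlier_scores(load[:, a], sd_cutoff) for a in range(want)]
    ) if want else np.zeros((y.shape[1], 0), dtype=bool)
    flags = axis_flags.any(axis=1)
    locus_ids = locus_ids or [f"locus{i}" for i in range(y.shape[1])]
    return RdaScanResult(
        locus_ids=locus_ids, loadings=load, flags=flags,
        axis_flags=axis_flags, sd_cutoff=sd_cutoff,
    )


# ---------------------------------------------------------------------------
# Core candidates
# ---------------------------------------------------------------------------


@dataclass
class GeaResult:
    locus_ids: list[str]
    lfmm: LfmmResult
    rda_scan: RdaScanResult
    core_ids: list[str]
    variables_of_core: dict[str, list[str]]

    def to_frame(self) -> pd.DataFrame:
        lf = set(self.lfmm.hit_ids())
        rd = self.rda_scan.hit_ids()
        return pd.DataFrame(
            {
                "locus_id": self.locus_ids,
                "lfmm_hit": [l in lf for l in self.locus_ids],
                "rda_hit": [l in rd for l in self.locus_ids],
                "core": [l in set(self.core_ids) for l in self.locus_ids],
                "variables": [
                    ";".join(self.variables_of_core.get(l, [])) for l in self.locus_ids
                ],
            }
        )


def core_candidates(
    lfmm_res: LfmmResult, rda_res: RdaScanResult, alpha: float = 0.05
) -> GeaResult:
    """Intersect the LFMM and RDA hit sets into the core GEA locus list,
    keeping the associated-variable list of each core locus."""
    if lfmm_res.locus_ids != rda_res.locus_ids:
        raise ValueError("scans were not run on the same locus set")
    lf = lfmm_res.hit_ids(alpha)
    rd = rda_res.hit_ids()
    core = [l for l in lfmm_res.locus_ids if l in lf and l in rd]
    variables = {l: lfmm_res.variables_of(l, alpha) for l in core}
    logger.info(
        "GEA: %d LFMM hits, %d RDA hits, %d core", len(lf), len(rd), len(core)
    )
    return GeaResult(
        locus_ids=lfmm_res.locus_ids, lfmm=lfmm_res, rda_scan=rda_res,
        core_ids=core, variables_of_core=variables,
    )


def gea_scan(
    y: np.ndarray,
    env: EnvTable,
    k: int = 3,
    locus_ids: list[str] | None = None,
    sd_cutoff: float = 3.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> GeaResult:
    """Run both scans on one response matrix and intersect them.

    Both scans are structure-corrected with ``k`` dimensions: LFMM through
    its latent factors, the RDA by conditioning on the first ``k`` principal
    components of the response.
    """
    lf = lfmm_scan(y, env, k=k, locus_ids=locus_ids, alpha=alpha)
    z = None
    if k > 0:
        yc = y - y.mean(axis=0)
        u, s, _ = np.linalg.svd(yc, full_matrices=False)
        z = (u * s)[:, :k]
    rd = rda_loading_scan(
        y, env, sd_cutoff=sd_cutoff, locus_ids=locus_ids, z=z, seed=seed
    )
    return core_candidates(lf, rd, alpha=alpha)


def gea_scan_by_group(
    freqs: AlleleFreqTable,
    env: EnvTable,
    group_of_pop: dict[str, str],
    k: int = 3,
    sd_cutoff: float = 3.0,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict[str, GeaResult]:
    """Per-genetic-group scans on the population subsets."""
    y = imputed_freq_matrix(freqs)
    out: dict[str, GeaResult] = {}
    for group in sorted(set(group_of_pop.values())):
        rows = np.array([group_of_pop[p] == group for p in freqs.pops])
        if rows.sum() < 4:
            logger.warning("group %s has too few populations; skipped", group)
            continue
        sub_env = EnvTable(
            pops=freqs.pops[rows], variables=env.variables,
            classes=env.classes, values=env.values[rows],
        )
        yg = y[rows]
        poly = yg.std(axis=0) > 0
        kk = min(k, rows.sum() - 2)
        out[group] = gea_scan(
            yg[:, poly], sub_env, k=kk,
            locus_ids=[l for l, keep in zip(freqs.locus_ids, poly) if keep],
            sd_cutoff=sd_cutoff, alpha=alpha, seed=seed,
        )
    return out
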