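"""F_ST-outlier scans and the neutral/outlier partition.

Two scans are implemented: a principal-component deviation scan (per-locus
z-scores on the leading PCs, robust Mahalanobis distance, genomic-inflation
calibration against chi-squared) and an F_ST-vs-heterozygosity envelope scan
whose null is a Balding-Nichols island model calibrated to the trimmed mean
observed F_ST. A locus is an outlier only when every configured method flags
it; an externally produced flag file (e.g. from a Bayesian F-model run) can
join the intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import chi2, trim_mean
from sklearn.covariance import MinCovDet
from statsmodels.stats.multitest import multipletests

from .genio import GenotypeMatrix
from .popstats import (
    AlleleFreqTable,
    _pop_counts,
    multilocus_theta,
    scaled_dosage_matrix,
    wc_components,
)

logger = logging.getLogger("landgen")


@dataclass
class ScanResult:
    locus_ids: list[str]
    stat: np.ndarray
    p: np.ndarray
    q: np.ndarray
    flag: np.ndarray
    gif: float = np.nan

    def flagged_ids(self) -> set[str]:
        return {l for l, f in zip(self.locus_ids, self.flag) if f}


def _bh(p: np.ndarray) -> np.ndarray:
    q = np.full_like(p, np.nan, dtype=float)
    ok = np.isfinite(p)
    if ok.any():
        q[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return q


# ---------------------------------------------------------------------------
# PC-deviation scan
# ---------------------------------------------------------------------------


def pc_scan(
    g: GenotypeMatrix, k: int = 3, alpha: float = 0.05, seed: int = 0
) -> ScanResult:
    """Flag loci deviating from the leading-PC background structure.

    Each locus's scaled dosage column is regressed on the first ``k``
    principal-component score vectors; the resulting z-score vectors are
    summarised by a robust Mahalanobis distance across loci, rescaled by the
    genomic inflation factor (median distance over the chi-squared-k median)
    and converted to BH-adjusted chi-squared p-values.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    x = scaled_dosage_matrix(g)
    n = x.shape[0]
    if k >= n:
        raise ValueError("k must be smaller than the number of individuals")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    basis = u[:, :k]                      # orthonormal score directions
    b = basis.T @ x                       # (k, L) regression coefficients
    rss = np.maximum((x**2).sum(axis=0) - (b**2).sum(axis=0), 0.0)
    df = max(n - k, 1)
    sigma = np.sqrt(rss / df)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (b / sigma).T                 # (L, k)
    z = np.where(np.isfinite(z), z, 0.0)
    mcd = MinCovDet(random_state=np.random.default_rng(seed).integers(2**31))
    mcd.fit(z)
    d2 = mcd.mahalanobis(z)
    gif = float(np.median(d2) / chi2.median(df=k))
    p = chi2.sf(d2 / gif, df=k)
    q = _bh(p)
    return ScanResult(
        locus_ids=g.locus_ids, stat=d2, p=p, q=q, flag=q < alpha, gif=gif
    )


# ---------------------------------------------------------------------------
# F_ST-vs-heterozygosity envelope scan
# ---------------------------------------------------------------------------


def _theta_and_het(n_ind: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Per-locus global theta and pooled expected heterozygosity."""
    a, b, c = wc_components(n_ind, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = a / (a + b + c)
        nz = np.where(n_ind > 0, n_ind, 0.0)
        pbar = (nz * np.where(n_ind > 0, p, 0.0)).sum(axis=0) / nz.sum(axis=0)
    return theta, 2 * pbar * (1 - pbar)


def simulate_null_loci(
    n_ind_per_pop: np.ndarray,
    fst: float,
    n_sims: int,
    rng: np.random.Generator,
):
    """Balding-Nichols island-model null: per simulated locus, ancestral
    frequency ~ U(0.02, 0.98), population frequencies ~ BN(fst), genotype
    counts ~ HWE multinomial at the observed per-population sample sizes.
    Returns (theta, het) arrays of length n_sims."""
    r = len(n_ind_per_pop)
    p_anc = rng.uniform(0.02, 0.98, size=n_sims)
    fst = min(max(fst, 1e-3), 0.99)
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    pop_p = rng.beta(a[None, :], b[None, :], size=(r, n_sims))
    n = np.empty((r, n_sims))
    p = np.empty((r, n_sims))
    h = np.empty((r, n_sims))
    for i in range(r):
        q = pop_p[i]
        pv = np.stack([q**2, 2 * q * (1 - q), (1 - q) ** 2], axis=-1)
        pv /= pv.sum(axis=-1, keepdims=True)
        counts = rng.multinomial(int(n_ind_per_pop[i]), pv)
        n_i = counts.sum(axis=-1)
        n[i] = n_i
        p[i] = (2 * counts[:, 0] + counts[:, 1]) / (2 * n_i)
        h[i] = counts[:, 1] / n_i
    return _theta_and_het(n, p, h)


def fdist_scan(
    g: GenotypeMatrix,
    n_sims: int = 1_000_000,
    alpha: float = 0.05,
    top_fraction: float = 0.01,
    n_bins: int = 20,
    min_bin_draws: int = 100,
    trim: float = 0.05,
    seed: int = 0,
) -> ScanResult:
    """Envelope scan of observed F_ST against a simulated neutral null.

    The null is calibrated to the trimmed mean of the observed per-locus
    theta ("neutral mean F_ST") and matched to observed per-population
    sample sizes. Each observed locus receives an upper-tail p-value from
    the null loci in its expected-heterozygosity bin (20 equal-width bins on
    [0, 0.5]; sparse bins are widened adaptively). A locus is flagged when
    it falls in the top ``top_fraction`` tail *and* its BH q-value is below
    ``alpha``; both criteria are also reported individually via p and q.
    """
    labels, n_ind, p, h = _pop_counts(g)
    theta_obs, het_obs = _theta_and_het(n_ind, p, h)
    finite = np.isfinite(theta_obs)
    fst_cal = float(trim_mean(theta_obs[finite], trim))
    logger.info("fdist_scan: calibrated neutral mean F_ST = %.4f", fst_cal)

    rng = np.random.default_rng(seed)
    mean_n = np.round(n_ind.mean(axis=1)).astype(int)
    mean_n = np.maximum(mean_n, 1)
    theta_null, het_null = simulate_null_loci(mean_n, fst_cal, n_sims, rng)
    ok_null = np.isfinite(theta_null)
    theta_null, het_null = theta_null[ok_null], het_null[ok_null]

    edges = np.linspace(0.0, 0.5, n_bins + 1)
    bin_null = np.clip(np.digitize(het_null, edges) - 1, 0, n_bins - 1)
    bin_obs = np.clip(np.digitize(het_obs, edges) - 1, 0, n_bins - 1)
    null_by_bin = [np.sort(theta_null[bin_null == b]) for b in range(n_bins)]

    pvals = np.full(g.n_loci, np.nan)
    widened = 0
    for b in range(n_bins):
        members = np.flatnonzero(finite & (bin_obs == b))
        if len(members) == 0:
            continue
        pool = null_by_bin[b]
        width = 0
        while len(pool) < min_bin_draws and width < n_bins:
            width += 1
            lo, hi = max(0, b - width), min(n_bins - 1, b + width)
            pool = np.sort(np.concatenate(null_by_bin[lo : hi + 1]))
            widened += 1
        if len(pool) == 0:
            continue
        # upper-tail p: fraction of null >= observed
        ge = len(pool) - np.searchsorted(pool, theta_obs[members], side="left")
        pvals[members] = (1 + ge) / (1 + len(pool))
    if widened:
        logger.info("fdist_scan: widened sparse heterozygosity bins %d times", widened)

    q = _bh(pvals)
    with np.errstate(invalid="ignore"):
        flag = (pvals <= top_fraction) & (q < alpha)
    flag = np.where(np.isfinite(pvals), flag, False).astype(bool)
    return ScanResult(locus_ids=g.locus_ids, stat=theta_obs, p=pvals, q=q, flag=flag)


# ---------------------------------------------------------------------------
# Partition
# ---------------------------------------------------------------------------


def read_external_flags(path: str | Path) -> set[str]:
    """Optional external method hook: TSV of (locus id, 0/1 flag)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["locus_id", "flag"])
    return set(df.loc[df["flag"].astype(int) == 1, "locus_id"])


@dataclass
class OutlierReport:
    table: pd.DataFrame          # per-locus methods, p/q, final class
    neutral_ids: list[str]
    outlier_ids: list[str]


def partition(
    locus_ids: list[str],
    method_flags: dict[str, set[str]],
) -> OutlierReport:
    """Intersect per-method outlier flag sets.

    Outliers are the loci every configured method flags; everything else is
    neutral. Counts per method and for the intersection are logged.
    """
    if not method_flags:
        raise ValueError("no scan results supplied")
    inter: set[str] | None = None
    for name, flags in method_flags.items():
        logger.info("partition: method %s flags %d loci", name, len(flags))
        inter = flags if inter is None else inter & flags
    outliers = inter & set(locus_ids) if inter else set()
    logger.info("partition: intersection outliers = %d", len(outliers))
    rows = {
        name: [l in flags for l in locus_ids]
        for name, flags in method_flags.items()
    }
    table = pd.DataFrame(rows, index=locus_ids)
    table["class"] = ["outlier" if l in outliers else "neutral" for l in locus_ids]
    neutral = [l for l in locus_ids if l not in outliers]
    outlier = [l for l in locus_ids if l in outliers]
    return OutlierReport(table=table, neutral_ids=neutral, outlier_ids=outlier)
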