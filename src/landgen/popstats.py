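"""SNP filtering and population-genetic summaries.

Estimator conventions
---------------------
* Expected heterozygosity / per-variant-site nucleotide diversity use the
  unbiased gene-diversity form ``2 p (1-p) n/(n-1)`` with ``n`` the number of
  sampled alleles; per-population values are means over the (variant) loci of
  the filtered matrix, so a site monomorphic within a population contributes
  zero.
* F_ST is Weir & Cockerham (1984) theta with the multilocus ratio-of-sums
  combination; small negative estimates are legitimate.
* F_IS = 1 - mean(H_O) / mean(H_E).
* The genotype PCA centres dosages by 2p and scales by sqrt(2p(1-p)) (the
  GRM convention); missing dosages are mean-imputed per locus.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genio import GenotypeMatrix, MISSING, RunConfig

logger = logging.getLogger("landgen")


# ---------------------------------------------------------------------------
# Allele frequencies
# ---------------------------------------------------------------------------


@dataclass
class AlleleFreqTable:
    """Populations x loci alternate-allele frequencies with allele sample
    sizes (2 x non-missing genotypes); p is NaN where n = 0."""

    pops: np.ndarray            # (n_pops,)
    locus_ids: list[str]
    p: np.ndarray               # (n_pops, n_loci)
    n: np.ndarray               # (n_pops, n_loci) allele counts, even

    @property
    def n_pops(self) -> int:
        return len(self.pops)

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.p, columns=self.locus_ids)
        df.insert(0, "pop", self.pops)
        return df


def _pop_counts(g: GenotypeMatrix):
    """Per-pop per-locus (n_ind_nonmissing, alt_freq, het_fraction)."""
    labels = g.pop_labels
    r = len(labels)
    n = np.zeros((r, g.n_loci))
    p = np.full((r, g.n_loci), np.nan)
    h = np.zeros((r, g.n_loci))
    idx = g.pop_indices()
    for k, lab in enumerate(labels):
        d = g.dosages[idx[lab]]
        obs = d != MISSING
        cnt = obs.sum(axis=0)
        n[k] = cnt
        with np.errstate(invalid="ignore", divide="ignore"):
            p[k] = np.where(cnt > 0, np.where(obs, d, 0).sum(axis=0) / (2 * cnt), np.nan)
            h[k] = np.where(cnt > 0, ((d == 1) & obs).sum(axis=0) / np.maximum(cnt, 1), 0.0)
    return np.array(labels, dtype=object), n, p, h


def allele_freq_table(g: GenotypeMatrix) -> AlleleFreqTable:
    labels, n, p, h = _pop_counts(g)
    return AlleleFreqTable(pops=labels, locus_ids=g.locus_ids, p=p, n=2 * n)


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterReport:
    n_input: int
    removed_first_snp: int
    removed_presence: int
    removed_maf: int
    removed_het: int
    n_kept: int


def filter_snps(
    g: GenotypeMatrix, cfg: RunConfig | None = None
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the RAD-seq SNP filters in sequence.

    Order: first SNP per locus group -> presence (genotyped in >=
    ``min_individual_presence`` of individuals and in >= ``min_populations``
    populations) -> global minor-allele frequency >= ``maf_min`` -> observed
    heterozygote fraction <= ``max_obs_het``. Removal counts per rule are
    logged and returned.
    """
    cfg = cfg or RunConfig()
    n_input = g.n_loci
    keep = np.ones(n_input, dtype=bool)

    # first SNP (lowest position, ties by column order) per locus group
    order = np.lexsort((np.arange(n_input), g.locus_pos))
    seen: set = set()
    first = np.zeros(n_input, dtype=bool)
    for i in order:
        if g.locus_chrom[i] not in seen:
            seen.add(g.locus_chrom[i])
            first[i] = True
    removed_first = int((~first).sum())
    keep &= first

    obs = g.dosages != MISSING
    # presence: individual fraction and population count
    ind_frac = obs.mean(axis=0)
    pop_counts = np.zeros(n_input)
    for idx in g.pop_indices().values():
        pop_counts += obs[idx].any(axis=0)
    presence_ok = (ind_frac >= cfg.min_individual_presence) & (
        pop_counts >= cfg.min_populations
    )
    removed_presence = int((keep & ~presence_ok).sum())
    keep &= presence_ok

    # global MAF
    cnt = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_hat = np.where(obs, g.dosages, 0).sum(axis=0) / np.maximum(2 * cnt, 1)
    maf = np.minimum(p_hat, 1 - p_hat)
    maf_ok = maf >= cfg.maf_min
    removed_maf = int((keep & ~maf_ok).sum())
    keep &= maf_ok

    # observed heterozygosity
    het = ((g.dosages == 1) & obs).sum(axis=0) / np.maximum(cnt, 1)
    het_ok = het <= cfg.max_obs_het
    removed_het = int((keep & ~het_ok).sum())
    keep &= het_ok

    report = FilterReport(
        n_input=n_input,
        removed_first_snp=removed_first,
        removed_presence=removed_presence,
        removed_maf=removed_maf,
        removed_het=removed_het,
        n_kept=int(keep.sum()),
    )
    logger.info(
        "filter_snps: %d -> %d (first-SNP -%d, presence -%d, MAF -%d, het -%d)",
        report.n_input, report.n_kept, report.removed_first_snp,
        report.removed_presence, report.removed_maf, report.removed_het,
    )
    if report.n_kept == 0:
        raise ValueError("no loci survive filtering; review the thresholds")
    return g.take_loci(np.flatnonzero(keep)), report


# ---------------------------------------------------------------------------
# Diversity
# ---------------------------------------------------------------------------


@dataclass
class DiversityStats:
    pops: np.ndarray
    pi: np.ndarray
    ho: np.ndarray
    he: np.ndarray
    fis: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pop": self.pops, "pi": self.pi, "ho": self.ho, "he": self.he,
             "fis": self.fis}
        )


def diversity(g: GenotypeMatrix) -> DiversityStats:
    """Per-population pi, H_O, H_E and F_IS over the variant sites of the
    matrix. Loci with fewer than two sampled alleles in a population are
    excluded from that population's means; a population with no usable loci
    reports NaN."""
    labels, n, p, h = _pop_counts(g)
    alleles = 2 * n
    usable = alleles >= 2
    with np.errstate(invalid="ignore", divide="ignore"):
        he_site = 2 * p * (1 - p) * alleles / np.maximum(alleles - 1, 1)
    r = len(labels)
    pi = np.full(r, np.nan)
    ho = np.full(r, np.nan)
    he = np.full(r, np.nan)
    fis = np.full(r, np.nan)
    for k in range(r):
        u = usable[k]
        if not u.any():
            continue
        he[k] = he_site[k, u].mean()
        ho[k] = h[k, u].mean()
        pi[k] = he[k]
        if he[k] > 0:
            fis[k] = 1 - ho[k] / he[k]
    return DiversityStats(pops=labels, pi=pi, ho=ho, he=he, fis=fis)


# ---------------------------------------------------------------------------
# Weir & Cockerham theta
# ---------------------------------------------------------------------------


def wc_components(n: np.ndarray, p: np.ndarray, h: np.ndarray):
    """Weir & Cockerham (1984) variance components a, b, c per locus.

    ``n`` (r x L) are per-population counts of genotyped diploids, ``p``
    alternate-allele frequencies and ``h`` observed heterozygote fractions.
    Populations with n = 0 at a locus are excluded there; loci with fewer
    than two populated samples or mean sample size <= 1 return NaN.
    """
    n = np.asarray(n, dtype=float)
    p = np.where(n > 0, p, 0.0)
    h = np.where(n > 0, h, 0.0)
    r = (n > 0).sum(axis=0).astype(float)
    nsum = n.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nbar = nsum / r
        nc = (nsum - (n**2).sum(axis=0) / nsum) / (r - 1)
        pbar = (n * p).sum(axis=0) / nsum
        s2 = (n * (p - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n * h).sum(axis=0) / nsum
        inner = pbar * (1 - pbar) - (r - 1) / r * s2
        a = nbar / nc * (s2 - (inner - hbar / 4) / (nbar - 1))
        b = nbar / (nbar - 1) * (inner - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
    bad = (r < 2) | (nbar <= 1) | ~np.isfinite(nc) | (nc <= 0)
    for arr in (a, b, c):
        arr[bad] = np.nan
    return a, b, c


def multilocus_theta(n: np.ndarray, p: np.ndarray, h: np.ndarray) -> float:
    """Ratio-of-sums multilocus theta over the loci with valid components."""
    a, b, c = wc_components(n, p, h)
    ok = np.isfinite(a) & np.isfinite(b) & np.isfinite(c)
    denom = (a + b + c)[ok].sum()
    if denom == 0:
        return np.nan
    return float(a[ok].sum() / denom)


def per_locus_theta(g: GenotypeMatrix) -> np.ndarray:
    """Global (all populations) per-locus theta."""
    _, n, p, h = _pop_counts(g)
    a, b, c = wc_components(n, p, h)
    with np.errstate(invalid="ignore", divide="ignore"):
        return a / (a + b + c)


@dataclass
class FstMatrix:
    pops: np.ndarray
    theta: np.ndarray          # symmetric, zero diagonal, NaN where undefined

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.theta, index=self.pops, columns=self.pops)


def pairwise_fst(g: GenotypeMatrix) -> FstMatrix:
    """Pairwise multilocus Weir & Cockerham theta between populations."""
    labels, n, p, h = _pop_counts(g)
    r = len(labels)
    if r < 2:
        raise ValueError("pairwise F_ST needs at least two populations")
    theta = np.zeros((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            sel = np.array([i, j])
            both = (n[sel] > 0).all(axis=0)
            if not both.any():
                theta[i, j] = theta[j, i] = np.nan
                continue
            t = multilocus_theta(n[sel][:, both], p[sel][:, both], h[sel][:, both])
            theta[i, j] = theta[j, i] = t
    return FstMatrix(pops=labels, theta=theta)


# ---------------------------------------------------------------------------
# Genotype PCA
# ---------------------------------------------------------------------------


@dataclass
class PcaResult:
    scores: np.ndarray             # (n_ind, k)
    eigenvalues: np.ndarray
    var_fractions: np.ndarray
    pop_labels: np.ndarray
    pop_scores: np.ndarray         # (n_pops, min(3, k)) population-mean scores

    def structure_proxies(self, k: int = 3) -> np.ndarray:
        return self.pop_scores[:, :k]


def scaled_dosage_matrix(g: GenotypeMatrix) -> np.ndarray:
    """Dosages centred by 2p and scaled by sqrt(2p(1-p)), missing cells
    mean-imputed (= 0 after centring); monomorphic loci are dropped."""
    d = g.dosages.astype(float)
    obs = d != MISSING
    cnt = obs.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(obs, d, 0).sum(axis=0) / np.maximum(2 * cnt, 1)
    poly = (p > 0) & (p < 1) & (cnt > 0)
    d = d[:, poly]
    obs = obs[:, poly]
    p = p[poly]
    x = np.where(obs, d - 2 * p, 0.0)
    return x / np.sqrt(2 * p * (1 - p))


def genotype_pca(g: GenotypeMatrix, n_components: int | None = None) -> PcaResult:
    """Eigen-decomposition of the individual covariance of the scaled
    dosage matrix (GRM convention)."""
    x = scaled_dosage_matrix(g)
    n_ind = x.shape[0]
    if n_components is not None and n_components >= n_ind:
        raise ValueError("fewer individuals than requested components")
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u * s
    eig = s**2 / max(n_ind - 1, 1)
    frac = s**2 / (s**2).sum()
    if n_components is not None:
        scores, eig, frac = scores[:, :n_components], eig[:n_components], frac[:n_components]
    labels = np.array(g.pop_labels, dtype=object)
    idx = g.pop_indices()
    k3 = min(3, scores.shape[1])
    pop_scores = np.vstack([scores[idx[l], :k3].mean(axis=0) for l in labels])
    return PcaResult(
        scores=scores, eigenvalues=eig, var_fractions=frac,
        pop_labels=labels, pop_scores=pop_scores,
    )
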