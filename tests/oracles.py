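"""Independent brute-force reference implementations used only by tests.

Everything here is written as literal transcriptions (loops, enumerations)
and stays independent of the package's vectorised code paths.
"""

from __future__ import annotations

import itertools

import numpy as np


def pi_pairwise(genotypes: list[int]) -> float:
    """Nucleotide diversity at one biallelic site from diploid dosages:
    fraction of differing allele pairs among all allele pairs."""
    alleles: list[int] = []
    for g in genotypes:
        alleles += [1] * g + [0] * (2 - g)
    n = len(alleles)
    if n < 2:
        return float("nan")
    diff = sum(a != b for a, b in itertools.combinations(alleles, 2))
    return diff / (n * (n - 1) / 2)


def ho_he_fis(genotype_columns: list[list[int]]):
    """Mean observed/expected heterozygosity and F_IS over sites for one
    population; genotype_columns[site] = diploid dosages (no missing)."""
    hos, hes = [], []
    for col in genotype_columns:
        n = 2 * len(col)
        p = sum(col) / n
        hos.append(sum(1 for g in col if g == 1) / len(col))
        hes.append(2 * p * (1 - p) * n / (n - 1))
    ho, he = float(np.mean(hos)), float(np.mean(hes))
    fis = 1 - ho / he if he > 0 else float("nan")
    return ho, he, fis


def wc_theta(pop_genotypes: list[list[list[int]]]) -> float:
    """Multilocus Weir & Cockerham (1984) theta, ratio of sums.

    pop_genotypes[pop][site] = list of diploid dosages (no missing).
    Direct transcription of the variance-component formulas.
    """
    n_sites = len(pop_genotypes[0])
    sum_a = sum_abc = 0.0
    for s in range(n_sites):
        cols = [pop[s] for pop in pop_genotypes]
        r = len(cols)
        n_i = [len(c) for c in cols]
        if min(n_i) == 0 or r < 2:
            continue
        p_i = [sum(c) / (2 * len(c)) for c in cols]
        h_i = [sum(1 for g in c if g == 1) / len(c) for c in cols]
        nbar = sum(n_i) / r
        if nbar <= 1:
            continue
        nc = (sum(n_i) - sum(x * x for x in n_i) / sum(n_i)) / (r - 1)
        pbar = sum(n * p for n, p in zip(n_i, p_i)) / sum(n_i)
        s2 = sum(n * (p - pbar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * nbar)
        hbar = sum(n * h for n, h in zip(n_i, h_i)) / sum(n_i)
        a = (nbar / nc) * (
            s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1)
        )
        b = (nbar / (nbar - 1)) * (
            pbar * (1 - pbar) - (r - 1) / r * s2 - (2 * nbar - 1) / (4 * nbar) * hbar
        )
        c = hbar / 2
        sum_a += a
        sum_abc += a + b + c
    return sum_a / sum_abc


def forward_offset_brute(
    comp_cur: np.ndarray, comp_fut: np.ndarray, geo: np.ndarray, radius: float
) -> np.ndarray:
    """Double-loop forward offset over flattened valid cells."""
    n = comp_cur.shape[0]
    out = np.empty(n)
    for i in range(n):
        best = np.inf
        for j in range(n):
            if i != j and geo[i, j] > radius:
                continue
            d = np.sqrt(((comp_cur[i] - comp_fut[j]) ** 2).sum())
            best = min(best, d)
        out[i] = best
    return out


def reverse_offset_brute(comp_cur: np.ndarray, comp_fut: np.ndarray) -> np.ndarray:
    n = comp_fut.shape[0]
    out = np.empty(n)
    for i in range(n):
        out[i] = min(
            np.sqrt(((comp_fut[i] - comp_cur[j]) ** 2).sum()) for j in range(n)
        )
    return out


def greedy_prune(values: np.ndarray, names: list[str], importance: dict, r_max: float):
    """Reference greedy collinearity pruning."""
    keep = list(names)
    while len(keep) > 1:
        idx = [names.index(k) for k in keep]
        c = np.abs(np.corrcoef(values[:, idx].T))
        np.fill_diagonal(c, 0)
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if c[i, j] <= r_max:
            break
        a, b = keep[i], keep[j]
        keep.remove(a if importance[a] <= importance[b] else b)
    return keep
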