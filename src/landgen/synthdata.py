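"""Synthetic landscape-genomic datasets with known truth.

The generator emulates the sampling design of a range-wide RAD-seq study of
an East Asian understory herb: 27 populations of 2-17 diploids arranged in
three geographic groups, thousands of biallelic SNPs with hierarchical
structure and isolation by distance, a small planted set of loci whose allele
frequencies follow logistic clines in specific climate variables, spatially
smooth environmental rasters, and future rasters = current + a structured
perturbation that grows with emission scenario and time horizon.

Neutral allele frequencies follow a hierarchical Balding-Nichols model:
ancestral frequency p ~ U(0.05, 0.95); group frequency ~ Beta with
differentiation F_between; population frequency ~ Beta around the group
frequency with F_within, coupled across populations through a Gaussian
copula with an exponential spatial kernel so that within-group
differentiation also carries isolation by distance. Adaptive locus
frequencies are inverse-logit clines in one standardised driver variable.
Genotypes are Binomial(2, p) draws with uniform missingness.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from scipy.stats import beta as beta_dist
from scipy.stats import norm

from .genio import (
    EnvTable,
    GenotypeMatrix,
    MISSING,
    PopulationFrame,
    RasterStack,
    write_popmap,
    write_raster_stack,
    write_vcf,
)
from .spatial import geo_distance_matrix

SOIL_VARS = ("CEC", "OCD", "sand", "TAXNWRB", "PH_H2O")

#: bioclim index -> latent-field family (temperature level; diurnal range /
#: isothermality; precipitation totals; precipitation seasonality)
_BIOCLIM_CLUSTER = {
    1: 0, 5: 0, 6: 0, 8: 0, 9: 0, 10: 0, 11: 0,
    2: 1, 3: 1, 4: 1, 7: 1,
    12: 2, 13: 2, 16: 2, 18: 2,
    14: 3, 15: 3, 17: 3, 19: 3,
}

#: epoch -> multiplier on the per-variable base climate shift
EPOCH_SCALE = {
    "SSP126_2041_2060": 0.5,
    "SSP126_2061_2080": 0.7,
    "SSP585_2041_2060": 1.0,
    "SSP585_2061_2080": 1.5,
}


@dataclass
class SynthConfig:
    """Study conditions for the synthetic generator.

    Defaults follow the emulated design: 27 populations of 2-17 diploids in
    3 groups, 3,000 neutral + 30 adaptive loci, moderate hierarchical
    differentiation, 19 bioclim + 5 soil variables on a 26 x 50 one-degree
    grid spanning an East-Asia-sized extent.
    """

    n_pops: int = 27
    ind_min: int = 2
    ind_max: int = 17
    n_neutral: int = 3000
    n_adaptive: int = 30
    n_groups: int = 3
    fst_between: float = 0.25
    fst_within: float = 0.05
    ibd_range_km: float = 800.0
    beta_min: float = 1.0
    beta_max: float = 3.0
    driver_vars: tuple[str, ...] = ("bio2", "bio5", "bio15", "bio18")
    n_bioclim: int = 19
    grid_nrows: int = 40
    grid_ncols: int = 72
    cell_deg: float = 0.5
    xll: float = 95.0
    yll: float = 20.0
    noise_sd: float = 0.3
    future_shift_sd: float = 1.0
    missing_rate: float = 0.05
    extra_snp_rate: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        for f in (self.fst_between, self.fst_within):
            if not 0 < f < 1:
                raise ValueError("F_ST parameters must lie in (0, 1)")
        if self.n_pops < self.n_groups:
            raise ValueError("need at least one population per group")
        if self.grid_nrows * self.grid_ncols < 4 * self.n_pops:
            raise ValueError("grid too small for the requested populations")


@dataclass
class SimulatedLandscape:
    current: RasterStack
    futures: dict[str, RasterStack]
    frame: PopulationFrame
    group_of_pop: dict[str, str]


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  wavelengths: int = 2) -> np.ndarray:
    """Low-frequency sinusoid mixture, unit-ish amplitude."""
    nrows, ncols = shape
    yy, xx = np.mgrid[0:nrows, 0:ncols]
    out = np.zeros(shape)
    for _ in range(wavelengths):
        fx, fy = rng.uniform(0.5, 2.0, size=2)
        phx, phy = rng.uniform(0, 2 * np.pi, size=2)
        out += np.sin(2 * np.pi * fx * xx / ncols + phx) * np.sin(
            2 * np.pi * fy * yy / nrows + phy
        )
    return out / wavelengths


def simulate_landscape(cfg: SynthConfig) -> SimulatedLandscape:
    """Build current + future raster stacks and place the populations.

    Each bioclim layer is a linear gradient plus a low-frequency sinusoid
    plus white noise; soil layers are independent smooth fields with no
    future shift. Future layers add a spatially structured perturbation
    scaled per scenario/period. Populations sit on non-nodata cell centres
    spanning the longitudinal gradient and are split into ``n_groups``
    contiguous longitudinal groups.
    """
    rng = np.random.default_rng(cfg.seed)
    shape = (cfg.grid_nrows, cfg.grid_ncols)
    yy, xx = np.mgrid[0 : cfg.grid_nrows, 0 : cfg.grid_ncols]
    xn = xx / max(cfg.grid_ncols - 1, 1)
    yn = yy / max(cfg.grid_nrows - 1, 1)

    # nodata corner (an "ocean" wedge in the south-east)
    mask = (xn + (1 - yn)) > 1.82

    names: list[str] = [f"bio{i}" for i in range(1, cfg.n_bioclim + 1)] + list(
        SOIL_VARS
    )

    def unit(f: np.ndarray) -> np.ndarray:
        return (f - f[~mask].mean()) / f[~mask].std()

    # bioclim variables come in correlated families driven by shared latent
    # fields (temperature level; diurnal range / isothermality; precipitation
    # totals; precipitation seasonality), mimicking real WorldClim structure
    cluster_of = {i: _BIOCLIM_CLUSTER[((i - 1) % 19) + 1] for i in range(1, cfg.n_bioclim + 1)}
    latents = []
    for _ in range(max(cluster_of.values()) + 1):
        theta = rng.uniform(0, 2 * np.pi)
        grad = np.cos(theta) * xn + np.sin(theta) * yn
        latents.append(unit(grad + 0.5 * _smooth_field(rng, shape)))
    layers = []
    deltas = []
    for name in names:
        is_soil = name in SOIL_VARS
        base = rng.uniform(-5, 25)
        scale = rng.uniform(2, 12)
        if is_soil:
            field_ = unit(
                _smooth_field(rng, shape, wavelengths=3)
                + cfg.noise_sd * rng.standard_normal(shape)
            )
        else:
            i = int(name[3:])
            unique = unit(
                _smooth_field(rng, shape) + cfg.noise_sd * rng.standard_normal(shape)
            )
            field_ = 0.96 * latents[cluster_of[i]] + 0.28 * unique
        layer = base + scale * field_
        layers.append(layer)
        if is_soil:
            deltas.append(np.zeros(shape))
        else:
            sd = layer[~mask].std()
            pattern = 1.0 + 0.3 * _smooth_field(rng, shape)
            deltas.append(cfg.future_shift_sd * sd * pattern)

    data = np.stack(layers)
    current = RasterStack(
        names=names, data=data, mask=mask, xll=cfg.xll, yll=cfg.yll,
        cell=cfg.cell_deg, epoch="current",
    )
    futures = {
        epoch: RasterStack(
            names=names, data=data + s * np.stack(deltas), mask=mask,
            xll=cfg.xll, yll=cfg.yll, cell=cfg.cell_deg, epoch=epoch,
        )
        for epoch, s in EPOCH_SCALE.items()
    }

    # populations: stratify along longitude over valid cells
    valid = np.flatnonzero(~mask.ravel())
    cols_of_valid = valid % cfg.grid_ncols
    order = np.argsort(cols_of_valid, kind="stable")
    strata = np.array_split(valid[order], cfg.n_pops)
    cells = np.array([rng.choice(s) for s in strata])
    rows, cols = cells // cfg.grid_ncols, cells % cfg.grid_ncols
    lat = current.ytop - (rows + 0.5) * cfg.cell_deg
    lon = cfg.xll + (cols + 0.5) * cfg.cell_deg
    n = rng.integers(cfg.ind_min, cfg.ind_max + 1, size=cfg.n_pops)
    pops = np.array([f"P{i + 1:02d}" for i in range(cfg.n_pops)], dtype=object)
    frame = PopulationFrame(pop=pops, lat=lat, lon=lon, n=n)

    groups = np.array_split(np.arange(cfg.n_pops), cfg.n_groups)
    group_of_pop = {}
    for gi, idx in enumerate(groups):
        for i in idx:
            group_of_pop[pops[i]] = f"G{gi + 1}"
    return SimulatedLandscape(current=current, futures=futures, frame=frame,
                              group_of_pop=group_of_pop)


# ---------------------------------------------------------------------------
# Allele frequencies and genotypes
# ---------------------------------------------------------------------------


def balding_nichols_freqs(
    p_anc: np.ndarray, fst: float, n_pops: int, rng: np.random.Generator
) -> np.ndarray:
    """Independent Balding-Nichols draws: (n_pops, n_loci) frequencies with
    E[p] = p_anc and Var[p] = F * p_anc * (1 - p_anc)."""
    p_anc = np.clip(np.asarray(p_anc, dtype=float), 1e-4, 1 - 1e-4)
    a = p_anc * (1 - fst) / fst
    b = (1 - p_anc) * (1 - fst) / fst
    return rng.beta(a[None, :], b[None, :], size=(n_pops, len(p_anc)))


def _copula_bn_freqs(
    p_centre: np.ndarray, fst: float, corr_chol: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Balding-Nichols marginals around ``p_centre`` (n_loci,) for the
    populations encoded by the Cholesky factor of a spatial correlation
    matrix; returns (n_pops, n_loci)."""
    p_centre = np.clip(p_centre, 1e-4, 1 - 1e-4)
    n_pops = corr_chol.shape[0]
    z = corr_chol @ rng.standard_normal((n_pops, len(p_centre)))
    u = np.clip(norm.cdf(z), 1e-12, 1 - 1e-12)
    a = p_centre * (1 - fst) / fst
    b = (1 - p_centre) * (1 - fst) / fst
    return beta_dist.ppf(u, a[None, :], b[None, :])


def simulate_genotypes(
    cfg: SynthConfig,
    env: EnvTable,
    frame: PopulationFrame,
    group_of_pop: dict[str, str],
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw genotypes for every individual plus the adaptive-locus truth table.

    Neutral loci: hierarchical Balding-Nichols (group level ``fst_between``,
    population level ``fst_within`` with spatial copula). Adaptive loci:
    population frequency = expit(alpha + beta * z(driver)). A fraction
    ``extra_snp_rate`` of loci receive a second linked SNP on the same RAD
    tag (redrawn from the same frequencies) to exercise the first-SNP rule.
    """
    rng = np.random.default_rng(cfg.seed + 1)
    if list(env.pops) != list(frame.pop):
        raise ValueError("env rows must match the population frame")
    n_pops = frame.n_pops
    groups = sorted(set(group_of_pop.values()))
    pop_group = np.array([group_of_pop[p] for p in frame.pop], dtype=object)

    d_km = geo_distance_matrix(frame)
    chol_of_group = {}
    for gname in groups:
        idx = np.flatnonzero(pop_group == gname)
        corr = np.exp(-d_km[np.ix_(idx, idx)] / cfg.ibd_range_km)
        chol_of_group[gname] = (idx, np.linalg.cholesky(corr + 1e-9 * np.eye(len(idx))))

    # neutral frequencies
    p_anc = rng.uniform(0.05, 0.95, size=cfg.n_neutral)
    p_group = {
        gname: balding_nichols_freqs(p_anc, cfg.fst_between, 1, rng)[0]
        for gname in groups
    }
    p_neutral = np.empty((n_pops, cfg.n_neutral))
    for gname in groups:
        idx, chol = chol_of_group[gname]
        p_neutral[idx] = _copula_bn_freqs(p_group[gname], cfg.fst_within, chol, rng)

    # adaptive cline frequencies
    truth_rows = []
    p_adapt = np.empty((n_pops, cfg.n_adaptive))
    for j in range(cfg.n_adaptive):
        driver = cfg.driver_vars[j % len(cfg.driver_vars)]
        x = env.column(driver)
        z = (x - x.mean()) / x.std()
        b = rng.uniform(cfg.beta_min, cfg.beta_max) * rng.choice([-1.0, 1.0])
        alpha = logit(rng.uniform(0.25, 0.75))
        p_adapt[:, j] = expit(alpha + b * z)
        truth_rows.append({"driver": driver, "beta": b, "alpha": alpha})

    p_all = np.hstack([p_neutral, p_adapt])
    n_loci = p_all.shape[1]
    tags = np.array([f"tag{i + 1:05d}" for i in range(n_loci)], dtype=object)

    # linked second SNPs on a subset of tags (same frequency, fresh draw)
    extra = np.flatnonzero(rng.random(n_loci) < cfg.extra_snp_rate)
    p_full = np.hstack([p_all, p_all[:, extra]])
    chrom = np.concatenate([tags, tags[extra]])
    pos = np.concatenate(
        [np.full(n_loci, 10, dtype=np.int64), np.full(len(extra), 42, dtype=np.int64)]
    )
    is_adaptive = np.zeros(p_full.shape[1], dtype=bool)
    is_adaptive[cfg.n_neutral : n_loci] = True

    # genotypes
    ind_ids, ind_pop = [], []
    rows = []
    for i, pop in enumerate(frame.pop):
        k = int(frame.n[i])
        g = rng.binomial(2, np.clip(p_full[i], 0, 1), size=(k, p_full.shape[1]))
        rows.append(g)
        ind_ids += [f"{pop}_{j + 1:02d}" for j in range(k)]
        ind_pop += [pop] * k
    dos = np.vstack(rows).astype(np.int16)
    miss = rng.random(dos.shape) < cfg.missing_rate
    dos[miss] = MISSING

    g = GenotypeMatrix(
        dosages=dos,
        locus_chrom=chrom,
        locus_pos=pos,
        individual_ids=np.array(ind_ids, dtype=object),
        pop_of_individual=np.array(ind_pop, dtype=object),
    )
    truth = pd.DataFrame(truth_rows)
    truth.insert(
        0,
        "locus_id",
        [f"{tags[cfg.n_neutral + j]}:10" for j in range(cfg.n_adaptive)],
    )
    return g, truth


# ---------------------------------------------------------------------------
# Full dataset on disk
# ---------------------------------------------------------------------------


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    truth: pd.DataFrame
    env: EnvTable
    landscape: SimulatedLandscape


def env_classes(names: list[str]) -> dict[str, str]:
    return {n: ("soil" if n in SOIL_VARS else "bioclim") for n in names}


def final_env_variables(cfg: SynthConfig) -> tuple[str, ...]:
    """The ten-variable registry the emulated study retained after
    collinearity pruning: the driver climate variables plus isothermality
    and the five soil factors."""
    climate = tuple(dict.fromkeys(cfg.driver_vars + ("bio3",)))
    return climate + SOIL_VARS


def simulate_dataset(cfg: SynthConfig) -> SimulatedDataset:
    """Landscape, per-population environment and genotypes in one call."""
    from .genio import extract_env_at_points

    scape = simulate_landscape(cfg)
    env = extract_env_at_points(
        scape.current, scape.frame, classes=env_classes(scape.current.names)
    )
    g, truth = simulate_genotypes(cfg, env, scape.frame, scape.group_of_pop)
    return SimulatedDataset(genotypes=g, truth=truth, env=env, landscape=scape)


def write_dataset(cfg: SynthConfig, outdir: str | Path) -> SimulatedDataset:
    """Write the full external format set: VCF + popmap, population CSV,
    env CSV, per-epoch ASCII-grid rasters, truth-table CSV and group map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ds = simulate_dataset(cfg)
    write_vcf(ds.genotypes, outdir / "genotypes.vcf")
    write_popmap(ds.genotypes, outdir / "popmap.tsv")
    ds.landscape.frame.to_csv(outdir / "populations.csv")
    ds.env.to_csv(outdir / "env_current.csv")
    write_raster_stack(ds.landscape.current, outdir / "rasters" / "current")
    for epoch, stack in ds.landscape.futures.items():
        write_raster_stack(stack, outdir / "rasters" / epoch)
    ds.truth.to_csv(outdir / "adaptive_truth.csv", index=False)
    pd.DataFrame(
        sorted(ds.landscape.group_of_pop.items()), columns=["pop", "group"]
    ).to_csv(outdir / "groups.csv", index=False)
    return ds
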