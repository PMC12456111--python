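"""Readers, writers and core containers for the formats the pipeline touches.

Genotypes travel as a dense dosage matrix (individuals x loci, alternate-allele
counts 0/1/2 with a dedicated missing sentinel), populations as a small
coordinate frame, per-population environment as a table with a variable
registry, and gridded climate as stacks of ESRI ASCII grids sharing one
geotransform and nodata mask.

Conventions
-----------
* VCF coordinates are 1-based; internally everything is 0-based half-open.
* Raster row 0 is the north edge; a point maps to the cell whose half-open
  interval contains it (floor of the offset divided by the cell size).
* The missing-dosage sentinel is ``MISSING`` (-1), never 0 — 0 is a legal
  homozygote.
* The locus-group identifier used by the "first SNP per locus" filter is the
  VCF CHROM field, which is where de-novo RAD tags end up.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("landgen")

MISSING: int = -1

EPOCHS = (
    "current",
    "SSP126_2041_2060",
    "SSP126_2061_2080",
    "SSP585_2041_2060",
    "SSP585_2061_2080",
)

VARIABLE_CLASSES = ("bioclim", "soil", "spatial", "structure")


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Biallelic dosages for diploid individuals grouped into populations.

    dosages[i, l] is the alternate-allele count (0/1/2) of individual ``i``
    at locus ``l``, or ``MISSING``.
    """

    dosages: np.ndarray                      # (n_ind, n_loci) int16
    locus_chrom: np.ndarray                  # (n_loci,) str — locus-group id
    locus_pos: np.ndarray                    # (n_loci,) int
    individual_ids: np.ndarray               # (n_ind,) str
    pop_of_individual: np.ndarray            # (n_ind,) str
    ploidy: int = 2

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int16)
        self.locus_chrom = np.asarray(self.locus_chrom, dtype=object)
        self.locus_pos = np.asarray(self.locus_pos, dtype=np.int64)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.pop_of_individual = np.asarray(self.pop_of_individual, dtype=object)
        ok = (self.dosages == MISSING) | (
            (self.dosages >= 0) & (self.dosages <= self.ploidy)
        )
        if not ok.all():
            raise ValueError("dosages must be 0..ploidy or the missing sentinel")
        ids = self.locus_ids
        if len(set(ids)) != len(ids):
            raise ValueError("locus ids are not unique")
        if self.dosages.shape != (len(self.individual_ids), len(self.locus_chrom)):
            raise ValueError("dosage shape does not match id vectors")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosages.shape[1]

    @property
    def locus_ids(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.locus_chrom, self.locus_pos)]

    @property
    def pop_labels(self) -> list[str]:
        """Population labels in order of first appearance."""
        seen: dict[str, None] = {}
        for p in self.pop_of_individual:
            seen.setdefault(p, None)
        return list(seen)

    def pop_indices(self) -> dict[str, np.ndarray]:
        return {
            p: np.flatnonzero(self.pop_of_individual == p) for p in self.pop_labels
        }

    def take_loci(self, idx: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            dosages=self.dosages[:, idx],
            locus_chrom=self.locus_chrom[idx],
            locus_pos=self.locus_pos[idx],
        )

    def take_individuals(self, idx: np.ndarray) -> "GenotypeMatrix":
        return replace(
            self,
            dosages=self.dosages[idx],
            individual_ids=self.individual_ids[idx],
            pop_of_individual=self.pop_of_individual[idx],
        )


@dataclass
class PopulationFrame:
    """Population labels with WGS84 coordinates and sample sizes."""

    pop: np.ndarray        # (n_pops,) str
    lat: np.ndarray        # decimal degrees
    lon: np.ndarray
    n: np.ndarray          # individuals sampled

    def __post_init__(self) -> None:
        self.pop = np.asarray(self.pop, dtype=object)
        self.lat = np.asarray(self.lat, dtype=float)
        self.lon = np.asarray(self.lon, dtype=float)
        self.n = np.asarray(self.n, dtype=int)
        if len(set(self.pop)) != len(self.pop):
            raise ValueError("population labels are not unique")
        if np.any(np.abs(self.lat) > 90) or np.any(np.abs(self.lon) > 180):
            raise ValueError("coordinates outside WGS84 bounds")
        if np.any(self.n < 1):
            raise ValueError("sample sizes must be >= 1")

    @property
    def n_pops(self) -> int:
        return len(self.pop)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"pop": self.pop, "lat": self.lat, "lon": self.lon, "n": self.n}
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "PopulationFrame":
        df = pd.read_csv(path)
        return cls(
            pop=df["pop"].to_numpy(),
            lat=df["lat"].to_numpy(),
            lon=df["lon"].to_numpy(),
            n=df["n"].to_numpy(),
        )


@dataclass
class EnvTable:
    """Per-population environmental values plus a variable registry."""

    pops: np.ndarray                 # (n_pops,) str, row order
    variables: np.ndarray            # (n_vars,) str
    classes: dict[str, str]          # variable -> class
    values: np.ndarray               # (n_pops, n_vars) float

    def __post_init__(self) -> None:
        self.pops = np.asarray(self.pops, dtype=object)
        self.variables = np.asarray(self.variables, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.variables)) != len(self.variables):
            raise ValueError("variable names are not unique")
        if self.values.shape != (len(self.pops), len(self.variables)):
            raise ValueError("value matrix shape mismatch")
        if np.isnan(self.values).any():
            raise ValueError("EnvTable may not contain missing values")
        for v in self.variables:
            if self.classes.get(v) not in VARIABLE_CLASSES:
                raise ValueError(f"variable {v!r} has no valid class")

    @property
    def n_pops(self) -> int:
        return len(self.pops)

    def select(self, names: Sequence[str]) -> "EnvTable":
        idx = [list(self.variables).index(n) for n in names]
        return EnvTable(
            pops=self.pops,
            variables=self.variables[idx],
            classes={n: self.classes[n] for n in names},
            values=self.values[:, idx],
        )

    def select_class(self, klass: str) -> "EnvTable":
        names = [v for v in self.variables if self.classes[v] == klass]
        return self.select(names)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, list(self.variables).index(name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.variables))
        df.insert(0, "pop", self.pops)
        return df

    def to_csv(self, path: str | Path) -> None:
        df = self.to_frame()
        # second header row carries the variable class registry
        classes = ["class"] + [self.classes[v] for v in self.variables]
        with open(path, "w") as fh:
            fh.write(",".join(["pop"] + list(self.variables)) + "\n")
            fh.write(",".join(classes) + "\n")
        df.to_csv(path, mode="a", header=False, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "EnvTable":
        with open(path) as fh:
            header = fh.readline().strip().split(",")
            class_row = fh.readline().strip().split(",")
        if class_row[0] != "class":
            raise ValueError(f"{path}: expected a 'class' registry row")
        variables = header[1:]
        classes = dict(zip(variables, class_row[1:]))
        df = pd.read_csv(path, skiprows=2, names=header)
        return cls(
            pops=df["pop"].to_numpy(),
            variables=np.array(variables, dtype=object),
            classes=classes,
            values=df[variables].to_numpy(dtype=float),
        )


@dataclass
class RasterStack:
    """Co-registered gridded layers with one shared nodata mask.

    ``data`` has shape (n_layers, nrows, ncols); row 0 is the north edge.
    ``xll``/``yll`` are the coordinates of the lower-left grid corner and
    ``cell`` the (square) cell size, in the same units as the population
    coordinates (decimal degrees for the synthetic landscapes).
    """

    names: list[str]
    data: np.ndarray            # (n_layers, nrows, ncols) float
    mask: np.ndarray            # (nrows, ncols) bool, True = nodata
    xll: float
    yll: float
    cell: float
    crs: str = "EPSG:4326"
    epoch: str = "current"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3 or self.data.shape[0] != len(self.names):
            raise ValueError("data must be (n_layers, nrows, ncols)")
        if self.mask.shape != self.data.shape[1:]:
            raise ValueError("mask shape mismatch")
        if self.epoch not in EPOCHS:
            raise ValueError(f"unknown epoch {self.epoch!r}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]

    @property
    def nrows(self) -> int:
        return self.data.shape[1]

    @property
    def ncols(self) -> int:
        return self.data.shape[2]

    @property
    def ytop(self) -> float:
        return self.yll + self.nrows * self.cell

    def layer(self, name: str) -> np.ndarray:
        return self.data[self.names.index(name)]

    def select(self, names: Sequence[str]) -> "RasterStack":
        idx = [self.names.index(n) for n in names]
        return RasterStack(
            names=list(names),
            data=self.data[idx],
            mask=self.mask,
            xll=self.xll,
            yll=self.yll,
            cell=self.cell,
            crs=self.crs,
            epoch=self.epoch,
        )

    def cell_of(self, lat: float, lon: float) -> tuple[int, int]:
        """Half-open cell lookup; raises if the point is outside the grid."""
        col = int(np.floor((lon - self.xll) / self.cell))
        row = int(np.floor((self.ytop - lat) / self.cell))
        if not (0 <= row < self.nrows and 0 <= col < self.ncols):
            raise ValueError(f"point ({lat}, {lon}) falls outside the grid")
        return row, col

    def cell_centres(self) -> tuple[np.ndarray, np.ndarray]:
        """(lat, lon) of every cell centre, each of shape (nrows, ncols)."""
        lon = self.xll + (np.arange(self.ncols) + 0.5) * self.cell
        lat = self.ytop - (np.arange(self.nrows) + 0.5) * self.cell
        return np.broadcast_to(lat[:, None], self.shape).copy(), np.broadcast_to(
            lon[None, :], self.shape
        ).copy()


# ---------------------------------------------------------------------------
# VCF + popmap
# ---------------------------------------------------------------------------


def read_popmap(path: str | Path) -> dict[str, str]:
    """Stacks-style two-column tab-separated individual -> population map."""
    df = pd.read_csv(path, sep="\t", header=None, names=["individual", "pop"],
                     dtype=str, comment="#")
    if df["individual"].duplicated().any():
        dups = df.loc[df["individual"].duplicated(), "individual"].tolist()
        raise ValueError(f"duplicate individuals in popmap: {dups}")
    return dict(zip(df["individual"], df["pop"]))


def read_vcf_genotypes(vcf_path: str | Path, popmap_path: str | Path) -> GenotypeMatrix:
    """Load biallelic GT dosages from a VCF plus a population map.

    Multi-allelic records are rejected with a logged count; ``./.`` becomes
    the missing sentinel; individuals in the VCF but absent from the popmap
    raise an error naming them.
    """
    from cyvcf2 import VCF

    popmap = read_popmap(popmap_path)
    vcf = VCF(str(vcf_path), gts012=True)
    samples = list(vcf.samples)
    unknown = [s for s in samples if s not in popmap]
    if unknown:
        raise ValueError(
            f"individuals in VCF missing from popmap: {', '.join(unknown)}"
        )
    chroms: list[str] = []
    poss: list[int] = []
    cols: list[np.ndarray] = []
    n_multi = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        # gts012: 0/1/2 dosage, 3 = unknown
        d = np.asarray(var.gt_types, dtype=np.int16)
        d[d == 3] = MISSING
        chroms.append(str(var.CHROM))
        poss.append(int(var.POS))
        cols.append(d)
    if n_multi:
        logger.info("rejected %d multi-allelic records", n_multi)
    if not cols:
        raise ValueError(f"no biallelic records found in {vcf_path}")
    return GenotypeMatrix(
        dosages=np.stack(cols, axis=1),
        locus_chrom=np.array(chroms, dtype=object),
        locus_pos=np.array(poss),
        individual_ids=np.array(samples, dtype=object),
        pop_of_individual=np.array([popmap[s] for s in samples], dtype=object),
    )


def write_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as a minimal VCF 4.2 with GT fields only."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in dict.fromkeys(g.locus_chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.individual_ids)
            + "\n"
        )
        for l in range(g.n_loci):
            gts = "\t".join(gt_of[int(d)] for d in g.dosages[:, l])
            fh.write(
                f"{g.locus_chrom[l]}\t{g.locus_pos[l]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_popmap(g: GenotypeMatrix, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind, pop in zip(g.individual_ids, g.pop_of_individual):
            fh.write(f"{ind}\t{pop}\n")


def read_dosage_tsv(path: str | Path, popmap_path: str | Path) -> GenotypeMatrix:
    """Fallback reader: loci x individuals TSV of dosages (NA = missing).

    First column is the locus id in ``chrom:pos`` form; remaining columns are
    individuals. Covers SNP deposits that are not distributed as VCF.
    """
    popmap = read_popmap(popmap_path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    unknown = [s for s in df.columns if s not in popmap]
    if unknown:
        raise ValueError(
            f"individuals in dosage table missing from popmap: {', '.join(unknown)}"
        )
    chroms, poss = zip(*(i.split(":") for i in df.index))
    d = df.to_numpy(dtype=float).T
    d = np.where(np.isnan(d), MISSING, d).astype(np.int16)
    return GenotypeMatrix(
        dosages=d,
        locus_chrom=np.array(chroms, dtype=object),
        locus_pos=np.array([int(p) for p in poss]),
        individual_ids=np.array(list(df.columns), dtype=object),
        pop_of_individual=np.array([popmap[s] for s in df.columns], dtype=object),
    )


# ---------------------------------------------------------------------------
# ESRI ASCII grid rasters
# ---------------------------------------------------------------------------

_NODATA = -9999.0


def write_ascii_grid(
    arr: np.ndarray, mask: np.ndarray, xll: float, yll: float, cell: float,
    path: str | Path,
) -> None:
    nrows, ncols = arr.shape
    out = np.where(mask, _NODATA, arr)
    with open(path, "w") as fh:
        fh.write(f"ncols {ncols}\n")
        fh.write(f"nrows {nrows}\n")
        fh.write(f"xllcorner {xll!r}\n")
        fh.write(f"yllcorner {yll!r}\n")
        fh.write(f"cellsize {cell!r}\n")
        fh.write(f"NODATA_value {_NODATA}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def read_ascii_grid(path: str | Path) -> tuple[np.ndarray, np.ndarray, float, float, float]:
    """Returns (data, mask, xll, yll, cellsize). Mask is True on nodata."""
    header: dict[str, float] = {}
    with open(path) as fh:
        lines = fh.readlines()
    for i, line in enumerate(lines[:6]):
        key, val = line.split()
        header[key.lower()] = float(val)
    need = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not need <= set(header):
        raise ValueError(f"{path}: malformed ASCII grid header")
    nodata = header.get("nodata_value", _NODATA)
    data = np.array(
        [[float(v) for v in line.split()] for line in lines[len(header):]]
    )
    if data.shape != (int(header["nrows"]), int(header["ncols"])):
        raise ValueError(f"{path}: grid body does not match header dimensions")
    mask = data == nodata
    return data, mask, header["xllcorner"], header["yllcorner"], header["cellsize"]


def read_raster_stack(
    paths: Mapping[str, str | Path], epoch: str = "current"
) -> RasterStack:
    """Read named ASCII-grid layers into one stack.

    The shared mask is the union of the per-layer nodata masks; a layer on a
    different grid raises an error naming it.
    """
    names, layers, masks = [], [], []
    geo: tuple[float, float, float] | None = None
    shape: tuple[int, int] | None = None
    for name, path in paths.items():
        data, mask, xll, yll, cell = read_ascii_grid(path)
        if geo is None:
            geo, shape = (xll, yll, cell), data.shape
        elif data.shape != shape or not np.allclose(geo, (xll, yll, cell)):
            raise ValueError(f"layer {name!r} is not on the shared grid")
        names.append(name)
        layers.append(data)
        masks.append(mask)
    if geo is None:
        raise ValueError("no layers given")
    mask = np.logical_or.reduce(masks)
    return RasterStack(
        names=names, data=np.stack(layers), mask=mask,
        xll=geo[0], yll=geo[1], cell=geo[2], epoch=epoch,
    )


def write_raster_stack(stack: RasterStack, outdir: str | Path) -> dict[str, Path]:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in stack.names:
        p = outdir / f"{name}.asc"
        write_ascii_grid(stack.layer(name), stack.mask, stack.xll, stack.yll,
                         stack.cell, p)
        paths[name] = p
    return paths


def resample_bilinear(stack: RasterStack, like: RasterStack) -> RasterStack:
    """Bilinearly resample a stack onto the grid of ``like``.

    Used when future layers ship at a coarser resolution than the current
    ones. Nodata cells are filled with the layer mean before interpolation
    and the mask is carried over by nearest neighbour.
    """
    from scipy.ndimage import map_coordinates

    if stack.shape == like.shape and np.allclose(
        (stack.xll, stack.yll, stack.cell), (like.xll, like.yll, like.cell)
    ):
        return stack
    lat, lon = like.cell_centres()
    rows = (stack.ytop - lat) / stack.cell - 0.5
    cols = (lon - stack.xll) / stack.cell - 0.5
    coords = np.stack([rows.ravel(), cols.ravel()])
    layers = []
    for j in range(len(stack.names)):
        layer = stack.data[j].copy()
        if stack.mask.any():
            layer[stack.mask] = layer[~stack.mask].mean()
        layers.append(
            map_coordinates(layer, coords, order=1, mode="nearest").reshape(
                like.shape
            )
        )
    mask = map_coordinates(
        stack.mask.astype(float), coords, order=0, mode="nearest"
    ).reshape(like.shape) > 0.5
    logger.info(
        "resampled %s stack from %s to %s (bilinear)",
        stack.epoch, stack.shape, like.shape,
    )
    return RasterStack(
        names=list(stack.names), data=np.stack(layers), mask=mask | like.mask,
        xll=like.xll, yll=like.yll, cell=like.cell, crs=like.crs,
        epoch=stack.epoch,
    )


def extract_env_at_points(
    stack: RasterStack, frame: PopulationFrame, classes: Mapping[str, str] | None = None
) -> EnvTable:
    """Sample each layer at the cell containing each population (no
    interpolation). A population falling on a nodata cell raises an error
    naming it."""
    values = np.empty((frame.n_pops, len(stack.names)))
    for i in range(frame.n_pops):
        row, col = stack.cell_of(frame.lat[i], frame.lon[i])
        if stack.mask[row, col]:
            raise ValueError(f"population {frame.pop[i]!r} falls on a nodata cell")
        values[i] = stack.data[:, row, col]
    if classes is None:
        classes = {n: "bioclim" for n in stack.names}
    return EnvTable(
        pops=frame.pop,
        variables=np.array(stack.names, dtype=object),
        classes=dict(classes),
        values=values,
    )


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Thresholds and sizes governing a pipeline run.

    Defaults mirror the analysis this package implements: MAF >= 0.05, max
    observed heterozygosity 0.5, presence in >= 85 % of individuals and >= 19
    populations, first SNP per RAD locus; K = 3 latent factors / genetic
    groups; RDA loading cutoff 3 SD; BH FDR 0.05; |r| > 0.75 variable
    pruning; migration radii 50/100/200/500 km and unlimited; 500 trees per
    SNP; 999 permutations.
    """

    maf_min: float = 0.05
    max_obs_het: float = 0.5
    min_individual_presence: float = 0.85
    min_populations: int = 19
    k_latent: int = 3
    n_groups: int = 3
    rda_sd_cutoff: float = 3.0
    fdr_alpha: float = 0.05
    corr_prune: float = 0.75
    fdist_n_sims: int = 1_000_000
    fdist_top_fraction: float = 0.01
    migration_radii_km: tuple[float, ...] = (50.0, 100.0, 200.0, 500.0, float("inf"))
    n_trees: int = 500
    gf_max_loci: int = 150
    n_permutations: int = 999
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.maf_min <= 0.5:
            raise ValueError("maf_min out of range")
        if not 0 < self.min_individual_presence <= 1:
            raise ValueError("min_individual_presence out of range")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha out of range")
        if self.min_populations < 1 or self.k_latent < 1:
            raise ValueError("counts must be positive")
        self.migration_radii_km = tuple(float(r) for r in self.migration_radii_km)

    def to_yaml(self, path: str | Path) -> None:
        d = self.__dict__.copy()
        d["migration_radii_km"] = [
            "inf" if np.isinf(r) else r for r in d["migration_radii_km"]
        ]
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "migration_radii_km" in d:
            d["migration_radii_km"] = tuple(
                float(r) for r in d["migration_radii_km"]
            )
        return cls(**d)


def setup_logging(logfile: str | Path | None = None, seed: int | None = None) -> None:
    """Structured log with the seed echoed at the top of every run."""
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if logfile is not None:
        handlers.append(logging.FileHandler(logfile))
    logging.basicConfig(
        level=logging.INFO,
        format="%(asctime)s %(name)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )
    if seed is not None:
        logger.info("rng_seed=%d", seed)
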