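"""End-to-end orchestration of the landscape-genomics stage graph.

Stages: simulate -> filter -> outliers -> envprep -> stats -> spatial ->
ibd_ibe -> varpart -> gea -> gf -> offset -> rona. Every stage reads its
inputs from files under the run directory and writes file outputs, so runs
are resumable: a stage is skipped when its content hash (config + input
files) matches the stored manifest and its outputs exist; a stage that does
run marks its descendants dirty.
"""

from __future__ import annotations

import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import genio, synthdata
from .gea import gea_scan, gea_scan_by_group, imputed_freq_matrix
from .genio import EnvTable, RunConfig, read_raster_stack
from .neutral_scan import fdist_scan, partition, pc_scan, read_external_flags
from .offsets import offset_surface, rgb_composite, rona
from .ordination import env_pca_distance, variance_partition
from .popstats import (
    allele_freq_table,
    diversity,
    filter_snps,
    genotype_pca,
    pairwise_fst,
)
from .spatial import build_mems, geo_distance_matrix, mantel
from .turnover import fit_gradient_forest, prune_variables
from .synthdata import SynthConfig

logger = logging.getLogger("landgen")

STAGES = [
    "simulate", "filter", "outliers", "envprep", "stats", "spatial",
    "ibd_ibe", "gea", "varpart", "gf", "offset", "rona",
]

DEPS: dict[str, list[str]] = {
    "simulate": [],
    "filter": ["simulate"],
    "outliers": ["filter"],
    "envprep": ["outliers"],
    "stats": ["outliers"],
    "spatial": ["simulate"],
    "ibd_ibe": ["stats", "spatial"],
    "gea": ["outliers", "envprep"],
    "varpart": ["stats", "spatial", "envprep", "gea"],
    "gf": ["gea", "envprep"],
    "offset": ["gf"],
    "rona": ["gea"],
}


@dataclass
class StageGraph:
    run_dir: Path
    status: dict[str, str] = field(default_factory=dict)   # ran | cached
    outputs: dict[str, list[str]] = field(default_factory=dict)


def _hash_paths(paths: list[Path]) -> str:
    h = hashlib.sha256()
    for p in sorted(paths):
        h.update(str(p.name).encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def _tree_files(root: Path) -> list[Path]:
    return [p for p in sorted(root.rglob("*")) if p.is_file()]


class Pipeline:
    """Runs the stage graph inside one run directory."""

    def __init__(
        self,
        run_dir: str | Path,
        cfg: RunConfig | None = None,
        synth: SynthConfig | None = None,
        data_dir: str | Path | None = None,
    ) -> None:
        self.run_dir = Path(run_dir)
        self.run_dir.mkdir(parents=True, exist_ok=True)
        self.cfg = cfg or RunConfig()
        self.synth = synth
        self.data_dir = Path(data_dir) if data_dir else self.run_dir / "data"
        self.manifest_path = self.run_dir / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists()
            else {"stages": {}}
        )

    # -- caching machinery -------------------------------------------------

    def _cfg_blob(self) -> str:
        synth = yaml.safe_dump(self.synth.__dict__) if self.synth else "external"
        cfg = {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in self.cfg.__dict__.items()
        }
        return yaml.safe_dump(cfg) + synth

    def _stage_dir(self, stage: str) -> Path:
        return self.data_dir if stage == "simulate" else self.run_dir / stage

    def _stage_hash(self, stage: str) -> str:
        h = hashlib.sha256(self._cfg_blob().encode())
        h.update(stage.encode())
        for dep in DEPS[stage]:
            dep_dir = self._stage_dir(dep)
            if dep_dir.exists():
                h.update(_hash_paths(_tree_files(dep_dir)).encode())
        return h.hexdigest()

    def run(self, until: str | None = None) -> StageGraph:
        graph = StageGraph(run_dir=self.run_dir)
        dirty: set[str] = set()
        wanted = STAGES[: STAGES.index(until) + 1] if until else STAGES
        for stage in wanted:
            if stage == "simulate" and self.synth is None:
                if not self.data_dir.exists():
                    raise FileNotFoundError(
                        f"no synthetic config and no data at {self.data_dir}"
                    )
                graph.status[stage] = "external"
                continue
            out_dir = self._stage_dir(stage)
            want_hash = self._stage_hash(stage)
            stored = self.manifest["stages"].get(stage)
            fresh = (
                stored is not None
                and stored["hash"] == want_hash
                and out_dir.exists()
                and all((self.run_dir / f).exists() for f in stored["outputs"])
                and not (set(DEPS[stage]) & dirty)
            )
            if fresh:
                graph.status[stage] = "cached"
                graph.outputs[stage] = stored["outputs"]
                continue
            logger.info("stage %s: running", stage)
            try:
                getattr(self, f"_run_{stage}")(out_dir)
            except Exception as err:
                raise RuntimeError(
                    f"stage {stage!r} failed (see log); cause: {err}"
                ) from err
            dirty.add(stage)
            outputs = [
                str(p.relative_to(self.run_dir))
                for p in _tree_files(out_dir)
            ] if out_dir.exists() else []
            self.manifest["stages"][stage] = {
                "hash": self._stage_hash(stage),
                "outputs": outputs,
            }
            self.manifest["seed"] = self.cfg.rng_seed
            self.manifest_path.write_text(json.dumps(self.manifest, indent=1))
            graph.status[stage] = "ran"
            graph.outputs[stage] = outputs
        return graph

    # -- shared loaders ----------------------------------------------------

    def _load_filtered(self):
        return genio.read_vcf_genotypes(
            self.run_dir / "filter" / "genotypes.vcf",
            self.run_dir / "filter" / "popmap.tsv",
        )

    def _load_frame(self):
        return genio.PopulationFrame.from_csv(self.data_dir / "populations.csv")

    def _load_env(self) -> EnvTable:
        return EnvTable.from_csv(self.data_dir / "env_current.csv")

    def _load_env_pruned(self) -> EnvTable:
        return EnvTable.from_csv(self.run_dir / "envprep" / "env_pruned.csv")

    def _neutral_ids(self) -> list[str]:
        return (
            (self.run_dir / "outliers" / "neutral_ids.txt")
            .read_text()
            .splitlines()
        )

    def _neutral_matrix(self):
        g = self._load_filtered()
        keep = set(self._neutral_ids())
        idx = np.array([l in keep for l in g.locus_ids])
        return g.take_loci(np.flatnonzero(idx))

    def _raster_stack(self, epoch: str, names: list[str]):
        root = self.data_dir / "rasters" / epoch
        return read_raster_stack(
            {n: root / f"{n}.asc" for n in names}, epoch=epoch
        )

    def _future_epochs(self) -> list[str]:
        root = self.data_dir / "rasters"
        return sorted(
            d.name for d in root.iterdir() if d.is_dir() and d.name != "current"
        )

    # -- stages ------------------------------------------------------------

    def _run_simulate(self, out: Path) -> None:
        if out.exists():
            shutil.rmtree(out)
        synthdata.write_dataset(self.synth, out)

    def _run_filter(self, out: Path) -> None:
        g = genio.read_vcf_genotypes(
            self.data_dir / "genotypes.vcf", self.data_dir / "popmap.tsv"
        )
        filt, report = filter_snps(g, self.cfg)
        out.mkdir(exist_ok=True)
        genio.write_vcf(filt, out / "genotypes.vcf")
        genio.write_popmap(filt, out / "popmap.tsv")
        (out / "filter_report.json").write_text(json.dumps(report.__dict__))

    def _run_outliers(self, out: Path) -> None:
        g = self._load_filtered()
        pc = pc_scan(g, k=self.cfg.k_latent, alpha=self.cfg.fdr_alpha,
                     seed=self.cfg.rng_seed)
        fd = fdist_scan(
            g, n_sims=self.cfg.fdist_n_sims, alpha=self.cfg.fdr_alpha,
            top_fraction=self.cfg.fdist_top_fraction, seed=self.cfg.rng_seed,
        )
        flags = {"pc_scan": pc.flagged_ids(), "fdist_scan": fd.flagged_ids()}
        external = self.data_dir / "external_flags.tsv"
        if external.exists():
            flags["external"] = read_external_flags(external)
        report = partition(g.locus_ids, flags)
        out.mkdir(exist_ok=True)
        table = report.table.copy()
        table["pc_p"], table["pc_q"] = pc.p, pc.q
        table["fdist_p"], table["fdist_q"] = fd.p, fd.q
        table.to_csv(out / "outlier_report.csv", index_label="locus_id")
        (out / "neutral_ids.txt").write_text("\n".join(report.neutral_ids))
        (out / "outlier_ids.txt").write_text("\n".join(report.outlier_ids))

    def _run_envprep(self, out: Path) -> None:
        env = self._load_env()
        g = self._neutral_matrix()
        freqs = allele_freq_table(g)
        y = imputed_freq_matrix(freqs)
        rng = np.random.default_rng(self.cfg.rng_seed)
        n_rank = min(self.cfg.gf_max_loci, y.shape[1])
        cols = rng.choice(y.shape[1], size=n_rank, replace=False)
        model = fit_gradient_forest(
            y[:, cols], env,
            locus_ids=[freqs.locus_ids[c] for c in cols],
            n_trees=self.cfg.n_trees, seed=self.cfg.rng_seed,
        )
        pruned = prune_variables(env, model.importance, self.cfg.corr_prune)
        out.mkdir(exist_ok=True)
        pruned.to_csv(out / "env_pruned.csv")
        pd.Series(model.importance).to_csv(
            out / "gf_rank_importance.csv", header=["importance"]
        )

    def _run_stats(self, out: Path) -> None:
        g = self._neutral_matrix()
        out.mkdir(exist_ok=True)
        diversity(g).to_frame().to_csv(out / "diversity.csv", index=False)
        pairwise_fst(g).to_frame().to_csv(out / "fst.csv")
        pca = genotype_pca(g)
        pd.DataFrame(
            pca.scores[:, :10],
            columns=[f"PC{i+1}" for i in range(min(10, pca.scores.shape[1]))],
            index=g.individual_ids,
        ).to_csv(out / "pca_scores.csv", index_label="individual")
        pop_scores = pd.DataFrame(
            pca.pop_scores, columns=[f"PC{i+1}" for i in range(pca.pop_scores.shape[1])]
        )
        pop_scores.insert(0, "pop", pca.pop_labels)
        pop_scores.to_csv(out / "pca_pop_scores.csv", index=False)
        pd.DataFrame(
            {"eigenvalue": pca.eigenvalues, "var_fraction": pca.var_fractions}
        ).to_csv(out / "pca_eigen.csv", index=False)

    def _run_spatial(self, out: Path) -> None:
        frame = self._load_frame()
        out.mkdir(exist_ok=True)
        d = geo_distance_matrix(frame)
        pd.DataFrame(d, index=frame.pop, columns=frame.pop).to_csv(
            out / "geo_km.csv"
        )
        mems = build_mems(frame, n_permutations=self.cfg.n_permutations,
                          seed=self.cfg.rng_seed)
        mem_df = pd.DataFrame(
            mems.vectors,
            columns=[f"MEM{i+1}" for i in range(mems.n_vectors)],
        )
        mem_df.insert(0, "pop", frame.pop)
        mem_df.to_csv(out / "mems.csv", index=False)
        pd.DataFrame(
            {"eigenvalue": mems.eigenvalues, "moran_i": mems.moran_i,
             "moran_p": mems.moran_p}
        ).to_csv(out / "mem_tests.csv", index=False)

    def _run_ibd_ibe(self, out: Path) -> None:
        frame = self._load_frame()
        fst = pd.read_csv(self.run_dir / "stats" / "fst.csv", index_col=0)
        fst = fst.loc[frame.pop, frame.pop].to_numpy()
        fst = np.nan_to_num(fst, nan=float(np.nanmean(fst)))
        env = self._load_env()
        rows = []
        geo = geo_distance_matrix(frame)
        for name, dmat in (
            ("ibd", geo),
            ("ibe_climate", env_pca_distance(env, "bioclim")),
            ("ibe_soil", env_pca_distance(env, "soil")),
        ):
            r, p = mantel(fst, dmat, n_permutations=self.cfg.n_permutations,
                          seed=self.cfg.rng_seed)
            rows.append({"test": name, "r": r, "p": p})
        out.mkdir(exist_ok=True)
        pd.DataFrame(rows).to_csv(out / "mantel.csv", index=False)

    def _run_varpart(self, out: Path) -> None:
        frame = self._load_frame()
        env = self._load_env_pruned()
        mems = pd.read_csv(self.run_dir / "spatial" / "mems.csv")
        tests = pd.read_csv(self.run_dir / "spatial" / "mem_tests.csv")
        sig = [
            f"MEM{i+1}"
            for i in range(len(tests))
            if tests.loc[i, "moran_i"] > 0 and tests.loc[i, "moran_p"] < 0.05
        ][:3] or ["MEM1", "MEM2", "MEM3"]
        sig = [c for c in sig if c in mems.columns]
        geog = mems[sig].to_numpy()
        pcs = pd.read_csv(self.run_dir / "stats" / "pca_pop_scores.csv")
        struct = pcs[[c for c in ("PC1", "PC2", "PC3") if c in pcs]].to_numpy()
        sets = {"env": env.values, "geog": geog, "struct": struct}

        g = self._neutral_matrix()
        freqs = allele_freq_table(g)
        y = imputed_freq_matrix(freqs)
        out.mkdir(exist_ok=True)
        vp = variance_partition(y, sets, n_permutations=self.cfg.n_permutations,
                                seed=self.cfg.rng_seed)
        vp.table.to_csv(out / "varpart_neutral.csv", index_label="component")

        core = (self.run_dir / "gea" / "core_ids.txt").read_text().splitlines()
        core = [c for c in core if c]
        if len(core) >= 2:
            gall = self._load_filtered()
            keep = set(core)
            idx = np.flatnonzero(np.array([l in keep for l in gall.locus_ids]))
            ya = imputed_freq_matrix(allele_freq_table(gall.take_loci(idx)))
            vpa = variance_partition(
                ya, sets, n_permutations=self.cfg.n_permutations,
                seed=self.cfg.rng_seed,
            )
            vpa.table.to_csv(out / "varpart_adaptive.csv", index_label="component")

    def _run_gea(self, out: Path) -> None:
        g = self._neutral_matrix()    # non-F_ST-outlier loci only
        freqs = allele_freq_table(g)
        y = imputed_freq_matrix(freqs)
        poly = y.std(axis=0) > 0
        ids = [l for l, k in zip(freqs.locus_ids, poly) if k]
        env = self._load_env_pruned()
        res = gea_scan(
            y[:, poly], env, k=self.cfg.k_latent, locus_ids=ids,
            sd_cutoff=self.cfg.rda_sd_cutoff, alpha=self.cfg.fdr_alpha,
            seed=self.cfg.rng_seed,
        )
        out.mkdir(exist_ok=True)
        res.to_frame().to_csv(out / "gea_table.csv", index=False)
        (out / "core_ids.txt").write_text("\n".join(res.core_ids))
        groups = self._groups_for_gea()
        per_group = gea_scan_by_group(
            freqs, env, groups, k=self.cfg.k_latent,
            sd_cutoff=self.cfg.rda_sd_cutoff, alpha=self.cfg.fdr_alpha,
            seed=self.cfg.rng_seed,
        )
        for name, r in per_group.items():
            r.to_frame().to_csv(out / f"gea_{name}.csv", index=False)

    def _groups_for_gea(self) -> dict[str, str]:
        path = self.data_dir / "groups.csv"
        if path.exists():
            df = pd.read_csv(path)
            return dict(zip(df["pop"], df["group"]))
        from sklearn.cluster import KMeans

        g = self._neutral_matrix()
        pca = genotype_pca(g)
        km = KMeans(
            n_clusters=self.cfg.n_groups, n_init=10,
            random_state=self.cfg.rng_seed,
        ).fit(pca.pop_scores[:, :2])
        return {p: f"G{l + 1}" for p, l in zip(pca.pop_labels, km.labels_)}

    def _run_gf(self, out: Path) -> None:
        env = self._load_env_pruned()
        g = self._neutral_matrix()
        freqs = allele_freq_table(g)
        y = imputed_freq_matrix(freqs)
        rng = np.random.default_rng(self.cfg.rng_seed)
        n_fit = min(self.cfg.gf_max_loci, y.shape[1])
        cols = rng.choice(y.shape[1], size=n_fit, replace=False)
        out.mkdir(exist_ok=True)
        model_neutral = fit_gradient_forest(
            y[:, cols], env,
            locus_ids=[freqs.locus_ids[c] for c in cols],
            n_trees=self.cfg.n_trees, seed=self.cfg.rng_seed,
        )
        model_neutral.to_json(out / "turnover_neutral.json")
        core = (self.run_dir / "gea" / "core_ids.txt").read_text().splitlines()
        core = [c for c in core if c]
        gall = self._load_filtered()
        keep = set(core)
        idx = np.flatnonzero(np.array([l in keep for l in gall.locus_ids]))
        if len(idx) >= 1:
            ya = imputed_freq_matrix(allele_freq_table(gall.take_loci(idx)))
            try:
                model_core = fit_gradient_forest(
                    ya, env, locus_ids=[gall.locus_ids[i] for i in idx],
                    n_trees=self.cfg.n_trees, seed=self.cfg.rng_seed,
                )
                model_core.to_json(out / "turnover_core.json")
            except ValueError as err:
                logger.warning("core-locus turnover model skipped: %s", err)

    def _run_offset(self, out: Path) -> None:
        from .turnover import TurnoverModel

        out.mkdir(exist_ok=True)
        models = {}
        for tag in ("neutral", "core"):
            path = self.run_dir / "gf" / f"turnover_{tag}.json"
            if path.exists():
                models[tag] = TurnoverModel.from_json(path)
        rows = []
        for tag, model in models.items():
            names = model.predictors
            cur = self._raster_stack("current", names)
            for epoch in self._future_epochs():
                fut = self._raster_stack(epoch, names)
                surf = offset_surface(
                    model, cur, fut, radii_km=self.cfg.migration_radii_km,
                    locus_set=tag,
                )
                edir = out / tag / epoch
                edir.mkdir(parents=True, exist_ok=True)
                mask = ~np.isfinite(surf.local)
                geo = (cur.xll, cur.yll, cur.cell)
                genio.write_ascii_grid(
                    np.nan_to_num(surf.local), mask, *geo, edir / "local.asc"
                )
                for r, grid in surf.forward.items():
                    label = "inf" if np.isinf(r) else f"{int(r)}km"
                    genio.write_ascii_grid(
                        np.nan_to_num(grid), mask, *geo,
                        edir / f"forward_{label}.asc",
                    )
                genio.write_ascii_grid(
                    np.nan_to_num(surf.reverse), mask, *geo, edir / "reverse.asc"
                )
                fwd_inf = surf.forward[
                    [r for r in surf.forward if np.isinf(r)][0]
                    if any(np.isinf(r) for r in surf.forward)
                    else list(surf.forward)[-1]
                ]
                rgb, meta = rgb_composite(surf.local, fwd_inf, surf.reverse)
                (edir / "rgb_meta.json").write_text(json.dumps(meta))
                for band, name in zip(rgb, ("r", "g", "b")):
                    genio.write_ascii_grid(
                        band.astype(float), mask, *geo, edir / f"rgb_{name}.asc"
                    )
                row = {"locus_set": tag, "epoch": epoch,
                       "mean_local": float(np.nanmean(surf.local)),
                       "mean_reverse": float(np.nanmean(surf.reverse))}
                for r, grid in surf.forward.items():
                    label = "inf" if np.isinf(r) else f"{int(r)}km"
                    row[f"mean_forward_{label}"] = float(np.nanmean(grid))
                rows.append(row)
        pd.DataFrame(rows).to_csv(out / "offset_summary.csv", index=False)

    def _run_rona(self, out: Path) -> None:
        from .gea import GeaResult, LfmmResult, RdaScanResult  # noqa: F401

        g = self._neutral_matrix()
        freqs = allele_freq_table(g)
        env = self._load_env_pruned()
        frame = self._load_frame()
        gea_table = pd.read_csv(self.run_dir / "gea" / "gea_table.csv")
        core_rows = gea_table[gea_table["core"]]
        variables_of_core = {
            r["locus_id"]: [v for v in str(r["variables"]).split(";") if v]
            for _, r in core_rows.iterrows()
        }
        core = _CoreView(list(variables_of_core), variables_of_core)
        out.mkdir(exist_ok=True)
        for epoch in self._future_epochs():
            fut_stack = self._raster_stack(epoch, list(env.variables))
            env_fut = genio.extract_env_at_points(
                fut_stack, frame, classes=env.classes
            )
            table = rona(freqs, core, env, env_fut)
            if not table.summary.empty:
                table.summary.to_csv(out / f"rona_{epoch}.csv", index=False)


@dataclass
class _CoreView:
    """Minimal core-locus view consumed by the RONA calculation."""

    core_ids: list[str]
    variables_of_core: dict[str, list[str]]


def run_pipeline(
    run_dir: str | Path,
    cfg: RunConfig | None = None,
    synth: SynthConfig | None = None,
    data_dir: str | Path | None = None,
    until: str | None = None,
) -> StageGraph:
    """Convenience wrapper: build a Pipeline and run it (optionally only up
    to the named stage)."""
    return Pipeline(run_dir, cfg=cfg, synth=synth, data_dir=data_dir).run(until)
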