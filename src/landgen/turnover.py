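"""Gradient-forest turnover modelling.

Each locus's population allele frequencies are regressed on the
environmental predictors with a random forest (500 trees per SNP by
default); loci with positive out-of-bag R-squared are retained. Predictor
importance is the mean over retained loci of permutation importance
weighted by locus R-squared, and every split's impurity improvement is
credited to its predictor at the split value. Binned along each predictor's
observed range and normalised so the total rise equals the predictor's
weighted importance, the cumulative sums give the turnover functions
F_p(x) that map raw environmental space into "genetic composition" space.
Outside the training range F_p is clamped, never extrapolated.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestRegressor

from .genio import EnvTable, RasterStack

logger = logging.getLogger("landgen")


@dataclass
class TurnoverModel:
    predictors: list[str]
    bin_edges: dict[str, np.ndarray]      # predictor -> (n_bins+1,)
    cumulative: dict[str, np.ndarray]     # predictor -> (n_bins+1,), starts at 0
    importance: dict[str, float]          # R2-weighted importance
    locus_r2: dict[str, float]            # retained loci only
    n_trees: int
    seed: int

    @property
    def ranking(self) -> list[str]:
        return sorted(self.predictors, key=lambda p: -self.importance[p])

    def transform_values(self, predictor: str, values: np.ndarray) -> np.ndarray:
        """Evaluate F_p with clamping to the training range."""
        edges = self.bin_edges[predictor]
        cum = self.cumulative[predictor]
        v = np.clip(values, edges[0], edges[-1])
        return np.interp(v, edges, cum)

    def transform_matrix(self, names: list[str], values: np.ndarray) -> np.ndarray:
        """Columnwise transform of a (n, P) matrix given predictor names."""
        out = np.empty_like(values, dtype=float)
        for j, name in enumerate(names):
            out[:, j] = self.transform_values(name, values[:, j])
        return out

    def to_json(self, path: str | Path) -> None:
        doc = {
            "predictors": self.predictors,
            "bin_edges": {k: v.tolist() for k, v in self.bin_edges.items()},
            "cumulative": {k: v.tolist() for k, v in self.cumulative.items()},
            "importance": self.importance,
            "locus_r2": self.locus_r2,
            "n_trees": self.n_trees,
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(doc))

    @classmethod
    def from_json(cls, path: str | Path) -> "TurnoverModel":
        doc = json.loads(Path(path).read_text())
        return cls(
            predictors=doc["predictors"],
            bin_edges={k: np.array(v) for k, v in doc["bin_edges"].items()},
            cumulative={k: np.array(v) for k, v in doc["cumulative"].items()},
            importance=doc["importance"],
            locus_r2=doc["locus_r2"],
            n_trees=doc["n_trees"],
            seed=doc["seed"],
        )


def _permutation_importance(
    rf, x: np.ndarray, y: np.ndarray, n_repeats: int, rng: np.random.Generator
) -> np.ndarray:
    """Out-of-bag permutation importance in R-squared units.

    For every tree, its out-of-bag samples are predicted once as-is and once
    per shuffled predictor column (all shuffles stacked into one predict call
    per tree); the importance of a predictor is the mean increase in OOB
    squared error, scaled by the total variance of ``y``.
    """
    n, P = x.shape
    var_tot = ((y - y.mean()) ** 2).mean()
    if var_tot == 0:
        return np.zeros(P)
    inc = np.zeros(P)
    used = 0
    all_idx = np.arange(n)
    for tree, samp in zip(rf.estimators_, rf.estimators_samples_):
        oob = np.setdiff1d(all_idx, samp)
        m = len(oob)
        if m == 0:
            continue
        used += 1
        xo = x[oob]
        batch = np.tile(xo, (1 + n_repeats * P, 1, 1))
        for rep in range(n_repeats):
            for j in range(P):
                batch[1 + rep * P + j, :, j] = xo[rng.permutation(m), j]
        pred = tree.predict(batch.reshape(-1, P)).reshape(-1, m)
        mse = ((y[oob][None, :] - pred) ** 2).mean(axis=1)
        inc += (mse[1:].reshape(n_repeats, P).mean(axis=0) - mse[0])
    if used == 0:
        return np.zeros(P)
    return inc / used / var_tot


def _tree_split_improvements(tree, n_features: int):
    """(feature, threshold, improvement) triples for one fitted tree.

    Improvement is the weighted impurity decrease of each internal node,
    with node weights relative to the root sample count.
    """
    t = tree.tree_
    internal = t.children_left != -1
    w = t.weighted_n_node_samples / t.weighted_n_node_samples[0]
    left, right = t.children_left[internal], t.children_right[internal]
    imp = (
        w[internal] * t.impurity[internal]
        - w[left] * t.impurity[left]
        - w[right] * t.impurity[right]
    )
    return t.feature[internal], t.threshold[internal], np.maximum(imp, 0.0)


def fit_gradient_forest(
    y: np.ndarray,
    env: EnvTable,
    locus_ids: list[str] | None = None,
    n_trees: int = 500,
    n_bins: int = 201,
    seed: int = 0,
    n_permutation_repeats: int = 3,
) -> TurnoverModel:
    """Fit per-locus random forests and aggregate them into turnover curves.

    ``y`` is the population x locus allele-frequency matrix aligned with
    ``env``. Forest hyperparameters follow the usual gradient-forest
    defaults: mtry = ceil(P/3), unlimited depth, bootstrap resampling of
    populations, all deterministic under ``seed``.
    """
    y = np.asarray(y, dtype=float)
    n, L = y.shape
    if n < 5:
        raise ValueError("need at least 5 populations")
    if L < 1:
        raise ValueError("need at least one locus")
    locus_ids = locus_ids or [f"locus{i}" for i in range(L)]
    x = np.asarray(env.values, dtype=float)
    predictors = list(env.variables)
    P = len(predictors)
    mtry = max(1, int(np.ceil(P / 3)))
    rng = np.random.default_rng(seed)

    mins, maxs = x.min(axis=0), x.max(axis=0)
    widths = np.where(maxs > mins, (maxs - mins) / n_bins, 1.0)
    edges = {
        p: np.linspace(mins[j], maxs[j], n_bins + 1) for j, p in enumerate(predictors)
    }
    hist2d = np.zeros((P, n_bins))
    imp_sum = np.zeros(P)
    r2_of: dict[str, float] = {}
    n_retained = 0
    for l in range(L):
        yl = y[:, l]
        if yl.std() == 0:
            continue
        rf = RandomForestRegressor(
            n_estimators=n_trees,
            max_features=mtry,
            bootstrap=True,
            oob_score=True,
            random_state=int(rng.integers(2**31)),
            n_jobs=1,
        )
        rf.fit(x, yl)
        r2 = float(rf.oob_score_)
        if not np.isfinite(r2) or r2 <= 0:
            continue
        n_retained += 1
        r2_of[locus_ids[l]] = r2
        imp = _permutation_importance(
            rf, x, yl, n_permutation_repeats, np.random.default_rng(rng.integers(2**31))
        )
        imp_sum += r2 * np.maximum(imp, 0.0)
        for est in rf.estimators_:
            feats, thresh, gains = _tree_split_improvements(est, P)
            idx = np.clip(
                ((thresh - mins[feats]) / widths[feats]).astype(int), 0, n_bins - 1
            )
            np.add.at(hist2d, (feats, idx), gains)
    if n_retained == 0:
        raise ValueError("no predictable turnover: no locus has positive OOB R^2")
    logger.info("gradient forest: retained %d / %d loci", n_retained, L)
    hist = {p: hist2d[j] for j, p in enumerate(predictors)}
    importance = {p: float(imp_sum[j] / n_retained) for j, p in enumerate(predictors)}
    cumulative = {}
    for p in predictors:
        total = hist[p].sum()
        mass = hist[p] * (importance[p] / total) if total > 0 else hist[p]
        cumulative[p] = np.concatenate([[0.0], np.cumsum(mass)])
    return TurnoverModel(
        predictors=predictors, bin_edges=edges, cumulative=cumulative,
        importance=importance, locus_r2=r2_of, n_trees=n_trees, seed=seed,
    )


# ---------------------------------------------------------------------------
# Variable pruning
# ---------------------------------------------------------------------------


def prune_variables(
    env: EnvTable, importance: dict[str, float], r_max: float = 0.75
) -> EnvTable:
    """Greedy collinearity pruning: while any pair of variables has
    |Pearson r| > r_max, drop the lower-importance member of the most
    correlated pair."""
    keep = list(env.variables)
    while len(keep) > 1:
        sub = env.select(keep)
        c = np.corrcoef(sub.values.T)
        np.fill_diagonal(c, 0.0)
        c = np.abs(np.nan_to_num(c))
        i, j = np.unravel_index(np.argmax(c), c.shape)
        if c[i, j] <= r_max:
            break
        drop = keep[i] if importance.get(keep[i], 0) <= importance.get(keep[j], 0) else keep[j]
        logger.info(
            "prune_variables: |r|=%.3f between %s and %s; dropping %s",
            c[i, j], keep[i], keep[j], drop,
        )
        keep.remove(drop)
    return env.select(keep)


# ---------------------------------------------------------------------------
# Raster transform
# ---------------------------------------------------------------------------


def transform_env(model: TurnoverModel, stack: RasterStack) -> RasterStack:
    """Map every layer of a raster stack through its turnover function.

    The result is the "genetic composition" stack; values outside the
    training range are clamped to the range ends before evaluation.
    """
    missing = [n for n in stack.names if n not in model.predictors]
    if missing:
        raise ValueError(f"predictors missing from model: {missing}")
    data = np.stack(
        [model.transform_values(n, stack.layer(n)) for n in stack.names]
    )
    return RasterStack(
        names=list(stack.names), data=data, mask=stack.mask,
        xll=stack.xll, yll=stack.yll, cell=stack.cell,
        crs=stack.crs, epoch=stack.epoch,
    )
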