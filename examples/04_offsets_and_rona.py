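"""Gradient-forest turnover, genomic offsets and RONA.

Fits per-locus random forests on population allele frequencies, turns the
split-importance profiles into cumulative turnover functions, and maps the
climate grids into genetic-composition space. Offsets are distances in that
space: local (same cell, current vs future), forward (best reachable cell
within a migration radius) and reverse (how close any current cell comes to
a cell's future climate). RONA is the per-variable mean allele-frequency
shift demanded by the future climate.
"""

import numpy as np

from landgen import RunConfig, SynthConfig, filter_snps, fit_gradient_forest
from landgen.gea import imputed_freq_matrix
from landgen.offsets import offset_surface, rona
from landgen.popstats import allele_freq_table
from landgen.synthdata import final_env_variables, simulate_dataset
from landgen.genio import extract_env_at_points

cfg = SynthConfig(seed=1, n_neutral=400, n_adaptive=20)
ds = simulate_dataset(cfg)
filtered, _ = filter_snps(ds.genotypes, RunConfig())
freqs = allele_freq_table(filtered)
y = imputed_freq_matrix(freqs)

env = ds.env.select(list(final_env_variables(cfg)))
model = fit_gradient_forest(y[:, :80], env, n_trees=100, seed=1)
top = model.ranking[:3]
print("top predictors by R2-weighted importance:",
      ", ".join(f"{p} ({model.importance[p]:.4f})" for p in top))

names = list(env.variables)
cur = ds.landscape.current.select(names)
fut = ds.landscape.futures["SSP585_2041_2060"].select(names)
surf = offset_surface(model, cur, fut, radii_km=(50, 100, 200, 500, np.inf))
print(f"mean local offset {np.nanmean(surf.local):.4f}")
for r in (50, 100, 200, 500, np.inf):
    print(f"  mean forward offset, radius {r} km: "
          f"{np.nanmean(surf.forward[float(r)]):.4f}")
print("forward offsets shrink as the migration radius grows: populations "
      "that can move further can find closer climate analogues.")

# RONA for the planted loci against their own drivers
truth_map = {r.locus_id: [r.driver] for _, r in ds.truth.iterrows()
             if r.locus_id in freqs.locus_ids}


class Core:
    core_ids = list(truth_map)
    variables_of_core = truth_map


env_fut = extract_env_at_points(fut, ds.landscape.frame, classes=env.classes)
table = rona(freqs, Core, env.select(names), env_fut)
by_var = table.summary.groupby("variable")["rona"].mean()
print("mean RONA by driver variable:")
for var, val in by_var.items():
    print(f"  {var}: {val:.3f}")
print("RONA is the mean absolute allele-frequency change the regression "
      "predicts populations need to track the future climate.")
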