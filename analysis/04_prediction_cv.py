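#!/usr/bin/env python
"""Measure prediction accuracy of all six models under three CV schemes.

Random Lines holds out whole lines (all their environments); Random
Observations holds out individual line-by-environment cells; New
Environment holds out one entire environment per fold. Accuracy is the
R-squared of regressing true on predicted phenotypes, pooled over the
test set and averaged within environments. The multi-trait model is
structurally unable to predict into an unobserved environment and is
reported as "not fittable" there; the random regression model needs an
explicitly supplied gradient position for a held-out environment (here
the per-environment phenotype mean, which is not available without
leakage in a real New Environment setting — it serves as an upper bound).
"""

import argparse
from pathlib import Path

import pandas as pd

from gxeforge import (
    grm_vanraden,
    plan_new_environment,
    plan_random_lines,
    plan_random_observations,
    read_genotypes,
    run_cv,
)
from gxeforge.data_io import assemble_records
from gxeforge.report import accuracy_table, per_env_accuracy_table

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--data", type=Path, default=Path("results/dataset"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--reps", type=int, default=6)
args = parser.parse_args()

genotypes = read_genotypes(args.data / "genotypes.bed", "plink-bed")
records = assemble_records(
    pd.read_csv(args.data / "phenotypes.csv"),
    pd.read_csv(args.data / "environments.csv"),
)
grm = grm_vanraden(genotypes)
env_means = records.table.groupby("env_id")["phenotype"].mean().to_dict()

plans = {
    "random_lines": plan_random_lines(records, 0.17, args.reps, args.seed),
    "random_observations": plan_random_observations(records, 0.17, args.reps, args.seed + 1),
    "new_environment": plan_new_environment(records),
}
models = ("G-BLUP", "E-BLUP", "GE-BLUP", "GxE-BLUP", "mvG-BLUP", "RRM")
results = []
for scheme, plan in plans.items():
    for model in models:
        res = run_cv(records, model, plan, grm, seed=args.seed,
                     rrm_env_values=env_means)
        results.append(res)
        shown = f"{res.pooled_mean:.3f}" if res.fittable else "not fittable"
        print(f"{scheme:22s} {model:10s} pooled R2 = {shown}")

args.out.mkdir(parents=True, exist_ok=True)
accuracy_table(results, "pooled").to_csv(args.out / "accuracy_pooled.csv")
accuracy_table(results, "within").to_csv(args.out / "accuracy_within_env.csv")
newenv = [r for r in results if r.scheme == "new_environment"]
per_env_accuracy_table(newenv).to_csv(args.out / "accuracy_new_environment_per_env.csv")
print(f"\nwrote accuracy tables to {args.out}")
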