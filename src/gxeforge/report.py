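"""Tabular summaries of fits and cross-validation sweeps.

Produces machine-readable CSV/JSON outputs plus a plain-text digest:
variance partitions (PVE) per model, cross-environment genetic correlations
and per-environment heritabilities from the multi-trait model, pooled and
within-environment prediction accuracies per model and CV scheme, and the
per-environment accuracy table for the held-out-environment scheme.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .cv import CVResult
from .mtm import MTMFit, genetic_correlations, heritability
from .reml import VarianceFit

__all__ = [
    "pve_table",
    "mtm_tables",
    "accuracy_table",
    "per_env_accuracy_table",
    "fit_report",
    "write_report",
]

NOT_FITTABLE = "not fittable"


def pve_table(fits: dict[str, VarianceFit]) -> pd.DataFrame:
    """Variance-partition table: one column per model, one row per component."""
    rows = sorted({c for f in fits.values() for c in f.sigma2})
    order = [c for c in ("genetic", "environment", "gxe", "residual") if c in rows]
    order += [c for c in rows if c not in order]
    data = {
        name: [fit.pve.get(c, np.nan) for c in order] for name, fit in fits.items()
    }
    return pd.DataFrame(data, index=pd.Index(order, name="component"))


def mtm_tables(fit: MTMFit) -> tuple[pd.DataFrame, pd.Series]:
    """Cross-environment genetic correlation matrix and per-env heritability."""
    envs = [str(e) for e in fit.env_ids]
    ra = pd.DataFrame(genetic_correlations(fit), index=envs, columns=envs)
    h2 = pd.Series(heritability(fit), index=envs, name="h2")
    return ra, h2


def accuracy_table(results: list[CVResult], metric: str = "pooled") -> pd.DataFrame:
    """Model x scheme accuracy grid; infeasible combinations are labelled."""
    models = list(dict.fromkeys(r.model for r in results))
    schemes = list(dict.fromkeys(r.scheme for r in results))
    out = pd.DataFrame(index=pd.Index(models, name="model"), columns=schemes, dtype=object)
    for r in results:
        if not r.fittable:
            out.loc[r.model, r.scheme] = NOT_FITTABLE
        else:
            val = r.pooled_mean if metric == "pooled" else r.within_env_mean
            out.loc[r.model, r.scheme] = round(float(val), 4)
    return out


def per_env_accuracy_table(results: list[CVResult]) -> pd.DataFrame:
    """Per-environment mean R2, one column per model (held-out-environment style)."""
    cols = {}
    envs: list = []
    for r in results:
        if not r.fittable:
            continue
        means = r.per_env_means()
        envs = sorted(set(envs) | set(means))
        cols[r.model] = means
    table = pd.DataFrame(index=pd.Index(envs, name="env"))
    for model, means in cols.items():
        table[model] = [round(means.get(e, np.nan), 4) for e in envs]
    for r in results:
        if not r.fittable:
            table[r.model] = NOT_FITTABLE
    return table


def fit_report(fit: VarianceFit) -> dict:
    """JSON-serializable run report for a single REML fit."""
    return {
        "model": fit.model,
        "sigma2": fit.sigma2,
        "pve": fit.pve,
        "beta": fit.beta.tolist(),
        "reml_loglik": fit.reml_loglik,
        "converged": fit.converged,
        "n_iter": fit.n_iter,
        "se_sigma2": fit.se_sigma2,
        "loglik_trace": [float(v) for v in fit.loglik_trace],
    }


def write_report(
    outdir,
    fits: dict[str, VarianceFit] | None = None,
    mtm_fit: MTMFit | None = None,
    cv_results: list[CVResult] | None = None,
    provenance: dict | None = None,
) -> list[Path]:
    """Write all available tables under ``outdir``; returns the paths written."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    lines = ["run summary", "==========="]
    if fits:
        tab = pve_table(fits)
        tab.to_csv(out / "pve.csv")
        written.append(out / "pve.csv")
        with open(out / "fits.json", "w") as fh:
            json.dump({m: fit_report(f) for m, f in fits.items()}, fh, indent=1)
        written.append(out / "fits.json")
        lines += ["", "variance partition (PVE):", tab.round(4).to_string()]
    if mtm_fit is not None:
        ra, h2 = mtm_tables(mtm_fit)
        ra.to_csv(out / "genetic_correlations.csv")
        h2.to_csv(out / "heritability.csv")
        written += [out / "genetic_correlations.csv", out / "heritability.csv"]
        lines += ["", "cross-environment genetic correlations (rA):", ra.round(3).to_string(),
                  "", "per-environment heritability:", h2.round(3).to_string()]
    if cv_results:
        pooled = accuracy_table(cv_results, "pooled")
        pooled.to_csv(out / "accuracy_pooled.csv")
        written.append(out / "accuracy_pooled.csv")
        within = accuracy_table(cv_results, "within")
        within.to_csv(out / "accuracy_within_env.csv")
        written.append(out / "accuracy_within_env.csv")
        lines += ["", "pooled R2 (model x scheme):", pooled.to_string(),
                  "", "mean within-environment R2:", within.to_string()]
        newenv = [r for r in cv_results if r.scheme == "new_environment"]
        if newenv:
            tab1 = per_env_accuracy_table(newenv)
            tab1.to_csv(out / "accuracy_new_environment_per_env.csv")
            written.append(out / "accuracy_new_environment_per_env.csv")
            lines += ["", "per-environment R2, held-out environment scheme:", tab1.to_string()]
    if provenance:
        with open(out / "provenance.json", "w") as fh:
            json.dump(provenance, fh, indent=1, default=str)
        written.append(out / "provenance.json")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
    written.append(out / "summary.txt")
    return written
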