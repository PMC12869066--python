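"""End-to-end orchestration: data -> kernels -> fits -> CV -> report.

A :class:`RunConfig` either points at genotype/phenotype/environment files
or embeds synthetic-generator settings. The pipeline then applies the line
and variant filters, builds the GRM (cached by content hash under the
output directory), fits the requested models on the full data, runs the
requested CV schemes, and writes the report tables. Every seed, threshold
and iteration count ends up in ``provenance.json``.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import data_io
from .cv import (
    CV_MODELS,
    plan_new_environment,
    plan_random_lines,
    plan_random_observations,
    run_cv,
)
from .datatypes import RecordFrame
from .kernels import Kernel, grm_vanraden
from .mtm import PRODUCTION_CHAIN, TEST_CHAIN, gibbs_fit
from .reml import MODEL_KERNELS, build_model_spec, reml_fit
from .report import write_report
from .rrm import env_covariate_from_training, legendre_basis, rrm_fit
from .synth import SimConfig, simulate_dataset
from .cv import CVResult

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "load_config"]

RKHS_MODELS = tuple(MODEL_KERNELS)
DEFAULT_MODELS = RKHS_MODELS + ("mvG-BLUP", "RRM")
DEFAULT_SCHEMES = ("random_lines", "random_observations", "new_environment")
MCMC_PROFILES = {"test": TEST_CHAIN, "production": PRODUCTION_CHAIN}


@dataclass
class RunConfig:
    outdir: str = "gxeforge_run"
    seed: int = 1
    # either synthetic-generator settings ...
    sim: dict | None = None
    # ... or paths to real inputs
    genotypes: str | None = None
    genotype_format: str = "plink-bed"
    phenotypes: str | None = None  # CSV: line_id, env_id, phenotype
    environments: str | None = None  # CSV: env_id + covariate columns
    maf_min: float = 0.05
    max_missing: float = 0.2
    filter_variants_before_line_filter: bool = False
    models: tuple = DEFAULT_MODELS
    schemes: tuple = DEFAULT_SCHEMES
    reps: int = 6
    test_fraction: float = 0.17
    mcmc_profile: str = "test"
    rrm_order: int = 1
    rrm_new_env_values: dict | None = None
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        unknown = [m for m in self.models if m not in CV_MODELS]
        if unknown:
            raise ValueError(f"unknown model(s) {unknown}; choose from {CV_MODELS}")
        unknown = [s for s in self.schemes if s not in DEFAULT_SCHEMES]
        if unknown:
            raise ValueError(f"unknown scheme(s) {unknown}")
        if self.mcmc_profile not in MCMC_PROFILES:
            raise ValueError(f"unknown MCMC profile {self.mcmc_profile!r}")
        if self.sim is None and self.genotypes is None:
            raise ValueError("config needs either 'sim' settings or input paths")
        if self.sim is not None:
            SimConfig(**{**self.sim, "seed": self.seed})  # validate early


def load_config(path) -> RunConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return RunConfig(**payload)


def _content_hash(*arrays) -> str:
    h = hashlib.sha256()
    for a in arrays:
        h.update(np.ascontiguousarray(a).tobytes())
    return h.hexdigest()[:16]


def _cached_grm(genotypes, cache_dir: Path) -> Kernel:
    """GRM with a content-hash cache; corrupted entries are recomputed."""
    cache_dir.mkdir(parents=True, exist_ok=True)
    key = _content_hash(np.nan_to_num(genotypes.dosages, nan=-1.0))
    path = cache_dir / f"grm_{key}.npy"
    if path.exists():
        try:
            values = np.load(path)
            if values.shape == (genotypes.n_lines,) * 2 and np.isfinite(values).all():
                logger.info("GRM cache hit: %s", path.name)
                return Kernel(genotypes.line_ids, values, "line", "G", {"cache": str(path)})
            raise ValueError("shape or finiteness check failed")
        except Exception as err:
            logger.warning("corrupted GRM cache entry %s (%s): recomputing", path.name, err)
    grm = grm_vanraden(genotypes)
    np.save(path, grm.values)
    return grm


def _load_real(cfg: RunConfig):
    g = data_io.read_genotypes(cfg.genotypes, cfg.genotype_format)
    pheno = pd.read_csv(cfg.phenotypes)
    env = pd.read_csv(cfg.environments)
    records = data_io.assemble_records(pheno, env)
    if cfg.filter_variants_before_line_filter:
        g = data_io.filter_variants(g, cfg.maf_min, cfg.max_missing)
    records = data_io.complete_case_lines(records, list(records.env_ids))
    g = g.subset_lines(records.line_ids)
    if not cfg.filter_variants_before_line_filter:
        g = data_io.filter_variants(g, cfg.maf_min, cfg.max_missing)
    return g, records


def run_pipeline(cfg: RunConfig) -> dict:
    """Run the configured analysis end to end; returns the in-memory artifacts."""
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    if cfg.sim is not None:
        ds = simulate_dataset(SimConfig(**{**cfg.sim, "seed": cfg.seed}))
        genotypes, records = ds.genotypes, ds.records
        truth = {"fractions": list(ds.fractions), "mu": ds.mu}
    else:
        genotypes, records = _load_real(cfg)
        truth = None
    grm = _cached_grm(genotypes, out / "cache")

    fits = {}
    for model in cfg.models:
        if model in RKHS_MODELS:
            fits[model] = reml_fit(records, build_model_spec(model, records, grm))
            logger.info("%s PVE: %s", model, {k: round(v, 3) for k, v in fits[model].pve.items()})

    mtm_fit = None
    if "mvG-BLUP" in cfg.models:
        Y, g_aligned, envs = _records_to_matrix(records, grm)
        mtm_fit = gibbs_fit(
            Y, g_aligned, seed=cfg.seed, env_ids=envs, **MCMC_PROFILES[cfg.mcmc_profile]
        )

    rrm_full = None
    if "RRM" in cfg.models:
        env_vals = env_covariate_from_training(records, np.arange(records.q))
        basis = legendre_basis(env_vals, T=cfg.rrm_order)
        rrm_full = rrm_fit(records, basis, grm)

    cv_results: list[CVResult] = []
    planners = {
        "random_lines": lambda: plan_random_lines(
            records, cfg.test_fraction, cfg.reps, cfg.seed
        ),
        "random_observations": lambda: plan_random_observations(
            records, cfg.test_fraction, cfg.reps, cfg.seed + 1
        ),
        "new_environment": lambda: plan_new_environment(records),
    }
    for scheme in cfg.schemes:
        plan = planners[scheme]()
        plan.to_json(out / f"cvplan_{scheme}.json")
        for model in cfg.models:
            res = run_cv(
                records, model, plan, grm,
                seed=cfg.seed,
                mcmc=MCMC_PROFILES[cfg.mcmc_profile],
                rrm_order=cfg.rrm_order,
                rrm_env_values=cfg.rrm_new_env_values,
            )
            cv_results.append(res)
            logger.info(
                "%s / %s: pooled R2 = %s", model, scheme,
                f"{res.pooled_mean:.3f}" if res.fittable else res.reason,
            )

    provenance = {
        "config": asdict(cfg),
        "n_lines": records.n_lines,
        "n_envs": records.n_envs,
        "q": records.q,
        "n_variants": genotypes.n_variants,
        "truth": truth,
        "reml_iterations": {m: f.n_iter for m, f in fits.items()},
    }
    write_report(out, fits=fits or None, mtm_fit=mtm_fit, cv_results=cv_results or None,
                 provenance=provenance)
    return {
        "genotypes": genotypes,
        "records": records,
        "grm": grm,
        "fits": fits,
        "mtm": mtm_fit,
        "rrm": rrm_full,
        "cv_results": cv_results,
        "outdir": out,
    }


def _records_to_matrix(records: RecordFrame, grm: Kernel):
    lines, envs = records.line_ids, records.env_ids
    lpos = {l: i for i, l in enumerate(lines)}
    epos = {e: j for j, e in enumerate(envs)}
    Y = np.full((len(lines), len(envs)), np.nan)
    tab = records.table
    Y[tab["line_id"].map(lpos), tab["env_id"].map(epos)] = records.phenotype
    pos = {l: i for i, l in enumerate(grm.ids)}
    idx = np.array([pos[l] for l in lines], dtype=int)
    g_aligned = Kernel(lines, grm.values[np.ix_(idx, idx)], "line", grm.name, dict(grm.meta))
    return Y, g_aligned, envs
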