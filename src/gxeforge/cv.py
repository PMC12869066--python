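"""Cross-validation schemes and prediction-accuracy metrics.

Three schemes mimic different training/test relationships:

- ``random_lines``: whole lines (all their environments) held out — tests
  transfer to new genotypes;
- ``random_observations``: random line-by-environment cells held out —
  every line and environment remains represented in training;
- ``new_environment``: one entire environment held out per fold — tests
  transfer to unseen conditions.

Accuracy is the R-squared from regressing true phenotypes on predictions
(equal to the squared Pearson correlation), pooled over the test set and,
optionally, within each environment and averaged.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np

from .datatypes import RecordFrame
from .kernels import Kernel
from .mtm import TEST_CHAIN, gibbs_fit, mtm_predict
from .reml import MODEL_KERNELS, ModelSpec, blup_predict, build_model_spec, reml_fit
from .rrm import env_covariate_from_training, legendre_basis, rrm_fit, rrm_predict

logger = logging.getLogger(__name__)

__all__ = [
    "CVPlan",
    "CVResult",
    "R2",
    "plan_random_lines",
    "plan_random_observations",
    "plan_new_environment",
    "r2_pooled",
    "r2_within_env",
    "run_cv",
]

SCHEMES = ("random_lines", "random_observations", "new_environment")
CV_MODELS = tuple(MODEL_KERNELS) + ("mvG-BLUP", "RRM")


class R2(float):
    """An R-squared value carrying a definedness flag.

    Behaves as a plain float; ``defined`` is False when the predictions had
    zero variance (the value is then reported as 0), e.g. E-BLUP within a
    single environment, whose predictions are constant there.
    """

    defined: bool

    def __new__(cls, value: float, defined: bool = True):
        obj = super().__new__(cls, value)
        obj.defined = defined
        return obj


@dataclass
class CVPlan:
    """Train/test record-index partitions for one CV scheme."""

    scheme: str
    replicates: list[tuple[np.ndarray, np.ndarray]]
    seed: int | None
    test_fraction: float
    labels: list[str] = field(default_factory=list)  # e.g. held-out env per fold

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for tr, te in self.replicates:
            if np.intersect1d(tr, te).size:
                raise ValueError("train/test overlap within a replicate")

    def to_json(self, path) -> None:
        payload = {
            "scheme": self.scheme,
            "seed": self.seed,
            "test_fraction": self.test_fraction,
            "labels": self.labels,
            "replicates": [
                {"train": tr.tolist(), "test": te.tolist()} for tr, te in self.replicates
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "CVPlan":
        with open(path) as fh:
            p = json.load(fh)
        reps = [
            (np.asarray(r["train"], int), np.asarray(r["test"], int))
            for r in p["replicates"]
        ]
        return cls(p["scheme"], reps, p["seed"], p["test_fraction"], p.get("labels", []))


def _split(q: int, test_mask: np.ndarray):
    idx = np.arange(q)
    return idx[~test_mask], idx[test_mask]


def plan_random_lines(
    records: RecordFrame, frac: float = 0.17, reps: int = 6, seed: int | None = None
) -> CVPlan:
    """Hold out round(n * frac) whole lines per replicate (independent redraws)."""
    lines = np.asarray(records.line_ids)
    n_test = int(np.rint(len(lines) * frac))
    if n_test < 1:
        raise ValueError(f"frac {frac} selects no lines out of {len(lines)}")
    rng = np.random.default_rng(seed)
    replicates = []
    rec_lines = records.table["line_id"].to_numpy()
    for _ in range(reps):
        test_lines = set(rng.choice(lines, size=n_test, replace=False))
        mask = np.array([l in test_lines for l in rec_lines])
        replicates.append(_split(records.q, mask))
    return CVPlan("random_lines", replicates, seed, frac)


def plan_random_observations(
    records: RecordFrame, frac: float = 0.17, reps: int = 6, seed: int | None = None
) -> CVPlan:
    """Hold out round(q * frac) individual records per replicate."""
    q = records.q
    n_test = int(np.rint(q * frac))
    if n_test < 1:
        raise ValueError(f"frac {frac} selects no records out of {q}")
    rng = np.random.default_rng(seed)
    tab = records.table
    replicates = []
    for rep in range(reps):
        test_idx = rng.choice(q, size=n_test, replace=False)
        mask = np.zeros(q, dtype=bool)
        mask[test_idx] = True
        tr, te = _split(q, mask)
        for col in ("line_id", "env_id"):
            absent = set(tab[col]) - set(tab[col].iloc[tr])
            if absent:
                logger.warning(
                    "replicate %d: %s absent from training: %s", rep, col, sorted(absent)[:5]
                )
        replicates.append((tr, te))
    return CVPlan("random_observations", replicates, seed, frac)


def plan_new_environment(records: RecordFrame) -> CVPlan:
    """One deterministic fold per environment, holding out all its records."""
    envs = records.env_ids
    if len(envs) < 2:
        raise ValueError("new_environment needs at least 2 environments")
    rec_envs = records.table["env_id"].to_numpy()
    replicates = [_split(records.q, rec_envs == env) for env in envs]
    return CVPlan(
        "new_environment",
        replicates,
        None,
        1.0 / len(envs),
        labels=[str(e) for e in envs],
    )


# ---------------------------------------------------------------------------
# metrics


def r2_pooled(y_true, y_pred) -> R2:
    """R-squared of the OLS regression of y_true on y_pred.

    Equals the squared Pearson correlation, hence invariant to affine
    transformations of the predictions with nonzero slope. Zero-variance
    predictions make the regression undefined; the value is then 0 with
    ``defined=False``.
    """
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    if len(y_true) != len(y_pred) or len(y_true) < 3:
        raise ValueError("need equal-length vectors with >= 3 entries")
    if np.std(y_pred) == 0.0 or np.std(y_true) == 0.0:
        return R2(0.0, defined=False)
    r = np.corrcoef(y_true, y_pred)[0, 1]
    return R2(float(r * r), defined=True)


@dataclass
class WithinEnvR2:
    per_env: dict
    mean: float
    n_undefined: int


def r2_within_env(y_true, y_pred, env_ids) -> WithinEnvR2:
    """Pooled R-squared inside each environment, plus their unweighted mean.

    Environments with fewer than 3 test records are skipped; undefined
    (constant-prediction) environments contribute 0 and are counted in
    ``n_undefined``. The mean is over all evaluated environments.
    """
    env_ids = np.asarray(env_ids)
    y_true = np.asarray(y_true, float)
    y_pred = np.asarray(y_pred, float)
    per_env: dict = {}
    n_undef = 0
    for env in np.unique(env_ids):
        mask = env_ids == env
        if mask.sum() < 3:
            continue
        val = r2_pooled(y_true[mask], y_pred[mask])
        per_env[env] = float(val)
        n_undef += not val.defined
    if not per_env:
        raise ValueError("no environment with >= 3 test records")
    return WithinEnvR2(per_env, float(np.mean(list(per_env.values()))), n_undef)


# ---------------------------------------------------------------------------
# orchestration


@dataclass
class CVResult:
    """Accuracy summaries for one model under one CV plan."""

    model: str
    scheme: str
    fittable: bool
    pooled: list[float] = field(default_factory=list)
    within_env: list[WithinEnvR2] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)
    reason: str | None = None
    provenance: dict = field(default_factory=dict)

    @property
    def pooled_mean(self) -> float:
        return float(np.mean(self.pooled)) if self.pooled else float("nan")

    @property
    def within_env_mean(self) -> float:
        if not self.within_env:
            return float("nan")
        return float(np.mean([w.mean for w in self.within_env]))

    def per_env_means(self) -> dict:
        """Mean within-environment R2 per environment over replicates."""
        envs: dict = {}
        for w in self.within_env:
            for env, v in w.per_env.items():
                envs.setdefault(env, []).append(v)
        return {env: float(np.mean(v)) for env, v in envs.items()}


def _subset_kernel(k: Kernel, idx: np.ndarray) -> Kernel:
    return Kernel(k.ids[idx], k.values[np.ix_(idx, idx)], k.level, k.name, dict(k.meta))


def _run_rkhs(records, model, plan, g):
    spec_full = build_model_spec(model, records, g)
    result = CVResult(model, plan.scheme, fittable=True)
    y = records.phenotype
    envs = records.table["env_id"].to_numpy()
    for rep, (tr, te) in enumerate(plan.replicates):
        try:
            spec_tr = ModelSpec(
                spec_full.name, [_subset_kernel(k, tr) for k in spec_full.kernels]
            )
            fit = reml_fit(records.subset(tr), spec_tr)
            yhat = blup_predict(fit, tr, te, spec_full.kernels)
            result.pooled.append(float(r2_pooled(y[te], yhat)))
            result.within_env.append(r2_within_env(y[te], yhat, envs[te]))
        except Exception as err:  # recorded, not fatal to the sweep
            logger.warning("%s replicate %d failed: %s", model, rep, err)
            result.failures.append(f"replicate {rep}: {err}")
    return result


def _run_mtm(records, plan, g, mcmc, seed):
    result = CVResult("mvG-BLUP", plan.scheme, fittable=True)
    if plan.scheme == "new_environment":
        # the trait list is fixed by Y's columns: an unobserved environment
        # has no column, so this model cannot predict into it
        return CVResult(
            "mvG-BLUP", plan.scheme, fittable=False,
            reason="mvG-BLUP cannot predict in an environment absent from training",
        )
    tab = records.table
    lines = records.line_ids
    envs = records.env_ids
    lpos = {l: i for i, l in enumerate(lines)}
    epos = {e: j for j, e in enumerate(envs)}
    rows = tab["line_id"].map(lpos).to_numpy()
    cols = tab["env_id"].map(epos).to_numpy()
    Y_full = np.full((len(lines), len(envs)), np.nan)
    Y_full[rows, cols] = records.phenotype
    g_aligned = Kernel(
        lines, _reindex(g, lines), level="line", name=g.name, meta=dict(g.meta)
    )
    y = records.phenotype
    env_arr = tab["env_id"].to_numpy()
    for rep, (tr, te) in enumerate(plan.replicates):
        try:
            Y = Y_full.copy()
            Y[rows[te], cols[te]] = np.nan
            fit = gibbs_fit(
                Y, g_aligned, seed=None if seed is None else seed + rep,
                env_ids=envs, **mcmc,
            )
            yhat = mtm_predict(fit, np.column_stack([rows[te], cols[te]]))
            result.pooled.append(float(r2_pooled(y[te], yhat)))
            result.within_env.append(r2_within_env(y[te], yhat, env_arr[te]))
        except Exception as err:
            logger.warning("mvG-BLUP replicate %d failed: %s", rep, err)
            result.failures.append(f"replicate {rep}: {err}")
    return result


def _reindex(g: Kernel, lines) -> np.ndarray:
    pos = {l: i for i, l in enumerate(g.ids)}
    idx = np.array([pos[l] for l in lines], dtype=int)
    return g.values[np.ix_(idx, idx)]


def _run_rrm(records, plan, g, order, env_values_override):
    result = CVResult("RRM", plan.scheme, fittable=True)
    y = records.phenotype
    env_arr = records.table["env_id"].to_numpy()
    for rep, (tr, te) in enumerate(plan.replicates):
        try:
            env_vals = env_covariate_from_training(records, tr)
            test_envs = set(env_arr[te])
            missing = sorted(test_envs - set(env_vals))
            if missing:
                if not env_values_override:
                    return CVResult(
                        "RRM", plan.scheme, fittable=False,
                        reason=(
                            "environment(s) unseen in training have no gradient value; "
                            "supply rrm_env_values explicitly"
                        ),
                    )
                for env in missing:
                    if env not in env_values_override:
                        raise KeyError(f"no gradient value supplied for unseen env {env!r}")
            if len(env_vals) < 2:
                raise ValueError("RRM needs >= 2 training environments")
            basis = legendre_basis(env_vals, T=order)
            for env in missing:
                basis = basis.with_env(env, env_values_override[env])
            fit = rrm_fit(records.subset(tr), basis, g)
            yhat = rrm_predict(fit, basis, records.subset(te))
            result.pooled.append(float(r2_pooled(y[te], yhat)))
            result.within_env.append(r2_within_env(y[te], yhat, env_arr[te]))
        except Exception as err:
            logger.warning("RRM replicate %d failed: %s", rep, err)
            result.failures.append(f"replicate {rep}: {err}")
    if result.failures and not result.pooled:
        result.fittable = False
        result.reason = result.failures[0]
    return result


def run_cv(
    records: RecordFrame,
    model: str,
    plan: CVPlan,
    g: Kernel,
    seed: int | None = None,
    mcmc: dict | None = None,
    rrm_order: int = 1,
    rrm_env_values: dict | None = None,
) -> CVResult:
    """Fit ``model`` on each training split of ``plan`` and score the test split.

    Model names: the four RKHS models (``G-BLUP``, ``E-BLUP``, ``GE-BLUP``,
    ``GxE-BLUP``), ``mvG-BLUP`` (Gibbs chain settings via ``mcmc``; the
    reduced test profile is the default here), and ``RRM`` (gradient values
    for environments unseen in training must come through
    ``rrm_env_values`` — deriving them from held-out data would leak).

    Structurally infeasible combinations (mvG-BLUP or value-less RRM under
    ``new_environment``) return a result flagged not fittable rather than
    raising. Per-replicate fit failures are recorded and skipped.
    """
    if model in MODEL_KERNELS:
        result = _run_rkhs(records, model, plan, g)
    elif model == "mvG-BLUP":
        result = _run_mtm(records, plan, g, dict(mcmc or TEST_CHAIN), seed)
    elif model == "RRM":
        result = _run_rrm(records, plan, g, rrm_order, rrm_env_values)
    else:
        raise ValueError(f"unknown model {model!r}; expected one of {CV_MODELS}")
    result.provenance = {
        "scheme": plan.scheme,
        "plan_seed": plan.seed,
        "test_fraction": plan.test_fraction,
        "replicates": len(plan.replicates),
        "seed": seed,
    }
    return result
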