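"""Bayesian multiple-trait model (mvG-BLUP) fitted by Gibbs sampling.

The phenotype of each line in each environment is treated as a separate,
genetically correlated trait: Y = 1 m' + A + R with A ~ MN(0, G, Sigma_A)
and R ~ MN(0, I, Sigma_R), Sigma_R diagonal. Missing cells are handled by
data augmentation, which is what makes prediction of held-out cells (or of
whole held-out lines) coherent in this model. Because the trait list is
fixed by Y's columns, predicting into an environment that was never
observed is structurally impossible here — the API offers no way to ask
for it.

The sampler exploits the eigendecomposition G = U D U': after rotating the
data by U', the rows of the genetic-value matrix are independent, so each
Gibbs update of A reduces to n independent r x r Gaussian draws.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .kernels import Kernel

logger = logging.getLogger(__name__)

__all__ = ["MTMFit", "MTMPriors", "gibbs_fit", "genetic_correlations", "heritability", "mtm_predict"]

#: the production chain profile (300k iterations, 200k burn-in, thin 50)
PRODUCTION_CHAIN = {"iters": 300_000, "burnin": 200_000, "thin": 50}
#: reduced profile for tests and desk-scale runs
TEST_CHAIN = {"iters": 6_000, "burnin": 2_000, "thin": 4}


@dataclass
class MTMPriors:
    """Weakly-informative conjugate priors for the multi-trait model.

    Sigma_A ~ inverse-Wishart(df = r + 2, scale = 0.5 * diag(var_j));
    each Sigma_R[j,j] ~ scaled inverse-chi2(df = 5, scale = 0.5 * var_j);
    the intercepts m are flat. var_j is the per-environment phenotypic
    variance of the observed cells.
    """

    sa_df_extra: float = 2.0
    sa_scale_frac: float = 0.5
    sr_df: float = 5.0
    sr_scale_frac: float = 0.5


@dataclass
class MTMFit:
    """Posterior summaries and retained draws from the Gibbs chain."""

    env_ids: np.ndarray
    line_ids: np.ndarray
    m_mean: np.ndarray  # (r,)
    A_mean: np.ndarray  # (n, r)
    SA_mean: np.ndarray  # (r, r)
    SR_mean: np.ndarray  # (r,) diagonal
    SA_draws: np.ndarray  # (ndraws, r, r)
    SR_draws: np.ndarray  # (ndraws, r)
    m_draws: np.ndarray  # (ndraws, r)
    observed: np.ndarray  # (n, r) bool mask of cells seen during fitting
    settings: dict = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        return self.SA_draws.shape[0]

    @property
    def rA_draws(self) -> np.ndarray:
        sd = np.sqrt(np.einsum("kii->ki", self.SA_draws))
        return self.SA_draws / (sd[:, :, None] * sd[:, None, :])

    def draws_table(self):
        """Retained draws in long format (iteration, parameter, value)."""
        import pandas as pd

        rows = []
        for it in range(self.n_draws):
            for j, ej in enumerate(self.env_ids):
                rows.append((it, f"m[{ej}]", self.m_draws[it, j]))
                rows.append((it, f"SR[{ej}]", self.SR_draws[it, j]))
                for k, ek in enumerate(self.env_ids[: j + 1]):
                    rows.append((it, f"SA[{ek},{ej}]", self.SA_draws[it, k, j]))
        return pd.DataFrame(rows, columns=["iteration", "parameter", "value"])

    def effective_sample_sizes(self) -> dict[str, float]:
        """Autocorrelation-based ESS for the genetic and residual variances."""
        out = {}
        for j, env in enumerate(self.env_ids):
            out[f"SA[{env},{env}]"] = _ess(self.SA_draws[:, j, j])
            out[f"SR[{env}]"] = _ess(self.SR_draws[:, j])
        return out


def _ess(x: np.ndarray) -> float:
    """Effective sample size via the initial-positive-sequence estimator."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 4 or np.var(x) == 0.0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    tau = 1.0
    for lag in range(1, n // 2):
        if acf[lag] <= 0.0:
            break
        tau += 2.0 * acf[lag]
    return float(n / max(tau, 1.0))


def gibbs_fit(
    Y: np.ndarray,
    G: Kernel,
    iters: int = PRODUCTION_CHAIN["iters"],
    burnin: int = PRODUCTION_CHAIN["burnin"],
    thin: int = PRODUCTION_CHAIN["thin"],
    seed: int | None = None,
    priors: MTMPriors | None = None,
    env_ids=None,
) -> MTMFit:
    """Run the Gibbs sampler for the multi-trait model on an n x r matrix Y.

    ``nan`` cells are missing and sampled by data augmentation each cycle.
    The chain is reproducible for a fixed ``seed``. Rows of Y must align
    with the line-level kernel ``G``; every environment (column) needs at
    least 2 observed values.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2:
        raise ValueError("Y must be an n x r matrix")
    n, r = Y.shape
    if G.level != "line" or G.size != n:
        raise ValueError("G must be a line-level kernel aligned to the rows of Y")
    observed = ~np.isnan(Y)
    if (observed.sum(axis=0) < 2).any():
        bad = np.flatnonzero(observed.sum(axis=0) < 2)
        raise ValueError(f"environments with <2 observed values: {bad}")
    if burnin >= iters:
        raise ValueError("burnin must be smaller than iters")
    priors = priors or MTMPriors()
    rng = np.random.default_rng(seed)
    env_ids = np.asarray(env_ids if env_ids is not None else np.arange(r), dtype=object)

    # eigenstructure of G; jitter if numerically singular
    w, U = np.linalg.eigh(G.values)
    if w.min() < 1e-8 * max(w.max(), 1.0):
        logger.warning("G numerically singular (min eig %.2e): adding 1e-6 jitter", w.min())
        w = w + 1e-6
    d = w  # (n,)

    var_env = np.array([np.nanvar(Y[:, j][observed[:, j]], ddof=1) for j in range(r)])
    var_env = np.maximum(var_env, 1e-12)
    sa_df0 = r + priors.sa_df_extra
    sa_S0 = priors.sa_scale_frac * np.diag(var_env)
    sr_df0 = priors.sr_df
    sr_s0 = priors.sr_scale_frac * var_env

    # initial state
    col_mean = np.array([Y[:, j][observed[:, j]].mean() for j in range(r)])
    m = col_mean.copy()
    A = np.zeros((n, r))
    SA = 0.5 * np.diag(var_env)
    SR = 0.5 * var_env
    Yc = np.where(observed, Y, col_mean[None, :])

    n_keep = (iters - burnin) // thin
    SA_draws = np.empty((n_keep, r, r))
    SR_draws = np.empty((n_keep, r))
    m_draws = np.empty((n_keep, r))
    A_sum = np.zeros((n, r))
    kept = 0

    Ut = U.T
    for it in range(iters):
        # 1. impute missing cells
        if (~observed).any():
            noise = rng.standard_normal(Y.shape) * np.sqrt(SR)[None, :]
            Yc = np.where(observed, Y, m[None, :] + A + noise)
        # 2. intercepts (flat prior)
        resid_mean = (Yc - A).mean(axis=0)
        m = resid_mean + rng.standard_normal(r) * np.sqrt(SR / n)
        # 3. genetic values in the eigenbasis of G: rows decouple
        SA_inv = np.linalg.inv(SA)
        SR_inv_diag = 1.0 / SR
        Yt = Ut @ (Yc - m[None, :])
        prec = SA_inv[None, :, :] / d[:, None, None] + np.diag(SR_inv_diag)[None, :, :]
        chol = np.linalg.cholesky(prec)  # stacked (n, r, r)
        rhs = Yt * SR_inv_diag[None, :]
        mean = _stacked_chol_solve(chol, rhs)
        z = rng.standard_normal((n, r))
        # draw = mean + L^-T z where prec = L L'
        At = mean + np.linalg.solve(np.transpose(chol, (0, 2, 1)), z[:, :, None])[:, :, 0]
        A = U @ At
        # 4. genetic covariance (inverse-Wishart full conditional)
        S_post = sa_S0 + (At / d[:, None]).T @ At
        S_post = (S_post + S_post.T) / 2.0
        for _ in range(3):
            try:
                SA = stats.invwishart.rvs(df=sa_df0 + n, scale=S_post, random_state=rng)
                SA = np.atleast_2d(SA)
                np.linalg.cholesky(SA)
                break
            except np.linalg.LinAlgError:
                logger.info("non-PD Sigma_A draw: resampling with inflated df")
                SA = stats.invwishart.rvs(df=sa_df0 + n + r, scale=S_post, random_state=rng)
                SA = np.atleast_2d(SA)
        # 5. residual variances (scaled inverse-chi2 full conditionals)
        E = Yc - m[None, :] - A
        ss = (E**2).sum(axis=0)
        SR = (sr_df0 * sr_s0 + ss) / rng.chisquare(sr_df0 + n, size=r)
        if it >= burnin and (it - burnin) % thin == 0 and kept < n_keep:
            SA_draws[kept] = SA
            SR_draws[kept] = SR
            m_draws[kept] = m
            A_sum += A
            kept += 1

    return MTMFit(
        env_ids=env_ids,
        line_ids=np.asarray(G.ids, dtype=object),
        m_mean=m_draws[:kept].mean(axis=0),
        A_mean=A_sum / max(kept, 1),
        SA_mean=SA_draws[:kept].mean(axis=0),
        SR_mean=SR_draws[:kept].mean(axis=0),
        SA_draws=SA_draws[:kept],
        SR_draws=SR_draws[:kept],
        m_draws=m_draws[:kept],
        observed=observed,
        settings={"iters": iters, "burnin": burnin, "thin": thin, "seed": seed},
    )


def _stacked_chol_solve(chol: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve (L L') x = rhs for stacked Cholesky factors L (n, r, r)."""
    y = np.linalg.solve(chol, rhs[:, :, None])
    return np.linalg.solve(np.transpose(chol, (0, 2, 1)), y)[:, :, 0]


def genetic_correlations(fit: MTMFit) -> np.ndarray:
    """Posterior mean cross-environment genetic correlation matrix rA.

    Computed per retained draw as SA[j,k] / sqrt(SA[j,j] SA[k,k]) and then
    averaged — not the correlation of the posterior mean covariance.
    """
    return fit.rA_draws.mean(axis=0)


def heritability(fit: MTMFit) -> np.ndarray:
    """Per-environment genomic heritability SA[j,j] / (SA[j,j] + SR[j,j])."""
    diag = np.einsum("kii->ki", fit.SA_draws)
    return (diag / (diag + fit.SR_draws)).mean(axis=0)


def mtm_predict(fit: MTMFit, target_cells) -> np.ndarray:
    """Posterior-mean predictions m_j + A_ij for cells held out during fitting.

    ``target_cells`` is a sequence of (row, column) indices into Y. Asking
    for a cell that was observed during fitting raises — that would leak
    training data into an accuracy estimate.
    """
    cells = np.asarray(target_cells, dtype=int)
    if cells.ndim != 2 or cells.shape[1] != 2:
        raise ValueError("target_cells must be (k, 2) row/column indices")
    leaked = [tuple(c) for c in cells if fit.observed[c[0], c[1]]]
    if leaked:
        raise ValueError(f"cells were observed during fitting: {leaked[:5]}")
    return fit.m_mean[cells[:, 1]] + fit.A_mean[cells[:, 0], cells[:, 1]]
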