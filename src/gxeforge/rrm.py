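"""Random regression (reaction norm) model over an environmental gradient.

Each line gets its own intercept-plus-slope (order T = 1 by default) on a
Legendre polynomial basis of the environmental value:

    y_ij = sum_t beta_t phi_t(j) + sum_t a_it phi_t(j) + eps_ij

with random coefficients a ~ N(0, G (x) Sigma_a) and per-environment
residual variances. The environmental value of an environment is, by
default, the mean phenotype across lines in the *training* records — so a
held-out environment has no value unless the caller supplies one
explicitly; silently reusing test data to place an environment on the
gradient would leak.

REML estimation exploits that the phenotypic covariance is linear in the
entries of Sigma_a and in the residual variances:

    V = G_rec o (Phi Sigma_a Phi') + diag(s2_env),

so Fisher scoring with the average-information matrix applies directly,
with step-halving to keep the restricted likelihood non-decreasing and
residual variances positive. Sigma_a is unconstrained during iteration and
projected to the PSD cone on exit if numerical noise pushed it outside.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg as sla

from .datatypes import RecordFrame
from .kernels import Kernel
from .reml import _factor_v

logger = logging.getLogger(__name__)

__all__ = [
    "LegendreBasis",
    "RRMFit",
    "env_covariate_from_training",
    "legendre_basis",
    "rrm_fit",
    "rrm_predict",
]


def _legendre_columns(x: np.ndarray, T: int) -> np.ndarray:
    """Plain (unnormalized) Legendre polynomials P_0..P_T at points x."""
    cols = [np.ones_like(x)]
    if T >= 1:
        cols.append(x.copy())
    for t in range(1, T):
        cols.append(((2 * t + 1) * x * cols[t] - t * cols[t - 1]) / (t + 1))
    return np.column_stack(cols)


@dataclass
class LegendreBasis:
    """Legendre polynomial basis over per-environment gradient positions.

    The affine normalization mapping min(env_values) -> -1 and max -> +1 is
    fixed at construction; environments added later (e.g. a held-out
    environment with a user-supplied value) pass through the same map and
    may fall outside [-1, 1], which triggers an extrapolation warning at
    prediction time.
    """

    env_ids: np.ndarray
    env_values: np.ndarray
    order: int
    vmin: float = field(init=False)
    vmax: float = field(init=False)
    x: np.ndarray = field(init=False)
    Phi: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.env_ids = np.asarray(self.env_ids, dtype=object)
        self.env_values = np.asarray(self.env_values, dtype=float)
        vals = self.env_values
        if len(np.unique(vals)) < 2:
            raise ValueError("need >= 2 distinct environmental values to normalize")
        self.vmin, self.vmax = float(vals.min()), float(vals.max())
        self.x = self.normalize(vals)
        self.Phi = _legendre_columns(self.x, self.order)

    def normalize(self, values) -> np.ndarray:
        return 2.0 * (np.asarray(values, float) - self.vmin) / (self.vmax - self.vmin) - 1.0

    def phi_for_env(self, env_id) -> np.ndarray:
        idx = np.flatnonzero(self.env_ids == env_id)
        if idx.size == 0:
            raise KeyError(
                f"environment {env_id!r} has no gradient value in this basis; "
                "supply one explicitly (it cannot be derived from held-out data)"
            )
        return self.Phi[idx[0]]

    def with_env(self, env_id, value: float) -> "LegendreBasis":
        """Return a basis extended with an extra environment at ``value``.

        The normalization bounds stay those of the original basis.
        """
        if env_id in self.env_ids:
            raise ValueError(f"environment {env_id!r} already in basis")
        out = LegendreBasis(
            np.append(self.env_ids, env_id),
            np.append(self.env_values, value),
            self.order,
        )
        # keep the parent's normalization map
        out.vmin, out.vmax = self.vmin, self.vmax
        out.x = out.normalize(out.env_values)
        out.Phi = _legendre_columns(out.x, out.order)
        return out

    def rows_for(self, env_ids) -> np.ndarray:
        return np.vstack([self.phi_for_env(e) for e in env_ids])


def env_covariate_from_training(records: RecordFrame, training_idx) -> dict:
    """Per-environment mean phenotype computed from training records only."""
    sub = records.table.iloc[np.asarray(training_idx, dtype=int)]
    means = sub.groupby("env_id")["phenotype"].mean()
    return {env: float(v) for env, v in means.items()}


def legendre_basis(env_values: dict, T: int = 1) -> LegendreBasis:
    """Build the r x (T+1) Legendre basis from an env_id -> gradient mapping."""
    if T < 0:
        raise ValueError("polynomial order must be >= 0")
    env_ids = np.array(sorted(env_values), dtype=object)
    vals = np.array([env_values[e] for e in env_ids], dtype=float)
    return LegendreBasis(env_ids, vals, T)


@dataclass
class RRMFit:
    """REML estimates for the random regression model."""

    beta: np.ndarray  # (T+1,) fixed polynomial coefficients
    Sigma_a: np.ndarray  # (T+1, T+1) coefficient covariance
    line_coefs: np.ndarray  # (n, T+1) BLUP coefficients per line of G
    line_ids: np.ndarray
    resid_var: dict  # env_id -> residual variance
    reml_loglik: float
    converged: bool
    n_iter: int
    order: int
    boundary: bool = False  # Sigma_a projected to PSD on exit


def rrm_fit(
    records: RecordFrame,
    basis: LegendreBasis,
    G: Kernel,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> RRMFit:
    """Fit the random regression model by AI-REML on its linear components.

    ``records`` are the training records (no missing phenotypes); ``basis``
    must cover every training environment; ``G`` is the line-level GRM
    covering at least the training lines (extra lines get BLUP coefficients
    through their genomic relationships, enabling prediction of unseen
    lines).
    """
    y = records.phenotype
    if np.isnan(y).any():
        raise ValueError("missing phenotypes among training records")
    q = len(y)
    Tp1 = basis.order + 1
    envs = records.table["env_id"].to_numpy()
    env_list = [e for e in basis.env_ids if e in set(envs)]
    env_pos = {e: j for j, e in enumerate(env_list)}
    r = len(env_list)
    env_idx = np.array([env_pos[e] for e in envs], dtype=int)
    Phi_rec = basis.rows_for(envs)  # (q, T+1)
    gpos = {lid: i for i, lid in enumerate(G.ids)}
    try:
        line_idx = np.array([gpos[l] for l in records.table["line_id"]], dtype=int)
    except KeyError as err:
        raise KeyError(f"line {err.args[0]!r} missing from G") from None
    G_rec = G.values[np.ix_(line_idx, line_idx)]
    X = Phi_rec

    vary = float(np.var(y))
    n_sa = Tp1 * (Tp1 + 1) // 2
    sa_pairs = [(t, s) for t in range(Tp1) for s in range(t, Tp1)]
    theta = np.concatenate(
        [
            [vary / (2 * Tp1) if t == s else 0.0 for t, s in sa_pairs],
            np.full(r, vary / 2.0),
        ]
    )
    floor = 1e-10 * vary

    def sigma_a(th):
        S = np.zeros((Tp1, Tp1))
        for k, (t, s) in enumerate(sa_pairs):
            S[t, s] = S[s, t] = th[k]
        return S

    def build_v(th):
        S = sigma_a(th)
        V = G_rec * (Phi_rec @ S @ Phi_rec.T)
        V[np.arange(q), np.arange(q)] += th[n_sa + env_idx]
        return V

    def quantities(th):
        V = build_v(th)
        cf, _ = _factor_v(V)
        logdet_v = 2.0 * np.sum(np.log(np.diag(cf[0])))
        Vi = sla.cho_solve(cf, np.eye(q))
        M = Vi @ X
        XtViX = X.T @ M
        cfx = sla.cho_factor(XtViX)
        logdet_x = 2.0 * np.sum(np.log(np.diag(cfx[0])))
        beta = sla.cho_solve(cfx, M.T @ y)
        w = Vi @ y - M @ beta
        ll = -0.5 * (logdet_v + logdet_x + float(y @ w))
        P = Vi - M @ sla.cho_solve(cfx, M.T)
        return ll, P, w, beta

    ll, P, w, beta = quantities(theta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        PG = P * G_rec
        Q = Phi_rec.T @ PG @ Phi_rec
        Phw = Phi_rec * w[:, None]
        R = Phw.T @ G_rec @ Phw
        score = np.empty(len(theta))
        for k, (t, s) in enumerate(sa_pairs):
            mult = 1.0 if t == s else 2.0
            score[k] = -0.5 * mult * (Q[t, s] - R[t, s])
        pdiag = np.diag(P)
        for j in range(r):
            mask = env_idx == j
            score[n_sa + j] = -0.5 * (pdiag[mask].sum() - float(w[mask] @ w[mask]))
        # AI matrix from u_k = (dV/dtheta_k) w
        Gw = G_rec @ Phw  # column t = G (phi_t o w)
        us = []
        for t, s in sa_pairs:
            if t == s:
                us.append(Phi_rec[:, t] * Gw[:, t])
            else:
                us.append(Phi_rec[:, t] * Gw[:, s] + Phi_rec[:, s] * Gw[:, t])
        for j in range(r):
            us.append(np.where(env_idx == j, w, 0.0))
        U = np.stack(us)
        PU = U @ P  # P symmetric
        AI = 0.5 * (U @ PU.T)
        AI = (AI + AI.T) / 2.0
        try:
            step = np.linalg.solve(AI + 1e-10 * np.trace(AI) * np.eye(len(theta)), score)
        except np.linalg.LinAlgError:
            step = score / max(np.trace(AI), 1.0)
        accepted = False
        frac = 1.0
        for _ in range(12):
            cand = theta + frac * step
            if (cand[n_sa:] > floor).all():
                try:
                    ll_new, P_n, w_n, beta_n = quantities(cand)
                except np.linalg.LinAlgError:
                    ll_new = -np.inf  # indefinite V: reject the step
                if np.isfinite(ll_new) and ll_new >= ll - 1e-10 * (abs(ll) + 1.0):
                    accepted = True
                    break
            frac /= 2.0
        if not accepted:
            converged = True  # no uphill step found: at (numerical) optimum
            break
        theta, P, w, beta = cand, P_n, w_n, beta_n
        if abs(ll_new - ll) < tol * (abs(ll) + 1.0):
            ll = ll_new
            converged = True
            break
        ll = ll_new
    else:
        logger.warning("RRM REML did not converge in %d iterations", max_iter)

    Sa = sigma_a(theta)
    evals, evecs = np.linalg.eigh(Sa)
    boundary = bool(evals[0] < -1e-10 * max(evals[-1], vary))
    if evals[0] < 0.0:
        if boundary:
            logger.info("Sigma_a left the PSD cone (min eig %.3e): projecting", evals[0])
        Sa = (evecs * np.maximum(evals, 0.0)) @ evecs.T

    # BLUP coefficients for every line of G through genomic relationships
    Gcols = G.values[:, line_idx]  # (n_G, q)
    line_coefs = Gcols @ (w[:, None] * (Phi_rec @ Sa))
    resid = {e: float(theta[n_sa + env_pos[e]]) for e in env_list}
    return RRMFit(
        beta=beta,
        Sigma_a=Sa,
        line_coefs=line_coefs,
        line_ids=np.asarray(G.ids, dtype=object),
        resid_var=resid,
        reml_loglik=float(ll) - 0.5 * (q - Tp1) * np.log(2.0 * np.pi),
        converged=converged,
        n_iter=it,
        order=basis.order,
        boundary=boundary,
    )


def rrm_predict(fit: RRMFit, basis: LegendreBasis, target_records: RecordFrame) -> np.ndarray:
    """Predict target records: yhat_ij = phi_j' (beta + a_i).

    Lines present in the GRM used at fit time get their BLUP coefficients
    (zero for lines genomically unrelated to training lines); lines absent
    from the GRM fall back to the fixed trajectory. Environments whose
    gradient position lies outside the training normalization range are
    predicted with an extrapolation warning.
    """
    tab = target_records.table
    phi = basis.rows_for(tab["env_id"])
    xnorm = phi[:, 1] if basis.order >= 1 else np.zeros(len(tab))
    if (np.abs(xnorm) > 1.0 + 1e-12).any():
        warnings.warn(
            "target environment(s) outside the training gradient range: extrapolating",
            stacklevel=2,
        )
    pos = {lid: i for i, lid in enumerate(fit.line_ids)}
    coefs = np.zeros((len(tab), fit.line_coefs.shape[1]))
    unknown = 0
    for k, lid in enumerate(tab["line_id"]):
        i = pos.get(lid)
        if i is None:
            unknown += 1
        else:
            coefs[k] = fit.line_coefs[i]
    if unknown:
        logger.warning("%d target line(s) absent from the GRM: fixed-trajectory prediction", unknown)
    return phi @ fit.beta + np.sum(phi * coefs, axis=1)
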