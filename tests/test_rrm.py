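import numpy as np
import pandas as pd
import pytest

from gxeforge import (
    Kernel,
    RecordFrame,
    env_covariate_from_training,
    grm_vanraden,
    legendre_basis,
    rrm_fit,
    rrm_predict,
)
from gxeforge.rrm import _legendre_columns

from conftest import SIX_ENVS, make_records


class TestLegendreBasis:
    def test_normalization_of_temperatures(self):
        """18/25/28 map to -1, 0.4, 1 and the order-1 column equals them."""
        basis = legendre_basis({"18": 18.0, "25": 25.0, "28": 28.0}, T=1)
        np.testing.assert_allclose(sorted(basis.x), [-1.0, 0.4, 1.0])
        np.testing.assert_allclose(basis.Phi[:, 0], 1.0)
        np.testing.assert_allclose(sorted(basis.Phi[:, 1]), [-1.0, 0.4, 1.0])

    def test_order_zero_is_all_ones(self):
        basis = legendre_basis({"a": 1.0, "b": 2.0}, T=0)
        np.testing.assert_allclose(basis.Phi, np.ones((2, 1)))

    def test_orthogonality_by_quadrature(self):
        """P_i P_j integrates to 0 over [-1, 1] for i != j up to order 4."""
        x, w = np.polynomial.legendre.leggauss(12)
        cols = _legendre_columns(x, 4)
        for i in range(5):
            for j in range(5):
                integral = np.sum(w * cols[:, i] * cols[:, j])
                if i != j:
                    assert abs(integral) < 1e-10
                else:
                    assert integral == pytest.approx(2.0 / (2 * i + 1), abs=1e-10)

    def test_constant_values_error(self):
        with pytest.raises(ValueError, match="distinct"):
            legendre_basis({"a": 1.0, "b": 1.0}, T=1)

    def test_unknown_env_errors_without_value(self):
        basis = legendre_basis({"a": 1.0, "b": 2.0}, T=1)
        with pytest.raises(KeyError, match="cannot be derived"):
            basis.phi_for_env("c")

    def test_extension_keeps_normalization(self):
        basis = legendre_basis({"a": 10.0, "b": 20.0}, T=1)
        ext = basis.with_env("c", 25.0)
        assert ext.normalize(10.0) == -1.0 and ext.normalize(20.0) == 1.0
        assert ext.phi_for_env("c")[1] == pytest.approx(2.0)  # extrapolated


class TestEnvCovariate:
    def test_training_means(self, records_factory):
        rec = records_factory(n_lines=2, phen=[10.0, 1.0, 20.0, 3.0])
        vals = env_covariate_from_training(rec, np.arange(4))
        assert vals["E1"] == pytest.approx(15.0)
        assert vals["E2"] == pytest.approx(2.0)

    def test_training_subset_only(self, records_factory):
        rec = records_factory(n_lines=2, phen=[10.0, 1.0, 20.0, 3.0])
        vals = env_covariate_from_training(rec, [0, 1])  # first line only
        assert vals["E1"] == pytest.approx(10.0)

    def test_unseen_env_absent(self, records_factory):
        rec = records_factory(n_lines=2)
        idx = np.flatnonzero(rec.table.env_id == "E1")
        vals = env_covariate_from_training(rec, idx)
        assert "E2" not in vals


def _rrm_data(n=40, seed=0, sigma_a=None, resid=0.05, beta=(1.0, 0.5), p=400):
    """Synthetic reaction-norm data on a six-environment gradient."""
    from gxeforge import SimConfig, simulate_genotypes

    rng = np.random.default_rng(seed)
    g = simulate_genotypes(SimConfig(n_lines=n, n_variants=p, seed=seed))
    grm = grm_vanraden(g)
    env_vals = {e: v for (e, _, _), v in zip(SIX_ENVS, [30.0, 50.0, 60.0, 28.0, 45.0, 55.0])}
    basis = legendre_basis(env_vals, T=1)
    if sigma_a is None:
        sigma_a = np.array([[0.4, -0.1], [-0.1, 0.2]])
    La = np.linalg.cholesky(sigma_a + 1e-12 * np.eye(2))
    Lg = np.linalg.cholesky(grm.values + 1e-8 * np.eye(n))
    coefs = Lg @ rng.standard_normal((n, 2)) @ La.T
    rows = []
    env_pos = {e: j for j, e in enumerate(basis.env_ids)}
    for i, lid in enumerate(grm.ids):
        for env_id, sex, temp in SIX_ENVS:
            phi = basis.Phi[env_pos[env_id]]
            y = phi @ np.asarray(beta) + phi @ coefs[i] + rng.normal(0, np.sqrt(resid))
            rows.append({"line_id": lid, "env_id": env_id, "phenotype": y,
                         "sex": sex, "temperature": temp})
    rec = RecordFrame(pd.DataFrame(rows), ["sex", "temperature"])
    return rec, basis, grm, coefs


class TestRRMFit:
    def test_recovers_known_covariance(self):
        rec, basis, grm, _ = _rrm_data(n=80, seed=3)
        fit = rrm_fit(rec, basis, grm)
        assert fit.converged
        assert fit.Sigma_a[0, 0] == pytest.approx(0.4, abs=0.15)
        assert fit.Sigma_a[1, 1] == pytest.approx(0.2, abs=0.1)
        assert fit.Sigma_a[0, 1] < 0.05  # negative correlation direction
        for v in fit.resid_var.values():
            assert v == pytest.approx(0.05, rel=0.6)

    def test_nesting_t1_beats_t0(self):
        rec, basis, grm, _ = _rrm_data(n=40, seed=4)
        fit1 = rrm_fit(rec, basis, grm)
        basis0 = legendre_basis(dict(zip(basis.env_ids, basis.env_values)), T=0)
        fit0 = rrm_fit(rec, basis0, grm)
        assert fit1.reml_loglik >= fit0.reml_loglik - 1e-6

    def test_zero_slope_variance_detected(self):
        """Data with no slope variance pins Sigma_a[1,1] near zero and the
        fit matches a random-intercept model with the same fixed trajectory."""
        from scipy.optimize import minimize

        from gxeforge.reml import restricted_loglik

        rec, basis, grm, _ = _rrm_data(
            n=60, seed=5, sigma_a=np.array([[0.5, 0.0], [0.0, 0.0]]), resid=0.1
        )
        fit = rrm_fit(rec, basis, grm)
        assert fit.Sigma_a[1, 1] < 0.03
        # oracle: REML of y = Phi beta + intercept-only random line effect,
        # optimized directly on the restricted likelihood
        y = rec.phenotype
        env_pos = {e: j for j, e in enumerate(basis.env_ids)}
        Phi = np.vstack([basis.Phi[env_pos[e]] for e in rec.table.env_id])
        gpos = {l: i for i, l in enumerate(grm.ids)}
        idx = [gpos[l] for l in rec.table.line_id]
        G_rec = grm.values[np.ix_(idx, idx)]
        obj = lambda lp: -restricted_loglik(y, Phi, [G_rec], np.exp(lp))
        res = minimize(obj, np.log([0.3, 0.2]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000})
        oracle_ll = -res.fun
        # nested: the full RRM can only do better, and not by much
        assert fit.reml_loglik >= oracle_ll - 1e-4
        assert fit.reml_loglik - oracle_ll < 6.0

    def test_t0_single_env_matches_univariate_gblup(self):
        """Order 0, one record per line, one residual = univariate G-BLUP."""
        from gxeforge import ModelSpec, reml_fit

        rng = np.random.default_rng(6)
        # family-structured relationships identify the genetic variance from
        # a single record per line (unrelated lines would leave a flat ridge)
        nf, fs = 30, 5
        n = nf * fs
        block = 1.5 * np.ones((fs, fs)) + 0.5 * np.eye(fs)
        grm = Kernel(
            np.array([f"L{i:04d}" for i in range(n)], dtype=object),
            np.kron(np.eye(nf), block), "line", "G",
        )
        Lg = np.linalg.cholesky(grm.values + 1e-8 * np.eye(n))
        y = 3.0 + Lg @ rng.standard_normal(n) * 0.8 + rng.normal(0, 0.5, n)
        rows = [
            {"line_id": lid, "env_id": e, "phenotype": y[i] if e == "E1" else np.nan,
             "x": float(e == "E2")}
            for i, lid in enumerate(grm.ids) for e in ("E1", "E2")
        ]
        tab = pd.DataFrame([r for r in rows if not np.isnan(r["phenotype"])])
        rec = RecordFrame(tab, ["x"])
        basis = legendre_basis({"E1": 0.0, "E2": 1.0}, T=0)
        fit = rrm_fit(rec, basis, grm, tol=1e-12)
        gpos = {l: i for i, l in enumerate(grm.ids)}
        idx = [gpos[l] for l in rec.table.line_id]
        rec_ids = np.array([f"{l}:E1" for l in rec.table.line_id], dtype=object)
        spec = ModelSpec(
            "G-BLUP", [Kernel(rec_ids, grm.values[np.ix_(idx, idx)], "record", "genetic")]
        )
        ref = reml_fit(rec, spec, tol=1e-12)
        assert fit.Sigma_a[0, 0] == pytest.approx(ref.sigma2["genetic"], abs=1e-5)
        assert fit.resid_var["E1"] == pytest.approx(ref.sigma2["residual"], abs=1e-5)
        assert fit.reml_loglik == pytest.approx(ref.reml_loglik, abs=1e-6)


class TestRRMPredict:
    def test_linear_in_gradient(self):
        """T=1 predictions are affine in the normalized gradient per line."""
        rec, basis, grm, _ = _rrm_data(n=30, seed=7)
        fit = rrm_fit(rec, basis, grm)
        yhat = rrm_predict(fit, basis, rec)
        tab = rec.table
        env_pos = {e: j for j, e in enumerate(basis.env_ids)}
        xs = np.array([basis.x[env_pos[e]] for e in tab.env_id])
        for lid in rec.line_ids[:5]:
            mask = (tab.line_id == lid).to_numpy()
            coef = np.polyfit(xs[mask], yhat[mask], 1)
            resid = yhat[mask] - np.polyval(coef, xs[mask])
            assert np.abs(resid).max() < 1e-8

    def test_midpoint_interpolation(self):
        rec, basis, grm, _ = _rrm_data(n=30, seed=8)
        fit = rrm_fit(rec, basis, grm)
        ext = basis.with_env("mid", (basis.vmin + basis.vmax) / 2)
        lid = rec.line_ids[0]
        sub = rec.table[rec.table.line_id == lid].copy()
        lo = sub.iloc[[np.argmin([basis.x[list(basis.env_ids).index(e)] for e in sub.env_id])]]
        tab = pd.DataFrame(
            [{"line_id": lid, "env_id": e, "phenotype": 0.0, "sex": 0.0, "temperature": 0.0}
             for e in list(basis.env_ids) + ["mid"]]
        )
        target = RecordFrame(tab, ["sex", "temperature"])
        pred = rrm_predict(fit, ext, target)
        env_order = list(target.table.env_id)
        x = np.array([ext.x[list(ext.env_ids).index(e)] for e in env_order])
        # prediction at x=0 equals the average of predictions at x = +-c
        p_of = dict(zip(env_order, pred))
        x_of = dict(zip(env_order, x))
        lo_e = min(x_of, key=x_of.get)
        hi_e = max(x_of, key=x_of.get)
        interp = p_of[lo_e] + (p_of[hi_e] - p_of[lo_e]) * (0.0 - x_of[lo_e]) / (
            x_of[hi_e] - x_of[lo_e]
        )
        assert p_of["mid"] == pytest.approx(interp, abs=1e-8)

    def test_unrelated_line_gets_fixed_trajectory(self):
        rec, basis, _, _ = _rrm_data(n=30, seed=9)
        n = 30
        ids = np.append(rec.line_ids, "STRANGER")
        vals = np.eye(n + 1)
        grm = Kernel(ids, vals, "line", "G")
        fit = rrm_fit(rec, basis, grm)
        tab = pd.DataFrame(
            [{"line_id": "STRANGER", "env_id": basis.env_ids[0], "phenotype": 0.0,
              "sex": 0.0, "temperature": 0.0}]
        )
        pred = rrm_predict(fit, basis, RecordFrame(tab, ["sex", "temperature"]))
        expected = basis.Phi[0] @ fit.beta
        assert pred[0] == pytest.approx(expected, abs=1e-10)

    def test_extrapolation_warns(self):
        rec, basis, grm, _ = _rrm_data(n=30, seed=10)
        fit = rrm_fit(rec, basis, grm)
        ext = basis.with_env("hot", basis.vmax + 10.0)
        tab = pd.DataFrame(
            [{"line_id": rec.line_ids[0], "env_id": "hot", "phenotype": 0.0,
              "sex": 0.0, "temperature": 0.0}] * 1
            + [{"line_id": rec.line_ids[1], "env_id": "hot", "phenotype": 0.0,
                "sex": 0.0, "temperature": 0.0}]
        )
        target = RecordFrame(tab, ["sex", "temperature"])
        with pytest.warns(UserWarning, match="extrapolating"):
            pred = rrm_predict(fit, ext, target)
        assert np.isfinite(pred).all()
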