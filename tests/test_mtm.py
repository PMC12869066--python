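import numpy as np
import pandas as pd
import pytest

from gxeforge import (
    Kernel,
    ModelSpec,
    RecordFrame,
    genetic_correlations,
    gibbs_fit,
    heritability,
    mtm_predict,
    reml_fit,
)
from gxeforge.mtm import MTMFit

CHAIN = {"iters": 4000, "burnin": 1500, "thin": 2}


def _grm(n, seed, p=600):
    rng = np.random.default_rng(seed)
    f = rng.uniform(0.1, 0.5, p)
    d = 2.0 * (rng.random((n, p)) < f)
    w = d - 2 * f
    G = w @ w.T / (2 * (f * (1 - f)).sum())
    ids = np.array([f"L{i}" for i in range(n)], dtype=object)
    return Kernel(ids, G, "line", "G")


def _draw_mtm(G, SA, SR_diag, m, seed):
    rng = np.random.default_rng(seed)
    n, r = G.size, len(m)
    Lg = np.linalg.cholesky(G.values + 1e-8 * np.eye(n))
    La = np.linalg.cholesky(SA)
    A = Lg @ rng.standard_normal((n, r)) @ La.T
    R = rng.standard_normal((n, r)) * np.sqrt(SR_diag)
    return np.asarray(m) + A + R, A


def family_grm(n_families=150, fam_size=5):
    """Block-family GRM: strong within-family relatedness identifies the
    genetic variance from a single record per line."""
    n = n_families * fam_size
    block = 1.5 * np.ones((fam_size, fam_size)) + 0.5 * np.eye(fam_size)
    ids = np.array([f"L{i:04d}" for i in range(n)], dtype=object)
    return Kernel(ids, np.kron(np.eye(n_families), block), "line", "G")


def reml_univariate(Y, G):
    """Single-trait REML G-BLUP oracle on an n x 1 phenotype matrix."""
    rows = [
        {"line_id": lid, "env_id": "E0", "phenotype": Y[i, 0], "x": 0.0}
        for i, lid in enumerate(G.ids)
    ]
    rec = RecordFrame(pd.DataFrame(rows), ["x"])
    gpos = {l: i for i, l in enumerate(G.ids)}
    idx = [gpos[l] for l in rec.table.line_id]
    rec_ids = np.array([f"{l}:E0" for l in rec.table.line_id], dtype=object)
    spec = ModelSpec(
        "G-BLUP", [Kernel(rec_ids, G.values[np.ix_(idx, idx)], "record", "genetic")]
    )
    return reml_fit(rec, spec)


class TestGibbsFit:
    def test_r1_matches_univariate_reml(self):
        """With one trait the posterior means agree with REML G-BLUP.

        The posterior mean and the REML mode coincide asymptotically
        (Bernstein-von Mises); at finite n they differ by an O(1/n) term,
        so agreement is asserted at a half posterior SD — far below the
        posterior uncertainty, far above Monte-Carlo noise.
        """
        G = family_grm()
        Y, _ = _draw_mtm(G, np.array([[0.5]]), np.array([0.4]), [10.0], seed=12)
        fit = gibbs_fit(Y, G, seed=13, **CHAIN)
        reml = reml_univariate(Y, G)
        for draws, key in ((fit.SA_draws[:, 0, 0], "genetic"), (fit.SR_draws[:, 0], "residual")):
            assert abs(draws.mean() - reml.sigma2[key]) < 0.5 * draws.std()

    def test_null_genetic_correlations(self):
        """Pure noise with an identity GRM gives rA off-diagonals near 0."""
        n, r = 120, 3
        rng = np.random.default_rng(5)
        ids = np.array([f"L{i}" for i in range(n)], dtype=object)
        G = Kernel(ids, np.eye(n), "line", "G")
        Y = rng.standard_normal((n, r))
        fit = gibbs_fit(Y, G, seed=6, **CHAIN)
        ra = genetic_correlations(fit)
        sd = fit.rA_draws.std(axis=0)
        off = ~np.eye(r, dtype=bool)
        assert (np.abs(ra[off]) < 3.0 * np.maximum(sd[off], 0.05)).all()
        np.testing.assert_allclose(np.diag(ra), 1.0, atol=1e-12)

    def test_ra_recovery_known_sigma_a(self):
        """Known genetic correlations (0.9 / 0.6 / 0.5) are recovered."""
        n, r = 176, 3
        G = _grm(n, seed=21, p=1500)
        corr = np.array([[1.0, 0.9, 0.6], [0.9, 1.0, 0.5], [0.6, 0.5, 1.0]])
        SA = 0.6 * corr
        Y, _ = _draw_mtm(G, SA, np.full(r, 0.25), [5.0, 6.0, 7.0], seed=22)
        fit = gibbs_fit(Y, G, seed=23, **CHAIN)
        ra = genetic_correlations(fit)
        sd = fit.rA_draws.std(axis=0)
        for j, k in ((0, 1), (0, 2), (1, 2)):
            assert abs(ra[j, k] - corr[j, k]) < 2.0 * max(sd[j, k], 0.02)

    def test_seed_reproducible(self):
        G = _grm(40, seed=31)
        Y, _ = _draw_mtm(G, np.array([[0.5, 0.2], [0.2, 0.5]]), np.array([0.3, 0.3]),
                         [0.0, 1.0], seed=32)
        chain = {"iters": 400, "burnin": 100, "thin": 2}
        f1 = gibbs_fit(Y, G, seed=99, **chain)
        f2 = gibbs_fit(Y, G, seed=99, **chain)
        np.testing.assert_array_equal(f1.SA_draws, f2.SA_draws)
        np.testing.assert_array_equal(f1.A_mean, f2.A_mean)

    def test_low_noise_fits_observed_cells(self):
        """As residual variance shrinks, fitted cell means approach the data.

        The residual prior must be weak here, or its mass keeps Sigma_R
        (and hence the fitted-value spread) away from zero.
        """
        from gxeforge.mtm import MTMPriors

        G = _grm(60, seed=41)
        Y, _ = _draw_mtm(G, np.array([[1.0, 0.8], [0.8, 1.0]]),
                         np.array([1e-3, 1e-3]), [2.0, 3.0], seed=42)
        fit = gibbs_fit(Y, G, seed=43, priors=MTMPriors(sr_df=1.0, sr_scale_frac=0.01),
                        **CHAIN)
        fitted = fit.m_mean[None, :] + fit.A_mean
        assert np.abs(fitted - Y).max() < 0.15

    def test_invalid_inputs(self):
        G = _grm(10, seed=1)
        with pytest.raises(ValueError, match="burnin"):
            gibbs_fit(np.zeros((10, 2)), G, iters=100, burnin=200, thin=1)
        with pytest.raises(ValueError, match="aligned"):
            gibbs_fit(np.zeros((9, 2)), G, **CHAIN)
        Y = np.full((10, 2), np.nan)
        Y[:, 0] = 1.0
        Y[0, 1] = 1.0  # second env has a single observation
        with pytest.raises(ValueError, match="<2 observed"):
            gibbs_fit(Y, G, **CHAIN)


class TestDerivedSummaries:
    def _fit_from_draws(self, SA_draws, SR_draws):
        k, r = SR_draws.shape
        return MTMFit(
            env_ids=np.arange(r).astype(object),
            line_ids=np.array(["L0"], dtype=object),
            m_mean=np.zeros(r),
            A_mean=np.zeros((1, r)),
            SA_mean=SA_draws.mean(axis=0),
            SR_mean=SR_draws.mean(axis=0),
            SA_draws=SA_draws,
            SR_draws=SR_draws,
            m_draws=np.zeros((k, r)),
            observed=np.ones((1, r), dtype=bool),
        )

    def test_diagonal_draws_give_identity_ra(self):
        SA = np.stack([np.diag([1.0, 2.0]), np.diag([0.5, 3.0])])
        fit = self._fit_from_draws(SA, np.ones((2, 2)))
        np.testing.assert_allclose(genetic_correlations(fit), np.eye(2))

    def test_rank_one_draws_give_unit_correlation(self):
        v = np.array([1.0, -2.0])
        SA = np.stack([np.outer(v, v), 2.0 * np.outer(v, v)])
        fit = self._fit_from_draws(SA, np.ones((2, 2)))
        ra = genetic_correlations(fit)
        np.testing.assert_allclose(np.abs(ra), 1.0)
        assert ra[0, 1] == pytest.approx(-1.0)

    def test_heritability_trivial_cases(self):
        SA = np.stack([np.diag([1.0, 0.0])] * 3)
        SR = np.tile([1.0, 2.0], (3, 1))
        fit = self._fit_from_draws(SA, SR)
        h2 = heritability(fit)
        assert h2[0] == pytest.approx(0.5)
        assert h2[1] == pytest.approx(0.0)

    def test_heritability_averaged_per_draw(self):
        """h2 is the mean of per-draw ratios, not the ratio of means."""
        SA = np.stack([np.diag([1.0]), np.diag([3.0])])
        SR = np.array([[1.0], [1.0]])
        fit = self._fit_from_draws(SA, SR)
        assert heritability(fit)[0] == pytest.approx((0.5 + 0.75) / 2)


class TestPrediction:
    def test_all_missing_line_with_identity_g(self):
        """A fully missing line with no genomic relatives predicts the intercepts."""
        n, r = 80, 2
        rng = np.random.default_rng(51)
        ids = np.array([f"L{i}" for i in range(n)], dtype=object)
        G = Kernel(ids, np.eye(n), "line", "G")
        Y = rng.standard_normal((n, r)) + np.array([4.0, 8.0])
        Y[0, :] = np.nan
        fit = gibbs_fit(Y, G, seed=52, **CHAIN)
        pred = mtm_predict(fit, [(0, 0), (0, 1)])
        np.testing.assert_allclose(pred, fit.m_mean, atol=0.3)

    def test_near_duplicate_line_borrowing(self):
        """A held-out copy of an observed line tracks that line's genetic value."""
        n = 60
        G = _grm(n, seed=61)
        vals = G.values.copy()
        vals[1, :] = vals[0, :]
        vals[:, 1] = vals[:, 0]
        vals[1, 1] = vals[0, 0]
        G = Kernel(G.ids, (vals + vals.T) / 2, "line", "G")
        SA = np.array([[0.9, 0.7], [0.7, 0.9]])
        Y, A = _draw_mtm(G, SA, np.array([0.05, 0.05]), [0.0, 0.0], seed=62)
        Y[1, :] = Y[0, :]  # identical line, identical phenotype
        Yobs = Y.copy()
        Yobs[1, 0] = np.nan  # hold out one cell of the duplicate
        fit = gibbs_fit(Yobs, G, seed=63, **CHAIN)
        pred = mtm_predict(fit, [(1, 0)])[0]
        fitted_obs = fit.m_mean[0] + fit.A_mean[0, 0]
        assert abs(pred - fitted_obs) < 0.35

    def test_observed_cell_rejected(self):
        G = _grm(20, seed=71)
        Y, _ = _draw_mtm(G, np.array([[0.5, 0.1], [0.1, 0.5]]), np.array([0.5, 0.5]),
                         [0.0, 0.0], seed=72)
        fit = gibbs_fit(Y, G, seed=73, iters=300, burnin=100, thin=2)
        with pytest.raises(ValueError, match="observed during fitting"):
            mtm_predict(fit, [(0, 0)])


def test_draws_table_long_format():
    """The draw archive is long-format (iteration, parameter, value)."""
    G = _grm(20, seed=81)
    Y, _ = _draw_mtm(G, np.array([[0.5, 0.1], [0.1, 0.5]]), np.array([0.4, 0.4]),
                     [0.0, 0.0], seed=82)
    fit = gibbs_fit(Y, G, seed=83, iters=200, burnin=100, thin=10, env_ids=["a", "b"])
    tab = fit.draws_table()
    assert set(tab.columns) == {"iteration", "parameter", "value"}
    # per iteration: 2 intercepts + 2 residuals + 3 covariance entries
    assert len(tab) == fit.n_draws * 7
    assert "SA[a,b]" in set(tab.parameter)
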